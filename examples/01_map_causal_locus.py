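"""Map a recessive locus on a simulated pooled cross.

Simulates the default cross (affected sire x two carrier dams, pools of 26
homozygous and 19 heterozygous offspring at ~30x), classifies every marker
for co-segregation, scans the genome in 1 Mb windows and calls the
candidate interval.
"""

from cosegmap import ClassifierParams, CrossConfig, classify_frame
from cosegmap.cross_simulator import simulate_cross
from cosegmap.genome_scan import call_interval, fine_scan, scan

cfg = CrossConfig(seed=1)
truth, pedigree, panel, founders = simulate_cross(cfg)
print(f"simulated {len(truth)} markers on {len(cfg.scaffold_lengths)} scaffolds; "
      f"causal locus at {cfg.scaffold_names[cfg.causal_scaffold]}:{cfg.causal_pos + 1}")

statuses = classify_frame(truth, ClassifierParams())
counts = statuses["status"].value_counts()
print(f"co-segregating sites: {counts.get('coseg', 0)} of "
      f"{counts.get('coseg', 0) + counts.get('non_coseg', 0)} informative")

lengths = dict(zip(cfg.scaffold_names, cfg.scaffold_lengths))
windows = scan(statuses, lengths)  # 1 Mb windows, 100 kb step, SNP/MNP only
interval = call_interval(windows)
print(f"candidate interval: {interval.scaffold}:{interval.start + 1}-{interval.end} "
      f"({interval.length_mb:.2f} Mb, peak proportion {interval.peak_proportion:.2f})")

fine = fine_scan(statuses, interval.scaffold, lengths[interval.scaffold])
peak = max((w for w in fine if w.proportion is not None and w.n_informative >= 5),
           key=lambda w: w.proportion)
print(f"fine-scale peak (200 kb windows, indels included): "
      f"{peak.scaffold}:{peak.start + 1}-{peak.end} at proportion {peak.proportion:.2f}")
print("the interval above should contain the causal position "
      f"({interval.start <= cfg.causal_pos < interval.end})")
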