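"""Shrink a candidate interval with individually genotyped recombinants.

Each genotyped offspring has an expected carrier-allele dose (2 for
affected homozygotes, 1 for carriers).  An individual discordant at some
interval markers and concordant at others carries a crossover; the causal
locus must lie on its concordant side.  Intersecting these constraints
narrows the interval.
"""

from cosegmap.genome_scan import CandidateInterval
from cosegmap.recombinant_refine import (
    IndividualGenotype,
    detect_recombinants,
    refine_interval,
)

# candidate interval from a genome scan: 2.86-14.91 Mb (12.05 Mb)
interval = CandidateInterval("super_scaffold_85", 2_860_000, 14_910_000,
                             peak_proportion=1.0, n_coseg_inside=0)
print(f"starting interval: {interval.length_mb:.2f} Mb")

# two informative recombinants genotyped at three markers each
genotypes = [
    IndividualGenotype("rec_1", "affected_hom",
                       [("super_scaffold_85", 3_000_000, 1),   # discordant
                        ("super_scaffold_85", 13_000_000, 1),  # discordant
                        ("super_scaffold_85", 13_500_000, 2)]),  # concordant
    IndividualGenotype("rec_2", "carrier_het",
                       [("super_scaffold_85", 13_200_000, 1),  # concordant
                        ("super_scaffold_85", 14_900_000, 2)]),  # discordant
]
profiles = detect_recombinants(genotypes, interval)
for p in profiles:
    print(f"  {p.individual_id}: recombinant={p.is_recombinant}, "
          f"breakpoint bounds={p.breakpoints}")

refined = refine_interval(interval, profiles)
print(f"refined interval: {refined.scaffold}:{refined.start + 1}-{refined.end} "
      f"({refined.length_mb:.2f} Mb) using {refined.n_recombinants_used} recombinants")
print("the causal locus must lie where every recombinant's genotype matches "
      "its phenotype; each recombinant trims the discordant side")
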