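# Methods

## The mapping model

The design is a recessive-cross bulked-segregant analysis. A homozygous
affected sire (*m/m*) is mated to heterozygous carrier dams (*m/+*).
Offspring are phenotype-sorted into a homozygous pool (*m/m*) and a
heterozygous pool (*m/+*) and sequenced as pools alongside the parents.

At a biallelic marker the parental configuration decides what the pools can
reveal. If the sire is homozygous for allele *A* and every dam is
heterozygous (*A/B*), each offspring receives *A* paternally and *A* or *B*
maternally — the maternal allele traces the inherited haplotype. Under
perfect linkage to *m*, the dam's *m*-bearing haplotype carries *A*, so the
homozygous pool is fixed for *A* and the heterozygous pool sits at
freq(*A*) = ½. Unlinked informative markers give freq(*A*) = ¾ in both
pools (½·1 + ½·½ maternally, plus the guaranteed paternal *A*). This gap —
(1, ½) versus (¾, ¾) — is what the classifier thresholds:

- `epsilon_fix` (default 0.05): tolerated deviation from fixation in the
  homozygous pool. At 30x, binomial sampling around a true frequency of ¾
  reaches ≥ 0.95 in well under 1% of sites, while a truly fixed site fails
  only through read error.
- `delta_het` (default 0.15): tolerated deviation from ½ in the
  heterozygous pool. The het pool of 19 individuals at 30x has a binomial
  standard deviation of ≈ 0.09 around ½, so a ±0.15 band keeps ~90% of
  truly linked sites per marker; windows aggregate over hundreds of
  markers, so the proportion statistic is insensitive to this per-site loss.
- `min_depth` (default 8 reads): sites below it in any library are set
  aside as `low_depth` rather than classified.

These tolerances are deliberately explicit parameters: the rule itself (and
not any particular threshold) is the method. Pool frequencies are computed
from raw allele depths; no genotype-likelihood model is fitted, matching
the proportion-of-variants statistic the scan consumes. The carrier allele
may be REF or ALT relative to the reference assembly — classification is
symmetric in allele labels. With two dams, both must be heterozygous by
default (`require_all_mothers_het`); a relaxed mode accepts one informative
dam for generality.

## Genome scan and interval call

Windows are anchored at coordinate 0 of each scaffold; the genome scan uses
1 Mb windows stepping 100 kb over scaffolds longer than 1 Mb and counts
SNP/MNP sites only, the fine scan 200 kb / 50 kb on a single scaffold with
indels included. A site belongs to every window containing its start
coordinate — one unambiguous assignment per site regardless of allele
length. Windows with no informative site get an undefined proportion (NA),
never zero: 0/0 is absence of evidence, not evidence against linkage, and
NA windows can never define a peak.

The candidate interval is the union of the maximal contiguous run of
windows, on the scaffold holding the global peak, whose proportion is at
least `frac_of_peak` (default 0.9) of the peak and whose informative count
meets `min_informative` (default 10). Ties on the peak break by larger
co-segregating count, then input order. The run-based rule is a
reconstruction — reported intervals in this design are usually read off the
proportion profile by eye — so both knobs are configuration, not claims.

## Recombinant refinement

Phenotype implies an expected carrier-allele dose (2 for affected
homozygotes, 1 for carriers). A genotyped individual discordant at some
interval markers and concordant at others is a recombinant; its crossover
lies between the nearest discordant/concordant marker pair, and the causal
locus must sit on the concordant side. The refined interval is the
intersection of these one-sided constraints. Three conservative choices:
the *outer* (discordant-marker) bound is used, so marker sparsity can never
exclude the causal locus; missing genotypes are skipped, not imputed;
discordant markers sandwiched between concordant ones (double crossover or
genotyping error) never trim, and an individual discordant at *every*
marker only trims under an explicit `trust_single` flag. An empty
intersection raises an error naming the conflicting individuals — with
error-free genotypes it is impossible, so it flags genotyping error or a
wrong interval.

## Splice-consequence model

The donor site is the first two intronic nucleotides after an exon
(canonically GT), the acceptor the last two. A variant overlapping a
donor/acceptor window is a splice variant only when the ALT allele actually
changes the spliced dinucleotide; any exonic sub-effect is retained as a
secondary annotation. Category precedence for multi-effect variants:
splice_donor/acceptor > nonsense > frameshift > missense > in-frame indel >
synonymous, so one variant-transcript pair always gets exactly one category.

A disrupted donor generates (a) the exon-skip transcript dropping the exon
immediately upstream, and (b) one intron-retention transcript per cryptic
GT dinucleotide within the first `max_scan` bp (default 2000) of the
intron, retaining the prefix before it. Cryptic donors are bare GT
dinucleotides — no splice-strength scoring — because this is the minimal
generative rule that produces the observed isoform classes; it will
over-enumerate relative to real spliceosome choice, which is why the output
is a candidate list, not a prediction of isoform abundance.

Translation starts at the reference start codon, uses the standard genetic
code (no selenocysteine), and runs to the first stop or transcript end
(flagged as runoff). *Truncation* is defined structurally: the stop used is
not the reference stop codon mapped into the aberrant transcript. An
in-frame exon skip that rejoins the reference frame and terminus is an
internal deletion, not a truncation. Domain loss is coordinate arithmetic
on a user-supplied domain table: a domain is lost when it starts beyond the
aberrant protein's end, partial when the end cuts through it.

The bundled domain table (`data/pmel_domains.tsv`) is the premelanosome
protein (PMEL) map used in the worked examples: signal peptide 1–20, core
amyloid fragment 152–227, PKD domain 238–299, repeat domain 306–510,
convertase cleavage site 506–511, Kringle-like domain 559–609,
transmembrane helix 638–660, cytoplasmic domain 661–713, on a 713-aa
protein. Any truncation shorter than residue 559 therefore loses the
Kringle-like domain, the transmembrane helix and the cytoplasmic tail —
the membrane-integrated Mβ portion.

## The synthetic-data generator

`cross_simulator` emulates the mapping cross end to end. Defaults are the
study conditions the package targets: one 20 Mb causal scaffold (causal
MNP, ACG→TCC, at position 13,272,041) plus four decoy scaffolds of 12, 8,
4 and 2 Mb; ~1 marker/kb (85% SNP, 10% MNP, 5% indel); 26 homozygous and 19
heterozygous offspring from two equally contributing dams; mean depth 30x;
per-read error 0.1%; recombination at 1 cM/Mb (1e-8 Morgans/bp).

Founders are phased: the sire carries the causal allele on both haplotypes,
each dam on exactly one. A configurable fraction of markers (default 0.3)
is informative; within the linkage radius (default: the whole causal
scaffold, i.e. chromosome-wide phasing) the dams' causal haplotype carries
the sire's allele, elsewhere phase is random. Decay of co-segregation with
distance therefore emerges from simulated recombination, not from the
radius. Crossovers follow the Haldane model — Poisson counts with uniform
positions and no interference — the simplest standard model; nothing in
the target design constrains interference. Offspring are generated until
the phenotype quotas are reached, matching fixed pool sizes rather than
binomial litters.

Pools are sampled at read level: per site and library, depth is
Poisson(mean), read alleles are drawn from the pool's true allele frequency
and miscalled with the error rate, so the classifier's tolerances face
realistic noise. A direct-frequency mode (`exact_depth`) emits rounded
expected counts instead, giving the infinite-depth limit used by the
sharpest invariant tests. The emitted VCF is formatted by the simulator
itself so byte-identical reproduction from a seed is guaranteed; reading it
back through cyvcf2 doubles as an independent round-trip check.

What the simulator does *not* model: linkage disequilibrium structure in
the founders, mapping and alignment artefacts, repeat-driven depth
inhomogeneity, allele-specific capture bias, or genotyping error in the
refinement table. Passing tests demonstrate the statistical machinery under
Mendelian inheritance with sequencing noise; they do not certify robustness
to alignment artefacts, which the repeat-mask input is meant to mitigate on
real data.

## Numerical and interface choices

- Internal coordinates are 0-based half-open everywhere; VCF/GFF3 I/O is
  1-based inclusive, BED 0-based half-open. MNPs are single sites keyed by
  their start coordinate.
- Pool libraries are read from allele-depth fields (AD, or Platypus-style
  NR/NV), never from pooled GT calls, which are meaningless for pools;
  individual libraries use GT with depth as a quality gate.
- `classify_site` is the per-site contract; `classify_frame` is a
  vectorised equivalent used by the multi-seed experiments, with a test
  asserting exact agreement.
- Window tiling: starts at multiples of the step up to the smallest start
  whose window reaches the scaffold end (the last window is clipped).
- The interval's internal co-segregating count uses a greedy disjoint
  subcover of the overlapping window run, so overlapping windows do not
  double-count sites.
- Replicate Ct values aggregate by arithmetic mean (geometric in linear
  space); amplification efficiency is exactly 2 unless a measured
  efficiency is supplied (E^−ΔΔCt). Replicate scatter propagates as
  sqrt(s_target² + s_reference²) on the Ct scale.

## Problem sizes used by the bundled experiments

The recovery and background experiments run 100 independent crosses at the
default configuration (~46,000 markers each); the refinement experiment
runs 100 single-scaffold crosses (6 Mb, 1 marker per 4 kb) with an
exaggerated recombination rate (2e-7 Morgans/bp) so that recombinants are
plentiful inside a 2.4 Mb interval. These sizes keep the full suite and the
acceptance script each under a minute on one CPU while leaving the binomial
tolerances meaningfully exercised.

## Known limitations

- The classifier has no significance test or smoothing; the scan consumes
  raw proportions by design.
- Cryptic-donor enumeration ignores splice-site strength and branch-point
  context; acceptor-side cryptic splicing is not enumerated.
- Refinement assumes correct phenotype labels; a mislabelled individual
  surfaces as an inconsistent-recombinant error rather than being detected.
- The qPCR statistics stop at ratio and propagated scatter; group
  comparisons are out of scope.
- No alignment, variant calling, or read counting: VCF, genotype tables
  and count tables are the input boundaries.
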