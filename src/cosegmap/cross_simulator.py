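"""Synthetic mapping cross: founders, offspring, pooled sequencing, VCF.

Emulates the mapping design the package targets: a homozygous affected sire
(carrying the causal recessive allele on both haplotypes) crossed to carrier
dams, offspring phenotype-sorted into a homozygous pool (default 26) and a
heterozygous pool (default 19), all libraries sequenced to ~30x.  Crossovers
follow the Haldane model (Poisson counts, uniform positions, no
interference).  Pools are modelled at read level: per-site depths are
Poisson, read alleles are drawn from the pool's true allele frequency and
miscalled with a per-read error rate, so downstream tolerances are
exercised against realistic noise.

The generator returns a ground-truth table alongside the emitted VCF so
every downstream stage can be checked against what was simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "CrossConfig",
    "MarkerPanel",
    "FounderHaplotypes",
    "Pedigree",
    "simulate_panel",
    "simulate_offspring",
    "build_truth_table",
    "sample_depths",
    "emit_vcf",
    "simulate_pools_and_emit",
    "simulate_cross",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CrossConfig:
    """Full parameterisation of the synthetic cross.

    Defaults mirror the mapping design: pools of 26 homozygous and 19
    heterozygous offspring from one affected sire and two carrier dams,
    ~30 reads/site, about one marker per kb, and a causal locus embedded
    at 13,272,041 bp of a 20 Mb scaffold among four decoy scaffolds.
    ``recomb_rate`` is in Morgans per bp (1e-8 = 1 cM/Mb).
    ``linked_radius`` bounds the region around the causal position whose
    informative markers are phase-linked to the causal allele in the dams;
    ``None`` means the whole causal scaffold (chromosome-wide phasing).
    """

    scaffold_lengths: Tuple[int, ...] = (
        20_000_000,
        12_000_000,
        8_000_000,
        4_000_000,
        2_000_000,
    )
    variant_density: float = 1.0 / 1000.0
    causal_scaffold: int = 0
    causal_pos: int = 13_272_041
    n_homo_offspring: int = 26
    n_het_offspring: int = 19
    n_mothers: int = 2
    mother_contributions: Optional[Tuple[float, ...]] = None
    depth_mean: float = 30.0
    error_rate: float = 0.001
    recomb_rate: float = 1e-8
    informative_fraction: float = 0.3
    linked_radius: Optional[int] = None
    snp_fraction: float = 0.85
    mnp_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.scaffold_lengths or any(l <= 0 for l in self.scaffold_lengths):
            raise ConfigurationError("scaffold_lengths must be positive")
        if not (0 <= self.causal_scaffold < len(self.scaffold_lengths)):
            raise ConfigurationError("causal_scaffold index out of range")
        if not (0 <= self.causal_pos < self.scaffold_lengths[self.causal_scaffold]):
            raise ConfigurationError("causal_pos must lie on the causal scaffold")
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be > 0")
        if not (0 <= self.error_rate < 0.5):
            raise ConfigurationError("error_rate must be in [0, 0.5)")
        if min(self.n_homo_offspring, self.n_het_offspring, self.n_mothers) <= 0:
            raise ConfigurationError("offspring and mother counts must be > 0")
        if self.variant_density < 0 or self.recomb_rate < 0:
            raise ConfigurationError("rates must be >= 0")
        if not (0 <= self.informative_fraction <= 1):
            raise ConfigurationError("informative_fraction must be in [0, 1]")
        if self.mother_contributions is not None and (
            len(self.mother_contributions) != self.n_mothers
            or abs(sum(self.mother_contributions) - 1.0) > 1e-9
        ):
            raise ConfigurationError("mother_contributions must sum to 1 over n_mothers")

    @property
    def scaffold_names(self) -> List[str]:
        return [f"scaffold_{i + 1}" for i in range(len(self.scaffold_lengths))]

    @property
    def contributions(self) -> np.ndarray:
        if self.mother_contributions is None:
            return np.full(self.n_mothers, 1.0 / self.n_mothers)
        return np.asarray(self.mother_contributions)


@dataclass
class MarkerPanel:
    """Marker positions and alleles, sorted by (scaffold index, position)."""

    scaffold_idx: np.ndarray  # int, index into config.scaffold_lengths
    pos: np.ndarray  # 0-based bp
    ref: np.ndarray  # allele strings
    alt: np.ndarray
    vclass: np.ndarray  # SNP / MNP / indel
    causal_index: int  # row of the causal marker

    @property
    def n(self) -> int:
        return len(self.pos)

    def scaffold_rows(self, idx: int) -> np.ndarray:
        return np.flatnonzero(self.scaffold_idx == idx)


@dataclass
class FounderHaplotypes:
    """Phased founder alleles over the marker panel (codes 0=REF, 1=ALT).

    The sire carries the causal allele on both haplotypes; each dam carries
    it on haplotype 0 (by convention).
    """

    father: np.ndarray  # (2, M)
    mothers: np.ndarray  # (n_mothers, 2, M)


@dataclass
class Pedigree:
    """Diploid offspring with phenotype labels and true crossover positions."""

    phenotype: np.ndarray  # 'affected_hom' / 'carrier_het'
    pat_alleles: np.ndarray  # (n, M)
    mat_alleles: np.ndarray  # (n, M)
    mother_idx: np.ndarray  # (n,)
    # crossovers[i] maps (parent, scaffold_idx) -> sorted bp positions
    crossovers: List[Dict[Tuple[str, int], np.ndarray]] = field(default_factory=list)


def _allele_pairs(vclass: np.ndarray, rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised REF/ALT strings per variant class (first base always differs)."""
    M = len(vclass)
    ref_i = rng.integers(0, 4, M)
    b_ref = _BASES[ref_i]
    b_alt = _BASES[(ref_i + rng.integers(1, 4, M)) % 4]
    x2 = _BASES[rng.integers(0, 4, M)]
    x3 = _BASES[rng.integers(0, 4, M)]
    ref = b_ref.astype(object)
    alt = b_alt.astype(object)
    mnp = vclass == "MNP"
    tail = np.char.add(x2, x3)
    ref[mnp] = np.char.add(b_ref, tail).astype(object)[mnp]
    alt[mnp] = np.char.add(b_alt, tail).astype(object)[mnp]
    indel = vclass == "indel"
    ins = np.char.add(b_ref, x2).astype(object)
    deletion = indel & (rng.random(M) < 0.5)
    insertion = indel & ~deletion
    ref[deletion] = ins[deletion]
    alt[deletion] = b_ref.astype(object)[deletion]
    alt[insertion] = ins[insertion]
    return ref, alt


def simulate_panel(
    config: CrossConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[MarkerPanel, FounderHaplotypes]:
    """Draw the marker panel and phased founder haplotypes.

    Marker counts per scaffold are Poisson(density x length) with uniform
    positions; a fixed fraction of sites is informative (sire homozygous,
    dams heterozygous).  Informative markers within ``linked_radius`` of the
    causal position have the sire's allele on every dam's causal-carrying
    haplotype; elsewhere the phase is random.  The causal site itself is
    always present, as an MNP (ACG->TCC) at ``causal_pos``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    scaff_idx: List[np.ndarray] = []
    positions: List[np.ndarray] = []
    for i, length in enumerate(config.scaffold_lengths):
        n = rng.poisson(config.variant_density * length)
        pos = np.unique(rng.integers(0, length, size=n))
        if i == config.causal_scaffold:
            pos = pos[pos != config.causal_pos]
        positions.append(pos)
        scaff_idx.append(np.full(len(pos), i))
    # insert the causal marker
    ci = config.causal_scaffold
    positions[ci] = np.sort(np.append(positions[ci], config.causal_pos))
    scaff_idx[ci] = np.full(len(positions[ci]), ci)
    if len(positions[ci]) == 0:
        raise ConfigurationError("no markers on the causal scaffold")

    scaffold_idx = np.concatenate(scaff_idx)
    pos = np.concatenate(positions)
    order = np.lexsort((pos, scaffold_idx))
    scaffold_idx, pos = scaffold_idx[order], pos[order]
    M = len(pos)
    causal_index = int(
        np.flatnonzero((scaffold_idx == ci) & (pos == config.causal_pos))[0]
    )

    u = rng.random(M)
    vclass = np.where(
        u < config.snp_fraction,
        "SNP",
        np.where(u < config.snp_fraction + config.mnp_fraction, "MNP", "indel"),
    ).astype(object)
    vclass[causal_index] = "MNP"
    ref, alt = _allele_pairs(vclass, rng)
    ref[causal_index], alt[causal_index] = "ACG", "TCC"

    informative = rng.random(M) < config.informative_fraction
    informative[causal_index] = True
    carrier = rng.integers(0, 2, M)
    carrier[causal_index] = 1  # causal allele is the ALT of its record

    radius = config.linked_radius
    if radius is None:
        linked_zone = scaffold_idx == ci
    else:
        linked_zone = (scaffold_idx == ci) & (
            np.abs(pos - config.causal_pos) <= radius
        )

    father = np.empty((2, M), dtype=np.int8)
    mothers = np.empty((config.n_mothers, 2, M), dtype=np.int8)

    # informative sites: sire homozygous for the carrier allele, dams het
    inf = informative
    father[0, inf] = carrier[inf]
    father[1, inf] = carrier[inf]
    for m in range(config.n_mothers):
        # haplotype 0 carries the causal allele; in the linked zone it also
        # carries the sire's marker allele, elsewhere the phase is random
        phase_linked = linked_zone[inf] | (rng.random(inf.sum()) < 0.5)
        hap0 = np.where(phase_linked, carrier[inf], 1 - carrier[inf])
        mothers[m, 0, inf] = hap0
        mothers[m, 1, inf] = 1 - hap0

    # non-informative sites: mix of configurations the classifier must reject
    # (0: sire het; 1: sire hom + all dams hom; 2: sire hom + only first dam het)
    nonidx = np.flatnonzero(~informative)
    nb = len(nonidx)
    branch = rng.integers(0, 3 if config.n_mothers > 1 else 2, nb)
    a = rng.integers(0, 2, nb)
    o = rng.integers(0, 2, nb)
    father[0, nonidx] = np.where(branch == 0, o, a)
    father[1, nonidx] = np.where(branch == 0, 1 - o, a)
    for m in range(config.n_mothers):
        r0 = rng.integers(0, 2, nb)
        r1 = rng.integers(0, 2, nb)
        hom = rng.integers(0, 2, nb)
        if m == 0:
            h0 = rng.integers(0, 2, nb)
            m0 = np.select([branch == 0, branch == 1], [r0, hom], default=h0)
            m1 = np.select([branch == 0, branch == 1], [r1, hom], default=1 - h0)
        else:
            m0 = np.where(branch == 0, r0, hom)
            m1 = np.where(branch == 0, r1, hom)
        mothers[m, 0, nonidx] = m0
        mothers[m, 1, nonidx] = m1

    panel = MarkerPanel(scaffold_idx, pos, ref, alt, vclass, causal_index)
    return panel, FounderHaplotypes(father, mothers)


def _gamete(
    haps: np.ndarray,
    panel: MarkerPanel,
    config: CrossConfig,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, int, Dict[int, np.ndarray]]:
    """One recombinant gamete: alleles, haplotype index at the causal locus,
    and crossover positions per scaffold (Haldane model)."""
    alleles = np.empty(panel.n, dtype=np.int8)
    causal_hap = 0
    breakpoints: Dict[int, np.ndarray] = {}
    for s, length in enumerate(config.scaffold_lengths):
        rows = panel.scaffold_rows(s)
        start = int(rng.integers(0, 2))
        k = rng.poisson(config.recomb_rate * length)
        bks = np.sort(rng.integers(0, length, size=k)) if k else np.empty(0, dtype=int)
        breakpoints[s] = bks
        if len(rows):
            h = (start + np.searchsorted(bks, panel.pos[rows], side="right")) % 2
            alleles[rows] = haps[h, rows]
        if s == config.causal_scaffold:
            causal_hap = int(
                (start + np.searchsorted(bks, config.causal_pos, side="right")) % 2
            )
    return alleles, causal_hap, breakpoints


def simulate_offspring(
    founders: FounderHaplotypes,
    panel: MarkerPanel,
    config: CrossConfig,
    rng: Optional[np.random.Generator] = None,
) -> Pedigree:
    """Generate offspring until the configured phenotype quotas are filled.

    Phenotype is read off the causal locus: the sire always transmits the
    causal allele, so the offspring is affected (homozygous) iff its
    maternal gamete carries the dam's causal haplotype there.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    want = {"affected_hom": config.n_homo_offspring, "carrier_het": config.n_het_offspring}
    have = {"affected_hom": 0, "carrier_het": 0}
    phenos: List[str] = []
    pats: List[np.ndarray] = []
    mats: List[np.ndarray] = []
    midx: List[int] = []
    xovers: List[Dict[Tuple[str, int], np.ndarray]] = []
    contributions = config.contributions
    while have != want:
        m = int(rng.choice(config.n_mothers, p=contributions))
        pat, _, pat_bks = _gamete(founders.father, panel, config, rng)
        mat, causal_hap, mat_bks = _gamete(founders.mothers[m], panel, config, rng)
        phenotype = "affected_hom" if causal_hap == 0 else "carrier_het"
        if have[phenotype] >= want[phenotype]:
            continue
        have[phenotype] += 1
        phenos.append(phenotype)
        pats.append(pat)
        mats.append(mat)
        midx.append(m)
        xovers.append(
            {("pat", s): bks for s, bks in pat_bks.items()}
            | {("mat", s): bks for s, bks in mat_bks.items()}
        )
    return Pedigree(
        phenotype=np.array(phenos, dtype=object),
        pat_alleles=np.vstack(pats),
        mat_alleles=np.vstack(mats),
        mother_idx=np.array(midx),
        crossovers=xovers,
    )


def build_truth_table(
    panel: MarkerPanel, founders: FounderHaplotypes, pedigree: Pedigree, config: CrossConfig
) -> pd.DataFrame:
    """Ground truth per marker: founder genotypes, phase, true pool frequencies."""
    names = config.scaffold_names
    homo = pedigree.phenotype == "affected_hom"
    het = ~homo
    dose = pedigree.pat_alleles.astype(np.int32) + pedigree.mat_alleles
    homo_freq = dose[homo].sum(axis=0) / (2.0 * homo.sum())
    het_freq = dose[het].sum(axis=0) / (2.0 * het.sum())

    father_sorted = np.sort(founders.father, axis=0)
    informative = (founders.father[0] == founders.father[1]) & np.all(
        founders.mothers[:, 0, :] != founders.mothers[:, 1, :], axis=0
    )
    carrier = founders.father[0]
    linked = (
        informative
        & (panel.scaffold_idx == config.causal_scaffold)
        & np.all(founders.mothers[:, 0, :] == carrier[None, :], axis=0)
    )

    data = {
        "scaffold": np.array(names, dtype=object)[panel.scaffold_idx],
        "pos": panel.pos,
        "ref": panel.ref,
        "alt": panel.alt,
        "vclass": panel.vclass,
        "father_a1": father_sorted[0],
        "father_a2": father_sorted[1],
        "informative": informative,
        "carrier_allele": np.where(
            informative, np.where(carrier == 1, "alt", "ref"), "none"
        ),
        "linked": linked,
        "true_homo_alt_freq": homo_freq,
        "true_het_alt_freq": het_freq,
    }
    for m in range(config.n_mothers):
        ms = np.sort(founders.mothers[m], axis=0)
        data[f"mother{m + 1}_a1"] = ms[0]
        data[f"mother{m + 1}_a2"] = ms[1]
    return pd.DataFrame(data)


def sample_depths(
    truth: pd.DataFrame,
    config: CrossConfig,
    rng: Optional[np.random.Generator] = None,
    exact_depth: Optional[int] = None,
) -> pd.DataFrame:
    """Add observed read depths per library to the truth table.

    Depths are Poisson(depth_mean); read alleles follow the true allele
    frequency of each library, miscalled with ``error_rate``.  With
    ``exact_depth`` set, depths are fixed and allele counts are rounded
    expectations (the infinite-depth, direct-frequency emission mode).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    out = truth.copy()
    M = len(out)
    e = config.error_rate

    def observe(true_freq: np.ndarray, prefix: str) -> None:
        p = true_freq * (1 - e) + (1 - true_freq) * e
        if exact_depth is not None:
            dp = np.full(M, exact_depth)
            alt = np.rint(p * dp).astype(int)
        else:
            dp = rng.poisson(config.depth_mean, size=M)
            alt = rng.binomial(dp, p)
        out[f"{prefix}_ref"] = dp - alt
        out[f"{prefix}_alt"] = alt
        out[f"{prefix}_dp"] = dp

    observe(out["true_homo_alt_freq"].to_numpy(), "homo")
    observe(out["true_het_alt_freq"].to_numpy(), "het")
    observe((out["father_a1"].to_numpy() + out["father_a2"].to_numpy()) / 2.0, "father")
    for m in range(1, config.n_mothers + 1):
        observe(
            (out[f"mother{m}_a1"].to_numpy() + out[f"mother{m}_a2"].to_numpy()) / 2.0,
            f"mother{m}",
        )
    return out


def emit_vcf(truth: pd.DataFrame, config: CrossConfig, path: str | Path) -> Path:
    """Write the simulated libraries as a plain-text VCF 4.2 (GT:AD:DP).

    Pools are emitted with missing genotypes and allele depths only;
    parents carry their true diploid genotypes plus sampled depths.  The
    writer formats records itself so identical inputs produce byte-identical
    files.
    """
    path = Path(path)
    samples = (
        ["FATHER"]
        + [f"MOTHER{m}" for m in range(1, config.n_mothers + 1)]
        + ["POOL_HOMO", "POOL_HET"]
    )
    lines = ["##fileformat=VCFv4.2", "##source=cosegmap-cross-simulator"]
    for name, length in zip(config.scaffold_names, config.scaffold_lengths):
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    cols = truth.to_dict("records")
    for row in cols:
        fields = [
            row["scaffold"],
            str(int(row["pos"]) + 1),
            ".",
            row["ref"],
            row["alt"],
            ".",
            "PASS",
            ".",
            "GT:AD:DP",
        ]
        father = (
            f"{row['father_a1']}/{row['father_a2']}:"
            f"{row['father_ref']},{row['father_alt']}:{row['father_dp']}"
        )
        fields.append(father)
        for m in range(1, config.n_mothers + 1):
            fields.append(
                f"{row[f'mother{m}_a1']}/{row[f'mother{m}_a2']}:"
                f"{row[f'mother{m}_ref']},{row[f'mother{m}_alt']}:{row[f'mother{m}_dp']}"
            )
        fields.append(f"./.:{row['homo_ref']},{row['homo_alt']}:{row['homo_dp']}")
        fields.append(f"./.:{row['het_ref']},{row['het_alt']}:{row['het_dp']}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


def simulate_pools_and_emit(
    pedigree: Pedigree,
    founders: FounderHaplotypes,
    panel: MarkerPanel,
    config: CrossConfig,
    out_vcf: Optional[str | Path] = None,
    rng: Optional[np.random.Generator] = None,
    exact_depth: Optional[int] = None,
) -> Tuple[pd.DataFrame, Optional[Path]]:
    """Sample library depths and optionally emit the VCF; returns the truth table."""
    truth = build_truth_table(panel, founders, pedigree, config)
    truth = sample_depths(truth, config, rng=rng, exact_depth=exact_depth)
    vcf_path = emit_vcf(truth, config, out_vcf) if out_vcf is not None else None
    return truth, vcf_path


def simulate_cross(
    config: CrossConfig,
    out_vcf: Optional[str | Path] = None,
    exact_depth: Optional[int] = None,
) -> Tuple[pd.DataFrame, Pedigree, MarkerPanel, FounderHaplotypes]:
    """End-to-end convenience wrapper: panel -> offspring -> pooled depths.

    All randomness derives from ``config.seed``; equal configs give
    byte-identical VCFs.
    """
    rng = np.random.default_rng(config.seed)
    panel, founders = simulate_panel(config, rng)
    pedigree = simulate_offspring(founders, panel, config, rng)
    truth, _ = simulate_pools_and_emit(
        pedigree, founders, panel, config, out_vcf=out_vcf, rng=rng,
        exact_depth=exact_depth,
    )
    return truth, pedigree, panel, founders
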