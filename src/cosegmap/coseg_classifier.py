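"""Co-segregation classification of biallelic sites under a recessive cross.

The cross design is a homozygous affected sire (two copies of the causal
allele) mated to heterozygous carrier dams, with offspring sequenced as two
phenotype-sorted pools: a homozygous-phenotype pool and a heterozygous-
phenotype pool.  A biallelic site is *informative* when the sire is
homozygous for some allele A and every dam is heterozygous: the maternally
transmitted allele then distinguishes the two inherited haplotypes.  At an
informative site perfectly linked to the causal locus, the homozygous pool
is fixed for A and the heterozygous pool sits at allele frequency 1/2; at an
unlinked informative site both pools are expected near 3/4 (every offspring
receives A from the sire, and A or the alternative with equal probability
from its dam).

``classify_site`` implements the per-site rule on a :class:`VariantSite`;
``classify_frame`` is an equivalent vectorised path over a pandas frame used
by the simulation experiments, and ``classify_table`` streams sites while
accumulating per-scaffold summary counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "VariantSite",
    "ClassifierParams",
    "SiteStatus",
    "ClassifySummary",
    "classify_site",
    "classify_table",
    "classify_frame",
    "variant_class",
]

# status labels
UNINFORMATIVE = "uninformative"
COSEG = "coseg"
NON_COSEG = "non_coseg"
LOW_DEPTH = "low_depth"

Genotype = Tuple[int, int]  # allele codes, 0 = REF, 1 = ALT


def variant_class(ref: str, alt: str) -> str:
    """SNP / MNP / indel from the allele strings of a biallelic record."""
    if len(ref) == len(alt):
        return "SNP" if len(ref) == 1 else "MNP"
    return "indel"


@dataclass
class VariantSite:
    """One biallelic record with per-library calls and pooled depths.

    Positions are 0-based internally. ``father_gt``/``mother_gts`` hold
    diploid genotypes over allele codes {0: REF, 1: ALT}, or ``None`` when
    the call is missing.  Pool entries are ``(ref_depth, alt_depth)`` read
    depths, or ``None`` when the VCF record carried no usable depth field.
    Parent depths are optional quality gates.
    """

    scaffold: str
    pos: int
    ref: str
    alt: str
    father_gt: Optional[Genotype]
    mother_gts: Sequence[Optional[Genotype]]
    homo_pool: Optional[Tuple[int, int]]
    het_pool: Optional[Tuple[int, int]]
    vclass: str = ""
    father_depth: Optional[int] = None
    mother_depths: Optional[Sequence[Optional[int]]] = None

    def __post_init__(self) -> None:
        if not self.vclass:
            self.vclass = variant_class(self.ref, self.alt)


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the co-segregation rule.

    min_depth
        Minimum read depth required in every library; below it the site is
        set aside as ``low_depth`` rather than classified.
    epsilon_fix
        Maximum tolerated deviation from fixation of the carrier allele in
        the homozygous pool.
    delta_het
        Maximum tolerated deviation from 1/2 of the carrier-allele frequency
        in the heterozygous pool.
    require_all_mothers_het
        With several dams, demand heterozygosity of all of them (the strict
        reading of the cross design); when False one heterozygous dam
        suffices and dams homozygous for the sire allele are tolerated.
    """

    min_depth: int = 8
    epsilon_fix: float = 0.05
    delta_het: float = 0.15
    require_all_mothers_het: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.epsilon_fix < 0.5):
            raise ValueError("epsilon_fix must be in [0, 0.5)")
        if not (0 < self.delta_het < 0.5):
            raise ValueError("delta_het must be in (0, 0.5)")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass
class SiteStatus:
    """Classification verdict for one site.

    ``carrier_allele`` is the allele code carried homozygously by the sire
    ('ref'/'alt'), set only for informative sites.  ``homo_freq``/
    ``het_freq`` are carrier-allele frequencies for informative sites and
    plain ALT-allele frequencies otherwise (``None`` when depth is absent).
    """

    scaffold: str
    pos: int
    vclass: str
    status: str
    carrier_allele: str = "none"
    homo_freq: Optional[float] = None
    het_freq: Optional[float] = None
    flags: Tuple[str, ...] = ()

    @property
    def informative(self) -> bool:
        return self.status in (COSEG, NON_COSEG)


def _pool_freq(pool: Optional[Tuple[int, int]], allele: int) -> Optional[float]:
    if pool is None:
        return None
    ref_d, alt_d = pool
    total = ref_d + alt_d
    if total == 0:
        return None
    return (alt_d if allele == 1 else ref_d) / total


def classify_site(site: VariantSite, params: ClassifierParams) -> SiteStatus:
    """Classify one biallelic site.

    Order of precedence: missing/low depth in any library -> ``low_depth``;
    missing parental genotype -> ``uninformative`` flagged ``missing-parent``;
    non-informative parental configuration -> ``uninformative``; otherwise
    the pooled carrier-allele frequencies decide ``coseg`` vs ``non_coseg``.
    """
    base = dict(scaffold=site.scaffold, pos=site.pos, vclass=site.vclass)

    depths = []
    for pool in (site.homo_pool, site.het_pool):
        depths.append(None if pool is None else pool[0] + pool[1])
    if site.father_depth is not None:
        depths.append(site.father_depth)
    if site.mother_depths is not None:
        depths.extend(site.mother_depths)
    if any(d is None for d in depths):
        return SiteStatus(status=LOW_DEPTH, flags=("no-depth",), **base)
    if any(d < params.min_depth for d in depths):
        return SiteStatus(status=LOW_DEPTH, **base)

    if site.father_gt is None or any(g is None for g in site.mother_gts):
        return SiteStatus(
            status=UNINFORMATIVE,
            flags=("missing-parent",),
            homo_freq=_pool_freq(site.homo_pool, 1),
            het_freq=_pool_freq(site.het_pool, 1),
            **base,
        )

    fa, fb = site.father_gt
    father_hom = fa == fb
    carrier = fa if father_hom else None

    mothers_het = [gt[0] != gt[1] for gt in site.mother_gts]
    if params.require_all_mothers_het:
        mothers_ok = all(mothers_het) and len(mothers_het) > 0
    else:
        mothers_ok = any(mothers_het)

    if not (father_hom and mothers_ok):
        return SiteStatus(
            status=UNINFORMATIVE,
            homo_freq=_pool_freq(site.homo_pool, 1),
            het_freq=_pool_freq(site.het_pool, 1),
            **base,
        )

    homo_f = _pool_freq(site.homo_pool, carrier)
    het_f = _pool_freq(site.het_pool, carrier)
    if homo_f is None or het_f is None:  # zero depth with min_depth == 0
        return SiteStatus(status=LOW_DEPTH, flags=("no-depth",), **base)
    is_coseg = (
        homo_f >= 1.0 - params.epsilon_fix
        and abs(het_f - 0.5) <= params.delta_het
    )
    return SiteStatus(
        status=COSEG if is_coseg else NON_COSEG,
        carrier_allele="alt" if carrier == 1 else "ref",
        homo_freq=homo_f,
        het_freq=het_f,
        **base,
    )


@dataclass
class ClassifySummary:
    """Additive per-scaffold counts of classified sites."""

    informative: Counter = field(default_factory=Counter)
    coseg: Counter = field(default_factory=Counter)
    total: Counter = field(default_factory=Counter)
    by_status: Counter = field(default_factory=Counter)

    def add(self, status: SiteStatus) -> None:
        self.total[status.scaffold] += 1
        self.by_status[status.status] += 1
        if status.informative:
            self.informative[status.scaffold] += 1
        if status.status == COSEG:
            self.coseg[status.scaffold] += 1

    def __add__(self, other: "ClassifySummary") -> "ClassifySummary":
        out = ClassifySummary()
        for name in ("informative", "coseg", "total", "by_status"):
            getattr(out, name).update(getattr(self, name))
            getattr(out, name).update(getattr(other, name))
        return out


def classify_table(
    sites: Iterable[VariantSite],
    params: ClassifierParams,
    summary: Optional[ClassifySummary] = None,
) -> Tuple[list, ClassifySummary]:
    """Classify a stream of sites, accumulating additive summary counts."""
    if summary is None:
        summary = ClassifySummary()
    statuses = []
    for site in sites:
        status = classify_site(site, params)
        summary.add(status)
        statuses.append(status)
    return statuses, summary


def iter_classify(
    sites: Iterable[VariantSite], params: ClassifierParams, summary: ClassifySummary
) -> Iterator[SiteStatus]:
    """Streaming variant of :func:`classify_table`."""
    for site in sites:
        status = classify_site(site, params)
        summary.add(status)
        yield status


def classify_frame(frame: pd.DataFrame, params: ClassifierParams) -> pd.DataFrame:
    """Vectorised classification over a site table.

    Expects columns ``scaffold, pos, vclass, father_a1, father_a2,
    mother{i}_a1, mother{i}_a2`` (i = 1..k), ``homo_ref, homo_alt, het_ref,
    het_alt`` and optionally ``father_dp, mother{i}_dp``.  Returns a frame
    with ``status, carrier_allele, homo_freq, het_freq`` columns appended.
    Agrees exactly with :func:`classify_site` applied row-wise.
    """
    n = len(frame)
    k = 1
    while f"mother{k}_a1" in frame.columns:
        k += 1
    n_mothers = k - 1
    if n_mothers == 0:
        raise ValueError("frame has no mother{i}_a1 columns")

    homo_ref = frame["homo_ref"].to_numpy(float)
    homo_alt = frame["homo_alt"].to_numpy(float)
    het_ref = frame["het_ref"].to_numpy(float)
    het_alt = frame["het_alt"].to_numpy(float)
    homo_dp = homo_ref + homo_alt
    het_dp = het_ref + het_alt

    low = (homo_dp < params.min_depth) | (het_dp < params.min_depth)
    if "father_dp" in frame.columns:
        low |= frame["father_dp"].to_numpy(float) < params.min_depth
    for i in range(1, n_mothers + 1):
        col = f"mother{i}_dp"
        if col in frame.columns:
            low |= frame[col].to_numpy(float) < params.min_depth

    fa = frame["father_a1"].to_numpy(int)
    fb = frame["father_a2"].to_numpy(int)
    father_hom = fa == fb

    het_flags = np.ones((n_mothers, n), dtype=bool)
    for i in range(1, n_mothers + 1):
        het_flags[i - 1] = (
            frame[f"mother{i}_a1"].to_numpy(int) != frame[f"mother{i}_a2"].to_numpy(int)
        )
    mothers_ok = het_flags.all(axis=0) if params.require_all_mothers_het else het_flags.any(axis=0)

    informative = father_hom & mothers_ok & ~low
    carrier_is_alt = fa == 1

    with np.errstate(invalid="ignore", divide="ignore"):
        homo_alt_f = np.where(homo_dp > 0, homo_alt / homo_dp, np.nan)
        het_alt_f = np.where(het_dp > 0, het_alt / het_dp, np.nan)
    homo_carrier = np.where(carrier_is_alt, homo_alt_f, 1.0 - homo_alt_f)
    het_carrier = np.where(carrier_is_alt, het_alt_f, 1.0 - het_alt_f)

    coseg = (
        informative
        & (homo_carrier >= 1.0 - params.epsilon_fix)
        & (np.abs(het_carrier - 0.5) <= params.delta_het)
    )

    status = np.full(n, UNINFORMATIVE, dtype=object)
    status[low] = LOW_DEPTH
    status[informative & ~coseg] = NON_COSEG
    status[coseg] = COSEG

    out = frame[["scaffold", "pos", "vclass"]].copy()
    out["status"] = status
    out["carrier_allele"] = np.where(
        informative, np.where(carrier_is_alt, "alt", "ref"), "none"
    )
    out["homo_freq"] = np.where(informative, homo_carrier, homo_alt_f)
    out["het_freq"] = np.where(informative, het_carrier, het_alt_f)
    return out
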