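"""Interval refinement from per-individual genotypes at interval markers.

Each genotyped offspring has an expected dose of the carrier-linked allele
implied by its phenotype (2 for affected homozygotes, 1 for carriers).  A
marker where the observed dose departs from that expectation is discordant;
an individual showing both discordant and concordant markers inside the
candidate interval is a recombinant, and its crossover breakpoint is
bounded by the nearest discordant/concordant marker pair.  Because the
causal locus must lie where genotype matches phenotype, each recombinant
restricts the interval to the concordant side of its breakpoint; the
refined interval is the intersection of these restrictions.

The procedure is deliberately conservative: breakpoints are bounded by
their flanking markers and the outer bound is used, missing genotypes are
skipped rather than imputed, and an individual showing only discordant
markers (a possible genotyping error) does not refine the interval unless
``trust_single`` is set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .errors import InconsistentRecombinantsError, ValidationError
from .genome_scan import CandidateInterval

logger = logging.getLogger(__name__)

__all__ = [
    "IndividualGenotype",
    "RecombinantProfile",
    "RefinedInterval",
    "expected_carrier_dose",
    "detect_recombinants",
    "refine_interval",
    "read_genotype_table",
]

PHENOTYPES = ("affected_hom", "carrier_het")

MarkerCall = Tuple[str, int, Optional[int]]  # scaffold, 0-based pos, dose or None


@dataclass
class IndividualGenotype:
    """Phenotyped individual with ordered marker calls (carrier-allele dose 0/1/2)."""

    individual_id: str
    phenotype: str
    marker_calls: Sequence[MarkerCall]

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValidationError(
                f"unknown phenotype {self.phenotype!r} for {self.individual_id}"
            )
        positions = [p for _, p, _ in self.marker_calls]
        if positions != sorted(positions):
            raise ValidationError(
                f"marker calls for {self.individual_id} must be sorted by position"
            )


@dataclass
class RecombinantProfile:
    """Per-individual discordance profile inside the candidate interval."""

    individual_id: str
    phenotype: str
    positions: List[int]
    concordant: List[bool]
    is_recombinant: bool
    # breakpoint bounds: (left marker pos, right marker pos) per concordance flip
    breakpoints: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def n_discordant(self) -> int:
        return sum(not c for c in self.concordant)


@dataclass(frozen=True)
class RefinedInterval:
    """Interval after recombinant-based refinement (0-based half-open)."""

    scaffold: str
    start: int
    end: int
    n_recombinants_used: int
    breakpoints: Tuple[Tuple[str, int, int], ...] = ()  # (individual, lo, hi)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError("refined interval start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def length_mb(self) -> float:
        return self.length / 1e6


def expected_carrier_dose(phenotype: str) -> int:
    """Copies of the carrier-linked allele implied by the phenotype."""
    if phenotype == "affected_hom":
        return 2
    if phenotype == "carrier_het":
        return 1
    raise ValidationError(f"unknown phenotype {phenotype!r}")


def detect_recombinants(
    genotypes: Sequence[IndividualGenotype], interval: CandidateInterval
) -> List[RecombinantProfile]:
    """Build discordance profiles for the markers inside the interval.

    Individuals with no usable (non-missing, in-interval) marker are
    excluded and logged.  An individual is a recombinant iff it shows at
    least one discordant and at least one concordant marker inside the
    interval.
    """
    profiles: List[RecombinantProfile] = []
    for indiv in genotypes:
        expected = expected_carrier_dose(indiv.phenotype)
        positions: List[int] = []
        concordant: List[bool] = []
        for scaffold, pos, dose in indiv.marker_calls:
            if scaffold != interval.scaffold or dose is None:
                continue
            if not (interval.start <= pos < interval.end):
                continue
            positions.append(pos)
            concordant.append(dose == expected)
        if not positions:
            logger.warning(
                "individual %s has no usable marker in the interval; excluded",
                indiv.individual_id,
            )
            continue
        breakpoints = [
            (positions[i], positions[i + 1])
            for i in range(len(positions) - 1)
            if concordant[i] != concordant[i + 1]
        ]
        profiles.append(
            RecombinantProfile(
                individual_id=indiv.individual_id,
                phenotype=indiv.phenotype,
                positions=positions,
                concordant=concordant,
                is_recombinant=any(concordant) and not all(concordant),
                breakpoints=breakpoints,
            )
        )
    return profiles


def _allowed_region(
    profile: RecombinantProfile, interval: CandidateInterval
) -> Tuple[int, int]:
    """Conservative bounds on where the causal locus may sit for one recombinant.

    Only discordant markers lying entirely left (right) of every concordant
    marker trim the interval; discordant markers sandwiched between
    concordant ones would indicate a double crossover or a genotyping error
    and are ignored (conservative choice).  Bounds are exclusive at the
    discordant marker itself.
    """
    conc = [p for p, c in zip(profile.positions, profile.concordant) if c]
    disc = [p for p, c in zip(profile.positions, profile.concordant) if not c]
    lo, hi = interval.start, interval.end
    left_disc = [p for p in disc if p < min(conc)]
    right_disc = [p for p in disc if p > max(conc)]
    if left_disc:
        lo = max(lo, max(left_disc) + 1)
    if right_disc:
        hi = min(hi, min(right_disc))
    return lo, hi


def refine_interval(
    interval: CandidateInterval,
    profiles: Sequence[RecombinantProfile],
    trust_single: bool = False,
) -> RefinedInterval:
    """Intersect the concordant sides of every recombinant's breakpoint.

    With zero recombinants the interval is returned unchanged.  Individuals
    that are discordant at every marker do not refine unless
    ``trust_single`` is set (then the region spanned by their discordant
    markers is excluded, keeping the larger remaining side).  An empty
    intersection raises :class:`InconsistentRecombinantsError` naming the
    individuals involved.
    """
    lo, hi = interval.start, interval.end
    used = 0
    bounds: List[Tuple[str, int, int]] = []
    contributing: List[str] = []
    for profile in profiles:
        if profile.is_recombinant:
            a, b = _allowed_region(profile, interval)
        elif trust_single and profile.n_discordant > 0:
            # all markers discordant: causal cannot sit among them; keep the
            # larger flanking side of the discordant block
            disc = profile.positions
            left = (interval.start, min(disc))
            right = (max(disc) + 1, interval.end)
            a, b = max((left, right), key=lambda ab: ab[1] - ab[0])
        else:
            continue
        used += 1
        contributing.append(profile.individual_id)
        bounds.append((profile.individual_id, a, b))
        lo, hi = max(lo, a), min(hi, b)
        if lo >= hi:
            raise InconsistentRecombinantsError(
                "recombinant constraints have an empty intersection "
                f"(individuals: {', '.join(contributing)}); suspect genotyping "
                "error or a wrong candidate interval",
                individuals=contributing,
            )
    return RefinedInterval(
        scaffold=interval.scaffold,
        start=lo,
        end=hi,
        n_recombinants_used=used,
        breakpoints=tuple(bounds),
    )


def read_genotype_table(path: str | Path) -> List[IndividualGenotype]:
    """Read a per-individual genotype TSV.

    Columns: ``individual_id, phenotype, scaffold, pos, dose`` with ``pos``
    1-based (converted to internal 0-based) and ``dose`` the carrier-allele
    count (0/1/2, empty or NA for missing).
    """
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    individuals = []
    for ind_id, group in df.groupby("individual_id", sort=False):
        phenotypes = group["phenotype"].unique()
        if len(phenotypes) != 1:
            raise ValidationError(f"conflicting phenotypes for individual {ind_id}")
        group = group.sort_values("pos")
        calls = [
            (
                row.scaffold,
                int(row.pos) - 1,
                None if pd.isna(row.dose) else int(row.dose),
            )
            for row in group.itertuples()
        ]
        individuals.append(IndividualGenotype(str(ind_id), phenotypes[0], calls))
    return individuals
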