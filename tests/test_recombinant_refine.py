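"""Recombinant detection and conservative interval refinement."""

import numpy as np
import pytest

from cosegmap.cross_simulator import CrossConfig, simulate_offspring, simulate_panel
from cosegmap.errors import InconsistentRecombinantsError, ValidationError
from cosegmap.genome_scan import CandidateInterval
from cosegmap.recombinant_refine import (
    IndividualGenotype,
    detect_recombinants,
    expected_carrier_dose,
    refine_interval,
)

INTERVAL = CandidateInterval("s", 1_000_000, 5_000_000, peak_proportion=1.0, n_coseg_inside=0)


def indiv(ind_id, phenotype, calls):
    return IndividualGenotype(ind_id, phenotype, [("s", p, d) for p, d in calls])


class TestExpectedDose:
    def test_affected_homozygote_expects_two_copies(self):
        assert expected_carrier_dose("affected_hom") == 2

    def test_carrier_expects_one_copy(self):
        assert expected_carrier_dose("carrier_het") == 1

    def test_unknown_phenotype_raises(self):
        with pytest.raises(ValidationError):
            expected_carrier_dose("mystery")


def test_fully_concordant_individual_is_not_a_recombinant():
    (p,) = detect_recombinants(
        [indiv("a", "affected_hom", [(1_500_000, 2), (3_000_000, 2), (4_500_000, 2)])],
        INTERVAL,
    )
    assert not p.is_recombinant
    assert p.breakpoints == []


def test_recombinant_breakpoint_is_bounded_by_flanking_markers():
    (p,) = detect_recombinants(
        [indiv("a", "affected_hom", [(1_500_000, 2), (3_000_000, 2), (4_500_000, 1)])],
        INTERVAL,
    )
    assert p.is_recombinant
    assert p.breakpoints == [(3_000_000, 4_500_000)]


def test_missing_and_outside_markers_are_skipped():
    (p,) = detect_recombinants(
        [
            indiv(
                "a",
                "carrier_het",
                [(500_000, 0), (1_500_000, 1), (2_000_000, None), (4_000_000, 1)],
            )
        ],
        INTERVAL,
    )
    assert p.positions == [1_500_000, 4_000_000]
    assert not p.is_recombinant


def test_no_recombinants_returns_interval_unchanged():
    refined = refine_interval(INTERVAL, [])
    assert (refined.start, refined.end) == (INTERVAL.start, INTERVAL.end)
    assert refined.n_recombinants_used == 0


def test_refinement_trims_the_discordant_side():
    profiles = detect_recombinants(
        [
            indiv("left", "affected_hom", [(1_200_000, 1), (2_000_000, 2), (4_800_000, 2)]),
            indiv("right", "affected_hom", [(1_200_000, 2), (3_500_000, 2), (4_200_000, 1)]),
        ],
        INTERVAL,
    )
    refined = refine_interval(INTERVAL, profiles)
    # causal must lie right of the left discordant marker (exclusive) and
    # left of the right discordant marker
    assert (refined.start, refined.end) == (1_200_001, 4_200_000)
    assert refined.n_recombinants_used == 2


def test_adding_recombinants_never_enlarges_and_order_does_not_matter():
    rng = np.random.default_rng(0)
    profiles = detect_recombinants(
        [
            indiv("a", "affected_hom", [(1_500_000, 1), (3_000_000, 2)]),
            indiv("b", "carrier_het", [(2_500_000, 1), (4_400_000, 2)]),
            indiv("c", "affected_hom", [(2_000_000, 2), (4_700_000, 1)]),
        ],
        INTERVAL,
    )
    base = refine_interval(INTERVAL, profiles[:1])
    more = refine_interval(INTERVAL, profiles[:2])
    full = refine_interval(INTERVAL, profiles)
    assert more.start >= base.start and more.end <= base.end
    assert full.start >= more.start and full.end <= more.end
    for _ in range(5):
        perm = list(rng.permutation(len(profiles)))
        shuffled = refine_interval(INTERVAL, [profiles[i] for i in perm])
        assert (shuffled.start, shuffled.end) == (full.start, full.end)


def test_inconsistent_recombinants_raise_with_individual_ids():
    profiles = detect_recombinants(
        [
            indiv("west", "affected_hom", [(2_000_000, 2), (2_500_000, 1)]),
            indiv("east", "affected_hom", [(3_000_000, 1), (3_500_000, 2)]),
        ],
        INTERVAL,
    )
    with pytest.raises(InconsistentRecombinantsError) as err:
        refine_interval(INTERVAL, profiles)
    assert set(err.value.individuals) == {"west", "east"}


def test_all_discordant_individual_needs_trust_single():
    profiles = detect_recombinants(
        [indiv("odd", "affected_hom", [(1_400_000, 1), (1_600_000, 1)])], INTERVAL
    )
    assert not profiles[0].is_recombinant
    unchanged = refine_interval(INTERVAL, profiles)
    assert (unchanged.start, unchanged.end) == (INTERVAL.start, INTERVAL.end)
    trusted = refine_interval(INTERVAL, profiles, trust_single=True)
    assert trusted.start == 1_600_001  # larger side kept, discordant block excluded


def _simulated_profiles(seed, interval_width=2_400_000):
    """Error-free genotyping of simulated offspring around the causal locus."""
    cfg = CrossConfig(
        scaffold_lengths=(6_000_000,),
        causal_pos=3_100_000,
        variant_density=1 / 4000,
        recomb_rate=2e-7,  # exaggerated to guarantee recombinants
        seed=seed,
    )
    panel, founders = simulate_panel(cfg)
    ped = simulate_offspring(founders, panel, cfg)
    interval = CandidateInterval(
        "scaffold_1",
        cfg.causal_pos - interval_width // 2,
        cfg.causal_pos + interval_width // 2,
        peak_proportion=1.0,
        n_coseg_inside=0,
    )
    informative = (founders.father[0] == founders.father[1]) & np.all(
        founders.mothers[:, 0, :] != founders.mothers[:, 1, :], axis=0
    )
    linked = informative & np.all(
        founders.mothers[:, 0, :] == founders.father[0][None, :], axis=0
    )
    rows = np.flatnonzero(
        linked
        & (panel.pos >= interval.start)
        & (panel.pos < interval.end)
    )
    carrier = founders.father[0]
    genotypes = []
    for i in range(len(ped.phenotype)):
        dose = (ped.pat_alleles[i, rows] == carrier[rows]).astype(int) + (
            ped.mat_alleles[i, rows] == carrier[rows]
        )
        calls = [("scaffold_1", int(panel.pos[r]), int(d)) for r, d in zip(rows, dose)]
        genotypes.append(IndividualGenotype(f"ind{i}", ped.phenotype[i], calls))
    return cfg, interval, ped, detect_recombinants(genotypes, interval)


def test_breakpoints_contain_a_true_crossover_and_causal_is_never_excluded():
    cfg, interval, ped, profiles = _simulated_profiles(seed=123)
    refined = refine_interval(interval, profiles)
    assert refined.start <= cfg.causal_pos < refined.end
    assert any(p.is_recombinant for p in profiles)
    # every inferred breakpoint interval brackets a true maternal crossover
    # (the sire is homozygous at these markers, so only maternal crossovers
    # can change the carrier dose)
    for p in profiles:
        if not p.is_recombinant:
            continue
        i = int(p.individual_id.removeprefix("ind"))
        xovers = ped.crossovers[i][("mat", 0)]
        for lo, hi in p.breakpoints:
            assert np.any((xovers >= lo) & (xovers <= hi)), (p.individual_id, lo, hi)
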