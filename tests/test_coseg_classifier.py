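"""Per-site co-segregation rule: examples, invariants, vectorised agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cosegmap.coseg_classifier import (
    ClassifierParams,
    ClassifySummary,
    VariantSite,
    classify_frame,
    classify_site,
    classify_table,
)

GENOTYPES = [(0, 0), (0, 1), (1, 1)]


def make_site(father=(1, 1), mothers=((0, 1), (0, 1)), homo=(0, 30), het=(15, 15)):
    return VariantSite(
        scaffold="s",
        pos=100,
        ref="A",
        alt="G",
        father_gt=father,
        mother_gts=list(mothers),
        homo_pool=homo,
        het_pool=het,
    )


class TestClassifySite:
    def test_textbook_cosegregating_configuration(self, default_params):
        """Sire hom-ALT, dams het, homo pool fixed, het pool at one half."""
        status = classify_site(make_site(), default_params)
        assert status.status == "coseg"
        assert status.carrier_allele == "alt"
        assert status.homo_freq == 1.0 and status.het_freq == 0.5

    def test_carrier_allele_may_be_reference(self, default_params):
        status = classify_site(
            make_site(father=(0, 0), homo=(30, 0), het=(15, 15)), default_params
        )
        assert status.status == "coseg"
        assert status.carrier_allele == "ref"

    def test_heterozygous_father_is_uninformative(self, default_params):
        status = classify_site(make_site(father=(0, 1)), default_params)
        assert status.status == "uninformative"
        assert status.carrier_allele == "none"

    def test_homozygous_mother_is_uninformative_by_default(self, default_params):
        site = make_site(mothers=((0, 1), (1, 1)))
        assert classify_site(site, default_params).status == "uninformative"
        relaxed = ClassifierParams(require_all_mothers_het=False)
        assert classify_site(site, relaxed).status == "coseg"

    def test_missing_parent_is_flagged_not_crashed(self, default_params):
        status = classify_site(make_site(father=None), default_params)
        assert status.status == "uninformative"
        assert "missing-parent" in status.flags

    def test_low_depth_gate(self):
        params = ClassifierParams(min_depth=8)
        status = classify_site(make_site(homo=(0, 5)), params)
        assert status.status == "low_depth"

    def test_missing_depth_never_crashes(self, default_params):
        status = classify_site(make_site(homo=None), default_params)
        assert status.status == "low_depth"
        assert "no-depth" in status.flags

    def test_non_cosegregating_pools(self, default_params):
        # both pools near 0.75: the unlinked informative expectation
        status = classify_site(make_site(homo=(8, 22), het=(7, 23)), default_params)
        assert status.status == "non_coseg"


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    father=st.sampled_from(GENOTYPES),
    m1=st.sampled_from(GENOTYPES),
    m2=st.sampled_from(GENOTYPES),
    homo_alt=st.integers(0, 40),
    het_alt=st.integers(0, 40),
    eps1=st.floats(0.01, 0.2),
    eps2=st.floats(0.0, 0.25),
    d1=st.floats(0.05, 0.3),
    d2=st.floats(0.0, 0.15),
)
def test_relaxing_tolerances_is_monotone(father, m1, m2, homo_alt, het_alt, eps1, eps2, d1, d2):
    """Widening epsilon_fix or delta_het never turns coseg into non_coseg."""
    site = make_site(father=father, mothers=(m1, m2), homo=(40 - homo_alt, homo_alt),
                     het=(40 - het_alt, het_alt))
    tight = ClassifierParams(epsilon_fix=eps1, delta_het=d1)
    loose = ClassifierParams(epsilon_fix=min(eps1 + eps2, 0.49), delta_het=min(d1 + d2, 0.49))
    s_tight = classify_site(site, tight).status
    s_loose = classify_site(site, loose).status
    if s_tight == "coseg":
        assert s_loose == "coseg"
    assert classify_site(site, tight).status == s_tight  # deterministic


def test_classify_table_counts_are_additive(default_params):
    sites = [make_site(), make_site(father=(0, 1)), make_site(homo=(8, 22), het=(8, 22))]
    _, s_all = classify_table(sites, default_params)
    _, s_a = classify_table(sites[:1], default_params)
    _, s_b = classify_table(sites[1:], default_params)
    merged = s_a + s_b
    assert merged.informative == s_all.informative
    assert merged.coseg == s_all.coseg
    assert merged.by_status == s_all.by_status


def test_empty_stream_gives_zero_counts(default_params):
    statuses, summary = classify_table([], default_params)
    assert statuses == []
    assert sum(summary.total.values()) == 0


def test_classify_frame_agrees_with_classify_site(rng, default_params):
    """The vectorised path is exactly the per-site rule."""
    n = 500
    gt = lambda: [GENOTYPES[i] for i in rng.integers(0, 3, n)]  # noqa: E731
    father, m1, m2 = gt(), gt(), gt()
    depths = rng.integers(0, 40, size=(n, 4))
    frame = pd.DataFrame(
        {
            "scaffold": ["s"] * n,
            "pos": np.arange(n),
            "vclass": ["SNP"] * n,
            "father_a1": [g[0] for g in father],
            "father_a2": [g[1] for g in father],
            "mother1_a1": [g[0] for g in m1],
            "mother1_a2": [g[1] for g in m1],
            "mother2_a1": [g[0] for g in m2],
            "mother2_a2": [g[1] for g in m2],
            "homo_ref": depths[:, 0],
            "homo_alt": depths[:, 1],
            "het_ref": depths[:, 2],
            "het_alt": depths[:, 3],
        }
    )
    vec = classify_frame(frame, default_params)
    for i in range(n):
        site = make_site(
            father=father[i],
            mothers=(m1[i], m2[i]),
            homo=(int(depths[i, 0]), int(depths[i, 1])),
            het=(int(depths[i, 2]), int(depths[i, 3])),
        )
        assert classify_site(site, default_params).status == vec["status"].iloc[i], i


def test_params_validation():
    with pytest.raises(ValueError):
        ClassifierParams(epsilon_fix=0.6)
    with pytest.raises(ValueError):
        ClassifierParams(delta_het=0.0)
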