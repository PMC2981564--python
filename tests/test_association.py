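"""Presence matrix, enrichment classification, chi-square (with an erfc
oracle), cross-cohort overlap, twin discordance and the permutation test."""

import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cnvassoc import (
    AssociationConfig,
    CnpRegion,
    Cohort,
    SampleMeta,
    ValidationError,
    VariantCall,
    build_presence_matrix,
    chi_square_presence,
    classify_enrichment,
    cohort_frequency,
    overlap_across_cohorts,
    permutation_overlap_test,
    twin_discordant_variants,
)
from cnvassoc.association import (
    AssociationResult,
    CohortStats,
    PresenceMatrix,
    associate,
    significance_stars,
)

CFG = AssociationConfig()


def sample(sid, cohort=Cohort.CTRL, pair=None):
    return SampleMeta(sid, cohort, pair, 0.99)


def var(sample_id, start, end, chrom="1", cn=1):
    return VariantCall(sample_id, chrom, start, end, cn, 9.0)


REGION = CnpRegion("R1", "1", 10_000, 20_000)


# ---------------------------------------------------------------------------
# presence matrix

def test_single_overlapping_call_sets_single_cell():
    m = build_presence_matrix(
        [var("s1", 12_000, 13_000)], [REGION], [sample("s1")]
    )
    assert m.present("s1", "R1")


def test_call_outside_all_regions_leaves_row_false():
    m = build_presence_matrix(
        [var("s1", 50_000, 60_000)], [REGION], [sample("s1")]
    )
    assert not m.df.loc["s1"].any()


def test_presence_is_idempotent_for_repeat_calls():
    m = build_presence_matrix(
        [var("s1", 12_000, 13_000), var("s1", 14_000, 15_000)],
        [REGION],
        [sample("s1")],
    )
    assert int(m.df.to_numpy().sum()) == 1


def test_unknown_sample_is_error():
    with pytest.raises(ValidationError, match="ghost"):
        build_presence_matrix([var("ghost", 1, 2)], [REGION], [sample("s1")])


def test_sample_without_calls_gets_all_false_row():
    m = build_presence_matrix([], [REGION], [sample("s1"), sample("s2")])
    assert list(m.samples) == ["s1", "s2"]
    assert not m.df.to_numpy().any()


# ---------------------------------------------------------------------------
# frequencies and enrichment

def _matrix(presence):
    return PresenceMatrix(pd.DataFrame(presence))


def test_cohort_frequency_renders_expected_percent():
    presence = pd.DataFrame(
        {"R1": [True] * 16 + [False] * 2}, index=[f"t{i}" for i in range(18)]
    )
    f = cohort_frequency(PresenceMatrix(presence), list(presence.index))
    assert int(f.at["R1", "n_present"]) == 16
    assert round(100 * f.at["R1", "freq"]) == 89


def test_cohort_frequency_empty_cohort_is_error():
    with pytest.raises(ValidationError):
        cohort_frequency(_matrix({"R1": [True]}), [])


@pytest.mark.parametrize(
    "fcase,fctrl,expected",
    [
        (0.89, 0.42, "enriched"),
        (0.39, 0.68, "depleted"),
        (0.40, 0.10, "neither"),  # strict > on the 40% threshold
        (0.74, 0.50, "neither"),  # fold 1.48, shy of 1.5
        (0.75, 0.50, "enriched"),  # the boundary fold 1.5 itself qualifies
        (0.50, 0.0, "enriched"),  # absent in controls
        (0.0, 0.50, "depleted"),
    ],
)
def test_classify_enrichment_rule(fcase, fctrl, expected):
    assert classify_enrichment(fcase, fctrl, CFG) == expected


@given(
    st.floats(min_value=0, max_value=1, allow_nan=False),
    st.floats(min_value=0, max_value=1, allow_nan=False),
)
def test_classify_enrichment_is_antisymmetric(fa, fb):
    """Swapping case and control maps enriched <-> depleted, fixes neither."""
    forward = classify_enrichment(fa, fb, CFG)
    backward = classify_enrichment(fb, fa, CFG)
    flip = {"enriched": "depleted", "depleted": "enriched", "neither": "neither"}
    assert backward == flip[forward]


# ---------------------------------------------------------------------------
# chi-square

def _yates_oracle(a, b, c, d):
    """Independent closed form: Yates statistic + 1-df survival via erfc."""
    n = a + b + c + d
    num = max(0.0, abs(a * d - b * c) - n / 2) ** 2 * n
    den = (a + b) * (c + d) * (a + c) * (b + d)
    stat = num / den
    return math.erfc(math.sqrt(stat / 2))


def test_chi_square_matches_erfc_oracle_on_reported_counts():
    """8/19 controls vs 16/18 cases: statistic ~6.94, p ~0.0084."""
    p = chi_square_presence(16, 8, 2, 11)
    assert p == pytest.approx(_yates_oracle(16, 8, 2, 11), rel=1e-10)
    assert p == pytest.approx(0.0084, abs=5e-4)


@given(
    st.integers(min_value=0, max_value=30),
    st.integers(min_value=0, max_value=30),
    st.integers(min_value=0, max_value=30),
    st.integers(min_value=0, max_value=30),
)
def test_chi_square_symmetries_and_oracle(a, b, c, d):
    if min(a + b, c + d, a + c, b + d) == 0:
        assert chi_square_presence(a, b, c, d) == 1.0
        return
    p = chi_square_presence(a, b, c, d)
    assert p == pytest.approx(_yates_oracle(a, b, c, d), rel=1e-9)
    assert p == pytest.approx(chi_square_presence(b, a, d, c), rel=1e-12)
    assert p == pytest.approx(chi_square_presence(c, d, a, b), rel=1e-12)


def test_chi_square_equal_proportions_is_one():
    assert chi_square_presence(5, 5, 5, 5) == pytest.approx(1.0)


def test_chi_square_zero_margin_warns_and_returns_one(caplog):
    with caplog.at_level(logging.WARNING):
        assert chi_square_presence(0, 0, 10, 9) == 1.0
    assert "zero margin" in caplog.text


# ---------------------------------------------------------------------------
# overlap and twins

def _result(rid, status):
    stats = CohortStats(5, 10)
    return AssociationResult(rid, stats, stats, 1.0, status, 0.5)


def test_overlap_across_cohorts_intersects_by_status():
    a = {"r1": _result("r1", "enriched"), "r2": _result("r2", "depleted")}
    b = {"r1": _result("r1", "enriched"), "r2": _result("r2", "enriched")}
    enriched, depleted = overlap_across_cohorts(a, b)
    assert enriched == ["r1"] and depleted == []


def test_overlap_requires_same_universe():
    a = {"r1": _result("r1", "enriched")}
    b = {"r2": _result("r2", "enriched")}
    with pytest.raises(ValidationError):
        overlap_across_cohorts(a, b)


def test_twin_discordance_counts():
    presence = pd.DataFrame(
        {
            "R1": {"a1": True, "u1": True, "a2": True, "u2": False,
                   "a3": False, "u3": True},
        }
    )
    m = PresenceMatrix(presence)
    counts = twin_discordant_variants(m, [("a1", "u1"), ("a2", "u2"), ("a3", "u3")])
    assert int(counts.at["R1", "affected_only"]) == 1
    assert int(counts.at["R1", "unaffected_only"]) == 1


def test_twin_discordance_additivity():
    presence = pd.DataFrame(
        {"R1": {f"a{i}": True for i in range(10)} | {f"u{i}": False for i in range(10)}}
    )
    m = PresenceMatrix(presence)
    pairs = [(f"a{i}", f"u{i}") for i in range(10)]
    counts = twin_discordant_variants(m, pairs)
    assert int(counts.at["R1", "affected_only"]) == 10
    assert int(counts.at["R1", "unaffected_only"]) == 0


def test_incomplete_pair_is_error():
    m = PresenceMatrix(pd.DataFrame({"R1": {"a1": True}}))
    with pytest.raises(ValidationError):
        twin_discordant_variants(m, [("a1", "missing")])


# ---------------------------------------------------------------------------
# permutation test

def _random_matrix(rng, n_samples=57, n_regions=30, p=0.5):
    cells = rng.random((n_samples, n_regions)) < p
    return PresenceMatrix(
        pd.DataFrame(
            cells,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"r{j}" for j in range(n_regions)],
        )
    )


def test_observed_zero_gives_p_one():
    m = _random_matrix(np.random.default_rng(0))
    res = permutation_overlap_test(
        m, (19, 18, 20), 0, AssociationConfig(n_permutations=50, rng_seed=1)
    )
    assert res.p_value == 1.0


def test_permutation_is_bit_reproducible():
    m = _random_matrix(np.random.default_rng(3))
    cfg = AssociationConfig(n_permutations=100, rng_seed=42)
    r1 = permutation_overlap_test(m, (19, 18, 20), 2, cfg)
    r2 = permutation_overlap_test(m, (19, 18, 20), 2, cfg)
    assert r1 == r2
    # p on the permutation grid
    assert r1.p_value in {i / 100 for i in range(101)}


def test_group_sizes_must_sum_to_samples():
    m = _random_matrix(np.random.default_rng(0))
    with pytest.raises(ValidationError):
        permutation_overlap_test(m, (19, 18, 19), 0, CFG)


def test_planted_effect_yields_small_p():
    """Five regions at 90% case / 20% control frequency are detected by the
    permutation null as a significant overlap."""
    rng = np.random.default_rng(1)
    n_ctrl, n_case, n_twin = 19, 18, 20
    rows = []
    for _ in range(n_ctrl):
        rows.append(rng.random(5) < 0.2)
    for _ in range(n_case + n_twin):
        rows.append(rng.random(5) < 0.9)
    m = PresenceMatrix(
        pd.DataFrame(
            np.array(rows),
            index=[f"s{i}" for i in range(57)],
            columns=[f"r{j}" for j in range(5)],
        )
    )
    ctrl_ids = [f"s{i}" for i in range(19)]
    case_ids = [f"s{i}" for i in range(19, 37)]
    twin_ids = [f"s{i}" for i in range(37, 57)]
    res_case = associate(m, case_ids, ctrl_ids)
    res_twin = associate(m, twin_ids, ctrl_ids)
    enriched, _ = overlap_across_cohorts(res_case, res_twin)
    res = permutation_overlap_test(
        m, (19, 18, 20), len(enriched),
        AssociationConfig(n_permutations=1000, rng_seed=1),
    )
    assert len(enriched) >= 3
    assert res.p_value <= 0.05


# ---------------------------------------------------------------------------
# table membership under the printed frequencies

TABLE_FREQS = {
    # region: (ctrl%, t1d%, twin%) as printed
    "CNP253": (42, 72, 70),
    "CNP934": (42, 89, 65),
    "CNP1162": (37, 78, 80),
    "CNP1303": (21, 61, 50),
    "CNP1956": (58, 89, 95),
    "CNP1102": (68, 39, 10),
    "CNP1879": (47, 22, 10),
    "A588": (58, 33, 10),
    "CNP2240": (42, 22, 0),
}


def test_reported_frequency_triplets_classify_five_and_four():
    """The nine published frequency triplets yield exactly the published
    membership: five regions enriched in both case cohorts, four depleted."""
    enriched, depleted = [], []
    for rid, (c, t, w) in TABLE_FREQS.items():
        s_case = classify_enrichment(t / 100, c / 100, CFG)
        s_twin = classify_enrichment(w / 100, c / 100, CFG)
        if s_case == s_twin == "enriched":
            enriched.append(rid)
        if s_case == s_twin == "depleted":
            depleted.append(rid)
    assert sorted(enriched) == [
        "CNP1162", "CNP1303", "CNP1956", "CNP253", "CNP934"
    ]
    assert sorted(depleted) == ["A588", "CNP1102", "CNP1879", "CNP2240"]


def test_significance_stars_tiers():
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.2) == ""
    assert significance_stars(0.0004) == "***"
    assert significance_stars(0.004) == "**"
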