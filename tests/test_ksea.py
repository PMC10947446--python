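"""Core scoring arithmetic, verified against independent oracles."""

import logging
import math
import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pamksea as pk
from pamksea.errors import ContractError, DegenerateDataError, DesignError

from helpers import (
    assert_scores_match_oracle,
    instance_to_objects,
    make_fc,
    make_intensity,
    make_map,
    oracle_scores,
    oracle_sf,
    random_instance,
)

# frozen by independent arithmetic: 0.2625 * sqrt(3) / 0.4
Z_ORACLE = 0.2625 * math.sqrt(3.0) / 0.4


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------


def test_fold_change_is_difference_of_replicate_means():
    table = make_intensity(
        ["S1"],
        {
            ("vehicle", 10, 1): [9.0], ("vehicle", 10, 2): [9.2],
            ("vehicle", 10, 3): [8.8], ("vehicle", 10, 4): [9.0],
            ("ex4", 10, 1): [10.0], ("ex4", 10, 2): [10.2],
            ("ex4", 10, 3): [9.8], ("ex4", 10, 4): [10.0],
        },
    )
    fc = pk.compute_fold_changes(table)
    assert fc.baseline == "vehicle"
    assert fc.log2fc.at["S1", ("ex4", 10)] == pytest.approx(1.0, abs=1e-12)


def test_fold_change_zero_when_treatment_equals_vehicle():
    vals = [9.1, 8.7, 10.3]
    cols = {}
    for r in (1, 2):
        cols[("vehicle", 10, r)] = vals
        cols[("ex4", 10, r)] = vals
    fc = pk.compute_fold_changes(make_intensity(["a", "b", "c"], cols))
    assert np.allclose(fc.log2fc[("ex4", 10)], 0.0)


def test_missing_replicate_averaged_over_the_rest():
    cols = {
        ("vehicle", 10, 1): [9.0], ("vehicle", 10, 2): [9.0],
        ("ex4", 10, 1): [10.0], ("ex4", 10, 2): [11.0],
        ("ex4", 10, 3): [12.0], ("ex4", 10, 4): [np.nan],
    }
    fc = pk.compute_fold_changes(make_intensity(["S1"], cols))
    assert fc.log2fc.at["S1", ("ex4", 10)] == pytest.approx(2.0)


def test_entirely_missing_condition_dropped_with_warning(caplog):
    cols = {
        ("vehicle", 10, 1): [9.0, 9.5], ("vehicle", 10, 2): [9.1, 9.4],
        ("ex4", 10, 1): [10.0, 9.9], ("ex4", 10, 2): [10.1, 10.2],
        ("phe1", 10, 1): [np.nan, np.nan], ("phe1", 10, 2): [np.nan, np.nan],
    }
    with caplog.at_level(logging.WARNING, logger="pamksea.ksea"):
        fc = pk.compute_fold_changes(make_intensity(["a", "b"], cols))
    assert ("phe1", 10) not in fc.conditions
    assert ("ex4", 10) in fc.conditions
    assert any("phe1" in rec.message for rec in caplog.records)


def test_missing_baseline_arm_is_design_error():
    cols = {
        ("vehicle", 10, 1): [9.0], ("vehicle", 10, 2): [9.1],
        ("phe1", 10, 1): [10.0], ("phe1", 10, 2): [10.1],
    }
    with pytest.raises(DesignError, match="ex4"):
        pk.compute_fold_changes(make_intensity(["S1"], cols), baseline_treatment="ex4")


# ---------------------------------------------------------------------------
# global statistics
# ---------------------------------------------------------------------------


def test_global_stats_closed_form():
    fc = make_fc(["a", "b"], {("ex4", 10): [1.0, -1.0]})
    stats = pk.global_stats(fc)
    assert stats.mean[("ex4", 10)] == pytest.approx(0.0)
    assert stats.sd[("ex4", 10)] == pytest.approx(math.sqrt(2.0))
    assert stats.n_sites_used[("ex4", 10)] == 2


def test_global_stats_constant_column_is_degenerate():
    fc = make_fc(["a", "b", "c"], {("ex4", 10): [0.5, 0.5, 0.5]})
    with pytest.raises(DegenerateDataError):
        pk.global_stats(fc)


def test_global_stats_counts_only_measured_sites():
    fc = make_fc(list("abcde"), {("ex4", 10): [1.0, 2.0, None, 0.5, -1.0]})
    assert pk.global_stats(fc).n_sites_used[("ex4", 10)] == 4


# ---------------------------------------------------------------------------
# scalar statistics
# ---------------------------------------------------------------------------


def test_weighted_mean_hand_computed_example():
    # (400*1.0 - 300*0.5 + 500*0.25) / 1200 = 375/1200
    assert pk.weighted_mean([1.0, -0.5, 0.25], [400, 300, 500]) == pytest.approx(0.3125)


def test_weighted_mean_equal_weights_is_plain_mean():
    vals = [0.3, -1.2, 0.7, 2.0]
    assert pk.weighted_mean(vals, [650.0] * 4) == pytest.approx(np.mean(vals))


def test_weighted_mean_single_substrate_returns_its_value():
    assert pk.weighted_mean([0.42], [999.0]) == 0.42


@pytest.mark.parametrize(
    "vals,weights",
    [([1.0], [1.0, 2.0]), ([1.0, 2.0], [3.0, 0.0]), ([1.0, 2.0], [3.0, -1.0])],
)
def test_weighted_mean_contract_violations(vals, weights):
    with pytest.raises(ContractError):
        pk.weighted_mean(vals, weights)


def test_kinase_z_matches_arithmetic_oracle():
    assert pk.kinase_z(0.3125, 0.05, 0.4, 3) == pytest.approx(Z_ORACLE, abs=1e-12)


def test_kinase_z_zero_when_s_w_equals_background():
    assert pk.kinase_z(0.123, 0.123, 0.7, 17) == 0.0


def test_kinase_z_scales_with_sqrt_m():
    z1 = pk.kinase_z(0.5, 0.1, 0.3, 1)
    z4 = pk.kinase_z(0.5, 0.1, 0.3, 4)
    assert z4 == pytest.approx(2.0 * z1)


@pytest.mark.parametrize("m,sd", [(0, 0.5), (3, 0.0), (3, -1.0)])
def test_kinase_z_contract_violations(m, sd):
    with pytest.raises(ContractError):
        pk.kinase_z(0.5, 0.0, sd, m)


def test_one_tail_p_at_zero_is_half():
    assert pk.one_tail_p(0.0) == pytest.approx(0.5)


def test_one_tail_p_matches_normal_tail_integral():
    z = Z_ORACLE
    assert pk.one_tail_p(z) == pytest.approx(0.1278, abs=1e-4)
    assert pk.one_tail_p(z) == pytest.approx(oracle_sf(z), abs=1e-12)


@given(st.floats(min_value=-8.0, max_value=8.0, allow_nan=False))
def test_one_tail_p_symmetric_and_monotone_in_magnitude(z):
    assert pk.one_tail_p(z) == pk.one_tail_p(-z)
    assert pk.one_tail_p(abs(z) + 0.1) < pk.one_tail_p(z)


def test_one_tail_p_rejects_non_finite():
    with pytest.raises(ContractError):
        pk.one_tail_p(float("nan"))


# ---------------------------------------------------------------------------
# score_all
# ---------------------------------------------------------------------------


def test_score_all_matches_bruteforce_on_random_instances():
    rng = random.Random(20240901)
    for _ in range(20):
        sites, fc_cols, submap = random_instance(rng)
        fc, ksmap = instance_to_objects(sites, fc_cols, submap)
        scores = pk.score_all(fc, ksmap)
        assert_scores_match_oracle(scores, oracle_scores(fc_cols, submap))


def test_z_is_monotone_in_s_w():
    zs = [pk.kinase_z(s_w, 0.05, 0.4, 5) for s_w in np.linspace(-2, 2, 9)]
    assert all(a < b for a, b in zip(zs, zs[1:]))


def test_kinase_with_all_substrates_masked_is_missing_in_that_column_only():
    fc = make_fc(
        list("abcd"),
        {("ex4", 10): [None, None, 0.5, -0.2], ("ex4", 120): [0.1, 0.4, -0.3, 0.9]},
    )
    ksmap = make_map([("KA", "a", 400.0), ("KA", "b", 500.0), ("KB", "c", 400.0)])
    df = pk.score_all(fc, ksmap).scores.set_index(["kinase", "treatment", "duration_min"])
    assert bool(df.loc[("KA", "ex4", 10), "missing"])
    assert not bool(df.loc[("KA", "ex4", 120), "missing"])
    assert not bool(df.loc[("KB", "ex4", 10), "missing"])


# ---------------------------------------------------------------------------
# selection and expression filtering
# ---------------------------------------------------------------------------


def _score_table(rows):
    import pandas as pd

    df = pd.DataFrame(rows, columns=["kinase", "treatment", "duration_min", "p_value"])
    df["m"] = 3
    df["s_w"] = 0.1
    df["z"] = 1.0
    df["p_adj"] = df["p_value"]
    df["missing"] = False
    return pk.KinaseScoreTable(chip_type="PTK", baseline="vehicle", scores=df)


def test_select_significant_uses_at_least_one_condition():
    table = _score_table(
        [
            ("KA", "asp3", 10, 0.01),
            ("KA", "asp3", 120, 0.9),
            ("KB", "asp3", 10, 0.2),
            ("KB", "asp3", 120, 0.6),
        ]
    )
    assert pk.select_significant(table, alpha=0.05) == ["KA"]


def test_select_significant_alpha_one_returns_everything():
    table = _score_table([("KA", "ex4", 10, 0.99), ("KB", "ex4", 10, 0.5)])
    assert pk.select_significant(table, alpha=1.0) == ["KA", "KB"]


def test_expression_filter_is_case_insensitive_and_order_preserving():
    kept = pk.filter_by_expression(["JNK1", "FOO", "insr"], ["jnk1", "INSR"])
    assert kept == ["JNK1", "insr"]


def test_expression_filter_superset_is_identity():
    assert pk.filter_by_expression(["A", "B"], ["A", "B", "C"]) == ["A", "B"]


def test_expression_filter_empty_allow_list_is_design_error():
    with pytest.raises(DesignError):
        pk.filter_by_expression(["A"], [])
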