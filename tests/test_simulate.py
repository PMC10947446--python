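"""Synthetic-experiment generator: determinism, design contracts,
propagation of injected effects, and recovery metrics."""

import logging

import numpy as np
import pandas as pd
import pytest

import pamksea as pk
from pamksea.mapping import DEFAULT_TOP_K


def _small_params(**kw):
    defaults = dict(chip_type="PTK", n_sites=60, n_kinases=12,
                    substrates_per_kinase=(4, 8), seed=5)
    defaults.update(kw)
    return pk.SimulationParams(**defaults)


def test_same_seed_reproduces_every_artifact():
    for _ in range(2):
        tables = []
        for _rep in range(2):
            params = _small_params()
            preds = pk.simulate_prediction_table(params)
            truth = pk.simulate_truth(params, n_active=3, delta=1.0)
            intensities = pk.simulate_intensities(params, preds, truth)
            tables.append((preds, truth, intensities))
        (p1, t1, i1), (p2, t2, i2) = tables
        pd.testing.assert_frame_equal(p1.records, p2.records)
        pd.testing.assert_frame_equal(t1.effects, t2.effects)
        pd.testing.assert_frame_equal(i1.values, i2.values)


def test_different_seeds_differ():
    i1 = pk.simulate_intensities(
        _small_params(seed=1),
        pk.simulate_prediction_table(_small_params(seed=1)),
        pk.simulate_truth(_small_params(seed=1), 0, 0.0),
    )
    i2 = pk.simulate_intensities(
        _small_params(seed=2),
        pk.simulate_prediction_table(_small_params(seed=2)),
        pk.simulate_truth(_small_params(seed=2), 0, 0.0),
    )
    assert not np.allclose(i1.values.to_numpy(), i2.values.to_numpy())


def test_prediction_table_respects_generator_contract():
    params = pk.SimulationParams(seed=3)  # full default PTK design
    preds = pk.simulate_prediction_table(params)
    assert (preds.records["v2_score"] > 300.0).all()
    per_kinase = preds.records.groupby("kinase").size()
    lo, _hi = params.substrates_per_kinase
    assert (per_kinase >= lo).all()
    assert set(preds.records["site_id"]) <= set(params.site_ids)


def test_oversubscribed_sites_exceed_cap_then_filter_trims_them():
    params = pk.SimulationParams(seed=3)
    preds = pk.simulate_prediction_table(params)
    per_site = preds.records.groupby("site_id").size()
    top_k = DEFAULT_TOP_K["PTK"]
    assert (per_site > top_k).any()  # boundary cases exist pre-filter
    filtered = pk.filter_predictions(pk.merge_sources(preds), pk.MappingConfig("PTK"))
    trimmed = filtered.records.groupby("site_id").size()
    assert trimmed.max() <= top_k
    oversub = per_site.index[per_site > top_k]
    assert (trimmed.loc[oversub] == top_k).all()


def test_truth_injects_requested_number_per_condition():
    params = _small_params()
    truth = pk.simulate_truth(params, n_active=3, delta=0.7)
    for col in truth.effects.columns:
        nonzero = truth.effects[col][truth.effects[col] != 0]
        assert len(nonzero) == 3
        assert set(np.abs(nonzero)) == {0.7}
    assert "vehicle" not in {t for t, _d in truth.effects.columns}


def test_truth_null_and_negative_delta_cases():
    params = _small_params()
    assert (pk.simulate_truth(params, 0, 1.0).effects == 0).all().all()
    down = pk.simulate_truth(params, 2, -0.5)
    assert set(np.abs(down.effects.to_numpy()[down.effects.to_numpy() != 0])) == {0.5}


def test_truth_zero_delta_with_active_kinases_warns(caplog):
    with caplog.at_level(logging.WARNING, logger="pamksea.simulate"):
        pk.simulate_truth(_small_params(), n_active=2, delta=0.0)
    assert any("null" in rec.message for rec in caplog.records)


def test_null_fold_changes_centred_on_zero():
    params = pk.SimulationParams(seed=8)
    preds = pk.simulate_prediction_table(params)
    truth = pk.simulate_truth(params, 0, 0.0)
    fc = pk.compute_fold_changes(pk.simulate_intensities(params, preds, truth))
    bound = 3 * params.noise_sd / np.sqrt(params.replicates * params.n_sites / 2)
    assert (fc.log2fc.mean().abs() < bound).all()


def test_injected_kinase_substrates_shift_above_background():
    params = pk.SimulationParams(seed=9, substrates_per_kinase=(15, 25))
    preds = pk.simulate_prediction_table(params)
    truth = pk.simulate_truth(params, 0, 0.0)
    truth.effects.loc["KIN001", ("ex4", 10)] = 1.0
    fc = pk.compute_fold_changes(pk.simulate_intensities(params, preds, truth))
    subs = set(preds.records.loc[preds.records["kinase"] == "KIN001", "site_id"])
    col = fc.log2fc[("ex4", 10)]
    margin = col[col.index.isin(subs)].mean() - col[~col.index.isin(subs)].mean()
    assert margin > 0.05


def test_mask_substrates_yields_not_found_in_that_condition_only():
    params = _small_params()
    preds = pk.simulate_prediction_table(params)
    truth = pk.simulate_truth(params, 0, 0.0)
    intensities = pk.simulate_intensities(params, preds, truth)
    kinase = "KIN003"
    sites = list(preds.records.loc[preds.records["kinase"] == kinase, "site_id"])
    masked = pk.mask_substrates(intensities, sites, "phe1", 10)
    fc = pk.compute_fold_changes(masked)
    cfg = pk.MappingConfig("PTK")
    ksmap = pk.build_map(pk.filter_predictions(pk.merge_sources(preds), cfg),
                         list(fc.log2fc.index), cfg)
    df = pk.score_all(fc, ksmap).scores.set_index(["kinase", "treatment", "duration_min"])
    assert bool(df.loc[(kinase, "phe1", 10), "missing"])
    assert not bool(df.loc[(kinase, "phe1", 120), "missing"])
    assert not bool(df.loc[(kinase, "asp3", 10), "missing"])


def test_null_recovery_has_undefined_sensitivity_and_nominal_scale_fpr():
    params = _small_params(n_sites=80, n_kinases=15, substrates_per_kinase=(6, 10))
    report = pk.recovery_experiment(params, n_active=0, delta=0.0, n_runs=10)
    assert np.isnan(report.sensitivity).all()
    # with the direction-of-score one-tail p, a null score is flagged at
    # alpha when |z| exceeds the upper-alpha quantile: ~2*alpha of scores
    assert 0.02 < report.mean_false_positive_rate < 0.2


def test_recovery_ranks_injected_kinases_near_the_top():
    params = pk.SimulationParams(seed=11, substrates_per_kinase=(15, 25))
    report = pk.recovery_experiment(params, n_active=5, delta=1.0, n_runs=5)
    assert report.mean_sensitivity > 0.5
    assert np.nanmean(report.mean_injected_rank) < 0.2


def test_recovery_is_deterministic_for_fixed_seed():
    params = _small_params()
    r1 = pk.recovery_experiment(params, n_active=2, delta=1.0, n_runs=3)
    r2 = pk.recovery_experiment(params, n_active=2, delta=1.0, n_runs=3)
    np.testing.assert_array_equal(r1.sensitivity, r2.sensitivity)
    np.testing.assert_array_equal(r1.false_positive_rate, r2.false_positive_rate)
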