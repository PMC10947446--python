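"""Synthetic kinome-array experiments with known ground truth.

The generator emulates the study design the analysis assumes: four
treatments (vehicle, a balanced reference agonist and two biased
derivatives) at two durations with four replicates each, on a tyrosine
(196-peptide) or serine/threonine (144-peptide) array.  It produces the
three inputs the pipeline consumes — a kinase-substrate prediction table,
a ground-truth kinase activity profile, and per-replicate log2 intensities
— so every stage is testable without external data and recovery of
injected activities can be quantified.

Noise model.  Replicate intensities are Gaussian on the log2 scale
(log-normal fluorescence noise, the standard assumption for such arrays).
Each site carries a fixed baseline offset, so vehicle normalization is
genuinely exercised, and an injected kinase activity delta propagates to a
substrate site in proportion to the kinase's prediction-score share of
that site:

    intensity = baseline + site_offset
                + sum_k (w_ks / sum_k' w_k's) * delta_k(condition)
                + N(0, noise_sd)     independently per replicate.

The score-proportional propagation makes the prediction-weighted mean the
efficient estimator of a kinase's activity, which is exactly the structure
the weighted enrichment statistic assumes.

All randomness flows through seeded :func:`numpy.random.default_rng`
generators keyed on ``(seed, stream)`` so each artifact is reproducible
independently of the others.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .io import (
    CHIP_SIZES,
    CHIP_TYPES,
    DURATIONS,
    TREATMENTS,
    PredictionTable,
    ReplicateIntensityTable,
)
from .ksea import DEFAULT_ALPHA, compute_fold_changes, score_all
from .mapping import MappingConfig, build_map, filter_predictions, merge_sources

logger = logging.getLogger(__name__)

_STREAMS = {"predictions": 1, "truth": 2, "intensities": 3, "runs": 4}


@dataclass
class SimulationParams:
    """Study-design and noise parameters of a synthetic experiment.

    Defaults mirror the emulated assay: full chip size (196 / 144 sites),
    60 candidate kinases with 5-25 predicted substrates each, 4 replicates,
    a 9.0 log2-unit mean baseline with 1.0 log2-unit between-site
    heterogeneity, 0.25 log2-unit replicate noise, and prediction weights
    uniform on (300, 1000].  ``oversubscribed_fraction`` of sites receive
    more predicted kinases than the per-site top-K cap so the mapping
    filter is exercised on both sides of its boundary.
    """

    chip_type: str = "PTK"
    n_sites: int | None = None
    n_kinases: int = 60
    substrates_per_kinase: tuple[int, int] = (5, 25)
    replicates: int = 4
    treatments: tuple[str, ...] = TREATMENTS
    durations: tuple[int, ...] = DURATIONS
    baseline_intensity: float = 9.0
    site_offset_sd: float = 1.0
    noise_sd: float = 0.25
    weight_range: tuple[float, float] = (300.0, 1000.0)
    oversubscribed_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chip_type not in CHIP_TYPES:
            raise ContractError(f"unknown chip type {self.chip_type!r}")
        if self.n_sites is None:
            self.n_sites = CHIP_SIZES[self.chip_type]
        if self.replicates < 2:
            raise ContractError("replicates must be >= 2")
        if self.noise_sd <= 0:
            raise ContractError("noise_sd must be > 0")
        lo, hi = self.substrates_per_kinase
        if not (1 <= lo <= hi <= self.n_sites):
            raise ContractError("substrates_per_kinase range must fit within n_sites")
        if "vehicle" not in self.treatments:
            raise ContractError("treatments must include the vehicle control")

    @property
    def site_ids(self) -> list[str]:
        return [f"{self.chip_type}_{i + 1:03d}" for i in range(self.n_sites)]

    @property
    def kinase_names(self) -> list[str]:
        return [f"KIN{i + 1:03d}" for i in range(self.n_kinases)]

    @property
    def conditions(self) -> list[tuple[str, int]]:
        """Non-vehicle (treatment, duration) cells."""
        return [(t, d) for t in self.treatments if t != "vehicle" for d in self.durations]

    def _rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


@dataclass
class SimulationTruth:
    """Injected kinase-activity effects, in log2FC units.

    ``effects`` is kinase x (treatment, duration) over non-vehicle
    conditions; zero means not injected.
    """

    effects: pd.DataFrame

    @property
    def injected(self) -> pd.DataFrame:
        return self.effects != 0.0

    def effect(self, kinase: str, treatment: str, duration: int) -> float:
        return float(self.effects.at[kinase, (treatment, duration)])


def _draw_weights(rng: np.random.Generator, n: int, weight_range: tuple[float, float]) -> np.ndarray:
    lo, hi = weight_range
    # (lo, hi]: strictly above the score threshold by construction
    return lo + (hi - lo) * (1.0 - rng.random(n))


def simulate_prediction_table(params: SimulationParams) -> PredictionTable:
    """Random kinase-substrate predictions with weights above the filter
    threshold.

    Each kinase draws its substrate count uniformly from the configured
    range and its sites without replacement.  A configurable fraction of
    sites is then oversubscribed past the chip's top-K cap by adding extra
    kinases, so downstream filtering trims real boundary cases.
    """
    rng = params._rng("predictions")
    site_ids = np.array(params.site_ids)
    kinases = params.kinase_names
    lo, hi = params.substrates_per_kinase

    records: dict[tuple[str, str], float] = {}
    for kinase in kinases:
        m_k = int(rng.integers(lo, hi + 1))
        sites = rng.choice(params.n_sites, size=m_k, replace=False)
        weights = _draw_weights(rng, m_k, params.weight_range)
        for s, w in zip(sites, weights):
            records[(kinase, site_ids[s])] = float(w)

    top_k = MappingConfig(params.chip_type).top_k
    n_over = int(round(params.oversubscribed_fraction * params.n_sites))
    if n_over and params.n_kinases > top_k:
        over_sites = rng.choice(params.n_sites, size=n_over, replace=False)
        for s in over_sites:
            site = site_ids[s]
            present = {k for (k, sid) in records if sid == site}
            target = min(params.n_kinases, top_k + int(rng.integers(1, 6)))
            absent = [k for k in kinases if k not in present]
            n_extra = max(0, target - len(present))
            extra = rng.choice(len(absent), size=n_extra, replace=False)
            weights = _draw_weights(rng, n_extra, params.weight_range)
            for j, w in zip(extra, weights):
                records[(absent[j], site)] = float(w)

    df = pd.DataFrame(
        {
            "kinase": [k for k, _s in records],
            "site_id": [s for _k, s in records],
            "v2_score": list(records.values()),
            "source": "synthetic",
        }
    )
    df = df.sort_values(["kinase", "site_id"], kind="mergesort").reset_index(drop=True)
    return PredictionTable(records=df)


def simulate_truth(params: SimulationParams, n_active: int, delta: float) -> SimulationTruth:
    """Inject ``n_active`` kinases per non-vehicle condition with effect
    ``delta`` (sign randomized per kinase-condition entry)."""
    if not 0 <= n_active <= params.n_kinases:
        raise ContractError("n_active must lie in [0, n_kinases]")
    if delta == 0.0 and n_active > 0:
        logger.warning("delta = 0 with n_active > 0: truth is null-equivalent")
    rng = params._rng("truth")
    conditions = params.conditions
    effects = pd.DataFrame(
        0.0,
        index=params.kinase_names,
        columns=pd.MultiIndex.from_tuples(conditions, names=("treatment", "duration_min")),
    )
    for cond in conditions:
        idx = rng.choice(params.n_kinases, size=n_active, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_active)
        effects.iloc[idx, effects.columns.get_loc(cond)] = signs * delta
    return SimulationTruth(effects=effects)


def simulate_intensities(
    params: SimulationParams,
    preds: PredictionTable,
    truth: SimulationTruth,
) -> ReplicateIntensityTable:
    """Per-replicate log2 intensities under the score-proportional
    propagation model described in the module docstring."""
    rng = params._rng("intensities")
    site_ids = params.site_ids
    offsets = rng.normal(0.0, params.site_offset_sd, size=params.n_sites)

    weight_matrix = (
        preds.records.pivot_table(
            index="site_id", columns="kinase", values="v2_score", aggfunc="max"
        )
        .reindex(index=site_ids, columns=truth.effects.index)
        .fillna(0.0)
        .to_numpy(dtype=float)
    )
    row_sums = weight_matrix.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row_sums > 0, weight_matrix / row_sums, 0.0)
    shifts = norm @ truth.effects.to_numpy(dtype=float)  # sites x conditions
    shift_by_cond = dict(zip(truth.effects.columns, shifts.T))

    columns: dict[tuple[str, int, int], np.ndarray] = {}
    for treatment in params.treatments:
        for duration in params.durations:
            cond_shift = (
                np.zeros(params.n_sites)
                if treatment == "vehicle"
                else shift_by_cond[(treatment, duration)]
            )
            for rep in range(1, params.replicates + 1):
                noise = rng.normal(0.0, params.noise_sd, size=params.n_sites)
                columns[(treatment, duration, rep)] = (
                    params.baseline_intensity + offsets + cond_shift + noise
                )
    values = pd.DataFrame(columns, index=pd.Index(site_ids, name="site_id"))
    values.columns = pd.MultiIndex.from_tuples(
        list(columns), names=("treatment", "duration_min", "replicate")
    )
    return ReplicateIntensityTable(chip_type=params.chip_type, values=values)


def mask_substrates(
    intensities: ReplicateIntensityTable,
    site_ids: Sequence[str],
    treatment: str,
    duration: int,
) -> ReplicateIntensityTable:
    """Mark selected sites missing in one (treatment, duration) sample —
    how "kinase not found" cells arise in real per-condition QC."""
    values = intensities.values.copy()
    cols = [
        c for c in values.columns if c[0] == treatment and int(c[1]) == int(duration)
    ]
    values.loc[list(site_ids), cols] = np.nan
    return ReplicateIntensityTable(chip_type=intensities.chip_type, values=values)


def run_pipeline(
    params: SimulationParams,
    n_active: int,
    delta: float,
    cfg: MappingConfig | None = None,
):
    """Simulate one experiment and run it through the full analysis.

    Returns ``(scores, truth, fc, ksmap)``: the vehicle-baselined kinase
    score table, the injected truth, the fold-change matrix and the
    substrate map used.
    """
    cfg = cfg or MappingConfig(params.chip_type)
    preds = simulate_prediction_table(params)
    truth = simulate_truth(params, n_active=n_active, delta=delta)
    intensities = simulate_intensities(params, preds, truth)
    fc = compute_fold_changes(intensities)
    ksmap = build_map(
        filter_predictions(merge_sources(preds), cfg),
        array_sites=list(fc.log2fc.index),
        cfg=cfg,
    )
    scores = score_all(fc, ksmap)
    return scores, truth, fc, ksmap


@dataclass
class RecoveryReport:
    """Per-run recovery metrics of injected kinase activities.

    sensitivity
        Fraction of injected (kinase, condition) entries scored at
        p < alpha with the correct sign, per run.
    false_positive_rate
        Fraction of uninjected, non-missing scores with p < alpha, per run.
    mean_injected_rank
        Mean normalized rank (0 = most significant) of injected entries
        within their condition column, per run.
    """

    sensitivity: np.ndarray
    false_positive_rate: np.ndarray
    mean_injected_rank: np.ndarray
    alpha: float

    @property
    def n_runs(self) -> int:
        return len(self.false_positive_rate)

    @property
    def mean_sensitivity(self) -> float:
        return float(np.nanmean(self.sensitivity))

    @property
    def mean_false_positive_rate(self) -> float:
        return float(np.mean(self.false_positive_rate))


def recovery_experiment(
    params: SimulationParams,
    n_active: int,
    delta: float,
    n_runs: int,
    alpha: float = DEFAULT_ALPHA,
) -> RecoveryReport:
    """Run the full simulate-map-score pipeline ``n_runs`` times with
    derived seeds and measure recovery of the injected activities."""
    if n_runs < 1:
        raise ContractError("n_runs must be >= 1")
    run_seeds = np.random.default_rng([int(params.seed), _STREAMS["runs"]]).integers(
        0, 2**31 - 1, size=n_runs
    )
    sens = np.full(n_runs, np.nan)
    fpr = np.zeros(n_runs)
    ranks = np.full(n_runs, np.nan)
    for r in range(n_runs):
        run_params = dataclasses.replace(params, seed=int(run_seeds[r]))
        scores, truth, _fc, _ksmap = run_pipeline(run_params, n_active=n_active, delta=delta)
        df = scores.scores.set_index(["kinase", "treatment", "duration_min"])

        injected = truth.effects[truth.effects != 0.0].stack([0, 1], future_stack=True).dropna()
        hits = 0
        rank_vals: list[float] = []
        for (kinase, treatment, duration), effect in injected.items():
            key = (kinase, treatment, int(duration))
            if key not in df.index:
                continue
            row = df.loc[key]
            if (
                not bool(row["missing"])
                and row["p_value"] < alpha
                and np.sign(row["z"]) == np.sign(effect)
            ):
                hits += 1
        if len(injected):
            sens[r] = hits / len(injected)

        null_flags: list[bool] = []
        for (kinase, treatment, duration), row in df.iterrows():
            if bool(row["missing"]):
                continue
            effect = truth.effect(kinase, treatment, int(duration))
            if effect == 0.0:
                null_flags.append(bool(row["p_value"] < alpha))
        fpr[r] = float(np.mean(null_flags)) if null_flags else 0.0

        # normalized rank of injected entries by ascending p within column
        per_cond = scores.scores.copy()
        per_cond["p_rank"] = per_cond.groupby(["treatment", "duration_min"])["p_value"].rank(
            method="average", na_option="bottom"
        )
        n_kin = per_cond["kinase"].nunique()
        for (kinase, treatment, duration), _effect in injected.items():
            sel = per_cond[
                (per_cond["kinase"] == kinase)
                & (per_cond["treatment"] == treatment)
                & (per_cond["duration_min"] == int(duration))
            ]
            if len(sel):
                rank_vals.append(float(sel["p_rank"].iloc[0] - 1) / max(n_kin - 1, 1))
        if rank_vals:
            ranks[r] = float(np.mean(rank_vals))
    return RecoveryReport(
        sensitivity=sens, false_positive_rate=fpr, mean_injected_rank=ranks, alpha=alpha
    )
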