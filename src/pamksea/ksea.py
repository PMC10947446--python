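"""Weighted kinase-substrate enrichment scoring.

For each kinase and condition the statistic is a weighted KSEA z score,

    s_w = sum_i(x_i * log2FC_i) / sum_i(x_i)
    Z   = (s_w - p_bar) * sqrt(m) / SD

where the x_i are kinase-substrate prediction scores (PhosphoNET V2 scale),
log2FC_i the substrate fold changes, m the number of substrates with a
measured fold change in that condition, and p_bar / SD the mean and sample
standard deviation of the fold changes of *all* phosphosites in the same
condition column.  Weighting by prediction score lets better-supported
substrates dominate the enrichment estimate; with equal weights the
statistic reduces exactly to classic (unweighted) KSEA.

Significance is a one-tail normal test on the score's own direction:
p = P(N(0,1) >= |z|).  Because the tail is taken in the direction of the
observed score, a nominal p < alpha flags |z| above the upper alpha
quantile, i.e. about 2*alpha of truly null scores — see docs/methods.md.
Raw p-values drive the reported significance markers; a Benjamini-Hochberg
adjusted column is emitted alongside for users who want multiplicity
control.

p_bar and SD are computed per condition column within one chip's dataset,
which makes z invariant to shifting a column by any constant or scaling it
by any positive constant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ContractError, DegenerateDataError, DesignError
from .io import FoldChangeMatrix, KinaseScoreTable, ReplicateIntensityTable
from .mapping import KinaseSubstrateMap

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class GlobalStats:
    """Per-condition background statistics over all phosphosites."""

    mean: pd.Series          # p_bar per condition column
    sd: pd.Series            # sample standard deviation (n-1 denominator)
    n_sites_used: pd.Series  # non-missing site count per column


def compute_fold_changes(
    intensities: ReplicateIntensityTable,
    baseline_treatment: str = "vehicle",
    treatments: Sequence[str] | None = None,
) -> FoldChangeMatrix:
    """Mean log2 fold change of each treatment against the matched baseline.

    For every non-baseline (treatment, duration), the fold change of a site
    is the mean of its treatment replicates minus the mean of the
    duration-matched baseline replicates (values are already on the log2
    scale).  A site missing one replicate is averaged over the remaining
    ones; a site with no measurement in either arm is missing in that
    column.  Columns that end up entirely missing are dropped with a
    warning.

    ``baseline_treatment`` defaults to the vehicle control; passing a
    treatment name (e.g. ``"ex4"``) normalizes directly against that arm
    instead, which is how rebaselined contrasts can be cross-checked from
    raw intensities.
    """
    samples = intensities.samples
    durations = intensities.durations
    for duration in durations:
        if (baseline_treatment, duration) not in samples:
            raise DesignError(
                f"no {baseline_treatment!r} sample at duration {duration} min"
            )
    columns: dict[tuple[str, int], pd.Series] = {}
    for duration in durations:
        base = intensities.replicate_columns(baseline_treatment, duration)
        base_mean = base.mean(axis=1, skipna=True)
        for treatment, dur in samples:
            if dur != duration or treatment == baseline_treatment:
                continue
            if treatments is not None and treatment not in treatments:
                continue
            arm = intensities.replicate_columns(treatment, duration)
            fc = arm.mean(axis=1, skipna=True) - base_mean
            if fc.isna().all():
                logger.warning(
                    "condition (%s, %d) is entirely missing; column dropped",
                    treatment, duration,
                )
                continue
            columns[(treatment, duration)] = fc
    log2fc = pd.DataFrame(columns)
    log2fc.columns = pd.MultiIndex.from_tuples(
        list(columns), names=("treatment", "duration_min")
    )
    return FoldChangeMatrix(
        chip_type=intensities.chip_type,
        baseline=baseline_treatment,
        log2fc=log2fc,
    )


def global_stats(fc: FoldChangeMatrix) -> GlobalStats:
    """Per-column mean and sample standard deviation over all phosphosites.

    Raises
    ------
    DegenerateDataError
        A column has fewer than 2 measured sites or zero variance.
    """
    means, sds, counts = {}, {}, {}
    for col in fc.log2fc.columns:
        vals = fc.log2fc[col].dropna()
        if len(vals) < 2:
            raise DegenerateDataError(
                f"column {tuple(col)} has {len(vals)} measured site(s); need >= 2"
            )
        sd = float(vals.std(ddof=1))
        if sd == 0.0:
            raise DegenerateDataError(f"column {tuple(col)} has zero variance")
        means[col] = float(vals.mean())
        sds[col] = sd
        counts[col] = int(len(vals))
    index = fc.log2fc.columns
    return GlobalStats(
        mean=pd.Series(means, index=index),
        sd=pd.Series(sds, index=index),
        n_sites_used=pd.Series(counts, index=index),
    )


def weighted_mean(fc_values: Sequence[float], weights: Sequence[float]) -> float:
    """s_w: prediction-score-weighted mean of substrate fold changes."""
    x = np.asarray(fc_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape or x.ndim != 1 or len(x) < 1:
        raise ContractError("fc_values and weights must be equal-length, non-empty 1-d")
    if (w <= 0).any():
        raise ContractError("all weights must be > 0")
    return float(np.dot(w, x) / w.sum())


def kinase_z(s_w: float, p_bar: float, sd: float, m: int) -> float:
    """Weighted KSEA z score: (s_w - p_bar) * sqrt(m) / sd."""
    if m < 1:
        raise ContractError("m must be >= 1")
    if sd <= 0:
        raise ContractError("sd must be > 0")
    return (s_w - p_bar) * math.sqrt(m) / sd


def one_tail_p(z: float) -> float:
    """One-tail normal p-value in the direction of the observed score.

    Returns the standard-normal upper-tail probability of ``|z|`` — the
    probability of a score at least as extreme as the one measured, in the
    score's own direction.  Symmetric: ``one_tail_p(z) == one_tail_p(-z)``.
    """
    if not math.isfinite(z):
        raise ContractError("z must be finite")
    return float(stats.norm.sf(abs(z)))


def score_all(fc: FoldChangeMatrix, ksmap: KinaseSubstrateMap) -> KinaseScoreTable:
    """Score every (kinase, condition) pair of a fold-change matrix.

    Per condition column, each kinase's substrate set is restricted to
    sites with a measured fold change and m is recomputed accordingly
    (missing values are never imputed).  Kinases with no usable substrate
    in a column yield a missing record — the "not found" state.  A
    Benjamini-Hochberg adjusted p-value is computed within each column
    over the non-missing kinases.
    """
    if ksmap.chip_type != fc.chip_type:
        raise ContractError(
            f"map chip type {ksmap.chip_type!r} != matrix chip type {fc.chip_type!r}"
        )
    gstats = global_stats(fc)
    weight_matrix = (
        ksmap.substrates.pivot(index="site_id", columns="kinase", values="weight")
        .reindex(fc.log2fc.index)
        .fillna(0.0)
    )
    kinases = list(weight_matrix.columns)
    W = weight_matrix.to_numpy(dtype=float)

    records: list[dict] = []
    for col in fc.log2fc.columns:
        treatment, duration = col
        f = fc.log2fc[col].to_numpy(dtype=float)
        valid = np.isfinite(f)
        Wv = W[valid]
        m = (Wv > 0).sum(axis=0)
        wsum = Wv.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            s_w = (Wv.T @ f[valid]) / wsum
        p_bar = gstats.mean[col]
        sd = gstats.sd[col]
        z = (s_w - p_bar) * np.sqrt(m) / sd
        p = stats.norm.sf(np.abs(z))
        for j, kinase in enumerate(kinases):
            if m[j] < 1:
                records.append(
                    dict(kinase=kinase, treatment=treatment, duration_min=int(duration),
                         m=np.nan, s_w=np.nan, z=np.nan, p_value=np.nan,
                         p_adj=np.nan, missing=True)
                )
            else:
                records.append(
                    dict(kinase=kinase, treatment=treatment, duration_min=int(duration),
                         m=int(m[j]), s_w=float(s_w[j]), z=float(z[j]),
                         p_value=float(p[j]), p_adj=np.nan, missing=False)
                )
    scores = pd.DataFrame.from_records(records)
    # BH adjustment within each condition column, non-missing kinases only
    for (_t, _d), idx in scores.groupby(["treatment", "duration_min"]).groups.items():
        sub = scores.loc[idx]
        ok = ~sub["missing"]
        if ok.any():
            _rej, p_adj, _a, _b = multipletests(
                sub.loc[ok, "p_value"].to_numpy(), method="fdr_bh"
            )
            scores.loc[sub.index[ok], "p_adj"] = p_adj
    return KinaseScoreTable(chip_type=fc.chip_type, baseline=fc.baseline, scores=scores)


def select_significant(scores: KinaseScoreTable, alpha: float = DEFAULT_ALPHA) -> list[str]:
    """Kinases with p < alpha in at least one condition, input order kept."""
    df = scores.scores
    hit = df.loc[~df["missing"] & (df["p_value"] < alpha), "kinase"]
    seen: dict[str, None] = {}
    order = {k: i for i, k in enumerate(dict.fromkeys(df["kinase"]))}
    for kinase in hit:
        seen[kinase] = None
    return sorted(seen, key=order.__getitem__)


def filter_by_expression(kinases: Sequence[str], allow_list: Sequence[str]) -> list[str]:
    """Keep kinases whose symbol appears in the expressed-gene allow-list.

    Matching is case-insensitive after whitespace stripping; input order is
    preserved and removed kinases are logged.  An empty allow-list is
    almost certainly a user mistake and raises :class:`DesignError`.
    """
    if len(allow_list) == 0:
        raise DesignError("allow-list is empty; refusing to drop every kinase")
    allowed = {s.strip().upper() for s in allow_list}
    kept: list[str] = []
    for kinase in kinases:
        if kinase.strip().upper() in allowed:
            kept.append(kinase)
        else:
            logger.info("kinase %s not in expression allow-list; removed", kinase)
    return kept
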