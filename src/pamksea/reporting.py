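"""Categorical reporting of kinase scores.

Scores are summarized the way kinome-profiling reports present them:

* arrow bins — z is discretized into symmetric bins of half-width 1.21
  (``-`` within +/-1.21, one arrow per further 1.21-wide band, capped at
  three arrows for |z| beyond 3.63);
* dot markers — ``•`` for p < .05, ``••`` for p < .01, ``•••`` for p < .001;
* family-grouped summary tables with ``✕`` marking kinases without a score
  in a condition;
* heatmap-ready numeric matrices (kinase x condition z values plus a
  parallel marker matrix);
* intersections of named kinase lists (e.g. pathway memberships), with
  per-region counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .io import DURATIONS, TREATMENTS, KinaseScoreTable

logger = logging.getLogger(__name__)

MISSING_SYMBOL = "✕"  # ✕ — kinase not found
NEUTRAL_SYMBOL = "-"
UP_ARROW = "↑"
DOWN_ARROW = "↓"
DOT = "•"

#: Canonical family ordering for summary tables; unknown families are
#: appended alphabetically, unannotated kinases fall under "Other".
FAMILY_ORDER = (
    "SRC", "RTK", "JAK", "TLK", "STE", "CK1", "AGC",
    "CAMK", "CMGC", "Other", "Atypical",
)


@dataclass(frozen=True)
class BinScheme:
    """Symmetric z-score binning with edges at +/- half_width * k.

    With the defaults (half_width 1.21, 3 levels) the labels and edges are
    ``-`` (-1.21, 1.21), ``↑`` [1.21, 2.42), ``↑↑`` [2.42, 3.63),
    ``↑↑↑`` [3.63, inf) and the mirrored down-arrow bins.  Positive bins
    are closed on the left and open on the right; negative bins are the
    mirror image.  |z| beyond the outermost edge maps to the outermost
    label.
    """

    half_width: float = 1.21
    n_levels: int = 3

    def __post_init__(self) -> None:
        if self.half_width <= 0 or self.n_levels < 1:
            raise ContractError("half_width must be > 0 and n_levels >= 1")

    @property
    def labels(self) -> tuple[str, ...]:
        down = [DOWN_ARROW * k for k in range(self.n_levels, 0, -1)]
        up = [UP_ARROW * k for k in range(1, self.n_levels + 1)]
        return tuple(down + [NEUTRAL_SYMBOL] + up)


def categorize(z: float | None, scheme: BinScheme | None = None) -> str:
    """Arrow-bin label for a z score; missing scores map to ``✕``.

    The bin index is ``min(n_levels, floor(|z| / half_width))`` with the
    sign of z choosing the arrow direction; a small tolerance keeps exact
    decimal edges like 2.42 on the correct side despite binary rounding.
    """
    scheme = scheme or BinScheme()
    if z is None or (isinstance(z, float) and math.isnan(z)):
        return MISSING_SYMBOL
    z = float(z)
    k = int(math.floor(abs(z) / scheme.half_width + 1e-9))
    k = min(k, scheme.n_levels)
    if k == 0:
        return NEUTRAL_SYMBOL
    return (UP_ARROW if z > 0 else DOWN_ARROW) * k


def significance_marker(p_value: float) -> str:
    """Dot marker for a p-value: most extreme strict threshold applies."""
    if not (0.0 < p_value <= 1.0):
        raise ContractError(f"p_value must lie in (0, 1], got {p_value}")
    if p_value < 0.001:
        return DOT * 3
    if p_value < 0.01:
        return DOT * 2
    if p_value < 0.05:
        return DOT
    return ""


def _condition_order(scores: pd.DataFrame) -> list[tuple[str, int]]:
    present = {(t, int(d)) for t, d in zip(scores["treatment"], scores["duration_min"])}
    ordered = [
        (t, d) for t in TREATMENTS for d in DURATIONS if (t, d) in present
    ]
    extras = sorted(present - set(ordered))
    return ordered + extras


def build_summary_table(
    scores: KinaseScoreTable,
    families: Mapping[str, str] | None = None,
    scheme: BinScheme | None = None,
) -> pd.DataFrame:
    """Family-grouped arrow-symbol summary, one column per condition.

    Rows are kinases grouped by family (canonical family order, then
    alphabetical); columns are named ``<treatment>_<duration>`` and hold
    the arrow label of the kinase's z in that condition, or ``✕`` where the
    kinase has no score.  Kinases missing in every column are omitted with
    a warning.
    """
    scheme = scheme or BinScheme()
    families = families or {}
    df = scores.scores
    conditions = _condition_order(df)
    z_wide = df.pivot(index="kinase", columns=["treatment", "duration_min"], values="z")

    rows = []
    for kinase in z_wide.index:
        zs = [z_wide.at[kinase, cond] if cond in z_wide.columns else np.nan
              for cond in conditions]
        if all(isinstance(v, float) and math.isnan(v) for v in zs):
            logger.warning("kinase %s has no score in any condition; omitted", kinase)
            continue
        row = {"family": families.get(kinase, "Other"), "kinase": kinase}
        for (treatment, duration), z in zip(conditions, zs):
            row[f"{treatment}_{duration}"] = categorize(z, scheme)
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    order = {f: i for i, f in enumerate(FAMILY_ORDER)}
    out = out.sort_values(
        by=["family", "kinase"],
        key=lambda col: (
            col.map(lambda f: (order.get(f, len(order)), f)) if col.name == "family" else col
        ),
        kind="mergesort",
    )
    return out.reset_index(drop=True)


def heatmap_matrix(scores: KinaseScoreTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kinase x condition z matrix plus the parallel marker matrix.

    Rows are ordered by descending mean |z| over measured conditions (ties
    broken by kinase symbol); kinases with no measured condition are
    excluded.  Returned column labels are ``<treatment>_<duration>``.
    """
    df = scores.scores
    if df.empty:
        raise ContractError("score table is empty")
    conditions = _condition_order(df)
    labels = [f"{t}_{d}" for t, d in conditions]
    z_wide = df.pivot(index="kinase", columns=["treatment", "duration_min"], values="z")
    p_wide = df.pivot(index="kinase", columns=["treatment", "duration_min"], values="p_value")
    z_wide = z_wide.reindex(columns=pd.MultiIndex.from_tuples(conditions))
    p_wide = p_wide.reindex(columns=pd.MultiIndex.from_tuples(conditions))
    z_wide.columns = labels
    p_wide.columns = labels

    keep = z_wide.notna().any(axis=1)
    z_wide, p_wide = z_wide[keep], p_wide[keep]
    strength = z_wide.abs().mean(axis=1, skipna=True)
    order = sorted(z_wide.index, key=lambda k: (-strength[k], k))
    z_wide = z_wide.loc[order]
    p_wide = p_wide.loc[order]
    markers = p_wide.map(
        lambda p: "" if (isinstance(p, float) and math.isnan(p)) else significance_marker(p)
    )
    return z_wide, markers


@dataclass
class IntersectionReport:
    """Membership counts per overlap region plus the common intersection."""

    region_counts: dict[tuple[str, ...], int]
    common: list[str]
    members: dict[tuple[str, ...], list[str]]


def intersect_kinase_lists(lists: Mapping[str, Sequence[str]]) -> IntersectionReport:
    """Venn-style intersection of named kinase lists.

    Each region is keyed by the tuple of list names (in input order) whose
    lists contain exactly that region's members.  Duplicates within a list
    are dropped with a warning; all orderings are deterministic
    (alphabetical members).
    """
    if len(lists) < 2:
        raise ContractError("need at least 2 named lists to intersect")
    clean: dict[str, list[str]] = {}
    for name, members in lists.items():
        deduped = list(dict.fromkeys(members))
        if len(deduped) < len(members):
            logger.warning("list %s contains duplicate kinases; deduplicated", name)
        clean[name] = deduped
    names = list(clean)
    membership: dict[str, tuple[str, ...]] = {}
    for kinase in dict.fromkeys(k for members in clean.values() for k in members):
        region = tuple(n for n in names if kinase in clean[n])
        membership[kinase] = region
    region_counts: dict[tuple[str, ...], int] = {}
    members: dict[tuple[str, ...], list[str]] = {}
    for kinase, region in membership.items():
        region_counts[region] = region_counts.get(region, 0) + 1
        members.setdefault(region, []).append(kinase)
    for region in members:
        members[region] = sorted(members[region])
    full = tuple(names)
    common = members.get(full, [])
    return IntersectionReport(region_counts=region_counts, common=common, members=members)
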