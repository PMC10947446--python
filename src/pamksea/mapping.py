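"""Build per-kinase weighted substrate sets from prediction tables.

The mapping step turns raw kinase-substrate prediction records into the
weighted substrate sets consumed by scoring.  Per phosphosite, only
predictions with a V2 score strictly above a threshold survive, and of
those at most the top-K kinases per site are kept (K = 25 for the tyrosine
array, 50 for the serine/threonine array) — ties at the K-th score are
broken by ascending kinase symbol so the filter is a total order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ContractError, DesignError
from .io import CHIP_TYPES, PredictionTable

logger = logging.getLogger(__name__)

#: Per-site cap on retained kinases, by chip type.
DEFAULT_TOP_K = {"PTK": 25, "STK": 50}
#: Minimum prediction V2 score (strict inequality).
DEFAULT_MIN_SCORE = 300.0
#: Priority used to break exact score ties between source databases.
SOURCE_PRIORITY = ("PhosphoNET", "UniProt", "PhosphoSite", "synthetic")


@dataclass
class MappingConfig:
    """Filter parameters for kinase-substrate mapping.

    Parameters
    ----------
    chip_type
        "PTK" or "STK"; sets the default ``top_k`` (25 / 50).
    top_k
        Maximum kinases retained per phosphosite.
    min_score
        Predictions must score strictly above this value.
    min_substrates
        Kinases mapping to fewer array substrates than this are dropped.
        The default of 1 keeps every mappable kinase; raise it to exclude
        statistically fragile single-substrate scores.
    """

    chip_type: str
    top_k: int | None = None
    min_score: float = DEFAULT_MIN_SCORE
    min_substrates: int = 1

    def __post_init__(self) -> None:
        if self.chip_type not in CHIP_TYPES:
            raise ContractError(f"unknown chip type {self.chip_type!r}")
        if self.top_k is None:
            self.top_k = DEFAULT_TOP_K[self.chip_type]
        if self.top_k < 1:
            raise ContractError("top_k must be >= 1")
        if self.min_score < 0:
            raise ContractError("min_score must be >= 0")
        if self.min_substrates < 1:
            raise ContractError("min_substrates must be >= 1")


@dataclass
class KinaseSubstrateMap:
    """Per-kinase weighted substrate sets restricted to the array.

    ``substrates`` has one row per (kinase, site_id) with the prediction
    score as weight; ``m`` counts a kinase's substrates present on the
    array.
    """

    chip_type: str
    substrates: pd.DataFrame  # columns: kinase, site_id, weight

    @property
    def kinases(self) -> list[str]:
        return sorted(self.substrates["kinase"].unique())

    @property
    def m(self) -> pd.Series:
        return self.substrates.groupby("kinase").size()

    def weights_for(self, kinase: str) -> pd.Series:
        sub = self.substrates[self.substrates["kinase"] == kinase]
        return pd.Series(sub["weight"].to_numpy(), index=sub["site_id"].to_numpy())

    def to_summary(self) -> pd.DataFrame:
        """Per-kinase summary: substrate count m and mean weight."""
        grouped = self.substrates.groupby("kinase")["weight"]
        return pd.DataFrame(
            {"kinase": grouped.mean().index, "m": grouped.size().to_numpy(),
             "mean_weight": grouped.mean().to_numpy()}
        ).reset_index(drop=True)


def merge_sources(preds: PredictionTable) -> PredictionTable:
    """Collapse multi-source duplicates to one record per (kinase, site).

    The maximum V2 score over sources is kept, so each substrate is counted
    once in the weighted mean while preserving the strongest evidence.
    Exact score ties are resolved by the fixed source priority
    (PhosphoNET > UniProt > PhosphoSite > synthetic).
    """
    df = preds.records.copy()
    if df.empty:
        return PredictionTable(records=df)
    rank = {s: i for i, s in enumerate(SOURCE_PRIORITY)}
    df["_rank"] = df["source"].map(lambda s: rank.get(s, len(rank)))
    df = df.sort_values(
        ["kinase", "site_id", "v2_score", "_rank"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).drop_duplicates(subset=["kinase", "site_id"], keep="first")
    return PredictionTable(records=df.drop(columns="_rank").reset_index(drop=True))


def filter_predictions(preds: PredictionTable, cfg: MappingConfig) -> PredictionTable:
    """Apply the per-phosphosite score threshold and top-K cap.

    Only records with ``v2_score > cfg.min_score`` survive (strict); of
    those, at most ``cfg.top_k`` kinases per site are retained, ordered by
    descending score with ties broken by ascending kinase symbol.  The
    operation is idempotent.
    """
    df = preds.records
    df = df[df["v2_score"] > cfg.min_score]
    if df.empty:
        logger.warning("no predictions survive the score filter (> %s)", cfg.min_score)
        return PredictionTable(records=df.reset_index(drop=True))
    df = df.sort_values(
        ["site_id", "v2_score", "kinase"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    df = df.groupby("site_id", sort=False).head(cfg.top_k)
    return PredictionTable(records=df.reset_index(drop=True))


def build_map(
    preds: PredictionTable,
    array_sites: Sequence[str],
    cfg: MappingConfig,
) -> KinaseSubstrateMap:
    """Restrict filtered, merged predictions to the array's phosphosites.

    Kinases whose surviving substrate count falls below
    ``cfg.min_substrates`` are dropped with a logged warning naming them.

    Raises
    ------
    DesignError
        If ``array_sites`` is empty.
    """
    if len(array_sites) == 0:
        raise DesignError("array_sites is empty; nothing to map against")
    sites = set(array_sites)
    df = preds.records[preds.records["site_id"].isin(sites)]
    df = df.rename(columns={"v2_score": "weight"})[["kinase", "site_id", "weight"]]
    counts = df.groupby("kinase").size()
    dropped = sorted(set(preds.records["kinase"].unique()) - set(counts.index))
    too_few = sorted(counts.index[counts < cfg.min_substrates])
    for kinase in dropped:
        logger.warning("kinase %s has no predicted substrate on the array; excluded", kinase)
    for kinase in too_few:
        logger.warning(
            "kinase %s maps to %d substrate(s) < min_substrates=%d; excluded",
            kinase, counts[kinase], cfg.min_substrates,
        )
    keep = counts.index[counts >= cfg.min_substrates]
    df = df[df["kinase"].isin(set(keep))]
    df = df.sort_values(["kinase", "site_id"], kind="mergesort").reset_index(drop=True)
    return KinaseSubstrateMap(chip_type=cfg.chip_type, substrates=df)
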