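"""Tabular I/O for kinome-array artifacts.

All artifacts are UTF-8 comma-separated text with a mandatory header row.
Missing values are written as the token ``NA`` and only that token is read
back as missing — readers never coerce missing cells to zero.  Real numbers
are serialized with 12 significant digits so that write-then-read round
trips are exact to well below test tolerances.  Matrix-shaped files carry
leading ``#key=value`` metadata lines recording the chip type and the
fold-change baseline.

Containers
----------
:class:`ReplicateIntensityTable`
    Per-replicate log2 fluorescence intensities, phosphosites x
    (treatment, duration, replicate).
:class:`FoldChangeMatrix`
    Phosphosites x (treatment, duration) log2 fold changes together with
    the baseline they are normalized against (vehicle or a reference
    agonist).
:class:`PredictionTable`
    Kinase-substrate prediction records (kinase, phosphosite, V2 score,
    source database).
:class:`KinaseScoreTable`
    Per (kinase, treatment, duration) enrichment scores: substrate count m,
    weighted mean fold change s_w, z score, one-tail p-value.

Phosphosite identifiers are opaque strings matched exactly (case-sensitive)
between fold-change matrices and prediction tables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Treatments of the underlying experimental design: vehicle control, the
#: balanced reference agonist exendin-4 and its two biased derivatives.
TREATMENTS = ("vehicle", "ex4", "phe1", "asp3")
#: Stimulation durations in minutes (acute / sustained).
DURATIONS = (10, 120)
#: Chip types: protein tyrosine kinase and serine/threonine kinase arrays.
CHIP_TYPES = ("PTK", "STK")
#: Number of unique substrate peptides per chip type.
CHIP_SIZES = {"PTK": 196, "STK": 144}
#: Recognized prediction-score source databases.
SOURCES = ("PhosphoNET", "UniProt", "PhosphoSite", "synthetic")

NA_TOKEN = "NA"
FLOAT_FORMAT = "%.12g"

_INTENSITY_COL_RE = re.compile(r"^([A-Za-z0-9]+)_(\d+)_r(\d+)$")
_FC_COL_RE = re.compile(r"^([A-Za-z0-9]+)_(\d+)$")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ReplicateIntensityTable:
    """Log2 intensities indexed by phosphosite with one column per
    (treatment, duration_min, replicate) cell."""

    chip_type: str
    values: pd.DataFrame  # columns: MultiIndex (treatment, duration, replicate)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.chip_type not in CHIP_TYPES:
            raise ValidationError(f"unknown chip type {self.chip_type!r}")
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate phosphosite id {dup!r}")
        cols = self.values.columns
        if cols.nlevels != 3:
            raise FormatError("intensity columns must be (treatment, duration, replicate)")
        for treatment, duration, _rep in cols:
            if treatment not in TREATMENTS:
                raise FormatError(f"unknown treatment {treatment!r}")
            if int(duration) not in DURATIONS:
                raise FormatError(f"unknown duration {duration!r}")
        for treatment, duration in self.samples:
            n_rep = self.replicate_columns(treatment, duration).shape[1]
            if n_rep < 2:
                raise DesignError(
                    f"sample ({treatment}, {duration}) has {n_rep} replicate(s); need >= 2"
                )
        for duration in self.durations:
            if ("vehicle", duration) not in self.samples:
                raise DesignError(f"no vehicle sample at duration {duration} min")

    @property
    def samples(self) -> list[tuple[str, int]]:
        seen: dict[tuple[str, int], None] = {}
        for treatment, duration, _rep in self.values.columns:
            seen[(treatment, int(duration))] = None
        return list(seen)

    @property
    def durations(self) -> list[int]:
        return sorted({d for _, d in self.samples})

    def replicate_columns(self, treatment: str, duration: int) -> pd.DataFrame:
        """All replicate columns of one (treatment, duration) sample."""
        mask = [
            t == treatment and int(d) == int(duration)
            for t, d, _r in self.values.columns
        ]
        return self.values.loc[:, mask]

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())


@dataclass
class FoldChangeMatrix:
    """Phosphosite x condition matrix of log2 fold changes.

    ``baseline`` records what the columns are normalized against:
    ``"vehicle"`` for the standard contrast, or a treatment name (e.g.
    ``"ex4"``) after rebaselining against a reference agonist, so the two
    kinds of matrix are never confusable.
    """

    chip_type: str
    baseline: str
    log2fc: pd.DataFrame  # columns: MultiIndex (treatment, duration)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.chip_type not in CHIP_TYPES:
            raise ValidationError(f"unknown chip type {self.chip_type!r}")
        if self.baseline != "vehicle" and self.baseline not in TREATMENTS:
            raise ValidationError(f"unknown baseline {self.baseline!r}")
        idx = self.log2fc.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate phosphosite id {dup!r}")
        if self.log2fc.columns.has_duplicates:
            raise FormatError("duplicate (treatment, duration) column")
        with np.errstate(invalid="ignore"):
            bad = np.isinf(self.log2fc.to_numpy(dtype=float, na_value=np.nan))
        if bad.any():
            raise ValidationError("non-finite log2FC value (use NA for missing)")

    @property
    def conditions(self) -> list[tuple[str, int]]:
        return [(t, int(d)) for t, d in self.log2fc.columns]

    @property
    def n_missing(self) -> int:
        return int(self.log2fc.isna().sum().sum())


@dataclass
class PredictionTable:
    """Kinase-substrate prediction records.

    One row per (kinase, phosphosite, source) with a nonnegative prediction
    score (PhosphoNET V2 scale).  Uniqueness of (kinase, phosphosite,
    source) is enforced; the same pair may appear under several sources
    until :func:`pamksea.mapping.merge_sources` resolves them.
    """

    records: pd.DataFrame  # columns: kinase, site_id, v2_score, source

    REQUIRED = ("kinase", "site_id", "v2_score")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.records
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"prediction table missing column(s) {missing}")
        if "source" not in df.columns:
            df["source"] = "PhosphoNET"
        if len(df) and (df["v2_score"].to_numpy(dtype=float) < 0).any():
            bad = df.loc[df["v2_score"] < 0].iloc[0]
            raise ValidationError(
                f"negative prediction score {bad['v2_score']} for "
                f"({bad['kinase']}, {bad['site_id']})"
            )
        if df.duplicated(subset=["kinase", "site_id", "source"]).any():
            raise ValidationError("duplicate (kinase, site_id, source) record")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class KinaseScoreTable:
    """Long-format kinase enrichment scores.

    Columns of ``scores``: kinase, treatment, duration_min, m, s_w, z,
    p_value, p_adj, missing.  A ``missing`` row (no usable substrate in
    that condition) carries NA for every statistic — the "kinase not
    found" state in summary tables.
    """

    chip_type: str
    baseline: str
    scores: pd.DataFrame

    COLUMNS = ("kinase", "treatment", "duration_min", "m", "s_w", "z", "p_value", "p_adj", "missing")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.scores
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"score table missing column(s) {missing}")
        ok = ~df["missing"].astype(bool)
        if len(df[ok]):
            p = df.loc[ok, "p_value"].to_numpy(dtype=float)
            if np.isnan(p).any() or (p <= 0).any() or (p >= 1).any():
                raise ValidationError("p_value outside (0, 1) in non-missing row")
            m = df.loc[ok, "m"].to_numpy(dtype=float)
            if (m < 1).any():
                raise ValidationError("m < 1 in non-missing row")
            z = df.loc[ok, "z"].to_numpy(dtype=float)
            if not np.isfinite(z).all():
                raise ValidationError("non-finite z in non-missing row")

    def __len__(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------


def _read_meta_and_csv(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    """Read leading '#key=value' lines, then the CSV body."""
    path = Path(path)
    meta: dict[str, str] = {}
    n_meta = 0
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    df = pd.read_csv(
        path,
        skiprows=n_meta,
        na_values=[NA_TOKEN],
        keep_default_na=False,
        dtype={"site_id": str, "kinase": str},
        encoding="utf-8",
    )
    return meta, df


def _write_csv(df: pd.DataFrame, path: str | Path, meta: Mapping[str, str] | None = None,
               index: bool = False) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"#{key}={value}\n")
        df.to_csv(fh, index=index, na_rep=NA_TOKEN, float_format=FLOAT_FORMAT)


def _check_duplicate_sites(site_ids: pd.Series) -> None:
    dup = site_ids[site_ids.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate phosphosite id {dup.iloc[0]!r}")


# ---------------------------------------------------------------------------
# intensity tables
# ---------------------------------------------------------------------------


def read_intensity_table(path: str | Path, chip_type: str) -> ReplicateIntensityTable:
    """Read a replicate-level log2 intensity CSV.

    Expected header: ``site_id`` followed by one column per sample
    replicate named ``<treatment>_<duration>_r<k>`` (e.g. ``ex4_10_r1``).

    Raises
    ------
    FormatError
        Duplicate phosphosite id or unparsable column name.
    DesignError
        No vehicle sample for one of the durations present.
    """
    _meta, df = _read_meta_and_csv(path)
    if "site_id" not in df.columns:
        raise FormatError(f"{path}: first column must be 'site_id'")
    _check_duplicate_sites(df["site_id"])
    tuples: list[tuple[str, int, int]] = []
    for col in df.columns:
        if col == "site_id":
            continue
        match = _INTENSITY_COL_RE.match(col)
        if not match:
            raise FormatError(f"{path}: cannot parse sample column {col!r}")
        tuples.append((match.group(1), int(match.group(2)), int(match.group(3))))
    values = df.set_index("site_id").astype(float)
    values.columns = pd.MultiIndex.from_tuples(
        tuples, names=("treatment", "duration_min", "replicate")
    )
    return ReplicateIntensityTable(chip_type=chip_type, values=values)


def write_intensity_table(table: ReplicateIntensityTable, path: str | Path) -> None:
    """Write a :class:`ReplicateIntensityTable` in the documented dialect."""
    flat = table.values.copy()
    flat.columns = [f"{t}_{int(d)}_r{int(r)}" for t, d, r in flat.columns]
    flat.index.name = "site_id"
    _write_csv(flat, path, meta={"chip_type": table.chip_type}, index=True)


# ---------------------------------------------------------------------------
# fold-change matrices
# ---------------------------------------------------------------------------


def read_fold_changes(path: str | Path) -> FoldChangeMatrix:
    """Read a fold-change matrix CSV.

    The file carries ``#chip_type=`` and ``#baseline=`` metadata lines;
    data columns are named ``<treatment>_<duration>``.
    """
    meta, df = _read_meta_and_csv(path)
    if "baseline" not in meta or "chip_type" not in meta:
        raise FormatError(f"{path}: missing '#baseline=' / '#chip_type=' metadata line")
    if "site_id" not in df.columns:
        raise FormatError(f"{path}: first column must be 'site_id'")
    _check_duplicate_sites(df["site_id"])
    tuples: list[tuple[str, int]] = []
    for col in df.columns:
        if col == "site_id":
            continue
        match = _FC_COL_RE.match(col)
        if not match:
            raise FormatError(f"{path}: cannot parse condition column {col!r}")
        tuples.append((match.group(1), int(match.group(2))))
    values = df.set_index("site_id").astype(float)
    values.columns = pd.MultiIndex.from_tuples(tuples, names=("treatment", "duration_min"))
    return FoldChangeMatrix(chip_type=meta["chip_type"], baseline=meta["baseline"], log2fc=values)


def write_fold_changes(fc: FoldChangeMatrix, path: str | Path) -> None:
    flat = fc.log2fc.copy()
    flat.columns = [f"{t}_{int(d)}" for t, d in flat.columns]
    flat.index.name = "site_id"
    _write_csv(flat, path, meta={"chip_type": fc.chip_type, "baseline": fc.baseline}, index=True)


# ---------------------------------------------------------------------------
# prediction tables
# ---------------------------------------------------------------------------

_PREDICTION_COLUMNS = {"kinase", "site_id", "v2_score", "source"}


def read_prediction_table(path: str | Path) -> PredictionTable:
    """Read kinase-substrate predictions (columns kinase, site_id,
    v2_score[, source]).

    Negative scores raise :class:`ValidationError`; unknown columns raise
    :class:`FormatError`.  An empty body (header only) yields an empty
    table with a logged warning.
    """
    _meta, df = _read_meta_and_csv(path)
    unknown = set(df.columns) - _PREDICTION_COLUMNS
    if unknown:
        raise FormatError(f"{path}: unknown prediction column(s) {sorted(unknown)}")
    missing = [c for c in PredictionTable.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing prediction column(s) {missing}")
    if df.empty:
        logger.warning("%s: prediction table is empty", path)
    df = df.copy()
    df["v2_score"] = df["v2_score"].astype(float)
    return PredictionTable(records=df.reset_index(drop=True))


def write_prediction_table(preds: PredictionTable, path: str | Path) -> None:
    _write_csv(preds.records[["kinase", "site_id", "v2_score", "source"]], path)


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------


def write_score_table(table: KinaseScoreTable, path: str | Path,
                      families: Mapping[str, str] | None = None) -> None:
    """Write a score table with per-row arrow categories and dot markers.

    Output columns: kinase[, family], treatment, duration, m, s_w, z,
    p_value, p_adj, category, marker.  A 0-row table is an error.
    """
    # deferred import: reporting consumes the containers defined above
    from .reporting import BinScheme, categorize, significance_marker

    if len(table) == 0:
        raise ValidationError("refusing to write an empty score table")
    scheme = BinScheme()
    df = table.scores.copy()
    out = pd.DataFrame({"kinase": df["kinase"]})
    if families is not None:
        out["family"] = [families.get(k, "Other") for k in df["kinase"]]
    out["treatment"] = df["treatment"]
    out["duration"] = df["duration_min"].astype(int)
    out["m"] = df["m"].astype("Int64")
    out["s_w"] = df["s_w"]
    out["z"] = df["z"]
    out["p_value"] = df["p_value"]
    out["p_adj"] = df["p_adj"]
    out["category"] = [categorize(z, scheme) for z in df["z"]]
    out["marker"] = [
        "" if not np.isfinite(p) else significance_marker(p) for p in df["p_value"]
    ]
    _write_csv(out, path, meta={"chip_type": table.chip_type, "baseline": table.baseline})


def read_score_table(path: str | Path) -> KinaseScoreTable:
    """Read back a score table written by :func:`write_score_table`."""
    meta, df = _read_meta_and_csv(path)
    if "baseline" not in meta or "chip_type" not in meta:
        raise FormatError(f"{path}: missing metadata lines")
    scores = pd.DataFrame(
        {
            "kinase": df["kinase"].astype(str),
            "treatment": df["treatment"].astype(str),
            "duration_min": df["duration"].astype(int),
            "m": df["m"].astype(float),
            "s_w": df["s_w"].astype(float),
            "z": df["z"].astype(float),
            "p_value": df["p_value"].astype(float),
            "p_adj": df["p_adj"].astype(float),
        }
    )
    scores["missing"] = scores["z"].isna()
    return KinaseScoreTable(chip_type=meta["chip_type"], baseline=meta["baseline"], scores=scores)


# ---------------------------------------------------------------------------
# allow-lists and family annotations
# ---------------------------------------------------------------------------


def read_allow_list(path: str | Path) -> list[str]:
    """Read an expressed-gene allow-list: one symbol per line, '#' comments."""
    symbols: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.append(line)
    return symbols


def write_allow_list(symbols: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(symbols) + "\n", encoding="utf-8")


def read_family_annotation(path: str | Path) -> dict[str, str]:
    """Read a kinase -> family CSV (columns kinase, family)."""
    _meta, df = _read_meta_and_csv(path)
    for col in ("kinase", "family"):
        if col not in df.columns:
            raise FormatError(f"{path}: family annotation needs column {col!r}")
    return dict(zip(df["kinase"].astype(str), df["family"].astype(str)))
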