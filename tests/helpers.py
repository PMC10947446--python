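"""Shared test utilities: container builders and an independent
brute-force oracle for the weighted enrichment statistic.

The oracle is deliberately written with plain Python loops, the
``statistics`` module and ``math.erfc`` so it shares no code path with the
implementation it checks.
"""

from __future__ import annotations

import math
import random
import statistics

import pandas as pd

import pamksea as pk

# ---------------------------------------------------------------------------
# container builders
# ---------------------------------------------------------------------------


def make_intensity(sites, columns, chip="PTK"):
    """columns: {(treatment, duration, replicate): [values per site]}."""
    df = pd.DataFrame(
        {k: list(v) for k, v in columns.items()},
        index=pd.Index(list(sites), name="site_id"),
        dtype=float,
    )
    df.columns = pd.MultiIndex.from_tuples(
        list(columns), names=("treatment", "duration_min", "replicate")
    )
    return pk.ReplicateIntensityTable(chip_type=chip, values=df)


def make_fc(sites, columns, chip="PTK", baseline="vehicle"):
    """columns: {(treatment, duration): [values per site, None = missing]}."""
    df = pd.DataFrame(
        {k: [float("nan") if v is None else float(v) for v in vals]
         for k, vals in columns.items()},
        index=pd.Index(list(sites), name="site_id"),
        dtype=float,
    )
    df.columns = pd.MultiIndex.from_tuples(
        list(columns), names=("treatment", "duration_min")
    )
    return pk.FoldChangeMatrix(chip_type=chip, baseline=baseline, log2fc=df)


def make_map(entries, chip="PTK"):
    """entries: iterable of (kinase, site_id, weight)."""
    df = pd.DataFrame(entries, columns=["kinase", "site_id", "weight"])
    return pk.KinaseSubstrateMap(chip_type=chip, substrates=df)


def make_predictions(entries):
    """entries: iterable of (kinase, site_id, v2_score[, source])."""
    rows = []
    for entry in entries:
        kinase, site, score, *rest = entry
        rows.append(
            {"kinase": kinase, "site_id": site, "v2_score": float(score),
             "source": rest[0] if rest else "PhosphoNET"}
        )
    return pk.PredictionTable(records=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def oracle_sf(x):
    """Standard-normal upper-tail probability via the error function."""
    return 0.5 * math.erfc(x / math.sqrt(2.0))


def oracle_scores(fc_cols, substrate_map):
    """Recompute every (kinase, condition) statistic from scratch.

    fc_cols: {condition: {site: value or None}};
    substrate_map: {kinase: {site: weight}}.
    Returns {(kinase, condition): None (missing) or (m, s_w, z, p)}.
    """
    out = {}
    for cond, site_vals in fc_cols.items():
        measured = {s: v for s, v in site_vals.items() if v is not None}
        values = list(measured.values())
        p_bar = statistics.fmean(values)
        sd = statistics.stdev(values)  # n-1 denominator
        for kinase, subs in substrate_map.items():
            pairs = [(w, measured[s]) for s, w in subs.items() if s in measured]
            if not pairs:
                out[(kinase, cond)] = None
                continue
            m = len(pairs)
            s_w = sum(w * v for w, v in pairs) / sum(w for w, _ in pairs)
            z = (s_w - p_bar) * math.sqrt(m) / sd
            out[(kinase, cond)] = (m, s_w, z, oracle_sf(abs(z)))
    return out


_CONDITIONS = [(t, d) for t in ("ex4", "phe1", "asp3") for d in (10, 120)]


def random_instance(rng: random.Random, max_sites=30, max_kinases=10, missing_prob=0.1):
    """Random small scoring instance: fold-change columns with occasional
    missing cells plus a random weighted substrate map."""
    n_sites = rng.randint(5, max_sites)
    n_kinases = rng.randint(1, max_kinases)
    n_cols = rng.randint(1, len(_CONDITIONS))
    sites = [f"S{i:03d}" for i in range(n_sites)]
    conds = rng.sample(_CONDITIONS, n_cols)
    fc_cols = {}
    for cond in conds:
        col = {}
        for s in sites:
            col[s] = None if rng.random() < missing_prob else rng.gauss(0.0, 0.5)
        # keep >= 2 measured and non-constant
        measured = [s for s in sites if col[s] is not None]
        while len(measured) < 2:
            s = rng.choice(sites)
            col[s] = rng.gauss(0.0, 0.5)
            measured = [s for s in sites if col[s] is not None]
        fc_cols[cond] = col
    substrate_map = {}
    for k in range(n_kinases):
        m = rng.randint(1, min(8, n_sites))
        chosen = rng.sample(sites, m)
        substrate_map[f"K{k:02d}"] = {s: rng.uniform(301.0, 1000.0) for s in chosen}
    return sites, fc_cols, substrate_map


def instance_to_objects(sites, fc_cols, substrate_map, chip="PTK"):
    fc = make_fc(sites, {c: [fc_cols[c][s] for s in sites] for c in fc_cols}, chip=chip)
    entries = [
        (kinase, site, weight)
        for kinase, subs in substrate_map.items()
        for site, weight in subs.items()
    ]
    return fc, make_map(entries, chip=chip)


def assert_scores_match_oracle(scores, oracle, tol=1e-10):
    """Compare a KinaseScoreTable against the brute-force oracle output."""
    df = scores.scores.set_index(["kinase", "treatment", "duration_min"])
    assert len(df) == len(oracle)
    for (kinase, cond), expected in oracle.items():
        row = df.loc[(kinase, cond[0], cond[1])]
        if expected is None:
            assert bool(row["missing"])
            continue
        m, s_w, z, p = expected
        assert not bool(row["missing"])
        assert int(row["m"]) == m
        assert abs(row["s_w"] - s_w) < tol
        assert abs(row["z"] - z) < tol
        assert abs(row["p_value"] - p) < tol
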