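"""Paired tumor/normal differential expression and summaries.

Per cancer type (with at least ``min_pairs`` complete tumor/normal pairs),
each feature gets a paired Student's t-test on log2 normalized expression;
p-values are Benjamini-Hochberg adjusted across features within the cancer
type.  A feature is called up if its linear fold change is >= 1.5 with
FDR < 0.05, down if the fold change is <= 1/1.5 with FDR < 0.05, otherwise
ns.  Fold changes are ratios of mean linear normalized values over the
paired samples (robust to the log pseudocount).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ExpressionMatrix

__all__ = [
    "fdr_adjust",
    "paired_de",
    "pervasiveness",
    "direction_tally",
    "classify_direction",
    "chi_square_balance",
]

logger = logging.getLogger(__name__)

FC_THRESHOLD = 1.5
FDR_THRESHOLD = 0.05


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN inputs propagate as NaN (with a warning) and do not count toward
    the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    if valid.sum() < p.size:
        warnings.warn("NaN p-values propagated through FDR adjustment")
    pv = p[valid]
    if (pv < 0).any() or (pv > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # step-up monotonicity: cumulative min from the largest p
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[valid] = adj
    return out


def _pair_samples(meta: pd.DataFrame) -> pd.DataFrame:
    """Match one tumor and one normal sample per patient."""
    tumors = meta[meta["tissue"] == "tumor"].drop_duplicates("patient_id")
    normals = meta[meta["tissue"] == "normal"].drop_duplicates("patient_id")
    merged = tumors.merge(
        normals, on="patient_id", suffixes=("_tumor", "_normal")
    )
    return merged[["patient_id", "sample_id_tumor", "sample_id_normal"]]


def paired_de(
    expr: ExpressionMatrix,
    metadata: pd.DataFrame,
    level: str = "trna",
    min_pairs: int = 5,
    fc_threshold: float = FC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Paired tumor/normal differential expression per cancer type.

    Cancer types with fewer than ``min_pairs`` complete pairs are skipped
    (logged).  Features whose paired log2 differences have zero variance
    get p = 1 by convention and are flagged ``degenerate``.

    Returns a table with columns: feature_id, level, cancer_type, n_pairs,
    fold_change, p, fdr, call, degenerate.
    """
    linear = expr.linear()
    rows: list[pd.DataFrame] = []
    for ctype, sub in metadata.groupby("cancer_type"):
        pairs = _pair_samples(sub)
        pairs = pairs[
            pairs["sample_id_tumor"].isin(expr.samples)
            & pairs["sample_id_normal"].isin(expr.samples)
        ]
        n_pairs = len(pairs)
        if n_pairs < min_pairs:
            logger.info(
                "skipping cancer type %s: %d pairs < %d required",
                ctype, n_pairs, min_pairs,
            )
            continue
        t_cols = pairs["sample_id_tumor"].to_numpy()
        n_cols = pairs["sample_id_normal"].to_numpy()
        log_t = expr.log2[t_cols].to_numpy()
        log_n = expr.log2[n_cols].to_numpy()
        diffs = log_t - log_n

        degenerate = np.ptp(diffs, axis=1) == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            t_stat, p = stats.ttest_rel(log_t, log_n, axis=1)
        p = np.where(degenerate, 1.0, p)

        mean_t = linear[t_cols].to_numpy().mean(axis=1)
        mean_n = linear[n_cols].to_numpy().mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(mean_n > 0, mean_t / mean_n, np.inf)
        fc = np.where((mean_n == 0) & (mean_t == 0), 1.0, fc)

        fdr = fdr_adjust(p)
        call = np.select(
            [
                (fc >= fc_threshold) & (fdr < fdr_threshold),
                (fc <= 1.0 / fc_threshold) & (fdr < fdr_threshold),
            ],
            ["up", "down"],
            default="ns",
        )
        rows.append(
            pd.DataFrame(
                {
                    "feature_id": expr.features,
                    "level": level,
                    "cancer_type": str(ctype),
                    "n_pairs": n_pairs,
                    "fold_change": fc,
                    "p": p,
                    "fdr": fdr,
                    "call": call,
                    "degenerate": degenerate,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "feature_id", "level", "cancer_type", "n_pairs",
                "fold_change", "p", "fdr", "call", "degenerate",
            ]
        )
    return pd.concat(rows, ignore_index=True)


def pervasiveness(de_table: pd.DataFrame, min_types: int = 8) -> pd.DataFrame:
    """Per-feature counts of cancer types with up/down calls.

    A feature is flagged pervasive when the number of cancer types in which
    it is significantly altered (up or down, summed) reaches ``min_types``
    — 8 by convention at the tRNA level, 5 at codon/amino-acid level.
    """
    if de_table.empty:
        return pd.DataFrame(columns=["feature_id", "n_up", "n_down", "pervasive"])
    tab = (
        de_table.pivot_table(
            index="feature_id",
            columns="call",
            values="cancer_type",
            aggfunc="count",
            fill_value=0,
        )
        .reindex(columns=["up", "down"], fill_value=0)
        .rename(columns={"up": "n_up", "down": "n_down"})
        .reset_index()
    )
    tab.columns.name = None
    tab["pervasive"] = (tab["n_up"] + tab["n_down"]) >= min_types
    return tab


def direction_tally(
    de_table: pd.DataFrame, n_detectable: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Up/down call counts per cancer type and pooled.

    Percentages are taken over the number of (feature, cancer type) tests
    present in the table, or over ``n_detectable`` features x cancer types
    if given.
    """
    if de_table.empty:
        return (
            pd.DataFrame(columns=["cancer_type", "n_up", "n_down", "n_tested", "direction"]),
            {"n_up": 0, "n_down": 0, "pct_up": 0.0, "pct_down": 0.0},
        )
    per_type = []
    for ctype, sub in de_table.groupby("cancer_type"):
        n_up = int((sub["call"] == "up").sum())
        n_down = int((sub["call"] == "down").sum())
        per_type.append(
            {
                "cancer_type": str(ctype),
                "n_up": n_up,
                "n_down": n_down,
                "n_tested": len(sub),
                "direction": classify_direction(n_up, n_down),
            }
        )
    per_type = pd.DataFrame(per_type)
    n_up = int(per_type["n_up"].sum())
    n_down = int(per_type["n_down"].sum())
    denom = (
        n_detectable * per_type.shape[0] if n_detectable is not None else len(de_table)
    )
    pooled = {
        "n_up": n_up,
        "n_down": n_down,
        "pct_up": 100.0 * n_up / denom if denom else 0.0,
        "pct_down": 100.0 * n_down / denom if denom else 0.0,
    }
    return per_type, pooled


def classify_direction(n_up: int, n_down: int, ratio: float = 2.0) -> str:
    """Predominance of a cancer type: 'up', 'down', or 'similar'.

    A type is predominantly up when up-calls outnumber down-calls by at
    least ``ratio`` (and symmetrically for down).  No cutoff is canonical;
    the default is a 2:1 rule, configurable.
    """
    if n_up > n_down and n_up >= ratio * n_down:
        return "up"
    if n_down > n_up and n_down >= ratio * n_up:
        return "down"
    return "similar"


def chi_square_balance(n_up: int, n_down: int) -> tuple[float, float]:
    """Goodness-of-fit of (n_up, n_down) against equal proportions.

    One degree of freedom, no continuity correction; two-sided p from the
    chi-square survival function.
    """
    if n_up < 0 or n_down < 0:
        raise ValueError("counts must be non-negative")
    total = n_up + n_down
    if total == 0:
        raise ValueError("need at least one up or down call")
    expected = total / 2.0
    chi2 = (n_up - expected) ** 2 / expected + (n_down - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p
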