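"""Survival association and expression-tier clustering.

Survival analysis screens each expression feature two ways: a two-sided
log-rank test between patients above vs at-or-below the median expression
(ties go to the low group), and a univariate Cox proportional-hazards fit
(Efron tie handling, Wald p).  Per-feature p-values are BH-adjusted.

Expression-tier clustering reproduces the high/medium/low grouping:
UPGMA (average-linkage) hierarchical clustering on Euclidean distances
over per-cancer-type median expression, cut into k=3 clusters, labeled by
their median expression, with the empirical tier boundary thresholds
reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy.cluster.hierarchy import fcluster, linkage

from .differential import fdr_adjust

__all__ = [
    "read_survival",
    "median_split_logrank",
    "cox_univariate",
    "survival_screen",
    "TierAssignment",
    "expression_tier_clustering",
]


def read_survival(path) -> pd.DataFrame:
    """Read a survival TSV with columns patient_id, time, event."""
    surv = pd.read_csv(path, sep="\t")
    missing = [c for c in ("patient_id", "time", "event") if c not in surv.columns]
    if missing:
        raise ValueError(f"survival table missing columns: {missing}")
    if (surv["time"] < 0).any():
        raise ValueError("survival times must be non-negative")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (death)")
    return surv


def _align(expression: pd.Series, survival: pd.DataFrame) -> pd.DataFrame:
    df = survival.set_index("patient_id")[["time", "event"]].copy()
    df["expression"] = expression.reindex(df.index)
    df = df.dropna()
    if df.empty:
        raise ValueError("no patients shared between expression and survival")
    return df


def median_split_logrank(
    expression: pd.Series, survival: pd.DataFrame
) -> tuple[float, float]:
    """Two-sided log-rank test between high and low expression groups.

    Groups are patients above the median ("high") vs at-or-below it
    ("low"); ties land in the low group.  Returns (statistic, p).  If all
    records are censored a warning is issued and p = 1.
    """
    df = _align(expression, survival)
    high = df["expression"] > df["expression"].median()
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError(
            f"degenerate median split: {int(high.sum())} high vs "
            f"{int((~high).sum())} low patients"
        )
    if df["event"].sum() == 0:
        warnings.warn("all records censored; log-rank p set to 1")
        return 0.0, 1.0
    res = logrank_test(
        df.loc[high, "time"],
        df.loc[~high, "time"],
        event_observed_A=df.loc[high, "event"],
        event_observed_B=df.loc[~high, "event"],
    )
    return float(res.test_statistic), float(res.p_value)


def cox_univariate(expression: pd.Series, survival: pd.DataFrame) -> dict:
    """Univariate Cox proportional-hazards fit for one expression feature.

    Efron tie handling, Wald p.  Requires >= 10 patients and >= 3 events.
    Non-convergence is flagged in the returned record rather than raised.
    Returns dict with log_hr, se, p, n, n_events, converged.
    """
    df = _align(expression, survival)
    n, n_events = len(df), int(df["event"].sum())
    if n < 10:
        raise ValueError(f"need >= 10 patients, got {n}")
    if n_events < 3:
        raise ValueError(f"need >= 3 events, got {n_events}")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        rec = {
            "log_hr": float(cph.params_["expression"]),
            "se": float(cph.standard_errors_["expression"]),
            "p": float(cph.summary.loc["expression", "p"]),
            "converged": True,
        }
    except (ConvergenceError, ValueError):
        rec = {"log_hr": np.nan, "se": np.nan, "p": np.nan, "converged": False}
    rec.update({"n": n, "n_events": n_events})
    return rec


def survival_screen(
    expression: pd.DataFrame, survival: pd.DataFrame, method: str = "logrank"
) -> pd.DataFrame:
    """Per-feature survival association with BH-adjusted p-values.

    ``expression`` is features x patients; ``method`` is ``"logrank"``
    (median split) or ``"cox"``.
    """
    rows = []
    for fid, vec in expression.iterrows():
        if method == "logrank":
            stat, p = median_split_logrank(vec, survival)
            rows.append({"feature_id": fid, "statistic": stat, "p": p})
        elif method == "cox":
            rec = cox_univariate(vec, survival)
            rows.append(
                {
                    "feature_id": fid,
                    "statistic": rec["log_hr"],
                    "se": rec["se"],
                    "p": rec["p"],
                    "converged": rec["converged"],
                }
            )
        else:
            raise ValueError(f"unknown method {method!r}")
    out = pd.DataFrame(rows)
    out["fdr"] = fdr_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Expression tiers
# ---------------------------------------------------------------------------

@dataclass
class TierAssignment:
    """High/medium/low expression tiers with empirical boundary thresholds.

    ``t_high`` is the smallest overall median expression in the high tier
    and ``t_low`` the largest in the low tier, so the rule "high iff
    median >= t_high, low iff median <= t_low" reproduces the assignment
    whenever the clusters are separable along the median axis
    (``consistent``).
    """

    tiers: pd.Series
    t_low: float
    t_high: float
    degenerate: bool = False
    consistent: bool = True
    linkage_matrix: np.ndarray | None = field(default=None, repr=False)


def expression_tier_clustering(medians: pd.DataFrame, k: int = 3) -> TierAssignment:
    """Cluster features into expression tiers by UPGMA.

    ``medians`` holds per-cancer-type median log2 expression (features x
    cancer types).  Features are clustered with average linkage on
    Euclidean distances and the dendrogram is cut into exactly ``k``
    clusters, which are labeled high/medium/low (k=3) by their median
    expression.  Relabeling or permuting the cancer-type columns leaves
    the assignment unchanged.
    """
    X = medians.to_numpy(dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of features ({n})")
    Z = linkage(X, method="average", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    n_clusters = len(np.unique(labels))
    degenerate = n_clusters < k
    if degenerate:
        warnings.warn(
            f"only {n_clusters} distinct cluster(s) found for k={k}; "
            "input may be degenerate"
        )

    overall = medians.median(axis=1)
    cluster_median = {c: overall[labels == c].median() for c in np.unique(labels)}
    order = sorted(cluster_median, key=cluster_median.get)  # low -> high
    if k == 3 and n_clusters == 3:
        names = {order[0]: "low", order[1]: "medium", order[2]: "high"}
    else:
        names = {c: f"tier{rank + 1}" for rank, c in enumerate(order)}
    tiers = pd.Series([names[c] for c in labels], index=medians.index, name="tier")

    if k == 3 and n_clusters == 3:
        t_low = float(overall[tiers == "low"].max())
        t_high = float(overall[tiers == "high"].min())
        consistent = (
            t_low < float(overall[tiers == "medium"].min())
            and float(overall[tiers == "medium"].max()) < t_high
        )
    else:
        t_low, t_high, consistent = float("nan"), float("nan"), False

    return TierAssignment(
        tiers=tiers,
        t_low=t_low,
        t_high=t_high,
        degenerate=degenerate,
        consistent=consistent,
        linkage_matrix=Z,
    )
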