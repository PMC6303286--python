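"""Translation-enzyme expression analysis and copy-number calls.

The differential-expression machinery is applied to curated panels of
translation-regulation enzymes (tRNA modification enzymes, cytosolic and
mitochondrial aminoacyl-tRNA synthetases, translation factors).  Panels
are inputs — plain gene lists with a category and optional paralog
grouping — never computed here.

Copy-number calls are a pure threshold function on log2-scale CNV scores:
gain if score > log2(3), loss if score < log2(1) = 0, strict inequalities,
boundary scores neutral.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .differential import chi_square_balance, paired_de
from .quantify import ExpressionMatrix

__all__ = [
    "GAIN_THRESHOLD",
    "LOSS_THRESHOLD",
    "read_panel",
    "enzyme_de",
    "cnv_call",
]

GAIN_THRESHOLD = float(np.log2(3.0))
LOSS_THRESHOLD = float(np.log2(1.0))

PANEL_CATEGORIES = (
    "modification",
    "ARS_cytosolic",
    "ARS_mitochondrial",
    "translation_factor",
)


def read_panel(path) -> pd.DataFrame:
    """Read an enzyme panel TSV: columns gene, category[, paralog_group]."""
    panel = pd.read_csv(path, sep="\t")
    return validate_panel(panel)


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    for col in ("gene", "category"):
        if col not in panel.columns:
            raise ValueError(f"panel missing column {col!r}")
    dup = panel.duplicated(subset=["gene", "category"])
    if dup.any():
        raise ValueError(
            f"duplicate genes within a category: {panel.loc[dup, 'gene'].tolist()}"
        )
    if "paralog_group" not in panel.columns:
        panel = panel.copy()
        panel["paralog_group"] = pd.NA
    return panel


def enzyme_de(
    expr: ExpressionMatrix,
    metadata: pd.DataFrame,
    panel: pd.DataFrame,
    **de_kwargs,
) -> dict:
    """Differential expression restricted to an enzyme panel.

    Statistics are identical to the full paired analysis (row-filtering
    the full result to the panel gives the same table).  Returns the
    restricted DE table, the panel genes missing from the matrix, a
    per-category tally with the up/down balance chi-square test, and a
    paralog contrast table (calls of paralog partners side by side).
    """
    panel = validate_panel(panel)
    present = panel[panel["gene"].isin(expr.features)]
    missing = sorted(set(panel["gene"]) - set(expr.features))
    if present.empty:
        raise ValueError("no panel genes present in the expression matrix")

    de = paired_de(expr, metadata, level="gene", **de_kwargs)
    de = de[de["feature_id"].isin(present["gene"])].reset_index(drop=True)
    de = de.merge(
        present[["gene", "category"]], left_on="feature_id", right_on="gene"
    ).drop(columns="gene")

    tallies = []
    for cat, sub in de.groupby("category"):
        n_up = int((sub["call"] == "up").sum())
        n_down = int((sub["call"] == "down").sum())
        if n_up + n_down > 0:
            chi2, p = chi_square_balance(n_up, n_down)
        else:
            chi2, p = np.nan, np.nan
        tallies.append(
            {"category": cat, "n_up": n_up, "n_down": n_down, "chi2": chi2, "p": p}
        )
    tallies = pd.DataFrame(tallies)

    paralogs = _paralog_contrast(de, present)
    return {"de": de, "missing": missing, "tallies": tallies, "paralogs": paralogs}


def _paralog_contrast(de: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Side-by-side calls for paralog partners (e.g. cytosolic vs mito ARS)."""
    grouped = panel.dropna(subset=["paralog_group"])
    rows = []
    for pg, sub in grouped.groupby("paralog_group"):
        for ctype, de_sub in de.groupby("cancer_type"):
            calls = {
                f"call_{row.category}": de_sub.loc[
                    de_sub["feature_id"] == row.gene, "call"
                ].squeeze()
                for row in sub.itertuples(index=False)
                if (de_sub["feature_id"] == row.gene).any()
            }
            if calls:
                rows.append(
                    {"paralog_group": pg, "cancer_type": ctype,
                     "genes": ",".join(sub["gene"]), **calls}
                )
    return pd.DataFrame(rows)


def cnv_call(
    scores: pd.DataFrame,
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call copy-number gain/loss from log2 CNV scores.

    ``scores`` is long-format with columns gene, sample, score.  Gain iff
    score > log2(3) (~1.585); loss iff score < log2(1) = 0; otherwise
    neutral — strict inequalities on both sides, so boundary scores are
    neutral.  NaN scores are flagged, not called.

    Returns ``(calls, per_gene)`` where ``per_gene`` has the gain/loss
    sample fractions for each gene.
    """
    for col in ("gene", "sample", "score"):
        if col not in scores.columns:
            raise ValueError(f"CNV table missing column {col!r}")
    calls = scores.copy()
    s = calls["score"].to_numpy(dtype=float)
    flagged = np.isnan(s)
    call = np.select(
        [flagged, s > gain_threshold, s < loss_threshold],
        ["flagged", "gain", "loss"],
        default="neutral",
    )
    calls["call"] = call
    calls["flagged"] = flagged

    valid = calls[~calls["flagged"]]
    per_gene = (
        valid.assign(
            is_gain=valid["call"] == "gain", is_loss=valid["call"] == "loss"
        )
        .groupby("gene")
        .agg(
            n_samples=("sample", "size"),
            gain_fraction=("is_gain", "mean"),
            loss_fraction=("is_loss", "mean"),
        )
        .reset_index()
    )
    return calls, per_gene
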