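"""Quantification of tRNA expression from small-RNA-seq alignments.

This module covers the upstream half of the pipeline: per-sample QC
filtering, read counting over annotated tRNA loci, TMM (trimmed mean of
M-values) normalization, the detectability filter, and a cross-platform
correlation check.

Counts are kept as a :class:`CountMatrix` (integer reads, features x
samples, plus per-sample library sizes).  Normalized expression is a
:class:`ExpressionMatrix` holding ``log2(TMM-scaled counts-per-million +
offset)`` together with the normalization metadata (per-sample factors,
reference sample, offset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "TRNAGene",
    "CountMatrix",
    "ExpressionMatrix",
    "read_annotation",
    "write_annotation",
    "qc_filter_samples",
    "count_reads",
    "tmm_factors",
    "normalize_expression",
    "normalize_counts",
    "detectability_filter",
    "detectable_by_group",
    "cross_platform_correlation",
]

_VALID_BASES = frozenset("ACGT")

ANNOTATION_COLUMNS = [
    "gene_id",
    "chrom",
    "start",
    "end",
    "strand",
    "anticodon",
    "amino_acid",
    "is_initiator",
]


@dataclass(frozen=True)
class TRNAGene:
    """One annotated tRNA locus.

    Coordinates are 0-based half-open.  ``anticodon`` is the DNA triplet
    read 5'->3'; the decoded codon is its reverse complement.  Initiator
    methionine (iMet) shares the CAT anticodon with elongator Met but is
    functionally distinct, hence the explicit flag.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    anticodon: str
    amino_acid: str
    is_initiator: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if len(self.anticodon) != 3 or not set(self.anticodon) <= _VALID_BASES:
            raise ValueError(
                f"{self.gene_id}: anticodon {self.anticodon!r} is not a DNA triplet"
            )


@dataclass
class CountMatrix:
    """Integer read counts (features x samples) with library sizes.

    ``lib_sizes`` are total mapped primary reads per sample -- a superset
    of the tRNA-assigned counts, so column sums need not equal them.
    """

    counts: pd.DataFrame
    lib_sizes: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.lib_sizes = self.lib_sizes.reindex(self.counts.columns)
        if self.lib_sizes.isna().any():
            missing = self.lib_sizes.index[self.lib_sizes.isna()].tolist()
            raise ValueError(f"library sizes missing for samples: {missing}")
        if (self.lib_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


@dataclass
class ExpressionMatrix:
    """log2 TMM-normalized expression with normalization metadata."""

    log2: pd.DataFrame
    factors: pd.Series
    lib_sizes: pd.Series
    reference_sample: str
    offset: float = 1.0

    def linear(self) -> pd.DataFrame:
        """Pre-log normalized values (TMM-scaled counts per million)."""
        return np.exp2(self.log2) - self.offset

    @property
    def features(self) -> pd.Index:
        return self.log2.index

    @property
    def samples(self) -> pd.Index:
        return self.log2.columns


def read_annotation(path) -> pd.DataFrame:
    """Read a BED-like tRNA annotation TSV.

    Expected columns: gene_id, chrom, start, end, strand, anticodon,
    amino_acid, is_initiator.  Coordinates in the file are 0-based
    half-open (convert GTF-style 1-based inputs before loading).
    """
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return validate_annotation(ann)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    if ann["gene_id"].duplicated().any():
        dups = ann.loc[ann["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene_id in annotation: {dups}")
    ann = ann.copy()
    ann["is_initiator"] = ann["is_initiator"].astype(bool)
    for row in ann.itertuples(index=False):
        TRNAGene(
            gene_id=row.gene_id,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            anticodon=row.anticodon,
            amino_acid=row.amino_acid,
            is_initiator=bool(row.is_initiator),
        )
    return ann


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------

def qc_filter_samples(
    metadata: pd.DataFrame,
    min_qc_fraction: float = 0.5,
    min_mapped_fraction: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop low-quality samples.

    A sample is kept iff ``qc_passed_reads/total_reads >= min_qc_fraction``
    AND ``mapped_reads/total_reads >= min_mapped_fraction``; the drop
    condition is "fewer than" the threshold, so boundary samples are kept.

    Returns ``(kept, dropped)``; ``dropped`` carries a ``drop_reason``
    column (``qc``, ``mapping``, or ``qc+mapping``).
    """
    for col in ("total_reads", "qc_passed_reads", "mapped_reads"):
        if col not in metadata.columns:
            raise ValueError(f"metadata missing column {col!r}")
    if (metadata["total_reads"] <= 0).any():
        bad = metadata.loc[metadata["total_reads"] <= 0, "sample_id"].tolist()
        raise ValueError(f"samples with non-positive total_reads: {bad}")

    qc_frac = metadata["qc_passed_reads"] / metadata["total_reads"]
    map_frac = metadata["mapped_reads"] / metadata["total_reads"]
    fail_qc = qc_frac < min_qc_fraction
    fail_map = map_frac < min_mapped_fraction

    kept = metadata.loc[~(fail_qc | fail_map)].copy()
    dropped = metadata.loc[fail_qc | fail_map].copy()
    reason = np.select(
        [fail_qc & fail_map, fail_qc, fail_map],
        ["qc+mapping", "qc", "mapping"],
        default="",
    )
    dropped["drop_reason"] = reason[(fail_qc | fail_map).to_numpy()]
    return kept, dropped


# ---------------------------------------------------------------------------
# Read counting
# ---------------------------------------------------------------------------

def _build_locus_trees(annotation: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in annotation.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            int(row.start), int(row.end), row.gene_id
        )
    return trees


def count_reads(
    alignments,
    annotation: pd.DataFrame,
) -> tuple[pd.Series, dict]:
    """Count primary mapped alignments per tRNA locus.

    Each primary, mapped, non-QC-fail alignment is assigned to the locus
    with the largest overlap; ties go to the lexicographically smallest
    ``gene_id``.  Reads overlapping no locus are ignored for counting but
    still contribute to the library size, which is the total number of
    mapped primary reads in the file (QC-fail reads included).

    Parameters
    ----------
    alignments : path to a SAM or BAM file
    annotation : validated annotation table

    Returns
    -------
    (counts, stats)
        ``counts`` is an int Series indexed by ``gene_id``; ``stats`` has
        ``library_size``, ``total_reads``, ``qc_passed_reads``,
        ``mapped_reads``.
    """
    annotation = validate_annotation(annotation)
    trees = _build_locus_trees(annotation)
    counts = {gid: 0 for gid in annotation["gene_id"]}

    total = mapped = qcfail = 0
    with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
        for rec_no, rec in enumerate(fh, start=1):
            try:
                if rec.is_secondary or rec.is_supplementary:
                    continue
                total += 1
                if rec.is_unmapped:
                    continue
                mapped += 1
                if rec.is_qcfail:
                    qcfail += 1
                    continue
                tree = trees.get(rec.reference_name)
                if tree is None:
                    continue
                start, end = rec.reference_start, rec.reference_end
                hits = tree.overlap(start, end)
                if not hits:
                    continue
                # largest overlap wins; ties -> smallest gene_id
                best = min(
                    hits,
                    key=lambda iv: (-(min(end, iv.end) - max(start, iv.begin)), iv.data),
                )
                counts[best.data] += 1
            except (ValueError, TypeError) as exc:  # malformed record
                raise ValueError(f"malformed alignment record #{rec_no}: {exc}") from exc

    stats_out = {
        "library_size": mapped,
        "total_reads": total,
        "mapped_reads": mapped,
        "qc_passed_reads": total - qcfail,
    }
    return pd.Series(counts, name="count").loc[annotation["gene_id"].to_numpy()], stats_out


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _choose_reference(counts: np.ndarray, lib_sizes: np.ndarray) -> int:
    # sample whose 75th percentile of count fractions is closest to the mean
    f75 = np.quantile(counts / lib_sizes, 0.75, axis=0)
    if np.all(f75 == 0):
        warnings.warn("all upper quartiles are zero; using first sample as reference")
        return 0
    return int(np.argmin(np.abs(f75 - f75.mean())))


def tmm_factors(
    cm: CountMatrix,
    reference: str | None = None,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> tuple[pd.Series, str]:
    """Per-sample TMM normalization factors.

    For sample k against reference r, over genes expressed in both
    (Y_gk > 0 and Y_gr > 0):

        M_g = log2((Y_gk/N_k) / (Y_gr/N_r))
        A_g = 1/2 * log2((Y_gk/N_k) * (Y_gr/N_r))
        w_g = 1 / ((N_k - Y_gk)/(N_k Y_gk) + (N_r - Y_gr)/(N_r Y_gr))

    the 30% most extreme M values and 5% most extreme A values are
    discarded (symmetric, rank-based), and the factor is
    2**(sum(w M)/sum(w)).  Factors are rescaled to geometric mean 1.

    Returns ``(factors, reference_sample_id)``.
    """
    Y = cm.counts.to_numpy(dtype=float)
    N = cm.lib_sizes.to_numpy(dtype=float)
    n_genes, n_samples = Y.shape
    if n_samples < 2:
        raise ValueError("TMM requires at least 2 samples")
    if (Y.sum(axis=0) == 0).any():
        raise ValueError("every sample needs at least one nonzero count")

    if reference is None:
        ref_idx = _choose_reference(Y, N)
    else:
        ref_idx = int(cm.samples.get_loc(reference))
    yr, nr = Y[:, ref_idx], N[ref_idx]

    log_factors = np.zeros(n_samples)
    for k in range(n_samples):
        if k == ref_idx:
            continue
        yk, nk = Y[:, k], N[k]
        both = (yk > 0) & (yr > 0)
        if not both.any():
            warnings.warn(
                f"sample {cm.samples[k]!r} shares no expressed genes with the "
                "reference; factor set to 1"
            )
            continue
        y1, y2 = yk[both], yr[both]
        m = np.log2((y1 / nk) / (y2 / nr))
        a = 0.5 * np.log2((y1 / nk) * (y2 / nr))
        v = (nk - y1) / (nk * y1) + (nr - y2) / (nr * y2)
        # degenerate: columns proportional -> factor 1
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = m.size
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abundance_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            continue
        w = 1.0 / v[keep]
        log_factors[k] = np.sum(w * m[keep]) / np.sum(w)

    log_factors -= log_factors.mean()  # geometric mean 1
    factors = pd.Series(np.exp2(log_factors), index=cm.samples, name="tmm_factor")
    return factors, str(cm.samples[ref_idx])


def normalize_expression(
    cm: CountMatrix,
    factors: pd.Series,
    offset: float = 1.0,
    reference_sample: str = "",
) -> ExpressionMatrix:
    """log2 TMM-scaled counts-per-million with a pseudocount.

        value_gk = log2( Y_gk / (N_k * f_k) * 1e6 + offset )
    """
    factors = factors.reindex(cm.samples)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("factors must be positive and cover every sample")
    eff = cm.lib_sizes.to_numpy(dtype=float) * factors.to_numpy()
    cpm = cm.counts.to_numpy(dtype=float) / eff * 1e6
    log2 = pd.DataFrame(
        np.log2(cpm + offset), index=cm.features, columns=cm.samples
    )
    return ExpressionMatrix(
        log2=log2,
        factors=factors,
        lib_sizes=cm.lib_sizes.copy(),
        reference_sample=reference_sample,
        offset=offset,
    )


def normalize_counts(cm: CountMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Convenience: TMM factors + normalization in one step."""
    factors, ref = tmm_factors(cm)
    return normalize_expression(cm, factors, offset=offset, reference_sample=ref)


# ---------------------------------------------------------------------------
# Detectability
# ---------------------------------------------------------------------------

def detectability_filter(
    expr: ExpressionMatrix,
    samples=None,
    min_mean: float = 1.0,
) -> pd.Index:
    """Features whose mean linear normalized value is >= ``min_mean``.

    The threshold is inclusive, on the pre-log per-million scale, averaged
    over the given samples (default: all).
    """
    linear = expr.linear()
    if samples is not None:
        samples = list(samples)
        if len(samples) == 0:
            raise ValueError("empty sample group")
        linear = linear[samples]
    return linear.index[linear.mean(axis=1) >= min_mean]


def detectable_by_group(
    expr: ExpressionMatrix, metadata: pd.DataFrame, min_mean: float = 1.0
) -> dict[str, pd.Index]:
    """Detectable feature set per cancer type."""
    out = {}
    for ctype, sub in metadata.groupby("cancer_type"):
        ids = [s for s in sub["sample_id"] if s in expr.samples]
        if not ids:
            raise ValueError(f"no expression samples for cancer type {ctype!r}")
        out[str(ctype)] = detectability_filter(expr, ids, min_mean=min_mean)
    return out


# ---------------------------------------------------------------------------
# Cross-platform validation
# ---------------------------------------------------------------------------

def cross_platform_correlation(
    expr_a: pd.Series, expr_b: pd.Series
) -> tuple[float, float]:
    """Spearman correlation between two expression vectors on shared features.

    Used to compare the small-RNA-seq-derived tRNA quantification with an
    orthogonal assay; ranks are averaged on ties, p is two-sided.
    """
    shared = expr_a.index.intersection(expr_b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared features; need >= 3")
    rho, p = stats.spearmanr(expr_a.loc[shared], expr_b.loc[shared])
    return float(rho), float(p)
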