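import math

import numpy as np
import pandas as pd
import pytest

from trnascape import (
    CountMatrix,
    count_reads,
    cross_platform_correlation,
    detectability_filter,
    normalize_counts,
    normalize_expression,
    qc_filter_samples,
    simulate_alignments,
    tmm_factors,
)

from conftest import random_count_matrix


def _meta(total, qc, mapped):
    return pd.DataFrame(
        [{"sample_id": "s1", "total_reads": total, "qc_passed_reads": qc,
          "mapped_reads": mapped}]
    )


@pytest.mark.parametrize(
    "total,qc,mapped,kept,reason",
    [
        (100, 50, 80, True, None),          # both exactly at threshold -> kept
        (100, 49, 100, False, "qc"),
        (100, 100, 79, False, "mapping"),
        (100, 49, 79, False, "qc+mapping"),
    ],
)
def test_qc_filter_boundaries(total, qc, mapped, kept, reason):
    kept_df, dropped = qc_filter_samples(_meta(total, qc, mapped))
    if kept:
        assert len(kept_df) == 1 and dropped.empty
    else:
        assert kept_df.empty and dropped["drop_reason"].iloc[0] == reason


def test_qc_filter_rejects_zero_total():
    with pytest.raises(ValueError, match="total_reads"):
        qc_filter_samples(_meta(0, 0, 0))


def test_count_reads_assigns_largest_overlap(tmp_path):
    ann = pd.DataFrame(
        [
            {"gene_id": "gA", "chrom": "chr1", "start": 0, "end": 72, "strand": "+",
             "anticodon": "ACG", "amino_acid": "Arg", "is_initiator": False},
            {"gene_id": "gB", "chrom": "chr1", "start": 60, "end": 132, "strand": "+",
             "anticodon": "GCA", "amino_acid": "Cys", "is_initiator": False},
        ]
    )
    sam = "\n".join(
        [
            "@HD\tVN:1.6",
            "@SQ\tSN:chr1\tLN:500",
            # fully inside gA
            "r1\t0\tchr1\t11\t30\t30M\t*\t0\t0\t" + "A" * 30 + "\t" + "I" * 30,
            # overlaps both: [55,85) -> 17 bases in gA, 25 in gB -> gB
            "r2\t0\tchr1\t56\t30\t30M\t*\t0\t0\t" + "A" * 30 + "\t" + "I" * 30,
            # unmapped: counted nowhere, not in library size
            "r3\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 30 + "\t" + "I" * 30,
            # QC-fail mapped: in library size, not counted
            "r4\t512\tchr1\t11\t30\t30M\t*\t0\t0\t" + "A" * 30 + "\t" + "I" * 30,
        ]
    ) + "\n"
    path = tmp_path / "toy.sam"
    path.write_text(sam)
    counts, stats = count_reads(path, ann)
    assert counts["gA"] == 1 and counts["gB"] == 1
    assert stats["library_size"] == 3  # r1, r2, r4 mapped primary
    assert stats["total_reads"] == 4
    assert stats["qc_passed_reads"] == 3


def test_count_reads_tie_breaks_lexicographically(tmp_path):
    # two loci with identical overlap for a read spanning the boundary
    ann = pd.DataFrame(
        [
            {"gene_id": "gB", "chrom": "chr1", "start": 0, "end": 100, "strand": "+",
             "anticodon": "ACG", "amino_acid": "Arg", "is_initiator": False},
            {"gene_id": "gA", "chrom": "chr1", "start": 85, "end": 185, "strand": "+",
             "anticodon": "GCA", "amino_acid": "Cys", "is_initiator": False},
        ]
    )
    # read [85,115): 15 bases in each locus
    sam = "\n".join(
        [
            "@HD\tVN:1.6",
            "@SQ\tSN:chr1\tLN:500",
            "r1\t0\tchr1\t86\t30\t30M\t*\t0\t0\t" + "A" * 30 + "\t" + "I" * 30,
        ]
    ) + "\n"
    path = tmp_path / "tie.sam"
    path.write_text(sam)
    counts, _ = count_reads(path, ann)
    assert counts["gA"] == 1 and counts["gB"] == 0


def test_roundtrip_with_contamination(annotation60, tmp_path):
    rng = np.random.default_rng(5)
    planted = pd.Series(
        rng.integers(0, 40, size=len(annotation60)), index=annotation60["gene_id"]
    )
    sam = simulate_alignments(
        planted, annotation60, seed=6, unmapped_fraction=0.3, qcfail_fraction=0.2
    )
    path = tmp_path / "sim.sam"
    path.write_text(sam)
    counts, stats = count_reads(path, annotation60)
    assert (counts == planted).all()
    assert stats["total_reads"] > stats["mapped_reads"] > int(planted.sum())


def tmm_oracle(Y, N, ref_idx, logratio_trim=0.30, abundance_trim=0.05):
    """Straight-loop reimplementation of the weighted trimmed-mean factors."""
    n_genes, n_samples = len(Y), len(Y[0])
    logf = []
    for k in range(n_samples):
        if k == ref_idx:
            logf.append(0.0)
            continue
        ms, aas, ws = [], [], []
        for g in range(n_genes):
            yk, yr = Y[g][k], Y[g][ref_idx]
            if yk > 0 and yr > 0:
                pk, pr = yk / N[k], yr / N[ref_idx]
                ms.append(math.log2(pk / pr))
                aas.append(0.5 * math.log2(pk * pr))
                ws.append(
                    1.0 / ((N[k] - yk) / (N[k] * yk) + (N[ref_idx] - yr) / (N[ref_idx] * yr))
                )
        n = len(ms)
        if n == 0 or max(abs(m) for m in ms) < 1e-6:
            logf.append(0.0)
            continue

        def avg_ranks(vals):
            order = sorted(range(n), key=lambda i: vals[i])
            r = [0.0] * n
            i = 0
            while i < n:
                j = i
                while j + 1 < n and vals[order[j + 1]] == vals[order[i]]:
                    j += 1
                for t in range(i, j + 1):
                    r[order[t]] = (i + j) / 2 + 1
                i = j + 1
            return r

        rm, ra = avg_ranks(ms), avg_ranks(aas)
        lo_m = math.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * abundance_trim) + 1
        hi_a = n + 1 - lo_a
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += ws[i] * ms[i]
                den += ws[i]
        logf.append(num / den if den > 0 else 0.0)
    mean = sum(logf) / n_samples
    return [2.0 ** (lf - mean) for lf in logf]


def test_tmm_duplicate_columns_give_unit_factors():
    cm0 = random_count_matrix(seed=3, n_samples=1)
    dup = pd.concat([cm0.counts["s0"]] * 4, axis=1)
    dup.columns = list("abcd")
    cm = CountMatrix(counts=dup, lib_sizes=pd.Series(10_000, index=dup.columns))
    factors, _ = tmm_factors(cm)
    assert np.allclose(factors, 1.0)


def test_tmm_library_scaling_removed_exactly():
    cm0 = random_count_matrix(seed=4, n_samples=1)
    y = cm0.counts["s0"]
    counts = pd.DataFrame({"a": y, "b": 2 * y})
    lib = pd.Series({"a": 10_000, "b": 20_000})
    cm = CountMatrix(counts=counts, lib_sizes=lib)
    factors, ref = tmm_factors(cm)
    assert np.allclose(factors, 1.0)
    expr = normalize_expression(cm, factors, reference_sample=ref)
    assert np.allclose(expr.log2["a"], expr.log2["b"])


def test_tmm_matches_straight_loop_oracle():
    cm = random_count_matrix(seed=11, n_features=200, n_samples=8)
    factors, ref = tmm_factors(cm)
    ref_idx = list(cm.samples).index(ref)
    oracle = tmm_oracle(cm.counts.to_numpy().tolist(), cm.lib_sizes.to_list(), ref_idx)
    assert np.max(np.abs(factors.to_numpy() - np.array(oracle))) < 1e-10


def test_tmm_factors_geometric_mean_one():
    for seed in (1, 2, 3):
        cm = random_count_matrix(seed=seed)
        factors, _ = tmm_factors(cm)
        assert abs(np.log(factors).mean()) < 1e-12
        assert (factors > 0).all()


def test_normalize_expression_values():
    counts = pd.DataFrame({"s": [0, 141]}, index=["g0", "g1"])
    cm = CountMatrix(counts=counts, lib_sizes=pd.Series({"s": 1_000_000}))
    expr = normalize_expression(cm, pd.Series({"s": 1.0}))
    assert expr.log2.loc["g0", "s"] == 0.0  # zero count, offset 1
    assert expr.log2.loc["g1", "s"] == pytest.approx(math.log2(142), abs=1e-12)


def test_normalize_expression_monotone_in_counts():
    counts = pd.DataFrame({"s": np.arange(0, 500, 7)})
    cm = CountMatrix(counts=counts, lib_sizes=pd.Series({"s": 10_000}))
    expr = normalize_expression(cm, pd.Series({"s": 1.0}))
    assert (np.diff(expr.log2["s"]) > 0).all()


def test_detectability_threshold_inclusive():
    # one feature with mean linear normalized value exactly 1, one at 0
    counts = pd.DataFrame({"a": [1, 0], "b": [1, 0]}, index=["g1", "g0"])
    lib = pd.Series({"a": 1_000_000, "b": 1_000_000})
    cm = CountMatrix(counts=counts, lib_sizes=lib)
    expr = normalize_expression(cm, pd.Series({"a": 1.0, "b": 1.0}))
    detectable = detectability_filter(expr)
    assert "g1" in detectable and "g0" not in detectable


def test_detectability_matches_planted_abundance_split(expr, cohort):
    truth_ab = cohort["truth"].base_abundance
    rel = truth_ab / truth_ab.sum()
    # true mean CPM across the cohort
    true_cpm = rel * 1e6
    detectable = set(detectability_filter(expr))
    clearly_high = set(true_cpm.index[true_cpm >= 10])
    clearly_low = set(true_cpm.index[true_cpm < 0.1])
    assert clearly_high <= detectable
    assert not (clearly_low & detectable)


def test_cross_platform_correlation_monotone_transform():
    a = pd.Series(np.linspace(1, 5, 30), index=[f"g{i}" for i in range(30)])
    rho, p = cross_platform_correlation(a, np.exp(a))
    assert rho == pytest.approx(1.0)
    rho, _ = cross_platform_correlation(a, -a)
    assert rho == pytest.approx(-1.0)


def test_cross_platform_correlation_null_is_small():
    rng = np.random.default_rng(12)
    idx = [f"g{i}" for i in range(100)]
    a = pd.Series(rng.normal(size=100), index=idx)
    b = pd.Series(rng.normal(size=100), index=idx)
    rho, _ = cross_platform_correlation(a, b)
    assert abs(rho) < 0.3


def test_cross_platform_correlation_needs_shared_features():
    a = pd.Series([1.0, 2.0], index=["g1", "g2"])
    with pytest.raises(ValueError, match="shared"):
        cross_platform_correlation(a, a)
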