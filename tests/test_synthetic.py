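import numpy as np
import pandas as pd
import pytest
from Bio import SeqIO

from trnascape import (
    SimConfig,
    cox_univariate,
    simulate_alignments,
    simulate_annotation,
    simulate_coding_sequences,
    simulate_paired_counts,
    simulate_survival,
)


def test_annotation_minimal_and_deterministic():
    one = simulate_annotation(1, seed=7)
    assert len(one) == 1
    assert set(one["anticodon"].iloc[0]) <= set("ACGT")
    assert one["strand"].iloc[0] in {"+", "-"}
    a = simulate_annotation(60, seed=1)
    b = simulate_annotation(60, seed=1)
    pd.testing.assert_frame_equal(a, b)


def test_annotation_copy_numbers_are_uneven():
    ann = simulate_annotation(60, seed=1)
    copies = ann.groupby(["amino_acid", "anticodon", "is_initiator"]).size()
    assert copies.max() >= 3
    assert (copies == 1).sum() >= 1


def test_annotation_loci_non_overlapping():
    ann = simulate_annotation(80, seed=2).sort_values("start")
    assert (ann["start"].to_numpy()[1:] >= ann["end"].to_numpy()[:-1]).all()


def test_annotation_includes_imet_and_sec():
    ann = simulate_annotation(40, seed=3)
    assert ann["is_initiator"].sum() >= 1
    assert (ann["amino_acid"] == "Sec").sum() >= 1


def test_annotation_rejects_nonpositive_n():
    with pytest.raises(ValueError):
        simulate_annotation(0, seed=1)


def test_null_config_balanced_means(annotation60):
    # no planted effects, near-zero dispersion, equal libraries
    cfg = SimConfig(
        n_trna_genes=60, n_pairs=40, dispersion=0.0,
        library_size_range=(1e6, 1e6), seed=5,
    )
    cm, meta, _ = simulate_paired_counts(cfg, annotation60)
    t_cols = meta.loc[meta["tissue"] == "tumor", "sample_id"]
    n_cols = meta.loc[meta["tissue"] == "normal", "sample_id"]
    mt = cm.counts[t_cols].mean(axis=1)
    mn = cm.counts[n_cols].mean(axis=1)
    se = np.sqrt(cm.counts[t_cols].var(axis=1) / len(t_cols)
                 + cm.counts[n_cols].var(axis=1) / len(n_cols))
    ok = (mt - mn).abs() <= 3 * se + 1e-9
    # Poisson means per feature: allow rare 3-SE excursions
    assert ok.mean() > 0.98


def test_planted_fold_change_realized(annotation60):
    g = annotation60["gene_id"].iloc[0]
    cfg = SimConfig(
        n_trna_genes=60, n_pairs=50,
        planted_effects=[(g, "trna", 3.0)], dispersion=0.1, seed=13,
    )
    cm, meta, truth = simulate_paired_counts(cfg, annotation60)
    t_cols = meta.loc[meta["tissue"] == "tumor", "sample_id"]
    n_cols = meta.loc[meta["tissue"] == "normal", "sample_id"]
    ratio = cm.counts.loc[g, t_cols].mean() / cm.counts.loc[g, n_cols].mean()
    assert 2.5 <= ratio <= 3.6
    assert truth.fc_trna[g] == 3.0


def test_group_level_truth_is_abundance_weighted(annotation60):
    from trnascape import build_hierarchy

    hmap = build_hierarchy(annotation60)
    g = annotation60["gene_id"].iloc[0]
    ckey = hmap.codon_of(g)
    cfg = SimConfig(
        n_trna_genes=60, n_pairs=5,
        planted_effects=[(g, "trna", 4.0)], seed=3,
    )
    _, _, truth = simulate_paired_counts(cfg, annotation60)
    members = [x for x, c in hmap.gene_to_codon.items() if c == ckey]
    w = truth.base_abundance[members]
    expected = float((truth.fc_trna[members] * w).sum() / w.sum())
    assert truth.fc_codon[ckey] == pytest.approx(expected, rel=1e-12)


def test_codon_level_effect_scales_all_members(annotation60):
    from trnascape import build_hierarchy

    hmap = build_hierarchy(annotation60)
    # pick a codon with several member genes
    counts = pd.Series(hmap.gene_to_codon).value_counts()
    ckey = counts.index[0]
    cfg = SimConfig(
        n_trna_genes=60, n_pairs=5,
        planted_effects=[(ckey, "codon", 2.0)], seed=4,
    )
    _, _, truth = simulate_paired_counts(cfg, annotation60)
    members = [g for g, c in hmap.gene_to_codon.items() if c == ckey]
    assert (truth.fc_trna[members] == 2.0).all()
    assert truth.fc_codon[ckey] == pytest.approx(2.0)


def test_unknown_planted_feature_is_named(annotation60):
    cfg = SimConfig(
        n_trna_genes=60, n_pairs=5,
        planted_effects=[("tRNA-Nope-XXX-1-1", "trna", 2.0)], seed=1,
    )
    with pytest.raises(KeyError, match="tRNA-Nope-XXX-1-1"):
        simulate_paired_counts(cfg, annotation60)


def test_counts_deterministic(annotation60):
    cfg = SimConfig(n_trna_genes=60, n_pairs=6, seed=99)
    cm1, m1, _ = simulate_paired_counts(cfg, annotation60)
    cm2, m2, _ = simulate_paired_counts(cfg, annotation60)
    pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
    pd.testing.assert_frame_equal(m1, m2)


def test_sim_config_validation():
    with pytest.raises(ValueError):
        SimConfig(n_pairs=0)
    with pytest.raises(ValueError):
        SimConfig(planted_effects=[("g", "trna", -1.0)])
    with pytest.raises(ValueError):
        SimConfig(planted_effects=[("g", "exon", 2.0)])
    with pytest.raises(ValueError):
        SimConfig(library_size_range=(0, 100))


def test_alignments_realize_exact_counts(annotation60):
    counts = pd.Series(0, index=annotation60["gene_id"])
    counts.iloc[0] = 5
    sam = simulate_alignments(counts, annotation60, seed=1)
    body = [l for l in sam.splitlines() if not l.startswith("@")]
    assert len(body) == 5
    g = annotation60.iloc[0]
    for line in body:
        fields = line.split("\t")
        pos0 = int(fields[3]) - 1
        assert fields[2] == g["chrom"]
        assert g["start"] <= pos0 and pos0 + 30 <= g["end"]


def test_alignments_contamination_counts(annotation60):
    counts = pd.Series(0, index=annotation60["gene_id"])
    counts.iloc[:10] = 10  # 100 mapped reads
    sam = simulate_alignments(counts, annotation60, seed=2, unmapped_fraction=0.5)
    body = [l.split("\t") for l in sam.splitlines() if not l.startswith("@")]
    unmapped = [f for f in body if int(f[1]) & 4]
    mapped = [f for f in body if not int(f[1]) & 4]
    assert len(mapped) == 100 and len(unmapped) == 100


def test_alignments_deterministic_and_reject_short_locus(annotation60):
    counts = pd.Series(1, index=annotation60["gene_id"])
    assert simulate_alignments(counts, annotation60, seed=3) == simulate_alignments(
        counts, annotation60, seed=3
    )
    with pytest.raises(ValueError, match="read length"):
        simulate_alignments(counts, annotation60, seed=3, read_length=100)


def test_cds_all_mass_on_one_codon():
    recs = simulate_coding_sequences(n_codons=50, seed=1, codon_bias={"ATG": 1.0})
    assert str(recs[0].seq) == "ATG" * 50


def test_cds_uniform_bias_converges():
    recs = simulate_coding_sequences(
        n_codons=100_000, seed=2, codon_bias={c: 1.0 for c in
        [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]}
    )
    seq = str(recs[0].seq)
    freqs = pd.Series(
        [seq[i : i + 3] for i in range(0, len(seq), 3)]
    ).value_counts(normalize=True)
    assert ((freqs - 1 / 64).abs() < 0.005).all()


def test_cds_deterministic_fasta(tmp_path):
    for run in ("a", "b"):
        recs = simulate_coding_sequences(n_codons=500, seed=4, n_genes=3)
        SeqIO.write(recs, tmp_path / f"{run}.fasta", "fasta")
    assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()


def test_cds_validates_base_freqs():
    with pytest.raises(ValueError, match="sum to 1"):
        simulate_coding_sequences(n_codons=10, seed=0, base_freqs=[0.5, 0.5, 0.5, 0.5])


def test_survival_null_cox_within_2se():
    rng = np.random.default_rng(11)
    expr = pd.Series(rng.normal(size=500), index=[f"P{i}" for i in range(500)])
    surv = simulate_survival(expr, log_hazard_ratio=0.0, baseline_rate=0.02, seed=12)
    rec = cox_univariate(expr, surv)
    assert abs(rec["log_hr"]) <= 2 * rec["se"]


def test_survival_full_censoring():
    expr = pd.Series(np.arange(10.0), index=[f"P{i}" for i in range(10)])
    surv = simulate_survival(expr, 0.5, 0.01, censor_rate=1.0, seed=1)
    assert (surv["event"] == 0).all()
    surv = simulate_survival(expr, 0.5, 0.01, censor_rate=0.0, seed=1)
    assert (surv["event"] == 1).all()


def test_survival_deterministic():
    expr = pd.Series(np.arange(20.0), index=[f"P{i}" for i in range(20)])
    s1 = simulate_survival(expr, 1.0, 0.01, seed=5)
    s2 = simulate_survival(expr, 1.0, 0.01, seed=5)
    pd.testing.assert_frame_equal(s1, s2)
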