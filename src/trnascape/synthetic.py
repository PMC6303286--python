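"""Synthetic inputs for the whole pipeline.

Everything the analysis consumes can be generated here with known ground
truth: a UCSC-style tRNA annotation on a toy chromosome, paired
tumor/normal negative-binomial count cohorts with planted fold changes at
any hierarchy level, SAM alignments realizing exact per-locus counts, toy
coding genomes with controlled base/codon composition, exponential
survival times with a planted hazard ratio, and CNV scores around known
gain/loss calls.

All randomness flows through one ``numpy.random.default_rng(seed)`` per
call — the same seed and configuration give byte-identical artifacts.

Counts are negative binomial with the mean/dispersion parameterization
``Var = mu + phi * mu**2`` (the standard RNA count model); ``phi -> 0``
recovers Poisson.  Planted codon- or amino-acid-level effects scale every
member tRNA gene equally, so the group-level true fold change equals the
gene-level one and level consistency is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon_usage import BASES, CODONS, GENETIC_CODE, SENSE_CODONS
from .hierarchy import HierarchyMap, anticodon_to_codon, build_hierarchy
from .quantify import CountMatrix, validate_annotation

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_annotation",
    "simulate_paired_counts",
    "simulate_alignments",
    "simulate_coding_sequences",
    "simulate_survival",
    "simulate_cnv_scores",
]

TOY_CHROM = "chrS1"
LOCUS_LENGTH = 72
LOCUS_GAP = 40
READ_LENGTH = 30
MAPQ = 30

_REVCOMP = str.maketrans("ACGT", "TGCA")


def _anticodon_pool() -> list[tuple[str, str, bool]]:
    """(amino_acid, anticodon, is_initiator) for every decodable codon.

    One entry per sense codon of the standard code (anticodon = reverse
    complement), plus initiator Met (CAT) and selenocysteine (TCA,
    decoding the recoded TGA).
    """
    pool = [
        (GENETIC_CODE[codon], codon.translate(_REVCOMP)[::-1], False)
        for codon in SENSE_CODONS
    ]
    pool.append(("Met", "CAT", True))  # iMet
    pool.append(("Sec", "TCA", False))
    return pool


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(n_genes: int, seed: int) -> pd.DataFrame:
    """Generate a toy tRNA annotation table.

    Gene copy numbers per anticodon are uneven (Zipf-like weights over a
    shuffled anticodon pool), mirroring the skewed real distribution where
    some codons are decoded by dozens of tRNA genes and others by a single
    one.  For ``n_genes >= 25`` one iMet and one Sec gene are guaranteed.
    Loci are non-overlapping on one toy chromosome.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    rng = np.random.default_rng(seed)
    # random copies come from the elongator pool; iMet and Sec get reserved
    # slots (single- or low-copy families, as in the real annotation)
    pool = [entry for entry in _anticodon_pool() if entry[0] != "Sec" and not entry[2]]
    order = rng.permutation(len(pool))
    weights = 1.0 / np.arange(1, len(pool) + 1)
    weights /= weights.sum()

    chosen: list[tuple[str, str, bool]] = []
    if n_genes >= 25:
        chosen.append(("Met", "CAT", True))
        chosen.append(("Sec", "TCA", False))
    n_draw = n_genes - len(chosen)
    idx = rng.choice(order, size=n_draw, replace=True, p=weights)
    chosen.extend(pool[i] for i in idx)

    copy_index: dict[tuple[str, str, bool], int] = {}
    rows = []
    pos = 100
    for aa, anticodon, is_init in chosen:
        key = (aa, anticodon, is_init)
        copy_index[key] = copy_index.get(key, 0) + 1
        label = "iMet" if is_init else aa
        gene_id = f"tRNA-{label}-{anticodon}-{copy_index[key]}-1"
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": TOY_CHROM,
                "start": pos,
                "end": pos + LOCUS_LENGTH,
                "strand": "+" if rng.random() < 0.5 else "-",
                "anticodon": anticodon,
                "amino_acid": aa,
                "is_initiator": is_init,
            }
        )
        pos += LOCUS_LENGTH + LOCUS_GAP
    return validate_annotation(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Paired counts
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Configuration for a paired tumor/normal count cohort.

    ``planted_effects`` is a list of ``(feature_id, level, fold_change)``
    with level in {"trna", "codon", "amino_acid"}; codon keys use the
    ``"AA:CODON"`` form.  ``dispersion`` is the NB phi in
    ``Var = mu + phi mu**2``.  Library sizes are drawn uniformly from
    ``library_size_range``.
    """

    n_trna_genes: int = 100
    n_pairs: int = 15
    cancer_type: str = "SYNT"
    planted_effects: list[tuple[str, str, float]] = field(default_factory=list)
    dispersion: float = 0.1
    mean_log2_abundance: float = 7.0
    abundance_sd: float = 2.0
    library_size_range: tuple[float, float] = (8e5, 1.2e6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trna_genes < 1:
            raise ValueError("n_trna_genes must be >= 1")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be positive with min <= max")
        for fid, level, fc in self.planted_effects:
            if level not in {"trna", "codon", "amino_acid"}:
                raise ValueError(f"unknown level {level!r} for planted effect {fid!r}")
            if fc <= 0:
                raise ValueError(f"fold_change must be > 0 for {fid!r}, got {fc}")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated cohort."""

    fc_trna: pd.Series
    fc_codon: pd.Series
    fc_amino_acid: pd.Series
    lib_scales: pd.Series
    base_abundance: pd.Series


def _members(feature_id: str, level: str, hmap: HierarchyMap) -> list[str]:
    if level == "trna":
        if feature_id not in hmap.gene_to_codon:
            raise KeyError(f"planted tRNA gene {feature_id!r} not in annotation")
        return [feature_id]
    if level == "codon":
        members = [g for g, c in hmap.gene_to_codon.items() if c == feature_id]
        if not members:
            raise KeyError(f"planted codon {feature_id!r} not in annotation")
        return members
    members = [g for g in hmap.gene_to_codon if hmap.aa_of(g) == feature_id]
    if not members:
        raise KeyError(f"planted amino acid {feature_id!r} not in annotation")
    return members


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    mu = np.maximum(mu, 1e-12)
    if phi <= 1e-12:
        return rng.poisson(mu)
    size = 1.0 / phi
    return rng.negative_binomial(size, size / (size + mu))


def _group_fc(fc_gene: pd.Series, abundance: pd.Series, groups: pd.Series) -> pd.Series:
    """Abundance-weighted group fold change implied by gene-level effects."""
    df = pd.DataFrame({"fc": fc_gene, "w": abundance, "g": groups})
    return df.groupby("g").apply(
        lambda s: float(np.sum(s["fc"] * s["w"]) / np.sum(s["w"])),
        include_groups=False,
    )


def simulate_paired_counts(
    config: SimConfig, annotation: pd.DataFrame
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate a paired tumor/normal NB count cohort.

    Gene abundances are log-normal around ``mean_log2_abundance``;
    per-sample library scales are uniform over ``library_size_range``;
    tumor means of planted features are multiplied by their fold change.
    Returns the counts, a sample metadata table (with QC read statistics
    that pass the sample filter), and the ground truth.
    """
    annotation = validate_annotation(annotation)
    rng = np.random.default_rng(config.seed)
    genes = annotation["gene_id"].to_numpy()
    hmap = build_hierarchy(annotation)

    log2_ab = rng.normal(config.mean_log2_abundance, config.abundance_sd, genes.size)
    abundance = pd.Series(np.exp2(log2_ab), index=genes)
    rel = abundance / abundance.sum()

    fc_gene = pd.Series(1.0, index=genes)
    for fid, level, fc in config.planted_effects:
        for g in _members(fid, level, hmap):
            fc_gene[g] *= fc

    lo, hi = config.library_size_range
    n = config.n_pairs
    lib = rng.uniform(lo, hi, size=2 * n)  # tumor, normal interleaved per patient

    patient_ids = [f"P{i + 1:04d}" for i in range(n)]
    sample_rows = []
    columns = {}
    for i, pid in enumerate(patient_ids):
        for j, tissue in enumerate(("tumor", "normal")):
            lib_k = lib[2 * i + j]
            mu = rel.to_numpy() * lib_k
            if tissue == "tumor":
                mu = mu * fc_gene.to_numpy()
            sid = f"{pid}-{'T' if tissue == 'tumor' else 'N'}"
            columns[sid] = _nb_draw(rng, mu, config.dispersion)
            mapped = int(round(lib_k))
            total = int(round(mapped / 0.95))
            sample_rows.append(
                {
                    "sample_id": sid,
                    "patient_id": pid,
                    "cancer_type": config.cancer_type,
                    "tissue": tissue,
                    "total_reads": total,
                    "qc_passed_reads": int(round(0.9 * total)),
                    "mapped_reads": mapped,
                }
            )

    counts = pd.DataFrame(columns, index=genes)
    metadata = pd.DataFrame(sample_rows)
    lib_sizes = metadata.set_index("sample_id")["mapped_reads"].astype(np.int64)
    cm = CountMatrix(counts=counts, lib_sizes=lib_sizes)

    codon_groups = pd.Series({g: hmap.codon_of(g) for g in genes})
    aa_groups = pd.Series({g: hmap.aa_of(g) for g in genes})
    truth = SyntheticTruth(
        fc_trna=fc_gene,
        fc_codon=_group_fc(fc_gene, abundance, codon_groups),
        fc_amino_acid=_group_fc(fc_gene, abundance, aa_groups),
        lib_scales=pd.Series(lib, index=counts.columns),
        base_abundance=abundance,
    )
    return cm, metadata, truth


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def simulate_alignments(
    counts: pd.Series,
    annotation: pd.DataFrame,
    seed: int,
    unmapped_fraction: float = 0.0,
    qcfail_fraction: float = 0.0,
    read_length: int = READ_LENGTH,
) -> str:
    """Emit SAM text realizing exact per-locus read counts.

    Exactly ``counts[g]`` primary mapped (flag 0/16) reads fall fully
    inside each locus ``g``.  ``qcfail_fraction`` adds mapped reads with
    the QC-fail flag (512) over random loci and ``unmapped_fraction`` adds
    unmapped records (flag 4); both are fractions of the corresponding
    final totals, so e.g. ``unmapped_fraction=0.5`` on 100 mapped reads
    appends 100 unmapped records.
    """
    annotation = validate_annotation(annotation)
    counts = counts.reindex(annotation["gene_id"]).fillna(0).astype(int)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if not 0 <= unmapped_fraction < 1 or not 0 <= qcfail_fraction < 1:
        raise ValueError("contamination fractions must be in [0, 1)")
    rng = np.random.default_rng(seed)

    loci = annotation.set_index("gene_id")
    short = loci[(loci["end"] - loci["start"]) < read_length]
    if not short.empty:
        raise ValueError(
            f"loci shorter than read length {read_length}: {short.index.tolist()}"
        )

    chrom_len = {
        chrom: int(sub["end"].max()) + 100
        for chrom, sub in annotation.groupby("chrom")
    }
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for chrom in sorted(chrom_len):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{chrom_len[chrom]}")

    def _read_line(name: str, flag: int, chrom: str, pos0: int) -> str:
        seq = "".join(rng.choice(list(BASES), size=read_length))
        if flag & 4:
            return f"{name}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{'I' * read_length}"
        return (
            f"{name}\t{flag}\t{chrom}\t{pos0 + 1}\t{MAPQ}\t{read_length}M"
            f"\t*\t0\t0\t{seq}\t{'I' * read_length}"
        )

    n_read = 0
    for gid, c in counts.items():
        row = loci.loc[gid]
        for _ in range(int(c)):
            pos0 = int(rng.integers(row["start"], row["end"] - read_length + 1))
            flag = 0 if rng.random() < 0.5 else 16
            lines.append(_read_line(f"r{n_read:07d}", flag, row["chrom"], pos0))
            n_read += 1

    n_counted = int(counts.sum())
    n_qcfail = int(round(n_counted * qcfail_fraction / (1 - qcfail_fraction)))
    gene_ids = loci.index.to_numpy()
    for _ in range(n_qcfail):
        row = loci.loc[gene_ids[rng.integers(gene_ids.size)]]
        pos0 = int(rng.integers(row["start"], row["end"] - read_length + 1))
        lines.append(_read_line(f"r{n_read:07d}", 512, row["chrom"], pos0))
        n_read += 1

    n_mapped = n_counted + n_qcfail
    n_unmapped = int(round(n_mapped * unmapped_fraction / (1 - unmapped_fraction)))
    for _ in range(n_unmapped):
        lines.append(_read_line(f"r{n_read:07d}", 4, "*", 0))
        n_read += 1

    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Coding sequences
# ---------------------------------------------------------------------------

def simulate_coding_sequences(
    n_codons: int,
    seed: int,
    base_freqs=None,
    codon_bias: dict[str, float] | None = None,
    n_genes: int = 1,
) -> list[SeqRecord]:
    """Generate toy CDS records with controlled codon composition.

    ``codon_bias`` maps codons to sampling weights; if omitted it defaults
    to the base-product model over sense codons from ``base_freqs``
    (uniform bases if neither is given).  Realized codon frequencies
    converge to the bias as ``n_codons`` grows.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if n_genes < 1 or n_genes > n_codons:
        raise ValueError("need 1 <= n_genes <= n_codons")
    rng = np.random.default_rng(seed)

    if codon_bias is None:
        if base_freqs is None:
            bf = pd.Series(0.25, index=list(BASES))
        else:
            bf = pd.Series(base_freqs, index=list(BASES)).astype(float)
            if (bf < 0).any() or abs(bf.sum() - 1.0) > 1e-8:
                raise ValueError("base_freqs must be non-negative and sum to 1")
        weights = {c: bf[c[0]] * bf[c[1]] * bf[c[2]] for c in SENSE_CODONS}
    else:
        bad = [c for c in codon_bias if c not in CODONS]
        if bad:
            raise ValueError(f"invalid codons in codon_bias: {bad}")
        weights = {c: float(w) for c, w in codon_bias.items() if w > 0}
        if not weights:
            raise ValueError("codon_bias has no positive weights")

    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    p /= p.sum()
    draws = rng.choice(len(keys), size=n_codons, p=p)
    codons = [keys[i] for i in draws]

    per_gene = np.full(n_genes, n_codons // n_genes)
    per_gene[: n_codons % n_genes] += 1
    records, offset = [], 0
    for i, k in enumerate(per_gene):
        seq = "".join(codons[offset : offset + k])
        offset += k
        records.append(
            SeqRecord(Seq(seq), id=f"synthgene{i + 1}", description="synthetic CDS")
        )
    return records


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def simulate_survival(
    expression: pd.Series,
    log_hazard_ratio: float,
    baseline_rate: float,
    censor_rate: float = 0.2,
    seed: int | None = None,
) -> pd.DataFrame:
    """Exponential survival times with hazard tied to expression.

    Event hazard for patient i is ``baseline_rate * exp(beta * z_i)`` with
    z the standardized expression.  Censoring is an independent
    exponential process whose rate is chosen so the expected censored
    fraction under the null is ``censor_rate``; ``censor_rate=1`` censors
    every record at its drawn event time.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be > 0")
    if not 0 <= censor_rate <= 1:
        raise ValueError("censor_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    x = expression.to_numpy(dtype=float)
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    rate = baseline_rate * np.exp(log_hazard_ratio * z)
    t_event = rng.exponential(1.0 / rate)

    if censor_rate >= 1:
        time, event = t_event, np.zeros(x.size, dtype=int)
    elif censor_rate == 0:
        time, event = t_event, np.ones(x.size, dtype=int)
    else:
        rate_c = baseline_rate * censor_rate / (1 - censor_rate)
        t_censor = rng.exponential(1.0 / rate_c, size=x.size)
        time = np.minimum(t_event, t_censor)
        event = (t_event <= t_censor).astype(int)

    return pd.DataFrame(
        {"patient_id": expression.index, "time": time, "event": event}
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# CNV scores
# ---------------------------------------------------------------------------

def simulate_cnv_scores(
    genes,
    n_samples: int,
    gain_genes=(),
    loss_genes=(),
    seed: int | None = None,
    noise_sd: float = 0.15,
) -> tuple[pd.DataFrame, pd.Series]:
    """Log2-scale CNV scores centered on known gain/loss/neutral states.

    Neutral genes sit around 1.0 (two copies on the log2 copy-number
    scale), gains around 2.0 (above the log2(3) gain cutoff) and losses
    around -0.5 (below the log2(1) loss cutoff).  Returns the long-format
    score table and the per-gene true state.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    centers = {"neutral": 1.0, "gain": 2.0, "loss": -0.5}
    truth = pd.Series("neutral", index=genes)
    truth[list(gain_genes)] = "gain"
    truth[list(loss_genes)] = "loss"
    rows = []
    for g in genes:
        mu = centers[truth[g]]
        for s in range(n_samples):
            rows.append(
                {
                    "gene": g,
                    "sample": f"S{s + 1:03d}",
                    "score": mu + rng.normal(0, noise_sd),
                }
            )
    return pd.DataFrame(rows), truth
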