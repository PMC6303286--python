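"""Observed/expected (O/E) codon and amino-acid usage statistics.

The expected frequency of a codon under the base-composition product model
is the product of the frequencies of its three bases, computed over all
coding positions; the expected frequency of an amino acid is the sum over
its synonymous codons.  Observed frequencies are direct codon counts over
the coding sequences, with stop codons excluded from the sense-codon
denominator and reported separately.  The O/E ratio is their elementwise
quotient.

Note the deliberate asymmetry: expected codon frequencies are the pure
base products (summing to 1 over all 64 codons, stops included) while
observed frequencies are over sense codons only.

The module also ties O/E to differential expression: a comparison of codon
O/E between pervasively up- and down-regulated codons (Welch t, rank-sum,
and a pooled-null bootstrap of the mean difference), and a Spearman
correlation of amino-acid O/E against expression alterations within a
cancer type.
"""

from __future__ import annotations

from collections import Counter
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from scipy import stats

__all__ = [
    "BASES",
    "CODONS",
    "GENETIC_CODE",
    "base_frequencies",
    "expected_frequencies",
    "observed_frequencies",
    "oe_table",
    "gene_oe_table",
    "compare_oe_by_direction",
    "correlate_oe_with_alteration",
]

BASES = ("A", "C", "G", "T")
CODONS = tuple("".join(c) for c in product(BASES, repeat=3))

_ONE_TO_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> three-letter amino acid, "*" for stops (standard genetic code)
GENETIC_CODE: dict[str, str] = {
    codon: _ONE_TO_THREE[aa] for codon, aa in _STANDARD.forward_table.items()
}
GENETIC_CODE.update({codon: "*" for codon in _STANDARD.stop_codons})

STOP_CODONS = tuple(_STANDARD.stop_codons)
SENSE_CODONS = tuple(c for c in CODONS if GENETIC_CODE[c] != "*")


def _genetic_code(sec_tga: bool) -> dict[str, str]:
    """Standard code, optionally recoding TGA as selenocysteine (Sec)."""
    code = dict(GENETIC_CODE)
    if sec_tga:
        code["TGA"] = "Sec"
    return code


def _iter_sequences(cds) -> list[str]:
    """Accept a FASTA path, SeqRecords, or plain strings."""
    if isinstance(cds, (str, Path)):
        records = SeqIO.parse(str(cds), "fasta")
        seqs = [str(r.seq).upper() for r in records]
    else:
        seqs = [
            str(getattr(s, "seq", s)).upper() for s in cds
        ]
    if not seqs:
        raise ValueError("no coding sequences supplied")
    for i, s in enumerate(seqs):
        if len(s) % 3 != 0:
            raise ValueError(f"sequence {i} has length {len(s)}, not divisible by 3")
    return seqs


def base_frequencies(cds) -> tuple[pd.Series, int]:
    """Base frequencies over all coding positions.

    Ambiguity codes are skipped; the count of skipped positions is
    returned alongside the A/C/G/T frequency vector (which sums to 1).
    """
    seqs = _iter_sequences(cds)
    counts = Counter()
    for s in seqs:
        counts.update(s)
    skipped = sum(v for b, v in counts.items() if b not in BASES)
    total = sum(counts[b] for b in BASES)
    if total == 0:
        raise ValueError("no unambiguous bases in input")
    freqs = pd.Series({b: counts[b] / total for b in BASES}, name="freq")
    return freqs, skipped


def expected_frequencies(
    base_freqs: pd.Series, sec_tga: bool = False
) -> tuple[pd.Series, pd.Series]:
    """Expected codon and amino-acid frequencies from base composition.

    Codon expectation is the product of its three base frequencies with no
    renormalization (the 64 expectations sum to 1, stop codons included).
    Amino-acid expectation sums the expectations of synonymous codons;
    stop codons are tracked under the ``"*"`` key.
    """
    bf = pd.Series(base_freqs).reindex(list(BASES))
    if bf.isna().any() or (bf < 0).any() or abs(bf.sum() - 1.0) > 1e-8:
        raise ValueError("base_freqs must be a non-negative A/C/G/T vector summing to 1")
    codon_exp = pd.Series(
        {c: bf[c[0]] * bf[c[1]] * bf[c[2]] for c in CODONS}, name="expected_freq"
    )
    code = _genetic_code(sec_tga)
    aa_exp = codon_exp.groupby(codon_exp.index.map(code.get)).sum()
    aa_exp.name = "expected_freq"
    return codon_exp, aa_exp


def observed_frequencies(cds, sec_tga: bool = False) -> dict:
    """Observed codon and amino-acid frequencies in coding sequences.

    Sense-codon frequencies sum to 1; stop codons are excluded from the
    denominator and reported separately (as counts and as a fraction of
    all codons).  With ``sec_tga=True`` TGA is treated as the Sec sense
    codon instead of a stop.
    """
    seqs = _iter_sequences(cds)
    code = _genetic_code(sec_tga)
    sense = [c for c in CODONS if code[c] != "*"]
    counts = Counter()
    skipped = 0
    for s in seqs:
        for i in range(0, len(s), 3):
            codon = s[i : i + 3]
            if set(codon) <= set(BASES):
                counts[codon] += 1
            else:
                skipped += 1
    n_stop = sum(counts[c] for c in CODONS if code[c] == "*")
    n_sense = sum(counts[c] for c in sense)
    if n_sense == 0:
        raise ValueError("no sense codons in input")
    codon_obs = pd.Series(
        {c: counts[c] / n_sense for c in sense}, name="observed_freq"
    )
    aa_obs = codon_obs.groupby(codon_obs.index.map(code.get)).sum()
    aa_obs.name = "observed_freq"
    total = n_sense + n_stop
    return {
        "codon": codon_obs,
        "amino_acid": aa_obs,
        "n_sense_codons": n_sense,
        "n_stop_codons": n_stop,
        "stop_fraction": n_stop / total if total else 0.0,
        "n_skipped_codons": skipped,
    }


def _oe_frame(unit: str, observed: pd.Series, expected: pd.Series) -> pd.DataFrame:
    expected = expected.reindex(observed.index)
    if (expected <= 0).any() or expected.isna().any():
        bad = expected.index[(expected <= 0) | expected.isna()].tolist()
        raise ValueError(f"expected frequency must be positive; offending keys: {bad}")
    return pd.DataFrame(
        {
            "unit": unit,
            "key": observed.index,
            "observed_freq": observed.to_numpy(),
            "expected_freq": expected.to_numpy(),
            "oe_ratio": observed.to_numpy() / expected.to_numpy(),
        }
    ).reset_index(drop=True)


def oe_table(cds, sec_tga: bool = False) -> pd.DataFrame:
    """Full O/E table (codon and amino-acid rows) for a CDS collection."""
    bf, _ = base_frequencies(cds)
    codon_exp, aa_exp = expected_frequencies(bf, sec_tga=sec_tga)
    obs = observed_frequencies(cds, sec_tga=sec_tga)
    codon_part = _oe_frame("codon", obs["codon"], codon_exp)
    aa_keys = [k for k in obs["amino_acid"].index if k != "*"]
    aa_part = _oe_frame("amino_acid", obs["amino_acid"].loc[aa_keys], aa_exp)
    return pd.concat([codon_part, aa_part], ignore_index=True)


def gene_oe_table(gene_cds, genome_expected: dict[str, pd.Series], sec_tga: bool = False) -> pd.DataFrame:
    """Per-gene O/E: the gene's observed usage over genome-level expectations.

    ``genome_expected`` maps ``{"codon": Series, "amino_acid": Series}`` as
    returned by :func:`expected_frequencies` on the genome-wide CDS set.
    """
    obs = observed_frequencies(gene_cds, sec_tga=sec_tga)
    codon_part = _oe_frame("codon", obs["codon"], genome_expected["codon"])
    aa_keys = [k for k in obs["amino_acid"].index if k != "*"]
    aa_part = _oe_frame(
        "amino_acid", obs["amino_acid"].loc[aa_keys], genome_expected["amino_acid"]
    )
    return pd.concat([codon_part, aa_part], ignore_index=True)


# ---------------------------------------------------------------------------
# O/E vs differential expression
# ---------------------------------------------------------------------------

def bootstrap_mean_diff_test(
    x: np.ndarray, y: np.ndarray, n_boot: int = 10_000, seed: int | None = None
) -> float:
    """Two-sided pooled-null bootstrap p for a difference in group means.

    Both groups are resampled (with replacement) from the pooled values,
    preserving group sizes; p = (1 + #{|T*| >= |T|}) / (B + 1).
    """
    if seed is None:
        raise ValueError("a seed is required for the bootstrap test")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    t_obs = abs(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    bx = rng.choice(pooled, size=(n_boot, x.size), replace=True).mean(axis=1)
    by = rng.choice(pooled, size=(n_boot, y.size), replace=True).mean(axis=1)
    t_star = np.abs(bx - by)
    return float((1 + np.sum(t_star >= t_obs)) / (n_boot + 1))


def compare_oe_by_direction(
    oe: pd.Series,
    up_keys,
    down_keys,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Compare O/E ratios of up-regulated vs down-regulated codon groups.

    Runs a two-sided Welch t-test, a two-sided rank-sum test, and a
    two-sided pooled-null bootstrap of the difference in group means.
    ``oe`` is indexed by codon key; ``up_keys``/``down_keys`` are typically
    the pervasively up-/down-regulated codons from the differential stage.
    """
    up = oe.reindex(list(up_keys)).dropna().to_numpy()
    down = oe.reindex(list(down_keys)).dropna().to_numpy()
    if up.size < 2 or down.size < 2:
        raise ValueError(
            f"need >= 2 codons per group; got up={up.size}, down={down.size}"
        )
    t_stat, t_p = stats.ttest_ind(up, down, equal_var=False)
    w_stat, w_p = stats.ranksums(up, down)
    boot_p = bootstrap_mean_diff_test(up, down, n_boot=n_boot, seed=seed)
    return {
        "mean_up": float(up.mean()),
        "mean_down": float(down.mean()),
        "t_stat": float(t_stat),
        "t_p": float(t_p),
        "wilcoxon_stat": float(w_stat),
        "wilcoxon_p": float(w_p),
        "bootstrap_p": boot_p,
        "n_up": int(up.size),
        "n_down": int(down.size),
    }


def correlate_oe_with_alteration(
    oe_aa: pd.Series, de_aa: pd.DataFrame, cancer_type: str
) -> tuple[float, float]:
    """Spearman correlation of amino-acid O/E vs expression alteration.

    ``de_aa`` is an amino-acid-level differential table; the alteration is
    the log2 fold change within ``cancer_type``.  Ranks are averaged on
    ties.  Requires at least 4 amino acids with both values.
    """
    sub = de_aa[de_aa["cancer_type"] == cancer_type]
    fc = pd.Series(
        np.log2(sub["fold_change"].to_numpy()), index=sub["feature_id"]
    )
    shared = fc.index.intersection(oe_aa.index)
    fc = fc.loc[shared].replace([np.inf, -np.inf], np.nan).dropna()
    shared = fc.index
    if len(shared) < 4:
        raise ValueError(
            f"only {len(shared)} amino acids with both O/E and fold change; need >= 4"
        )
    rho, p = stats.spearmanr(oe_aa.loc[shared], fc)
    return float(rho), float(p)
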