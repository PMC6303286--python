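"""Three-level tRNA hierarchy: gene -> codon -> amino acid.

A tRNA gene decodes the codon that is the strict Watson-Crick reverse
complement of its anticodon (no wobble expansion).  Genes sharing a
decoded codon (isodecoders) are merged at the codon level; codons sharing
an accepted amino acid are merged at the amino-acid level.  Initiator
methionine (iMet) is kept distinct from elongator Met at both levels, and
selenocysteine (Sec) is a first-class group.

Codon-level keys are strings ``"<AA>:<codon>"`` (e.g. ``"Arg:CGT"``);
amino-acid keys are the labels themselves (``"Arg"``, ``"iMet"``, ...).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .quantify import CountMatrix, validate_annotation

__all__ = [
    "HierarchyMap",
    "anticodon_to_codon",
    "codon_key",
    "build_hierarchy",
    "aggregate_counts",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_BASES = frozenset("ACGT")


def anticodon_to_codon(anticodon: str) -> str:
    """Decoded codon under strict Watson-Crick pairing: the reverse complement."""
    anticodon = anticodon.upper()
    if len(anticodon) != 3 or not set(anticodon) <= _VALID_BASES:
        raise ValueError(f"invalid anticodon {anticodon!r}: need a DNA triplet")
    return anticodon.translate(_COMPLEMENT)[::-1]


def codon_key(amino_acid: str, anticodon: str, is_initiator: bool = False) -> str:
    label = "iMet" if is_initiator else amino_acid
    return f"{label}:{anticodon_to_codon(anticodon)}"


@dataclass(frozen=True)
class HierarchyMap:
    """gene_id -> codon key -> amino-acid label mappings (total functions)."""

    gene_to_codon: dict[str, str]
    codon_to_aa: dict[str, str]

    def codon_of(self, gene_id: str) -> str:
        return self.gene_to_codon[gene_id]

    def aa_of(self, gene_id: str) -> str:
        return self.codon_to_aa[self.gene_to_codon[gene_id]]

    def group_of(self, gene_id: str, level: str) -> str:
        if level == "trna":
            return gene_id
        if level == "codon":
            return self.codon_of(gene_id)
        if level == "amino_acid":
            return self.aa_of(gene_id)
        raise ValueError(f"unknown level {level!r}")

    @property
    def codon_keys(self) -> list[str]:
        return sorted(set(self.gene_to_codon.values()))

    @property
    def amino_acids(self) -> list[str]:
        return sorted(set(self.codon_to_aa.values()))


def build_hierarchy(annotation: pd.DataFrame) -> HierarchyMap:
    """Build the gene/codon/amino-acid map from an annotation table.

    iMet genes (``is_initiator``) are grouped separately from elongator Met
    even though both carry the CAT anticodon.  The amino-acid panel is
    data-driven — whatever labels the annotation provides (21 standard
    amino acids plus Sec and iMet in the human annotation).
    """
    annotation = validate_annotation(annotation)
    gene_to_codon: dict[str, str] = {}
    codon_to_aa: dict[str, str] = {}
    for row in annotation.itertuples(index=False):
        label = "iMet" if row.is_initiator else row.amino_acid
        ckey = codon_key(row.amino_acid, row.anticodon, bool(row.is_initiator))
        gene_to_codon[row.gene_id] = ckey
        codon_to_aa[ckey] = label
    return HierarchyMap(gene_to_codon=gene_to_codon, codon_to_aa=codon_to_aa)


def aggregate_counts(cm: CountMatrix, hmap: HierarchyMap, level: str) -> CountMatrix:
    """Sum member-gene counts into codon- or amino-acid-level groups.

    Library sizes are unchanged (they are whole-sample totals).  Total
    counts are conserved exactly across levels.
    """
    if level not in {"codon", "amino_acid"}:
        raise ValueError(f"level must be 'codon' or 'amino_acid', got {level!r}")
    missing = [g for g in cm.features if g not in hmap.gene_to_codon]
    if missing:
        raise KeyError(f"features missing from hierarchy map: {missing}")
    groups = pd.Series(
        {g: hmap.group_of(g, level) for g in cm.features}, name="group"
    )
    agg = cm.counts.groupby(groups).sum().sort_index()
    return CountMatrix(counts=agg, lib_sizes=cm.lib_sizes.copy())
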