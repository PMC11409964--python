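"""Core domain types shared across the pipeline.

All protein-residue coordinates are 1-based inclusive, matching HGVS.p
style annotations such as ``p.Q294R``. All sequences are uppercase
strings over the 20 standard amino-acid one-letter codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Letters seen in MS exports that are not standard residues
#: (ambiguity codes, selenocysteine, pyrrolysine, unknowns).
NONSTANDARD_LETTERS = frozenset("BJOUXZ*")


def is_standard_sequence(seq: str) -> bool:
    """True iff ``seq`` is non-empty and uses only the 20 standard letters."""
    return bool(seq) and all(c in _AA_SET for c in seq)


class HLAClass(str, Enum):
    """HLA class of an eluted-peptide repertoire.

    Class I molecules present short peptides (8-12 residues here) to
    CD8+ T cells; class II present longer peptides (10-25) to CD4+.
    """

    I = "I"
    II = "II"


#: Ligand length bounds (inclusive) applied to MS peptide lists per class.
LENGTH_BOUNDS: dict[HLAClass, tuple[int, int]] = {
    HLAClass.I: (8, 12),
    HLAClass.II: (10, 25),
}


@dataclass(frozen=True)
class ProteinRecord:
    """One reference-proteome entry."""

    protein_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not is_standard_sequence(self.sequence):
            bad = next(
                (i for i, c in enumerate(self.sequence) if c not in _AA_SET), None
            )
            raise ValueError(
                f"protein {self.protein_id!r}: invalid residue at offset {bad}"
                if bad is not None
                else f"protein {self.protein_id!r}: empty sequence"
            )


@dataclass(frozen=True)
class MissenseMutation:
    """A somatic single-residue substitution in protein coordinates.

    ``position`` is the 1-based residue index; ``label`` is free text,
    conventionally ``"<gene> p.<ref><pos><alt>"``.
    """

    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str
    gene_id: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for name, aa in (("ref_aa", self.ref_aa), ("alt_aa", self.alt_aa)):
            if len(aa) != 1 or aa not in _AA_SET:
                raise ValueError(f"{name} {aa!r} is not a standard amino acid")
        if self.ref_aa == self.alt_aa:
            raise ValueError(
                f"ref_aa == alt_aa ({self.ref_aa!r}) at {self.protein_id}:"
                f"{self.position}: not a missense change"
            )

    @property
    def hgvs_p(self) -> str:
        return f"p.{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class SurrogatePeptidome:
    """A deduplicated HLA-eluted peptide set from non-tumor material.

    The surrogate repertoire (autologous LCL, normal mucosa, spleen)
    stands in for the tumor's own ligandome when searching for wild-type
    counterparts of candidate neoantigens.
    """

    peptides: frozenset[str]
    hla_class: HLAClass
    sample_label: str = ""

    def __post_init__(self) -> None:
        for p in self.peptides:
            if not is_standard_sequence(p):
                raise ValueError(f"invalid peptide {p!r}")
            if p != p.upper():
                raise ValueError(f"peptide {p!r} not uppercase-normalized")

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self):
        return iter(sorted(self.peptides))


@dataclass(frozen=True)
class ExpressionTable:
    """gene_id -> TPM (transcripts per million) from tumor RNA-seq."""

    tpm: Mapping[str, float]

    def __post_init__(self) -> None:
        for gene, value in self.tpm.items():
            if value < 0:
                raise ValueError(f"negative TPM for gene {gene!r}: {value}")

    def get(self, gene_id: str) -> float | None:
        return self.tpm.get(gene_id)

    def __len__(self) -> int:
        return len(self.tpm)


@dataclass(frozen=True)
class RankScoreTable:
    """(peptide, allele) -> %rank from an external binding predictor.

    %rank is a percentile where LOWER means stronger predicted binding;
    by NetMHCpan convention <0.5 marks strong and <2.0 weak binders.
    The predictor itself is consumed as a table, never embedded.
    """

    ranks: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (pep, allele), value in self.ranks.items():
            if value < 0:
                raise ValueError(f"negative %rank for ({pep}, {allele}): {value}")

    def get(self, peptide: str, allele: str) -> float | None:
        return self.ranks.get((peptide, allele))

    def __len__(self) -> int:
        return len(self.ranks)


#: Candidate filter flags.
FLAG_PASS = "PASS"
FLAG_LOW_EXPRESSION = "LOW_EXPRESSION"
FLAG_NO_EXPRESSION_DATA = "NO_EXPRESSION_DATA"


@dataclass(frozen=True)
class MutationSite:
    """One substitution applied to a protein in a proteome pair."""

    position: int
    ref_aa: str
    alt_aa: str
    gene_id: str
    label: str = ""


@dataclass(frozen=True)
class PeptideMatch:
    """A surrogate peptide occurrence in a wild-type protein that covers
    at least one mutated residue and is absent from every mutant sequence."""

    peptide: str
    protein_id: str
    start: int  # 1-based residue index of the first peptide residue
    covered_sites: tuple[int, ...]  # mutation positions inside the window

    @property
    def end(self) -> int:
        return self.start + len(self.peptide) - 1


@dataclass(frozen=True)
class CandidateNeoantigen:
    """A collapsed candidate: all length variants covering one exact
    set of substitutions in one protein, counted as a single peptide."""

    protein_id: str
    gene_id: str
    covered_sites: tuple[tuple[int, str, str], ...]  # (position, ref, alt) sorted
    members: tuple[tuple[str, str, int], ...]  # (wt_peptide, mutant_peptide, start)
    representative_wt: str
    representative_mut: str
    hla_class: HLAClass
    tpm: float | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def passed(self) -> bool:
        return FLAG_PASS in self.flags
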