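"""Tandem in vitro transcription/translation (IVTT) construct design.

Candidate peptides are screened for T-cell recognition by translating
them from synthetic DNA vectors in a reconstituted E. coli system. Each
"neoantigen unit" carries its own T7 promoter, ribosome binding site,
start codon, FLAG tag (DYKDDDDK) and the peptide's coding sequence,
followed by a stop codon and a 3'UTR stem-loop; enterokinase cleaves
after the FLAG tag's ...DDDDK, releasing the peptide with no extra
N-terminal residues. Up to ten units are packed in tandem per vector,
each flanked by unique restriction sites so single units can be excised
for second-round screening.

Codon choice is deterministic max-usage from a bundled E. coli K-12
table (the expression host of the reconstituted system) so repeated
designs are reproducible; a seeded usage-weighted mode is available.
The element sequences below are canonical published defaults and fully
configurable — the construct anatomy is fixed, the exact bases are not.
Restriction handling is recognition-site scanning only (forward strand;
the catalog sites are palindromic); cut-position chemistry is out of
scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .errors import CatalogExhaustedError, DesignError, SiteCollisionError

FLAG_TAG = "DYKDDDDK"

#: E. coli K-12 codon usage (fraction per amino acid). Used for
#: max-usage codon selection and for the optional weighted mode.
ECOLI_CODON_USAGE: dict[str, tuple[tuple[str, float], ...]] = {
    "A": (("GCG", 0.36), ("GCC", 0.27), ("GCA", 0.21), ("GCT", 0.16)),
    "R": (("CGT", 0.38), ("CGC", 0.40), ("CGG", 0.10), ("CGA", 0.06), ("AGA", 0.04), ("AGG", 0.02)),
    "N": (("AAC", 0.55), ("AAT", 0.45)),
    "D": (("GAT", 0.63), ("GAC", 0.37)),
    "C": (("TGC", 0.55), ("TGT", 0.45)),
    "Q": (("CAG", 0.65), ("CAA", 0.35)),
    "E": (("GAA", 0.69), ("GAG", 0.31)),
    "G": (("GGC", 0.40), ("GGT", 0.34), ("GGG", 0.15), ("GGA", 0.11)),
    "H": (("CAT", 0.57), ("CAC", 0.43)),
    "I": (("ATT", 0.51), ("ATC", 0.42), ("ATA", 0.07)),
    "L": (("CTG", 0.50), ("TTA", 0.13), ("TTG", 0.13), ("CTT", 0.10), ("CTC", 0.10), ("CTA", 0.04)),
    "K": (("AAA", 0.77), ("AAG", 0.23)),
    "M": (("ATG", 1.00),),
    "F": (("TTT", 0.57), ("TTC", 0.43)),
    "P": (("CCG", 0.52), ("CCA", 0.19), ("CCT", 0.16), ("CCC", 0.13)),
    "S": (("AGC", 0.28), ("TCT", 0.15), ("TCC", 0.15), ("TCG", 0.15), ("AGT", 0.15), ("TCA", 0.12)),
    "T": (("ACC", 0.44), ("ACG", 0.27), ("ACT", 0.17), ("ACA", 0.13)),
    "W": (("TGG", 1.00),),
    "Y": (("TAT", 0.57), ("TAC", 0.43)),
    "V": (("GTG", 0.37), ("GTT", 0.26), ("GTC", 0.22), ("GTA", 0.15)),
}

#: Common type-II enzymes with palindromic recognition sites, in the
#: deterministic assignment order.
RESTRICTION_ENZYMES: tuple[tuple[str, str], ...] = (
    ("EcoRI", "GAATTC"),
    ("BamHI", "GGATCC"),
    ("HindIII", "AAGCTT"),
    ("XhoI", "CTCGAG"),
    ("SalI", "GTCGAC"),
    ("XbaI", "TCTAGA"),
    ("NcoI", "CCATGG"),
    ("KpnI", "GGTACC"),
    ("SacI", "GAGCTC"),
    ("PstI", "CTGCAG"),
    ("SphI", "GCATGC"),
    ("NheI", "GCTAGC"),
    ("SpeI", "ACTAGT"),
    ("MluI", "ACGCGT"),
    ("BglII", "AGATCT"),
    ("EcoRV", "GATATC"),
    ("SmaI", "CCCGGG"),
    ("ApaI", "GGGCCC"),
    ("AvrII", "CCTAGG"),
    ("NotI", "GCGGCCGC"),
    ("AscI", "GGCGCGCC"),
    ("PacI", "TTAATTAA"),
    ("FseI", "GGCCGGCC"),
    ("SbfI", "CCTGCAGG"),
)


@dataclass(frozen=True)
class RegulatoryElements:
    """Fixed non-coding parts of a neoantigen unit (5' -> 3')."""

    t7_promoter: str = "TAATACGACTCACTATAGGG"
    rbs: str = "AAGGAGGTAATAAAT"  # Shine-Dalgarno + spacer, ends just before ATG
    stop_codon: str = "TAA"
    # T7 terminator class-I hairpin as the 3'UTR stem-loop
    stem_loop: str = "CTAGCATAACCCCTTGGGGCCTCTAAACGGGTCTTGAGGGGTTTTTTG"


@dataclass(frozen=True)
class RestrictionSite:
    name: str
    sequence: str


@dataclass(frozen=True)
class IVTTUnit:
    """One translatable neoantigen unit, optionally with assigned flanks."""

    peptide: str
    index: int
    nt_insert: str
    coding_start: int  # offset of ATG within nt_insert
    site_5p: RestrictionSite | None = None
    site_3p: RestrictionSite | None = None

    @property
    def coding_sequence(self) -> str:
        n = 3 * (1 + len(FLAG_TAG) + len(self.peptide)) + 3  # incl. stop
        return self.nt_insert[self.coding_start : self.coding_start + n]

    @property
    def translated(self) -> str:
        """Translation of the coding frame, without the stop."""
        return str(Seq(self.coding_sequence).translate()).rstrip("*")


@dataclass(frozen=True)
class TandemVector:
    """An ordered run of units sharing one synthetic vector."""

    name: str
    units: tuple[IVTTUnit, ...]

    def __post_init__(self) -> None:
        pairs = [
            (u.site_5p.name, u.site_3p.name)
            for u in self.units
            if u.site_5p and u.site_3p
        ]
        if len(set(pairs)) != len(pairs):
            raise DesignError(f"{self.name}: duplicate restriction-site pairs")

    @property
    def insert_sequence(self) -> str:
        """Full tandem insert: units interleaved with their flanking sites
        (a shared site between adjacent units is emitted once)."""
        pieces: list[str] = []
        prev_3p: str | None = None
        for u in self.units:
            if u.site_5p and u.site_5p.name != prev_3p:
                pieces.append(u.site_5p.sequence)
            pieces.append(u.nt_insert)
            if u.site_3p:
                pieces.append(u.site_3p.sequence)
                prev_3p = u.site_3p.name
            else:
                prev_3p = None
        return "".join(pieces)


def reverse_translate(
    peptide: str,
    codon_table: Mapping[str, Sequence[tuple[str, float]]] = ECOLI_CODON_USAGE,
    rng: np.random.Generator | None = None,
) -> str:
    """Back-translate a peptide into DNA.

    Deterministic by default: the most-used codon per residue (ties by
    alphabetical codon). With ``rng``, codons are sampled proportionally
    to usage, which avoids long repeated-codon runs in homopolymeric
    stretches.
    """
    codons: list[str] = []
    for aa in peptide:
        if aa not in codon_table:
            raise DesignError(f"no codons for residue {aa!r}")
        options = codon_table[aa]
        if rng is None:
            codons.append(min(options, key=lambda cf: (-cf[1], cf[0]))[0])
        else:
            weights = np.array([f for _, f in options], dtype=float)
            codons.append(options[rng.choice(len(options), p=weights / weights.sum())][0])
    return "".join(codons)


def build_unit(
    peptide: str,
    index: int,
    site_pair: tuple[RestrictionSite, RestrictionSite] | None = None,
    elements: RegulatoryElements = RegulatoryElements(),
    codon_table: Mapping[str, Sequence[tuple[str, float]]] = ECOLI_CODON_USAGE,
    rng: np.random.Generator | None = None,
) -> IVTTUnit:
    """Assemble one unit: [T7][RBS][ATG][FLAG][peptide][stop][stem-loop].

    Verifies the coding frame translates back to M + FLAG + peptide and,
    when a site pair is given, that neither recognition sequence occurs
    inside the insert (a collision would let the excision digest cut the
    unit itself); collisions raise :class:`SiteCollisionError` so the
    caller can reassign sites.
    """
    coding = (
        "ATG"
        + reverse_translate(FLAG_TAG, codon_table, rng)
        + reverse_translate(peptide, codon_table, rng)
        + elements.stop_codon
    )
    nt_insert = elements.t7_promoter + elements.rbs + coding + elements.stem_loop
    if set(nt_insert) - set("ACGT"):
        raise DesignError(f"unit {index}: non-ACGT characters in insert")
    unit = IVTTUnit(
        peptide=peptide,
        index=index,
        nt_insert=nt_insert,
        coding_start=len(elements.t7_promoter) + len(elements.rbs),
        site_5p=site_pair[0] if site_pair else None,
        site_3p=site_pair[1] if site_pair else None,
    )
    if unit.translated != "M" + FLAG_TAG + peptide:
        raise DesignError(
            f"unit {index}: coding frame translates to {unit.translated!r}"
        )
    if site_pair is not None:
        for site in site_pair:
            if site.sequence in nt_insert:
                raise SiteCollisionError(
                    f"unit {index}: recognition site {site.name} "
                    f"({site.sequence}) occurs inside the insert"
                )
    return unit


def pack_vectors(units: Sequence[IVTTUnit], capacity: int = 10) -> list[TandemVector]:
    """Greedy sequential packing preserving input order.

    Produces ceil(n / capacity) vectors named V01, V02, ... (zero-padded
    to at least width 2).
    """
    if capacity < 1:
        raise DesignError(f"capacity must be >= 1, got {capacity}")
    n_vectors = math.ceil(len(units) / capacity)
    width = max(2, len(str(n_vectors)))
    return [
        TandemVector(
            name=f"V{i + 1:0{width}d}",
            units=tuple(units[i * capacity : (i + 1) * capacity]),
        )
        for i in range(n_vectors)
    ]


def assign_sites(
    units: Sequence[IVTTUnit],
    enzyme_catalog: Sequence[tuple[str, str]] = RESTRICTION_ENZYMES,
    capacity: int = 10,
) -> list[IVTTUnit]:
    """Assign unique flanking restriction-site pairs within each vector.

    Units are grouped into vectors of ``capacity`` in order; within each
    group, consecutive catalog enzymes provide the flanks (unit i gets
    sites i and i+1, so adjacent units share a boundary site and a group
    of n units needs n+1 enzymes). Enzymes whose recognition sequence
    occurs in any insert of the group are skipped for that group.
    """
    if capacity < 1:
        raise DesignError(f"capacity must be >= 1, got {capacity}")
    assigned: list[IVTTUnit] = []
    for g in range(0, len(units), capacity):
        group = units[g : g + capacity]
        usable = [
            RestrictionSite(name, seq)
            for name, seq in enzyme_catalog
            if not any(seq in u.nt_insert for u in group)
        ]
        needed = len(group) + 1
        if len(usable) < needed:
            raise CatalogExhaustedError(
                f"vector starting at unit {g}: need {needed - len(usable)} more "
                f"collision-free enzymes ({len(usable)} usable of {needed} required)"
            )
        for i, unit in enumerate(group):
            assigned.append(replace(unit, site_5p=usable[i], site_3p=usable[i + 1]))
    return assigned


def design_tandem_vectors(
    peptides: Sequence[str],
    capacity: int = 10,
    enzyme_catalog: Sequence[tuple[str, str]] = RESTRICTION_ENZYMES,
    elements: RegulatoryElements = RegulatoryElements(),
    codon_table: Mapping[str, Sequence[tuple[str, float]]] = ECOLI_CODON_USAGE,
    rng: np.random.Generator | None = None,
) -> list[TandemVector]:
    """Full design: units, site assignment, packing — in input order."""
    units = [
        build_unit(p, i, None, elements, codon_table, rng)
        for i, p in enumerate(peptides, start=1)
    ]
    units = assign_sites(units, enzyme_catalog, capacity)
    # re-validate flanks against each insert now that sites are known
    for u in units:
        for site in (u.site_5p, u.site_3p):
            if site and site.sequence in u.nt_insert:
                raise SiteCollisionError(
                    f"unit {u.index}: assigned site {site.name} occurs in insert"
                )
    return pack_vectors(units, capacity)
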