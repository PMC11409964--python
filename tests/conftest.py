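"""Shared fixtures: the printed-peptide worked example and small helpers.

The worked example embeds the four published wild-type/neoantigen pairs
in a five-protein toy proteome:

* P1 carries RYLTVAAVF (RTF9) with its substitution OUTSIDE the peptide
  — the counterpart criterion must reject it;
* P2 carries KLNPQQFEV (KQV9) with the Q>R substitution inside (KRV9);
* P3 carries KLWDIINVNI (KII10) with I>V inside (KVI10);
* P4 carries KGEIAASIATHMRPY (KAY15) with A>V inside (KVY15);
* P5 carries a substitution covered by no surrogate peptide.
"""

from __future__ import annotations

import pytest

from nessie.proteome import build_proteome_pair
from nessie.types import (
    ExpressionTable,
    HLAClass,
    MissenseMutation,
    ProteinRecord,
    SurrogatePeptidome,
)

# the four published wild-type -> mutant transformations
PRINTED_PAIRS = {
    "RYLTVAAVF": "RYLAVAAVF",  # RTF9 -> RAF9 (T>A)
    "KLNPQQFEV": "KLNPQRFEV",  # KQV9 -> KRV9 (Q>R)
    "KLWDIINVNI": "KLWDIVNVNI",  # KII10 -> KVI10 (I>V)
    "KGEIAASIATHMRPY": "KGEIAASIVTHMRPY",  # KAY15 -> KVY15 (A>V)
}


@pytest.fixture(scope="session")
def toy_proteome() -> list[ProteinRecord]:
    return [
        ProteinRecord("P1", "GENE1", "MSTAYHKDRE" + "RYLTVAAVF" + "GWCHKNDPES"),
        ProteinRecord("P2", "STT3A", "MGAHW" + "KLNPQQFEV" + "DERTS"),
        ProteinRecord("P3", "GENE3", "MPW" + "KLWDIINVNI" + "CAES"),
        ProteinRecord("P4", "GENE4", "MKT" + "KGEIAASIATHMRPY" + "WQND"),
        ProteinRecord("P5", "GENE5", "MNDCEFGHIKWRSTVQAYLP"),
    ]


@pytest.fixture(scope="session")
def toy_mutations() -> list[MissenseMutation]:
    return [
        # P1: substitution outside the embedded peptide (peptide spans 11-19)
        MissenseMutation("P1", 3, "T", "A", "GENE1", "GENE1 p.T3A"),
        # P2: Q>R at protein position 11 = peptide position 6 of KLNPQQFEV
        MissenseMutation("P2", 11, "Q", "R", "STT3A", "STT3A p.Q11R"),
        # P3: I>V at protein position 9 = peptide position 6 of KLWDIINVNI
        MissenseMutation("P3", 9, "I", "V", "GENE3", "GENE3 p.I9V"),
        # P4: A>V at protein position 12 = peptide position 9 of KGEIAASIATHMRPY
        MissenseMutation("P4", 12, "A", "V", "GENE4", "GENE4 p.A12V"),
        # P5: substitution covered by no surrogate peptide
        MissenseMutation("P5", 5, "E", "K", "GENE5", "GENE5 p.E5K"),
    ]


#: Decoys drawn from unmutated regions of the toy proteins.
TOY_DECOYS = ("GWCHKNDPES", "MGAHWKLN", "FGHIKWRSTV", "THMRPYWQND")


@pytest.fixture(scope="session")
def toy_peptidome() -> SurrogatePeptidome:
    return SurrogatePeptidome(
        peptides=frozenset(PRINTED_PAIRS) | frozenset(TOY_DECOYS),
        hla_class=HLAClass.I,
        sample_label="toy-surrogate",
    )


@pytest.fixture(scope="session")
def toy_expression() -> ExpressionTable:
    return ExpressionTable(
        tpm={g: 10.0 for g in ("GENE1", "STT3A", "GENE3", "GENE4", "GENE5")}
    )


@pytest.fixture(scope="session")
def toy_pair(toy_proteome, toy_mutations):
    return build_proteome_pair(toy_proteome, toy_mutations)
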