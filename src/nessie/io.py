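"""Readers and writers for every external file the pipeline touches.

Dialects
--------
* Proteomes: FASTA with headers ``>protein_id`` or ``>protein_id|gene_id``;
  anything after the first whitespace is ignored. An optional sidecar TSV
  (protein_id, gene_id) overrides header-derived gene ids.
* Mutations, expression, %rank tables, candidate reports: UTF-8 TSV with a
  header row, ``.`` for missing values.
* Peptide lists: one peptide per line, or a TSV with a named sequence
  column; case-insensitive on read.

All other modules operate on the in-memory types from :mod:`nessie.types`;
nothing downstream re-parses files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from .types import (
    AMINO_ACIDS,
    CandidateNeoantigen,
    ExpressionTable,
    HLAClass,
    MissenseMutation,
    ProteinRecord,
    RankScoreTable,
    SurrogatePeptidome,
    is_standard_sequence,
)

logger = logging.getLogger(__name__)

_AA_SET = frozenset(AMINO_ACIDS)
MISSING = "."

#: Column names recognized as the peptide column in TSV peptide lists.
_PEPTIDE_COLUMNS = ("peptide", "sequence", "peptides", "pep", "seq", "annotated_sequence")


# ---------------------------------------------------------------------------
# proteomes


def read_proteome(path: str | Path, gene_map: str | Path | None = None) -> list[ProteinRecord]:
    """Read a reference proteome FASTA into :class:`ProteinRecord` objects.

    gene_id defaults to protein_id when neither the ``id|gene`` header
    dialect nor a sidecar mapping provides one.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    if gene_map is not None:
        df = pd.read_csv(gene_map, sep="\t", dtype=str)
        _require_columns(df, ("protein_id", "gene_id"), Path(gene_map))
        mapping = dict(zip(df["protein_id"], df["gene_id"]))

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.id  # SeqIO already drops everything after whitespace
        protein_id, _, gene_id = header.partition("|")
        gene_id = mapping.get(protein_id, gene_id or protein_id)
        if protein_id in seen:
            raise FormatError(f"{path}: duplicate protein_id {protein_id!r}")
        seen.add(protein_id)
        sequence = str(entry.seq).upper()
        bad = next((i for i, c in enumerate(sequence) if c not in _AA_SET), None)
        if bad is not None or not sequence:
            raise FormatError(
                f"{path}: record {protein_id!r} has a non-standard residue "
                f"at offset {bad}" if bad is not None
                else f"{path}: record {protein_id!r} is empty"
            )
        records.append(ProteinRecord(protein_id, gene_id, sequence))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_proteome(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records in the ``>id|gene`` dialect (plain ``>id`` when equal)."""
    entries = []
    for rec in records:
        header = rec.protein_id if rec.gene_id == rec.protein_id else f"{rec.protein_id}|{rec.gene_id}"
        entries.append(SeqRecord(Seq(rec.sequence), id=header, description=""))
    SeqIO.write(entries, str(path), "fasta")


# ---------------------------------------------------------------------------
# mutations


_MUTATION_COLUMNS = ("protein_id", "position", "ref_aa", "alt_aa", "gene_id", "label")


def read_mutations(path: str | Path) -> list[MissenseMutation]:
    """Read a missense-mutation TSV (protein coordinates, 1-based)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _MUTATION_COLUMNS, path)
    mutations: list[MissenseMutation] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        try:
            position = int(row.position)
        except ValueError:
            raise FormatError(f"{path}:{i}: non-integer position {row.position!r}") from None
        try:
            mutations.append(
                MissenseMutation(
                    protein_id=row.protein_id,
                    position=position,
                    ref_aa=row.ref_aa,
                    alt_aa=row.alt_aa,
                    gene_id=row.gene_id,
                    label=row.label,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: {exc}") from None
    return mutations


def write_mutations(mutations: Iterable[MissenseMutation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (m.protein_id, m.position, m.ref_aa, m.alt_aa, m.gene_id, m.label)
            for m in mutations
        ],
        columns=_MUTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# peptide lists


def read_peptides(
    path: str | Path,
    hla_class: HLAClass,
    sample_label: str = "",
    column: str | None = None,
    strict: bool = False,
) -> SurrogatePeptidome:
    """Read a peptide list (plain text or TSV) into a deduplicated set.

    Peptides containing letters outside the 20 standard codes (MS
    exports routinely contain B/J/O/U/X/Z) are dropped with a warning,
    or rejected under ``strict=True``. Duplicate sequences after
    uppercase normalization are collapsed; both counts are logged.
    """
    path = Path(path)
    raw = _extract_peptide_strings(path, column)
    if not raw:
        raise FormatError(f"{path}: empty peptide list")

    peptides: set[str] = set()
    n_dropped_nonstandard = 0
    n_duplicates = 0
    for pep in raw:
        pep = pep.upper()
        if not is_standard_sequence(pep):
            if strict:
                raise FormatError(f"{path}: peptide {pep!r} has non-standard letters")
            n_dropped_nonstandard += 1
            logger.warning("%s: dropping peptide %r (non-standard letter)", path, pep)
            continue
        if pep in peptides:
            n_duplicates += 1
        peptides.add(pep)
    logger.info(
        "%s: %d peptides kept, %d duplicates collapsed, %d non-standard dropped",
        path, len(peptides), n_duplicates, n_dropped_nonstandard,
    )
    if not peptides:
        raise FormatError(f"{path}: no valid peptides after filtering")
    return SurrogatePeptidome(
        peptides=frozenset(peptides),
        hla_class=hla_class,
        sample_label=sample_label or path.stem,
    )


def _extract_peptide_strings(path: Path, column: str | None) -> list[str]:
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        return []
    if column is not None or "\t" in lines[0]:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if column is None:
            lowered = {c.lower(): c for c in df.columns}
            for name in _PEPTIDE_COLUMNS:
                if name in lowered:
                    column = lowered[name]
                    break
            else:
                raise FormatError(
                    f"{path}: no peptide column among {list(df.columns)}; "
                    f"expected one of {_PEPTIDE_COLUMNS}"
                )
        elif column not in df.columns:
            raise FormatError(f"{path}: column {column!r} not found")
        return [p for p in df[column].tolist() if p]
    return lines


def write_peptides(peptidome: SurrogatePeptidome, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(peptidome.peptides)) + "\n")


# ---------------------------------------------------------------------------
# expression and %rank tables


def read_expression(path: str | Path) -> ExpressionTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "tpm": float})
    _require_columns(df, ("gene_id", "tpm"), path)
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    if (df["tpm"] < 0).any():
        raise FormatError(f"{path}: negative TPM values")
    return ExpressionTable(tpm=dict(zip(df["gene_id"], df["tpm"])))


def write_expression(expr: ExpressionTable, path: str | Path) -> None:
    df = pd.DataFrame(sorted(expr.tpm.items()), columns=["gene_id", "tpm"])
    df.to_csv(path, sep="\t", index=False)


def read_rank_table(path: str | Path) -> RankScoreTable:
    """Read a precomputed (peptide, allele, %rank) TSV, e.g. parsed
    NetMHCpan output."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "allele": str, "rank": float})
    _require_columns(df, ("peptide", "allele", "rank"), path)
    ranks: dict[tuple[str, str], float] = {}
    for row in df.itertuples(index=False):
        key = (row.peptide.upper(), row.allele)
        if key in ranks:
            raise FormatError(f"{path}: duplicate entry for {key}")
        ranks[key] = row.rank
    return RankScoreTable(ranks=ranks)


def write_rank_table(table: RankScoreTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [(pep, allele, rank) for (pep, allele), rank in sorted(table.ranks.items())],
        columns=["peptide", "allele", "rank"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# candidate reports

_CANDIDATE_COLUMNS = (
    "mutant_peptide",
    "wt_counterpart",
    "all_member_peptides",
    "protein_id",
    "gene_id",
    "covered_positions",
    "substitutions",
    "tpm",
    "hla_class",
    "filter_flags",
)


def candidate_sort_key(c: CandidateNeoantigen) -> tuple:
    return (c.protein_id, min(p for p, _, _ in c.covered_sites), c.representative_mut)


def write_candidates(candidates: Sequence[CandidateNeoantigen], path: str | Path) -> None:
    """Write the candidate report TSV in a deterministic row order
    (protein_id, smallest covered position, representative sequence)."""
    rows = []
    for c in sorted(candidates, key=candidate_sort_key):
        rows.append(
            (
                c.representative_mut,
                c.representative_wt,
                ";".join(f"{wt}>{mut}@{start}" for wt, mut, start in c.members),
                c.protein_id,
                c.gene_id,
                ",".join(str(p) for p, _, _ in c.covered_sites),
                ",".join(f"{ref}{p}{alt}" for p, ref, alt in c.covered_sites),
                MISSING if c.tpm is None else repr(float(c.tpm)),
                c.hla_class.value,
                ",".join(sorted(c.flags)) or MISSING,
            )
        )
    df = pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_candidates(path: str | Path) -> list[CandidateNeoantigen]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _CANDIDATE_COLUMNS, path)
    candidates = []
    for row in df.itertuples(index=False):
        members = tuple(
            (part.split(">")[0], part.split(">")[1].split("@")[0], int(part.split("@")[1]))
            for part in row.all_member_peptides.split(";")
        )
        positions = [int(p) for p in row.covered_positions.split(",")]
        subs = row.substitutions.split(",")
        covered = tuple(
            (pos, sub[0], sub[-1]) for pos, sub in zip(positions, subs)
        )
        candidates.append(
            CandidateNeoantigen(
                protein_id=row.protein_id,
                gene_id=row.gene_id,
                covered_sites=covered,
                members=members,
                representative_wt=row.wt_counterpart,
                representative_mut=row.mutant_peptide,
                hla_class=HLAClass(row.hla_class),
                tpm=None if row.tpm == MISSING else float(row.tpm),
                flags=frozenset() if row.filter_flags == MISSING else frozenset(row.filter_flags.split(",")),
            )
        )
    return candidates


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
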