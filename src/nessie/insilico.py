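"""In silico candidate counting over an external %rank table.

For each missense mutation, every 8- to 12-mer window of the MUTANT
protein that contains the substituted residue is scored against each
patient HLA allele using a supplied (peptide, allele) -> %rank table
(parsed output of an external predictor such as NetMHCpan; the
predictor is never embedded). The mutation's score is the best
predicted binder, i.e. the MINIMUM %rank over all windows and alleles —
%rank is smaller-is-stronger and the candidate rule is a "<" threshold.
Mutations with %rank < 2.0 and source-gene TPM > 1 count as candidate
neoantigens; %rank < 0.5 marks the strong-binder subset.

This module exists for side-by-side comparison with the counterpart
search, which typically emits far fewer candidates.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import MutationLookupError
from .proteome import ProteomePair
from .types import ExpressionTable, MissenseMutation, RankScoreTable

logger = logging.getLogger(__name__)

DEFAULT_KMER_LENGTHS: tuple[int, ...] = (8, 9, 10, 11, 12)
WEAK_RANK_THRESHOLD = 2.0
STRONG_RANK_THRESHOLD = 0.5


@dataclass(frozen=True)
class MutationRankSummary:
    """Best predicted binding of one mutation across windows and alleles."""

    mutation: MissenseMutation
    best_rank: float | None
    best_peptide: str
    best_allele: str
    tpm: float | None
    is_candidate: bool  # best_rank < weak threshold AND tpm > tpm threshold
    is_strong: bool  # best_rank < strong threshold


def enumerate_mutant_kmers(
    pair: ProteomePair,
    mutation: MissenseMutation,
    lengths: Iterable[int] = DEFAULT_KMER_LENGTHS,
) -> list[tuple[str, int]]:
    """All k-mer windows of the mutant protein containing the substituted
    residue, clipped at the protein ends.

    Returns (peptide, offset) pairs where ``offset`` is the 0-based
    position of the substituted residue within the peptide, in
    deterministic (k ascending, start ascending) order. An interior site
    yields min(k, ...) windows per k — up to 8+9+10+11+12 = 50 peptides
    for the default lengths.
    """
    if mutation.protein_id not in pair.mt:
        raise MutationLookupError(
            f"mutation {mutation.label or mutation.hgvs_p} references protein "
            f"{mutation.protein_id!r} absent from the proteome pair"
        )
    seq = pair.mt[mutation.protein_id]
    pos0 = mutation.position - 1  # 0-based site index
    windows: list[tuple[str, int]] = []
    for k in sorted(set(lengths)):
        first = max(0, pos0 - k + 1)
        last = min(pos0, len(seq) - k)
        for start in range(first, last + 1):
            windows.append((seq[start : start + k], pos0 - start))
    return windows


def summarize_mutation(
    mutation: MissenseMutation,
    pair: ProteomePair,
    table: RankScoreTable,
    alleles: Sequence[str],
    expr: ExpressionTable | None = None,
    weak: float = WEAK_RANK_THRESHOLD,
    strong: float = STRONG_RANK_THRESHOLD,
    tpm_threshold: float = 1.0,
    lengths: Iterable[int] = DEFAULT_KMER_LENGTHS,
    missing: str = "strict",
) -> MutationRankSummary:
    """Score one mutation: minimum %rank over windows x alleles.

    ``missing`` controls unscored (peptide, allele) pairs: ``"strict"``
    raises, ``"skip"`` ignores them with a warning. Expression absent
    from the table is treated as not passing the TPM condition.
    """
    best_rank: float | None = None
    best_peptide = ""
    best_allele = ""
    for peptide, _ in enumerate_mutant_kmers(pair, mutation, lengths):
        for allele in alleles:
            rank = table.get(peptide, allele)
            if rank is None:
                if missing == "strict":
                    raise MutationLookupError(
                        f"no %rank entry for ({peptide!r}, {allele!r})"
                    )
                logger.warning("skipping unscored pair (%s, %s)", peptide, allele)
                continue
            if best_rank is None or rank < best_rank:
                best_rank, best_peptide, best_allele = rank, peptide, allele
    tpm = expr.get(mutation.gene_id) if expr is not None else None
    expressed = tpm is not None and tpm > tpm_threshold
    return MutationRankSummary(
        mutation=mutation,
        best_rank=best_rank,
        best_peptide=best_peptide,
        best_allele=best_allele,
        tpm=tpm,
        is_candidate=best_rank is not None and best_rank < weak and expressed,
        is_strong=best_rank is not None and best_rank < strong,
    )


def count_candidates(
    mutations: Sequence[MissenseMutation],
    pair: ProteomePair,
    table: RankScoreTable,
    alleles: Sequence[str],
    expr: ExpressionTable | None = None,
    weak: float = WEAK_RANK_THRESHOLD,
    strong: float = STRONG_RANK_THRESHOLD,
    tpm_threshold: float = 1.0,
    lengths: Iterable[int] = DEFAULT_KMER_LENGTHS,
    missing: str = "strict",
) -> tuple[int, int, list[MutationRankSummary]]:
    """Candidate and strong-binder counts over all mutations.

    Returns (n_candidates, n_strong, per-mutation summaries), where
    n_strong counts candidates whose best %rank also clears the strong
    threshold — so n_strong <= n_candidates whenever strong < weak.
    """
    summaries = [
        summarize_mutation(
            m, pair, table, alleles, expr, weak, strong, tpm_threshold, lengths, missing
        )
        for m in mutations
    ]
    n_candidates = sum(s.is_candidate for s in summaries)
    n_strong = sum(s.is_candidate and s.is_strong for s in summaries)
    return n_candidates, n_strong, summaries


def pseudo_rank(peptide: str, allele: str) -> float:
    """Deterministic hash-based stand-in %rank in [0, 100).

    A test/demo scorer only: lets the counting machinery run end to end
    without an external predictor. Carries no binding information.
    """
    digest = hashlib.sha256(f"{peptide}|{allele}".encode()).digest()
    return int.from_bytes(digest[:6], "big") % 1_000_000 / 10_000.0


def pseudo_rank_table(
    pair: ProteomePair,
    mutations: Sequence[MissenseMutation],
    alleles: Sequence[str],
    lengths: Iterable[int] = DEFAULT_KMER_LENGTHS,
) -> RankScoreTable:
    """A complete pseudo-rank table covering every enumerated window."""
    ranks: dict[tuple[str, str], float] = {}
    for m in mutations:
        for peptide, _ in enumerate_mutant_kmers(pair, m, lengths):
            for allele in alleles:
                ranks[(peptide, allele)] = pseudo_rank(peptide, allele)
    return RankScoreTable(ranks=ranks)
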