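"""The counterpart-search algorithm.

The surrogate (non-tumor) immunopeptidome is searched for peptides whose
complete sequences occur in the wild-type versions of the mutated
proteins but nowhere in their mutant versions. Such peptides are
wild-type counterparts of patient-specific neoantigens: their sequences
are substituted with the corresponding mutant residues and counted as
candidate neoantigens. Overlapping length variants carrying the same
substitution are collapsed into a single candidate, and candidates whose
source gene is not expressed in the tumor (TPM <= 1) are excluded.

Membership is proteome-wide and literal: a peptide occurring in an
unchanged region of ANY mutated protein is "found in the mutant set" and
therefore excluded, even if another occurrence covers a mutation site.
This is deliberately conservative. An optional I/L-equivalent matching
mode treats isoleucine and leucine as one letter during the occurrence
search (MS cannot distinguish them); it is off by default.

Everything here is deterministic; there is no randomness in the core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .errors import ConsistencyError
from .proteome import ProteomePair, build_proteome_pair
from .types import (
    FLAG_LOW_EXPRESSION,
    FLAG_NO_EXPRESSION_DATA,
    FLAG_PASS,
    LENGTH_BOUNDS,
    CandidateNeoantigen,
    ExpressionTable,
    HLAClass,
    MissenseMutation,
    PeptideMatch,
    ProteinRecord,
    SurrogatePeptidome,
)

logger = logging.getLogger(__name__)


def length_filter(
    peptidome: SurrogatePeptidome, bounds: tuple[int, int] | None = None
) -> SurrogatePeptidome:
    """Keep only class-appropriate ligand lengths.

    Class I keeps 8-12-mers, class II 10-25-mers (inclusive); ``bounds``
    overrides the class default, e.g. for mixed-class fixtures.
    """
    lo, hi = bounds if bounds is not None else LENGTH_BOUNDS[peptidome.hla_class]
    kept = frozenset(p for p in peptidome.peptides if lo <= len(p) <= hi)
    removed = len(peptidome.peptides) - len(kept)
    if removed:
        logger.info(
            "length filter (%d-%d, class %s): removed %d of %d peptides",
            lo, hi, peptidome.hla_class.value, removed, len(peptidome.peptides),
        )
    return replace(peptidome, peptides=kept)


def _canon(seq: str, il_equivalent: bool) -> str:
    # I and L are isobaric and indistinguishable by standard MS.
    return seq.replace("L", "I") if il_equivalent else seq


def locate_occurrences(
    peptide: str,
    sequences: Mapping[str, str],
    il_equivalent: bool = False,
) -> list[tuple[str, int]]:
    """All exact (overlapping) occurrences of ``peptide`` in ``sequences``.

    Returns 1-based start positions in deterministic order
    (protein_id, start ascending).
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    needle = _canon(peptide, il_equivalent)
    hits: list[tuple[str, int]] = []
    for pid in sorted(sequences):
        hay = _canon(sequences[pid], il_equivalent)
        start = hay.find(needle)
        while start != -1:
            hits.append((pid, start + 1))
            start = hay.find(needle, start + 1)
    return hits


def find_counterparts(
    peptidome: SurrogatePeptidome,
    pair: ProteomePair,
    il_equivalent: bool = False,
) -> list[PeptideMatch]:
    """Wild-type-counterpart search: peptides found in the wild-type set
    and absent from the mutant set.

    For each qualifying peptide, one :class:`PeptideMatch` is emitted per
    wild-type occurrence. For pure substitutions every such occurrence
    necessarily covers >= 1 mutated residue (an occurrence in an
    unchanged region would recur verbatim in the mutant sequence and the
    peptide would have been excluded); this is asserted at runtime and a
    violation raises :class:`ConsistencyError`.
    """
    matches: list[PeptideMatch] = []
    for peptide in sorted(peptidome.peptides):
        wt_hits = locate_occurrences(peptide, pair.wt, il_equivalent)
        if not wt_hits:
            continue
        if locate_occurrences(peptide, pair.mt, il_equivalent):
            continue
        for pid, start in wt_hits:
            covered = pair.sites_in_window(pid, start, len(peptide))
            if not covered:
                raise ConsistencyError(
                    f"peptide {peptide!r} occurs in wt {pid}:{start} without "
                    "covering any mutated site yet is absent from the mutant "
                    "set; the proteome pair contains non-substitution edits"
                )
            matches.append(
                PeptideMatch(
                    peptide=peptide,
                    protein_id=pid,
                    start=start,
                    covered_sites=tuple(s.position for s in covered),
                )
            )
    return matches


def mutant_peptide(match: PeptideMatch, pair: ProteomePair) -> str:
    """Substitute the matched wild-type window with the mutant residues."""
    seq = pair.mt[match.protein_id]
    return seq[match.start - 1 : match.start - 1 + len(match.peptide)]


def collapse(
    matches: Sequence[PeptideMatch],
    pair: ProteomePair,
    hla_class: HLAClass,
) -> list[CandidateNeoantigen]:
    """Group length variants sharing one exact covered-site set into
    single candidates.

    The grouping key is (protein_id, exact set of covered substitutions):
    a peptide covering two adjacent sites and one covering only one of
    them form different candidates. The representative is the longest
    member; ties break lexicographically on the wild-type sequence.
    """
    groups: dict[tuple[str, frozenset[tuple[int, str, str]]], list[PeptideMatch]] = {}
    for m in matches:
        covered = pair.sites_in_window(m.protein_id, m.start, len(m.peptide))
        key = (m.protein_id, frozenset((s.position, s.ref_aa, s.alt_aa) for s in covered))
        groups.setdefault(key, []).append(m)

    candidates: list[CandidateNeoantigen] = []
    for (pid, covered_set) in sorted(groups, key=lambda k: (k[0], sorted(k[1]))):
        members_raw = groups[(pid, covered_set)]
        members = tuple(
            sorted(
                ((m.peptide, mutant_peptide(m, pair), m.start) for m in members_raw),
                key=lambda t: (t[2], t[0]),
            )
        )
        rep_wt, rep_mut, _ = min(members, key=lambda t: (-len(t[0]), t[0]))
        candidates.append(
            CandidateNeoantigen(
                protein_id=pid,
                gene_id=pair.gene_of(pid),
                covered_sites=tuple(sorted(covered_set)),
                members=members,
                representative_wt=rep_wt,
                representative_mut=rep_mut,
                hla_class=hla_class,
            )
        )
    return candidates


def expression_filter(
    candidates: Sequence[CandidateNeoantigen],
    expr: ExpressionTable | None,
    threshold: float = 1.0,
    strict: bool = False,
) -> list[CandidateNeoantigen]:
    """Flag candidates by tumor expression of their source gene.

    Candidates with TPM <= ``threshold`` are flagged LOW_EXPRESSION and
    leave the PASS set (the boundary itself is excluded). Genes absent
    from the table are flagged NO_EXPRESSION_DATA and retained unless
    ``strict`` — dropping them silently would turn any gene-id join
    failure into a false negative. All candidates are returned with
    flags; callers select ``c.passed`` for the final report.
    """
    out: list[CandidateNeoantigen] = []
    for c in candidates:
        tpm = expr.get(c.gene_id) if expr is not None else None
        if tpm is None:
            flags = {FLAG_NO_EXPRESSION_DATA} if strict else {FLAG_NO_EXPRESSION_DATA, FLAG_PASS}
        elif tpm <= threshold:
            flags = {FLAG_LOW_EXPRESSION}
        else:
            flags = {FLAG_PASS}
        out.append(replace(c, tpm=tpm, flags=frozenset(flags)))
    return out


@dataclass(frozen=True)
class NessieResult:
    """Candidates plus the per-stage run report."""

    candidates: tuple[CandidateNeoantigen, ...]
    report: dict

    @property
    def passed(self) -> tuple[CandidateNeoantigen, ...]:
        return tuple(c for c in self.candidates if c.passed)


def run_nessie(
    peptidome: SurrogatePeptidome,
    reference: Iterable[ProteinRecord],
    mutations: Sequence[MissenseMutation],
    expr: ExpressionTable | None = None,
    *,
    tpm_threshold: float = 1.0,
    strict_expression: bool = False,
    il_equivalent: bool = False,
    length_bounds: tuple[int, int] | None = None,
) -> NessieResult:
    """Full pipeline: length filter, pair construction, counterpart
    search, substitution, collapsing, expression filter.

    Returns all candidates (flagged) and a stage-count report. Fully
    deterministic: identical inputs give identical outputs and reports.
    """
    filtered = length_filter(peptidome, length_bounds)
    pair = build_proteome_pair(reference, mutations)
    matches = find_counterparts(filtered, pair, il_equivalent)
    candidates = collapse(matches, pair, peptidome.hla_class)
    candidates = expression_filter(candidates, expr, tpm_threshold, strict_expression)

    qualifying_peptides = {m.peptide for m in matches}
    wt_hit_peptides = {
        p for p in filtered.peptides if locate_occurrences(p, pair.wt, il_equivalent)
    }
    n_pass = sum(c.passed for c in candidates)
    report = {
        "hla_class": peptidome.hla_class.value,
        "parameters": {
            "tpm_threshold": tpm_threshold,
            "strict_expression": strict_expression,
            "il_equivalent": il_equivalent,
            "length_bounds": list(length_bounds or LENGTH_BOUNDS[peptidome.hla_class]),
        },
        "stages": {
            "peptides_in": len(peptidome.peptides),
            "after_length_filter": len(filtered.peptides),
            "wt_matched": len(wt_hit_peptides),
            "mt_excluded": len(wt_hit_peptides) - len(qualifying_peptides),
            "counterpart_peptides": len(qualifying_peptides),
            "candidate_groups": len(candidates),
            "low_expression": sum(FLAG_LOW_EXPRESSION in c.flags for c in candidates),
            "no_expression_data": sum(FLAG_NO_EXPRESSION_DATA in c.flags for c in candidates),
            "pass": n_pass,
        },
        "n_mutated_proteins": len(pair.wt),
        "n_mutations": len(mutations),
    }
    return NessieResult(candidates=tuple(candidates), report=report)
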