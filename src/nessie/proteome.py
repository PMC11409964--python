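"""Paired wild-type / mutant proteome construction.

Given the reference proteome and a missense-mutation list, this module
builds the two search spaces the counterpart search runs against: the
mutant sequences of every mutated protein (FASTA-mt) and the wild-type
versions of exactly those proteins (FASTA-wt). Unmutated reference
proteins appear in neither.

All substitutions on one protein are applied simultaneously to a single
mutant sequence. With one mutant record per mutation instead, a
wild-type peptide covering mutation A would still occur verbatim in the
record built for mutation B, and the "present in wild-type, absent from
mutant" criterion would never fire for co-mutated proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConsistencyError, CoordinateError, MutationLookupError
from .types import MissenseMutation, MutationSite, ProteinRecord


@dataclass(frozen=True)
class ProteomePair:
    """Wild-type and mutant sequences of the mutated proteins.

    Invariants (enforced on construction):

    * ``wt`` and ``mt`` have identical key sets and equal lengths per key
      (missense only — no indels, ever);
    * per protein, ``wt`` and ``mt`` differ at exactly the listed site
      positions, with ``wt[pos] == ref_aa`` and ``mt[pos] == alt_aa``.
    """

    wt: Mapping[str, str]
    mt: Mapping[str, str]
    sites: Mapping[str, tuple[MutationSite, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.wt) != set(self.mt) or set(self.wt) != set(self.sites):
            raise ConsistencyError("wt, mt and sites must share one key set")
        for pid in self.wt:
            w, m = self.wt[pid], self.mt[pid]
            if len(w) != len(m):
                raise ConsistencyError(f"{pid}: wt/mt length mismatch")
            diff = {i + 1 for i, (a, b) in enumerate(zip(w, m)) if a != b}
            listed = {s.position for s in self.sites[pid]}
            if diff != listed:
                raise ConsistencyError(
                    f"{pid}: wt/mt differ at {sorted(diff)} but sites list {sorted(listed)}"
                )
            for s in self.sites[pid]:
                if w[s.position - 1] != s.ref_aa or m[s.position - 1] != s.alt_aa:
                    raise ConsistencyError(
                        f"{pid}:{s.position}: sequences disagree with site "
                        f"{s.ref_aa}>{s.alt_aa}"
                    )

    def gene_of(self, protein_id: str) -> str:
        return self.sites[protein_id][0].gene_id

    def sites_in_window(self, protein_id: str, start: int, length: int) -> tuple[MutationSite, ...]:
        """Sites whose position lies in the 1-based window [start, start+length-1]."""
        end = start + length - 1
        return tuple(s for s in self.sites[protein_id] if start <= s.position <= end)


def build_proteome_pair(
    reference: Iterable[ProteinRecord], mutations: Sequence[MissenseMutation]
) -> ProteomePair:
    """Apply every mutation to its protein and return the wt/mt pair.

    Raises
    ------
    MutationLookupError
        A mutation's protein_id is absent from the reference.
    CoordinateError
        A position exceeds the protein length.
    ConsistencyError
        The reference residue differs from ref_aa, two mutations target
        the same residue, or mutations on one protein disagree on gene_id.
    """
    ref_index = {rec.protein_id: rec for rec in reference}

    by_protein: dict[str, list[MissenseMutation]] = {}
    for mut in mutations:
        by_protein.setdefault(mut.protein_id, []).append(mut)

    wt: dict[str, str] = {}
    mt: dict[str, str] = {}
    sites: dict[str, tuple[MutationSite, ...]] = {}
    for pid in sorted(by_protein):
        if pid not in ref_index:
            raise MutationLookupError(f"protein {pid!r} not found in the reference proteome")
        record = ref_index[pid]
        sequence = record.sequence
        muts = sorted(by_protein[pid], key=lambda m: m.position)

        genes = {m.gene_id for m in muts}
        if len(genes) > 1:
            raise ConsistencyError(f"{pid}: mutations disagree on gene_id ({sorted(genes)})")
        positions = [m.position for m in muts]
        if len(set(positions)) != len(positions):
            dup = next(p for p in positions if positions.count(p) > 1)
            raise ConsistencyError(f"{pid}: conflicting substitutions at position {dup}")

        mutant = list(sequence)
        for m in muts:
            if m.position > len(sequence):
                raise CoordinateError(
                    f"{pid}: position {m.position} beyond sequence length {len(sequence)}"
                )
            observed = sequence[m.position - 1]
            if observed != m.ref_aa:
                raise ConsistencyError(
                    f"{pid}:{m.position}: expected reference residue {m.ref_aa!r} "
                    f"but the proteome has {observed!r}"
                )
            mutant[m.position - 1] = m.alt_aa

        wt[pid] = sequence
        mt[pid] = "".join(mutant)
        sites[pid] = tuple(
            MutationSite(m.position, m.ref_aa, m.alt_aa, m.gene_id, m.label) for m in muts
        )
    return ProteomePair(wt=wt, mt=mt, sites=sites)


def pair_records(pair: ProteomePair, mutant: bool) -> list[ProteinRecord]:
    """Materialize the wt or mt half as :class:`ProteinRecord` objects
    (for FASTA export)."""
    source = pair.mt if mutant else pair.wt
    return [
        ProteinRecord(pid, pair.gene_of(pid), seq) for pid, seq in sorted(source.items())
    ]
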