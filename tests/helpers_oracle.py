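"""Independent brute-force oracles and random-instance generators.

The oracle enumerates every class-legal substring of every wild-type
protein by naive scanning and applies the membership criterion with
plain ``in`` checks — no shared code with the implementation's search
path beyond the domain types.
"""

from __future__ import annotations

import numpy as np

from nessie.proteome import ProteomePair, build_proteome_pair
from nessie.types import (
    AMINO_ACIDS,
    HLAClass,
    MissenseMutation,
    ProteinRecord,
    SurrogatePeptidome,
)

GroupKey = tuple[str, frozenset[tuple[int, str, str]]]


def oracle_candidate_groups(
    peptides: set[str], pair: ProteomePair, bounds: tuple[int, int]
) -> dict[GroupKey, set[str]]:
    """Brute-force candidate grouping: (protein, covered-site set) -> wt members."""
    lo, hi = bounds
    legal = {p for p in peptides if lo <= len(p) <= hi}

    def occurs_anywhere(pep: str, seqs: dict) -> bool:
        return any(pep in s for s in seqs.values())

    groups: dict[GroupKey, set[str]] = {}
    for pep in legal:
        if not occurs_anywhere(pep, dict(pair.wt)):
            continue
        if occurs_anywhere(pep, dict(pair.mt)):
            continue
        for pid, seq in pair.wt.items():
            for start0 in range(len(seq) - len(pep) + 1):
                if seq[start0 : start0 + len(pep)] != pep:
                    continue
                covered = frozenset(
                    (s.position, s.ref_aa, s.alt_aa)
                    for s in pair.sites[pid]
                    if start0 + 1 <= s.position <= start0 + len(pep)
                )
                groups.setdefault((pid, covered), set()).add(pep)
    return groups


def result_groups(candidates) -> dict[GroupKey, set[str]]:
    """Project pipeline candidates onto the oracle's group structure."""
    return {
        (c.protein_id, frozenset(c.covered_sites)): {wt for wt, _, _ in c.members}
        for c in candidates
    }


def random_instance(
    rng: np.random.Generator,
    max_proteins: int = 10,
    max_length: int = 200,
    max_mutations: int = 6,
    max_peptides: int = 50,
    bounds: tuple[int, int] = (8, 12),
):
    """A small random instance stressing every membership case.

    Peptides are a mixture of wild-type substrings (some covering sites,
    some not), mutant substrings, and fully random sequences, so the
    oracle comparison exercises qualification, both-membership
    exclusion, mutant-only exclusion and no-match paths.
    """
    aa = np.array(list(AMINO_ACIDS))
    n_proteins = int(rng.integers(2, max_proteins + 1))
    proteome = []
    for i in range(n_proteins):
        length = int(rng.integers(30, max_length + 1))
        seq = "".join(rng.choice(aa, size=length))
        proteome.append(ProteinRecord(f"P{i}", f"G{i}", seq))

    n_mut = int(rng.integers(1, max_mutations + 1))
    mutations: list[MissenseMutation] = []
    used: set[tuple[str, int]] = set()
    for _ in range(n_mut):
        rec = proteome[int(rng.integers(len(proteome)))]
        pos = int(rng.integers(1, len(rec.sequence) + 1))
        if (rec.protein_id, pos) in used:
            continue
        used.add((rec.protein_id, pos))
        ref = rec.sequence[pos - 1]
        alt = str(rng.choice([a for a in AMINO_ACIDS if a != ref]))
        mutations.append(MissenseMutation(rec.protein_id, pos, ref, alt, rec.gene_id))
    pair = build_proteome_pair(proteome, mutations)

    lo, hi = bounds
    peptides: set[str] = set()
    n_peptides = int(rng.integers(1, max_peptides + 1))
    mutated_ids = sorted(pair.wt)
    for _ in range(n_peptides):
        kind = rng.random()
        k = int(rng.integers(lo, hi + 1))
        if kind < 0.45:  # substring of a wild-type mutated protein
            pid = mutated_ids[int(rng.integers(len(mutated_ids)))]
            seq = pair.wt[pid]
        elif kind < 0.7:  # substring of a mutant protein
            pid = mutated_ids[int(rng.integers(len(mutated_ids)))]
            seq = pair.mt[pid]
        elif kind < 0.85:  # substring of any reference protein
            seq = proteome[int(rng.integers(len(proteome)))].sequence
        else:  # fully random
            peptides.add("".join(rng.choice(aa, size=k)))
            continue
        if len(seq) >= k:
            start0 = int(rng.integers(0, len(seq) - k + 1))
            peptides.add(seq[start0 : start0 + k])

    peptidome = SurrogatePeptidome(frozenset(peptides), HLAClass.I, "random")
    return proteome, mutations, peptidome, pair
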