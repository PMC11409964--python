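"""In-silico candidate counting: window enumeration and threshold rules."""

from __future__ import annotations

import numpy as np
import pytest

from nessie.errors import MutationLookupError
from nessie.insilico import (
    count_candidates,
    enumerate_mutant_kmers,
    pseudo_rank,
    pseudo_rank_table,
    summarize_mutation,
)
from nessie.proteome import build_proteome_pair
from nessie.types import (
    AMINO_ACIDS,
    ExpressionTable,
    MissenseMutation,
    ProteinRecord,
    RankScoreTable,
)


def _pair(seq="ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY", pos=20, gene="G1"):
    ref = [ProteinRecord("P1", gene, seq)]
    alt = "A" if seq[pos - 1] != "A" else "C"
    muts = [MissenseMutation("P1", pos, seq[pos - 1], alt, gene)]
    return build_proteome_pair(ref, muts), muts[0]


class TestEnumerate:
    def test_terminal_site_yields_single_window_per_k(self):
        pair, _ = _pair()
        mut = MissenseMutation("P1", 1, "A", "W", "G1")
        pair2, _ = (
            build_proteome_pair(
                [ProteinRecord("P1", "G1", pair.wt["P1"])], [mut]
            ),
            mut,
        )
        windows = enumerate_mutant_kmers(pair2, mut, lengths=[9])
        assert len(windows) == 1
        assert windows[0] == (pair2.mt["P1"][:9], 0)

    def test_interior_site_yields_k_windows(self):
        pair, mut = _pair()
        assert len(enumerate_mutant_kmers(pair, mut, lengths=[9])) == 9

    def test_interior_site_default_lengths_give_50_windows(self):
        pair, mut = _pair()
        assert len(enumerate_mutant_kmers(pair, mut)) == 8 + 9 + 10 + 11 + 12

    def test_every_window_contains_the_substituted_residue(self):
        pair, mut = _pair()
        for pep, offset in enumerate_mutant_kmers(pair, mut):
            assert pep[offset] == mut.alt_aa
            assert pep in pair.mt["P1"]

    def test_unknown_mutation_raises(self):
        pair, _ = _pair()
        with pytest.raises(MutationLookupError):
            enumerate_mutant_kmers(pair, MissenseMutation("PX", 1, "A", "C", "G"))

    def test_matches_exhaustive_substring_enumeration(self):
        rng = np.random.default_rng(31)
        aa = list(AMINO_ACIDS)
        for _ in range(20):
            length = int(rng.integers(10, 80))
            seq = "".join(rng.choice(aa, size=length))
            pos = int(rng.integers(1, length + 1))
            ref = seq[pos - 1]
            alt = str(rng.choice([a for a in AMINO_ACIDS if a != ref]))
            mut = MissenseMutation("P1", pos, ref, alt, "G1")
            pair = build_proteome_pair([ProteinRecord("P1", "G1", seq)], [mut])
            got = {p for p, _ in enumerate_mutant_kmers(pair, mut)}
            mt = pair.mt["P1"]
            expected = {
                mt[s : s + k]
                for k in range(8, 13)
                for s in range(len(mt) - k + 1)
                if s + 1 <= pos <= s + k
            }
            assert got == expected


class TestSummarize:
    def test_best_rank_is_the_minimum(self):
        pair, mut = _pair()
        windows = [p for p, _ in enumerate_mutant_kmers(pair, mut)]
        ranks = {(p, "HLA-A*02:01"): 5.0 for p in windows}
        ranks[(windows[3], "HLA-A*02:01")] = 0.3
        s = summarize_mutation(
            mut, pair, RankScoreTable(ranks=ranks), ["HLA-A*02:01"],
            ExpressionTable(tpm={"G1": 10.0}),
        )
        assert s.best_rank == 0.3 and s.best_peptide == windows[3]
        assert s.is_strong and s.is_candidate

    def test_all_ranks_at_threshold_never_candidate(self):
        pair, mut = _pair()
        table = pseudo_rank_table(pair, [mut], ["A1"])
        table = RankScoreTable(ranks={k: 2.0 for k in table.ranks})
        s = summarize_mutation(mut, pair, table, ["A1"], ExpressionTable(tpm={"G1": 99.0}))
        assert not s.is_candidate  # rule is strictly < 2.0

    def test_low_expression_blocks_candidacy_but_not_strong(self):
        pair, mut = _pair()
        table = pseudo_rank_table(pair, [mut], ["A1"])
        table = RankScoreTable(ranks={k: 0.1 for k in table.ranks})
        s = summarize_mutation(mut, pair, table, ["A1"], ExpressionTable(tpm={"G1": 1.0}))
        assert s.is_strong and not s.is_candidate

    def test_missing_entry_strict_raises_and_skip_warns(self):
        pair, mut = _pair()
        with pytest.raises(MutationLookupError, match="no %rank"):
            summarize_mutation(mut, pair, RankScoreTable(ranks={}), ["A1"])
        s = summarize_mutation(mut, pair, RankScoreTable(ranks={}), ["A1"], missing="skip")
        assert s.best_rank is None and not s.is_candidate

    def test_best_rank_equals_naive_min_over_random_tables(self):
        rng = np.random.default_rng(8)
        pair, mut = _pair()
        windows = [p for p, _ in enumerate_mutant_kmers(pair, mut)]
        alleles = ["A1", "A2", "A3"]
        for _ in range(10):
            ranks = {
                (p, a): round(float(rng.uniform(0, 30)), 4)
                for p in windows for a in alleles
            }
            s = summarize_mutation(
                mut, pair, RankScoreTable(ranks=ranks), alleles, missing="strict"
            )
            assert s.best_rank == min(ranks.values())

    def test_allele_order_is_irrelevant(self):
        pair, mut = _pair()
        alleles = ["A1", "A2"]
        table = pseudo_rank_table(pair, [mut], alleles)
        a = summarize_mutation(mut, pair, table, alleles)
        b = summarize_mutation(mut, pair, table, list(reversed(alleles)))
        assert a.best_rank == b.best_rank


class TestCount:
    def _planted(self):
        rng = np.random.default_rng(12)
        aa = list(AMINO_ACIDS)
        proteome, muts = [], []
        # plant designed best ranks: two candidates (one strong), one rank-fail
        designs = [(0.3, 50.0), (1.5, 50.0), (3.0, 50.0)]
        for i, (best, tpm) in enumerate(designs):
            seq = "".join(rng.choice(aa, size=60))
            pos = 30
            ref = seq[pos - 1]
            alt = str(rng.choice([a for a in AMINO_ACIDS if a != ref]))
            proteome.append(ProteinRecord(f"P{i}", f"G{i}", seq))
            muts.append(MissenseMutation(f"P{i}", pos, ref, alt, f"G{i}"))
        pair = build_proteome_pair(proteome, muts)
        ranks = {}
        for m, (best, _) in zip(muts, designs):
            windows = enumerate_mutant_kmers(pair, m)
            for j, (p, _) in enumerate(windows):
                ranks[(p, "A1")] = best if j == 0 else best + 10.0
        expr = ExpressionTable(tpm={f"G{i}": t for i, (_, t) in enumerate(designs)})
        return muts, pair, RankScoreTable(ranks=ranks), expr

    def test_planted_counts(self):
        muts, pair, table, expr = self._planted()
        n_cand, n_strong, summaries = count_candidates(muts, pair, table, ["A1"], expr)
        assert (n_cand, n_strong) == (2, 1)
        assert [s.is_candidate for s in summaries] == [True, True, False]

    def test_zero_mutations(self):
        _, pair, table, expr = self._planted()
        assert count_candidates([], pair, table, ["A1"], expr) == (0, 0, [])

    def test_strong_subset_and_weak_monotonicity(self):
        muts, pair, table, expr = self._planted()
        previous = None
        for weak in (4.0, 2.0, 1.0, 0.2):
            n_cand, n_strong, _ = count_candidates(
                muts, pair, table, ["A1"], expr, weak=weak
            )
            assert n_strong <= n_cand
            if previous is not None:
                assert n_cand <= previous  # lowering weak never adds candidates
            previous = n_cand


def test_pseudo_rank_is_deterministic_and_bounded():
    values = {pseudo_rank("KLNPQRFEV", f"A{i}") for i in range(50)}
    assert all(0 <= v < 100 for v in values)
    assert pseudo_rank("KLNPQRFEV", "A1") == pseudo_rank("KLNPQRFEV", "A1")
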