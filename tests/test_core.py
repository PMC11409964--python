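"""The counterpart-search algorithm: each stage plus its invariants."""

from __future__ import annotations

import numpy as np
import pytest

from helpers_oracle import oracle_candidate_groups, random_instance, result_groups
from nessie.core import (
    collapse,
    expression_filter,
    find_counterparts,
    length_filter,
    locate_occurrences,
    mutant_peptide,
    run_nessie,
)
from nessie.proteome import build_proteome_pair
from nessie.types import (
    FLAG_LOW_EXPRESSION,
    FLAG_NO_EXPRESSION_DATA,
    ExpressionTable,
    HLAClass,
    MissenseMutation,
    PeptideMatch,
    ProteinRecord,
    SurrogatePeptidome,
)


def _pome(peptides, cls=HLAClass.I):
    return SurrogatePeptidome(frozenset(peptides), cls, "t")


class TestLengthFilter:
    def test_class_one_keeps_8_to_12(self):
        pome = _pome({"A" * 7, "C" * 8, "D" * 12, "E" * 13})
        assert length_filter(pome).peptides == frozenset({"C" * 8, "D" * 12})

    def test_class_two_keeps_published_15mer(self):
        pome = _pome({"KGEIAASIVTHMRPY"}, HLAClass.II)
        assert length_filter(pome).peptides == frozenset({"KGEIAASIVTHMRPY"})

    def test_empty_input_allowed(self):
        assert length_filter(_pome(set())).peptides == frozenset()

    def test_explicit_bounds_override_class(self):
        pome = _pome({"A" * 7, "C" * 15})
        assert length_filter(pome, bounds=(7, 15)).peptides == pome.peptides


class TestLocate:
    def test_single_occurrence_is_one_based(self):
        assert locate_occurrences("KLNPQQFEV", {"P1": "AAKLNPQQFEVAA"}) == [("P1", 3)]

    def test_overlapping_occurrences_enumerated(self):
        assert locate_occurrences("AA", {"P1": "AAAA"}) == [("P1", 1), ("P1", 2), ("P1", 3)]

    def test_matches_naive_scan_on_random_input(self):
        rng = np.random.default_rng(3)
        alphabet = list("ACDE")  # tiny alphabet forces frequent hits
        seqs = {
            f"P{i}": "".join(rng.choice(alphabet, size=60)) for i in range(5)
        }
        for _ in range(50):
            pep = "".join(rng.choice(alphabet, size=int(rng.integers(1, 5))))
            naive = [
                (pid, i + 1)
                for pid in sorted(seqs)
                for i in range(len(seqs[pid]) - len(pep) + 1)
                if seqs[pid][i : i + len(pep)] == pep
            ]
            assert locate_occurrences(pep, seqs) == naive

    def test_il_equivalent_mode_merges_letters(self):
        assert locate_occurrences("KIK", {"P1": "AKLKA"}, il_equivalent=True) == [("P1", 2)]
        assert locate_occurrences("KIK", {"P1": "AKLKA"}, il_equivalent=False) == []


class TestFindCounterparts:
    def test_printed_counterpart_qualifies_and_substitutes(self):
        # RYLTVAAVF present in wt with T>A inside, hence absent from mt
        ref = [ProteinRecord("P1", "G1", "MA" + "RYLTVAAVF" + "WD")]
        muts = [MissenseMutation("P1", 6, "T", "A", "G1")]
        pair = build_proteome_pair(ref, muts)
        (match,) = find_counterparts(_pome({"RYLTVAAVF"}), pair)
        assert match == PeptideMatch("RYLTVAAVF", "P1", 3, (6,))
        assert mutant_peptide(match, pair) == "RYLAVAAVF"

    def test_peptide_in_unmutated_region_excluded(self, toy_pair):
        # present in both wt and mt -> not a counterpart
        assert find_counterparts(_pome({"GWCHKNDPES"}), toy_pair) == []

    def test_mutant_only_peptide_excluded(self, toy_pair):
        assert find_counterparts(_pome({"KLNPQRFEV"}), toy_pair) == []

    @pytest.mark.parametrize(
        "wt, mut",
        [
            ("KLNPQQFEV", "KLNPQRFEV"),
            ("KLWDIINVNI", "KLWDIVNVNI"),
            ("KGEIAASIATHMRPY", "KGEIAASIVTHMRPY"),
        ],
    )
    def test_published_substitutions_character_exact(self, toy_pair, wt, mut):
        (match,) = find_counterparts(_pome({wt}), toy_pair)
        assert mutant_peptide(match, toy_pair) == mut
        diffs = [i for i, (a, b) in enumerate(zip(wt, mut)) if a != b]
        assert len(diffs) == 1  # single-residue substitution, nowhere else


class TestCollapse:
    def test_length_variants_of_one_site_become_one_candidate(self):
        core = "KGEIAASIATHMRPY"
        ref = [ProteinRecord("P1", "G1", "MW" + core + "QNDE")]
        muts = [MissenseMutation("P1", 11, "A", "V", "G1")]  # the A at peptide pos 9
        pair = build_proteome_pair(ref, muts)
        variants = {core, core[1:], "W" + core, core + "Q"}
        matches = find_counterparts(_pome(variants, HLAClass.II), pair)
        (candidate,) = collapse(matches, pair, HLAClass.II)
        assert len(candidate.members) == 4
        # representative is the longest member; 16-mer tie broken lexicographically
        assert candidate.representative_wt == "KGEIAASIATHMRPYQ"

    def test_single_match_single_candidate(self, toy_pair):
        matches = find_counterparts(_pome({"KLNPQQFEV"}), toy_pair)
        (candidate,) = collapse(matches, toy_pair, HLAClass.I)
        assert candidate.members == (("KLNPQQFEV", "KLNPQRFEV", 6),)
        assert candidate.covered_sites == ((11, "Q", "R"),)

    def test_distinct_covered_site_sets_stay_separate(self):
        # adjacent sites: one peptide covers both, one covers only the first
        ref = [ProteinRecord("P1", "G1", "AAAACDEFGHIKLMNPQRSTVWYAAAA")]
        muts = [
            MissenseMutation("P1", 6, "D", "E", "G1"),
            MissenseMutation("P1", 14, "M", "T", "G1"),
        ]
        pair = build_proteome_pair(ref, muts)
        both = pair.wt["P1"][3:15]  # covers positions 4..15 -> sites 6 and 14
        one = pair.wt["P1"][3:11]  # covers positions 4..11 -> site 6 only
        matches = find_counterparts(_pome({both, one}), pair)
        candidates = collapse(matches, pair, HLAClass.I)
        assert len(candidates) == 2
        assert {len(c.covered_sites) for c in candidates} == {1, 2}


class TestExpressionFilter:
    def _candidate(self, gene="G1"):
        return collapse(
            find_counterparts(
                _pome({"KLNPQQFEV"}),
                build_proteome_pair(
                    [ProteinRecord("P1", gene, "AAKLNPQQFEVAA")],
                    [MissenseMutation("P1", 8, "Q", "R", gene)],
                ),
            ),
            build_proteome_pair(
                [ProteinRecord("P1", gene, "AAKLNPQQFEVAA")],
                [MissenseMutation("P1", 8, "Q", "R", gene)],
            ),
            HLAClass.I,
        )

    @pytest.mark.parametrize("tpm, passed", [(0.5, False), (1.0, False), (1.0001, True)])
    def test_threshold_boundary_is_excluded(self, tpm, passed):
        out = expression_filter(self._candidate(), ExpressionTable(tpm={"G1": tpm}))
        assert out[0].passed is passed
        if not passed:
            assert FLAG_LOW_EXPRESSION in out[0].flags

    def test_missing_gene_retained_with_flag_by_default(self):
        out = expression_filter(self._candidate(), ExpressionTable(tpm={}))
        assert out[0].passed and FLAG_NO_EXPRESSION_DATA in out[0].flags

    def test_strict_mode_excludes_missing_gene(self):
        out = expression_filter(self._candidate(), ExpressionTable(tpm={}), strict=True)
        assert not out[0].passed

    def test_pass_set_equals_tpm_above_threshold(self):
        rng = np.random.default_rng(17)
        base = self._candidate()[0]
        from dataclasses import replace

        candidates, tpms = [], {}
        for i in range(50):
            gene = f"G{i}"
            candidates.append(replace(base, gene_id=gene))
            tpms[gene] = round(float(rng.uniform(0, 3)), 3)
        out = expression_filter(candidates, ExpressionTable(tpm=tpms))
        assert {c.gene_id for c in out if c.passed} == {g for g, t in tpms.items() if t > 1.0}


class TestRunNessie:
    def test_empty_peptidome_zero_everywhere(self, toy_proteome, toy_mutations):
        result = run_nessie(_pome(set()), toy_proteome, toy_mutations)
        assert result.candidates == ()
        assert all(v == 0 for v in result.report["stages"].values())

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            proteome, muts, pome, pair = random_instance(rng)
            result = run_nessie(pome, proteome, muts, length_bounds=(8, 12))
            assert result_groups(result.candidates) == oracle_candidate_groups(
                set(pome.peptides), pair, (8, 12)
            )

    def test_soundness_of_pass_candidates(self):
        rng = np.random.default_rng(99)
        proteome, muts, pome, pair = random_instance(rng, max_peptides=50)
        expr = ExpressionTable(tpm={rec.gene_id: 5.0 for rec in proteome})
        result = run_nessie(pome, proteome, muts, expr, length_bounds=(8, 12))
        for c in result.passed:
            wt = c.representative_wt
            assert wt in pome.peptides
            assert any(wt in s for s in pair.wt.values())
            assert not any(wt in s for s in pair.mt.values())
            assert c.representative_mut in pair.mt[c.protein_id]

    def test_adding_mutant_set_peptides_never_changes_output(self):
        rng = np.random.default_rng(4)
        proteome, muts, pome, pair = random_instance(rng)
        base = run_nessie(pome, proteome, muts, length_bounds=(8, 12))
        extra = {seq[i : i + 9] for seq in pair.mt.values() for i in (0, 5)}
        bigger = SurrogatePeptidome(pome.peptides | frozenset(extra), pome.hla_class, "t")
        grown = run_nessie(bigger, proteome, muts, length_bounds=(8, 12))
        assert result_groups(grown.candidates) == result_groups(base.candidates)

    def test_raising_tpm_threshold_never_increases_pass_count(self, toy_proteome, toy_mutations, toy_peptidome, toy_expression):
        counts = [
            len(
                run_nessie(
                    toy_peptidome, toy_proteome, toy_mutations, toy_expression,
                    tpm_threshold=t, length_bounds=(8, 25),
                ).passed
            )
            for t in (0.5, 1.0, 9.0, 10.0, 50.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_reports_are_identical_across_runs(self, toy_proteome, toy_mutations, toy_peptidome, toy_expression):
        run = lambda: run_nessie(
            toy_peptidome, toy_proteome, toy_mutations, toy_expression, length_bounds=(8, 25)
        )
        a, b = run(), run()
        assert a.report == b.report and a.candidates == b.candidates
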