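# nessie

Candidate neoantigen selection using a **surrogate immunopeptidome** —
an HLA-eluted peptide repertoire measured from autologous *non-tumor*
material (lymphoblastoid cell lines, normal mucosa, spleen) instead of
scarce tumor tissue.

## Who this is for

Tumor immunologists and computational biologists prioritizing somatic
missense mutations for T-cell assays. The usual inputs are available
from routine workflows: a reference proteome, somatic missense calls in
protein coordinates (SnpEff-style `p.Q294R` annotations), tumor RNA-seq
TPM, and a mass-spectrometry peptide list from an immunoaffinity
pull-down of surrogate material (already FDR-filtered upstream).

## The selection rule

Let `FASTA-wt` be the wild-type sequences of the mutated proteins and
`FASTA-mt` the same proteins with all of their substitutions applied.
A surrogate peptide *p* (after the class length filter: 8–12-mers for
HLA-I, 10–25-mers for HLA-II) is a **wild-type counterpart** iff

```
p ⊑ FASTA-wt   and   p ⋢ FASTA-mt
```

(⊑ = exact substring of some sequence in the set). Because the only
edits are single-residue substitutions, every qualifying occurrence
necessarily covers ≥ 1 mutated position. The counterpart's window is
then substituted with the mutant residues to give the candidate
neoantigen. Overlapping length variants carrying the same substitution
set are collapsed into a single candidate, and candidates whose source
gene has tumor TPM ≤ 1 are excluded. The presence of the wild-type
counterpart on surrogate HLA implies the mutant form is likely
presented by the tumor.

Companion modules provide the in-silico comparison rule (per mutation,
minimum %rank over all mutant 8–12-mers × patient alleles from an
external predictor table; candidates need %rank < 2.0 and TPM > 1,
strong binders < 0.5), descriptive peptidome statistics (sharing,
overlap, lengths, source-gene TPM densities), a tandem in-vitro
transcription/translation (IVTT) construct designer for screening
candidates (≤ 10 units per vector, each `[T7][RBS][ATG][FLAG][peptide]
[stop][stem-loop]` with unique flanking restriction sites), and a
ground-truthed synthetic-data generator.

## Worked example

A five-protein toy proteome embeds four known wild-type/neoantigen
pairs. P2 carries `KLNPQQFEV` with a Q→R substitution inside the
peptide, P3 `KLWDIINVNI` (I→V inside), P4 `KGEIAASIATHMRPY` (A→V
inside); P1 carries `RYLTVAAVF` but its substitution lies *outside*
the peptide, and P5's substitution is covered by no surrogate peptide.
The surrogate list holds those four peptides plus four decoys from
unmutated regions; every gene has TPM 10.

```python
from nessie import (HLAClass, MissenseMutation, ProteinRecord,
                    SurrogatePeptidome, ExpressionTable, run_nessie)

proteome = [
    ProteinRecord("P1", "GENE1", "MSTAYHKDRE" "RYLTVAAVF" "GWCHKNDPES"),
    ProteinRecord("P2", "STT3A", "MGAHW" "KLNPQQFEV" "DERTS"),
    ProteinRecord("P3", "GENE3", "MPW" "KLWDIINVNI" "CAES"),
    ProteinRecord("P4", "GENE4", "MKT" "KGEIAASIATHMRPY" "WQND"),
    ProteinRecord("P5", "GENE5", "MNDCEFGHIKWRSTVQAYLP"),
]
mutations = [
    MissenseMutation("P1", 3, "T", "A", "GENE1"),
    MissenseMutation("P2", 11, "Q", "R", "STT3A", "STT3A p.Q11R"),
    MissenseMutation("P3", 9, "I", "V", "GENE3"),
    MissenseMutation("P4", 12, "A", "V", "GENE4"),
    MissenseMutation("P5", 5, "E", "K", "GENE5"),
]
peptidome = SurrogatePeptidome(
    frozenset({"RYLTVAAVF", "KLNPQQFEV", "KLWDIINVNI", "KGEIAASIATHMRPY",
               "GWCHKNDPES", "MGAHWKLN", "FGHIKWRSTV", "THMRPYWQND"}),
    HLAClass.I, "toy-surrogate")
expr = ExpressionTable(tpm={r.gene_id: 10.0 for r in proteome})

result = run_nessie(peptidome, proteome, mutations, expr,
                    length_bounds=(8, 25))   # mixed I/II fixture
print(sorted(c.representative_mut for c in result.passed))
print(result.report["stages"])
```

prints

```
['KGEIAASIVTHMRPY', 'KLNPQRFEV', 'KLWDIVNVNI']
{'peptides_in': 8, 'after_length_filter': 8, 'wt_matched': 8,
 'mt_excluded': 5, 'counterpart_peptides': 3, 'candidate_groups': 3,
 'low_expression': 0, 'no_expression_data': 0, 'pass': 3}
```

Three candidates survive: exactly the mutant forms of the three
peptides whose substitution falls inside the peptide. `RYLTVAAVF` is
rejected because its unchanged window recurs in the mutant sequence,
as are all four decoys (`mt_excluded: 5`); P5's mutation yields nothing
because no surrogate peptide covers it.

The same run is available from the shell:

```sh
nessie run --peptides peptides.txt --hla-class I \
    --proteome proteome.fasta --mutations mutations.tsv \
    --expression expression.tsv --out candidates.tsv
```

Other subcommands: `build-proteomes` (write the wt/mt FASTA pair),
`insilico` (count candidates from a %rank table, or `--emit-peptides`
to export mutant k-mers for external scoring), `stats`, `ivtt`,
`simulate`.

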