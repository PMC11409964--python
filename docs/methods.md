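# Methods

## The selection procedure and its assumptions

The pipeline identifies candidate tumor neoantigens without measuring
the tumor's own immunopeptidome. Its premise: HLA-eluted repertoires of
a patient's tumor and of autologous non-tumor material (LCL, normal
mucosa) overlap substantially, so if the **wild-type counterpart** of a
mutated peptide is presented by surrogate HLA, the mutant form is
likely presented by the tumor. The procedure is pure sequence algebra:

1. **Length filter.** MS peptide lists are restricted to
   class-appropriate ligand lengths — 8–12 residues for HLA-I, 10–25
   for HLA-II (inclusive). Filtering happens before matching; for
   literal substring matching the outcome is identical either way, and
   filtering first keeps the stage counts interpretable. Explicit
   bounds can override the class default (the worked example mixes a
   15-mer into a class-I list and runs at 8–25).
2. **Proteome pair.** Only mutated proteins enter the search space.
   All substitutions on one protein are applied simultaneously to a
   single mutant sequence. With one record per mutation instead, a
   wild-type peptide covering mutation A would still occur verbatim in
   the record built for mutation B and could never satisfy the
   criterion; simultaneous application preserves it. Phasing of
   co-occurring somatic mutations is unknowable at this level, so this
   is a modeling choice, stated rather than inferred. Two mutations at
   the same residue are rejected as conflicting.
3. **Counterpart criterion.** A peptide qualifies iff it occurs as an
   exact substring somewhere in the wild-type set and nowhere in the
   mutant set. Membership is proteome-wide and literal: an occurrence
   in an unchanged region of *any* mutated protein disqualifies the
   peptide even if another occurrence covers a mutation site. This is
   conservative by construction. Since the only edits are single-residue
   substitutions, every occurrence of a qualifying peptide must cover
   ≥ 1 site; the code asserts this and raises if the proteome pair
   contains anything but substitutions.
4. **Substitution.** The qualifying window is read out of the mutant
   sequence at the same coordinates, so the mutant peptide differs from
   its counterpart at exactly the covered sites.
5. **Collapsing.** Matches are grouped by (protein, exact covered-site
   set); N-/C-terminal length variants of one substitution count as a
   single candidate. "Same substitution" is read strictly: a peptide
   covering two adjacent sites and one covering only one of them form
   different candidates. The representative is the longest member,
   ties broken lexicographically on the wild-type sequence.
6. **Expression filter.** Candidates whose source gene has tumor
   TPM ≤ 1 leave the PASS set (the boundary is excluded). Genes absent
   from the table are flagged `NO_EXPRESSION_DATA` and retained by
   default — silently dropping them would turn gene-id join failures
   into false negatives; a strict mode excludes them. Because
   candidates are per-protein there is never more than one gene per
   candidate and no TPM aggregation rule is needed.

The core is fully deterministic: sorted iteration everywhere, no
randomness, identical inputs give identical candidate tables and
reports.

**Isoleucine/leucine.** Standard MS cannot distinguish the isobaric I
and L. Matching is literal by default; an optional mode merges I and L
into one letter during occurrence search (wild-type sequences are used
for reporting). It is off by default because a counterpart list derived
from a search engine's own arbitrary I/L choice is best matched
literally.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| class length bounds | I: 8–12, II: 10–25 | inclusive ligand lengths kept from MS lists |
| `tpm_threshold` | 1.0 TPM | candidates with source-gene TPM ≤ threshold are excluded |
| `strict_expression` | off | exclude candidates with no expression entry |
| `il_equivalent` | off | treat I/L as one letter during matching |
| in-silico `weak` / `strong` | 2.0 / 0.5 %rank | predictor thresholds for candidate / strong binder |
| in-silico k-mer lengths | 8–12 | mutant windows scored per mutation |
| IVTT `capacity` | 10 | neoantigen units per tandem vector |

## The in-silico comparison rule

For each mutation, every 8–12-mer window of the mutant protein
containing the substituted residue (clipped at the termini; an interior
site yields 8+9+10+11+12 = 50 windows) is looked up in a supplied
(peptide, allele) → %rank table; the predictor itself (e.g. NetMHCpan)
is external, licensed software and is consumed only as a table. The
mutation's score is the **minimum** %rank over windows × alleles.
"Best score" is deliberately read as the strongest predicted binder:
%rank is smaller-is-stronger and the candidate rule is a `< 2.0`
threshold, which a literal maximum would render nearly unsatisfiable.
Candidates require %rank < 2.0 and TPM > 1; the strong subset requires
%rank < 0.5. A missing table entry raises under the strict policy and
is skipped with a warning under the lenient one. The `--emit-peptides`
flag exports the enumerated windows as FASTA so a real predictor can be
run externally and its output fed back in.

## Peptidome statistics

Sharing and overlap are exhaustive set operations on deduplicated
peptide sets. Source-gene expression profiles map each peptide to
proteins by exact substring search; a multi-mapping peptide takes the
**maximum** TPM over its source genes — under abundance bias the most
expressed source is the most plausible origin; no established
convention exists for this choice. Gene-level TPM is used throughout,
matching the expression filter. Densities are Gaussian KDEs of
log10(TPM + 0.01); the pseudocount keeps zero-TPM genes finite and is
below the resolution anyone interprets on these plots. Plotting itself
is left to the caller; the module returns tables and (grid, density)
arrays.

## IVTT construct design

Each unit is `[T7 promoter][RBS][ATG][FLAG][peptide][stop][stem-loop]`.
The FLAG tag DYKDDDDK ends in the enterokinase recognition
DDDDK↓, so cleavage after translation releases the peptide with no
extra N-terminal residues (a design rationale, not a simulated
reaction). Element sequences are canonical published defaults — T7
promoter with GGG initiation, a Shine–Dalgarno RBS with spacer, and a
T7-terminator-class hairpin as the 3'UTR stem-loop — and fully
configurable, because only the anatomy is fixed, not the bases.

Codon choice is deterministic max-usage from a bundled E. coli K-12
table (the reconstituted translation system is E. coli-based); a seeded
usage-weighted mode exists for avoiding repeated-codon runs. Units pack
greedily, ≤ 10 per vector, preserving input order: n units give
⌈n/10⌉ vectors named V01, V02, … Within a vector, consecutive catalog
enzymes flank the units (unit *i* gets sites *i* and *i*+1, so n units
need n+1 enzymes and adjacent units share a boundary site); any enzyme
whose recognition sequence occurs inside an insert of that vector is
skipped, and an exhausted catalog reports exactly how many more enzymes
are needed. Restriction handling scans the forward strand for
recognition sequences — the bundled catalog is palindromic, so the
reverse strand adds nothing — and cut chemistry, vector backbones and
synthesis formats are out of scope.

## Synthetic data: what it emulates and what it does not

The generator produces a random proteome (uniform residue composition
by default — matching behavior is composition-independent, and lengths
of 200–400 keep accidental 8+-mer collisions negligible; empirical
frequencies are configurable), missense mutations with correct
reference residues, and a peptide list of three verified classes:

* **counterparts** — windows of wild-type mutated proteins covering
  exactly one designated site, with several length variants per site to
  exercise collapsing; each is *verified* present in the wild-type set,
  absent from every mutant sequence, and free of confounding secondary
  occurrences (draws failing any check are rejected and redrawn);
* **wild-type decoys** — windows from unmutated regions or unmutated
  proteins, verified to fail qualification;
* **mutant decoys** — windows of mutant sequences, verified present in
  the mutant set.

TPM is log-normal (ln-space μ = 0.5, σ = 1.5, median ≈ 1.6 — a
realistic bulk RNA-seq spread); a designated fraction of mutated genes
is forced to TPM ≤ threshold, with the first such gene set *exactly* to
the threshold so the boundary ("≤ is excluded") is always exercised.
The answer key lists expected candidate groups and per-peptide labels;
`n_counterpart_peptides` counts covered sites, i.e. expected candidate
groups. Under this construction the pipeline must achieve sensitivity
1.0 with zero false positives on every seed — the recovery tests
demonstrate algorithmic correctness, not robustness to real-data
pathologies the generator does not model: MS identification errors and
FDR behavior, HLA binding motifs (decoys are not motif-matched),
expression estimation noise, or transcript-isoform effects.

Default problem sizes (20 proteins, 6 mutated, 4 covered sites, ~20
peptides) keep a full 50-seed recovery sweep under a few seconds while
still exercising every decoy class; the instance generator for the
oracle-equivalence suite uses ≤ 10 proteins × ≤ 200 residues so the
brute-force oracle stays exhaustive.

## Numerical and degenerate-input choices

* All file coordinates are 1-based inclusive (HGVS.p convention);
  0-based offsets appear only inside window arithmetic.
* Peptides with non-standard letters (B, J, O, U, X, Z) in MS exports
  are dropped with a logged warning by default; strict mode errors.
* Empty peptidomes, zero candidates and header-only reports are valid
  outcomes, not errors; the CLI exits 0 with zero candidates.
* Candidate TSV rows are ordered by (protein, smallest covered
  position, representative mutant sequence); reports are
  stage-consistent by assertion.
* Expression comparisons are exact floating-point against the
  threshold; the boundary value itself is excluded by `<=`.

## Known limitations

* Missense substitutions only: frameshift, stop-loss, splice and
  fusion products are out of scope by design.
* The counterpart criterion is conservative: peptides recurring in any
  unchanged region are discarded proteome-wide, which can suppress
  candidates from repetitive or paralogous sequence.
* Mutations must arrive in protein coordinates; there is no VCF
  parsing or transcript-to-protein projection.
* The in-silico module counts candidates from an externally produced
  score table; it makes no binding predictions of its own.
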