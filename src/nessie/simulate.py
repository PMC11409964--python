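"""Ground-truthed synthetic datasets for end-to-end testing.

The generator emulates the structure of the pipeline's real inputs — a
reference proteome, somatic missense calls in protein coordinates, an
HLA-eluted peptide list from surrogate (non-tumor) material, and a
tumor RNA-seq TPM table — with a full answer key:

* counterpart peptides: class-length windows of wild-type mutated
  proteins covering a known substitution site, verified present in the
  wild-type set and absent from every mutant sequence; several length
  variants per site exercise the collapsing step;
* wild-type decoys: windows from unmutated regions (present in both
  wild-type and mutant sets, so they must be rejected);
* mutant decoys: windows of the MUTANT sequences covering a site
  (present in the mutant set, so they must be rejected);
* expression: log-normal TPM per gene, with a designated fraction of
  mutated genes forced to TPM <= threshold (the first such gene sits
  exactly on the boundary, which must be excluded).

Every implanted peptide's intended qualification or failure mode is
verified by running the membership tests, not assumed; draws that
accidentally qualify (or fail to) are rejected and redrawn. Amino-acid
composition defaults to uniform over the 20 letters — matching behavior
is composition-independent — and is configurable to empirical
frequencies. Fixed seed + params give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io
from .core import locate_occurrences
from .errors import ParameterError
from .proteome import ProteomePair, build_proteome_pair
from .types import (
    AMINO_ACIDS,
    LENGTH_BOUNDS,
    ExpressionTable,
    HLAClass,
    MissenseMutation,
    ProteinRecord,
    SurrogatePeptidome,
)


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic-data generator.

    Defaults model a small desk-scale instance: a 20-protein proteome
    with 6 mutated proteins, one substitution each, 4 covered sites with
    2 length variants apiece, plus both decoy classes, and log-normal
    TPM with a median near 1.6 (log-space mu=0.5, sigma=1.5 — a
    realistic bulk RNA-seq spread).
    """

    seed: int = 0
    n_proteins: int = 20
    protein_length_range: tuple[int, int] = (200, 400)
    n_mutated_proteins: int = 6
    mutations_per_protein: int = 1
    hla_class: HLAClass = HLAClass.I
    n_counterpart_peptides: int = 4  # number of covered sites -> expected candidates
    length_variants_per_site: int = 2
    n_decoy_peptides: int = 10
    n_mt_decoys: int = 4
    tpm_lognormal: tuple[float, float] = (0.5, 1.5)  # (mu, sigma) in ln space
    fraction_low_expression: float = 0.0
    tpm_threshold: float = 1.0
    aa_frequencies: tuple[float, ...] = field(default_factory=lambda: (0.05,) * 20)

    def __post_init__(self) -> None:
        lo, hi = self.protein_length_range
        cls_lo, cls_hi = LENGTH_BOUNDS[self.hla_class]
        if lo < cls_hi:
            raise ParameterError(
                f"min protein length {lo} shorter than max peptide length {cls_hi}"
            )
        counts = (
            self.n_proteins, self.n_mutated_proteins, self.mutations_per_protein,
            self.n_counterpart_peptides, self.length_variants_per_site,
            self.n_decoy_peptides, self.n_mt_decoys,
        )
        if any(c < 0 for c in counts):
            raise ParameterError("all counts must be >= 0")
        if self.n_mutated_proteins > self.n_proteins:
            raise ParameterError("more mutated proteins than proteins")
        if self.mutations_per_protein >= 1 and self.n_mutated_proteins >= 1:
            n_sites = self.n_mutated_proteins * self.mutations_per_protein
            if self.n_counterpart_peptides > n_sites:
                raise ParameterError(
                    f"{self.n_counterpart_peptides} covered sites requested but "
                    f"only {n_sites} mutation sites exist"
                )
        if not 0.0 <= self.fraction_low_expression <= 1.0:
            raise ParameterError("fraction_low_expression must be in [0, 1]")
        if abs(sum(self.aa_frequencies) - 1.0) > 1e-6 or len(self.aa_frequencies) != 20:
            raise ParameterError("aa_frequencies must be 20 values summing to 1")


@dataclass(frozen=True)
class TruthGroup:
    """One expected candidate: a covered-site set with its members."""

    protein_id: str
    gene_id: str
    covered_sites: tuple[tuple[int, str, str], ...]
    wt_members: tuple[str, ...]
    mutant_members: tuple[str, ...]
    expression_pass: bool
    tpm: float


@dataclass(frozen=True)
class SimTruth:
    """Answer key: expected candidate groups and per-peptide labels."""

    groups: tuple[TruthGroup, ...]
    peptide_labels: dict[str, str]  # counterpart | decoy_wt_unmutated_region | decoy_in_mt

    @property
    def expected_pass_groups(self) -> tuple[TruthGroup, ...]:
        return tuple(g for g in self.groups if g.expression_pass)


@dataclass(frozen=True)
class SimulatedDataset:
    """In-memory view of one simulated instance."""

    proteome: tuple[ProteinRecord, ...]
    mutations: tuple[MissenseMutation, ...]
    peptidome: SurrogatePeptidome
    expression: ExpressionTable
    truth: SimTruth
    pair: ProteomePair


def simulate_dataset(
    params: SimulationParams, out_dir: str | Path | None = None
) -> SimulatedDataset:
    """Generate one instance; optionally write it to ``out_dir`` in the
    standard file dialects (proteome.fasta, mutations.tsv, peptides.txt,
    expression.tsv, truth.tsv)."""
    rng = np.random.default_rng(params.seed)
    aa = np.array(list(AMINO_ACIDS))
    freqs = np.asarray(params.aa_frequencies)

    def random_seq(length: int) -> str:
        return "".join(rng.choice(aa, size=length, p=freqs))

    lo, hi = params.protein_length_range
    proteome = tuple(
        ProteinRecord(f"PROT{i:04d}", f"GENE{i:04d}", random_seq(int(rng.integers(lo, hi + 1))))
        for i in range(1, params.n_proteins + 1)
    )

    mutated = list(rng.choice(len(proteome), size=params.n_mutated_proteins, replace=False))
    mutations: list[MissenseMutation] = []
    for idx in sorted(mutated):
        rec = proteome[idx]
        positions = rng.choice(
            len(rec.sequence), size=params.mutations_per_protein, replace=False
        )
        for pos0 in sorted(int(p) for p in positions):
            ref = rec.sequence[pos0]
            alt = str(rng.choice([a for a in AMINO_ACIDS if a != ref]))
            mutations.append(
                MissenseMutation(
                    protein_id=rec.protein_id,
                    position=pos0 + 1,
                    ref_aa=ref,
                    alt_aa=alt,
                    gene_id=rec.gene_id,
                    label=f"{rec.gene_id} p.{ref}{pos0 + 1}{alt}",
                )
            )
    pair = build_proteome_pair(proteome, mutations)

    cls_lo, cls_hi = LENGTH_BOUNDS[params.hla_class]
    peptides: dict[str, str] = {}  # peptide -> label
    truth_groups: list[TruthGroup] = []

    # --- counterpart peptides: windows covering a chosen site, wt-only
    site_order = [(m.protein_id, m.position) for m in mutations]
    chosen_sites = site_order[: params.n_counterpart_peptides]
    for pid, position in chosen_sites:
        wt_seq = pair.wt[pid]
        other_sites = {s.position for s in pair.sites[pid]} - {position}
        members: list[tuple[str, int]] = []
        drawn: set[str] = set()
        attempts = 0
        while len(members) < max(1, params.length_variants_per_site):
            attempts += 1
            if attempts > 2000:
                raise ParameterError(
                    f"cannot implant {params.length_variants_per_site} counterpart "
                    f"variants at {pid}:{position}; sequences too constrained"
                )
            k = int(rng.integers(cls_lo, cls_hi + 1))
            start0_min = max(0, position - k)
            start0_max = min(position - 1, len(wt_seq) - k)
            if start0_max < start0_min:
                continue
            start0 = int(rng.integers(start0_min, start0_max + 1))
            pep = wt_seq[start0 : start0 + k]
            covered = {p for p in range(start0 + 1, start0 + k + 1)} & (
                other_sites | {position}
            )
            if covered != {position}:  # must cover exactly this one site
                continue
            if pep in drawn or pep in peptides:
                continue
            # verify the qualification: somewhere in wt, nowhere in mt,
            # and every wt occurrence covers exactly this site set
            if locate_occurrences(pep, pair.mt):
                continue
            occs = locate_occurrences(pep, pair.wt)
            if any(
                {s.position for s in pair.sites_in_window(p, st, k)} != {position}
                or p != pid
                for p, st in occs
            ):
                continue
            drawn.add(pep)
            members.append((pep, start0))
        site = next(s for s in pair.sites[pid] if s.position == position)
        mt_seq = pair.mt[pid]
        wt_members = tuple(sorted(p for p, _ in members))
        mutant_members = tuple(
            sorted(mt_seq[s : s + len(p)] for p, s in members)
        )
        truth_groups.append(
            TruthGroup(
                protein_id=pid,
                gene_id=site.gene_id,
                covered_sites=((site.position, site.ref_aa, site.alt_aa),),
                wt_members=wt_members,
                mutant_members=mutant_members,
                expression_pass=True,  # filled in after TPM assignment
                tpm=0.0,
            )
        )
        for p, _ in members:
            peptides[p] = "counterpart"

    # --- wild-type decoys: windows hitting no mutated site anywhere
    def draw_decoy(from_mutant: bool) -> str:
        for _ in range(2000):
            idx = int(rng.integers(len(proteome)))
            rec = proteome[idx]
            seq = pair.mt.get(rec.protein_id, rec.sequence) if from_mutant else rec.sequence
            k = int(rng.integers(cls_lo, cls_hi + 1))
            if len(seq) < k:
                continue
            start0 = int(rng.integers(0, len(seq) - k + 1))
            pep = seq[start0 : start0 + k]
            if pep in peptides:
                continue
            in_wt = bool(locate_occurrences(pep, pair.wt))
            in_mt = bool(locate_occurrences(pep, pair.mt))
            if from_mutant:
                if in_mt:  # anything in the mutant set is rejected by the search
                    return pep
            else:
                # must fail qualification: either absent from wt entirely
                # (drawn from an unmutated protein) or present in both
                if not in_wt or in_mt:
                    return pep
        raise ParameterError("cannot draw a verified decoy; parameters too tight")

    for _ in range(params.n_decoy_peptides):
        peptides[draw_decoy(from_mutant=False)] = "decoy_wt_unmutated_region"
    if params.n_mt_decoys and not pair.mt:
        raise ParameterError("mutant decoys requested but no mutated proteins")
    for _ in range(params.n_mt_decoys):
        peptides[draw_decoy(from_mutant=True)] = "decoy_in_mt"

    # --- expression: log-normal TPM; a designated fraction of mutated
    # genes forced to <= threshold, the first exactly on the boundary
    mu, sigma = params.tpm_lognormal
    tpm: dict[str, float] = {}
    for rec in proteome:
        value = float(rng.lognormal(mu, sigma))
        tpm[rec.gene_id] = round(value, 4)
    mutated_genes = sorted({m.gene_id for m in mutations})
    n_low = int(round(params.fraction_low_expression * len(mutated_genes)))
    low_genes = set(mutated_genes[:n_low])
    for i, gene in enumerate(sorted(low_genes)):
        tpm[gene] = params.tpm_threshold if i == 0 else round(
            float(rng.uniform(0, params.tpm_threshold)), 4
        )
    for gene in mutated_genes:
        if gene not in low_genes and tpm[gene] <= params.tpm_threshold:
            tpm[gene] = round(params.tpm_threshold + float(rng.uniform(0.5, 50.0)), 4)
    expression = ExpressionTable(tpm=tpm)

    truth_groups = [
        TruthGroup(
            protein_id=g.protein_id,
            gene_id=g.gene_id,
            covered_sites=g.covered_sites,
            wt_members=g.wt_members,
            mutant_members=g.mutant_members,
            expression_pass=tpm[g.gene_id] > params.tpm_threshold,
            tpm=tpm[g.gene_id],
        )
        for g in truth_groups
    ]

    peptidome = SurrogatePeptidome(
        peptides=frozenset(peptides),
        hla_class=params.hla_class,
        sample_label=f"sim-seed{params.seed}",
    )
    truth = SimTruth(groups=tuple(truth_groups), peptide_labels=dict(sorted(peptides.items())))
    dataset = SimulatedDataset(
        proteome=proteome,
        mutations=tuple(mutations),
        peptidome=peptidome,
        expression=expression,
        truth=truth,
        pair=pair,
    )
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir))
    return dataset


def _write_dataset(ds: SimulatedDataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_proteome(ds.proteome, out_dir / "proteome.fasta")
    io.write_mutations(ds.mutations, out_dir / "mutations.tsv")
    io.write_peptides(ds.peptidome, out_dir / "peptides.txt")
    io.write_expression(ds.expression, out_dir / "expression.tsv")
    lines = ["peptide\tlabel"]
    lines += [f"{p}\t{label}" for p, label in sorted(ds.truth.peptide_labels.items())]
    lines.append("")
    (out_dir / "truth.tsv").write_text("\n".join(lines))
    group_lines = [
        "protein_id\tgene_id\tcovered_sites\twt_members\tmutant_members\texpression_pass\ttpm"
    ]
    for g in ds.truth.groups:
        group_lines.append(
            "\t".join(
                (
                    g.protein_id,
                    g.gene_id,
                    ",".join(f"{r}{p}{a}" for p, r, a in g.covered_sites),
                    ",".join(g.wt_members),
                    ",".join(g.mutant_members),
                    str(g.expression_pass),
                    repr(g.tpm),
                )
            )
        )
    group_lines.append("")
    (out_dir / "truth_groups.tsv").write_text("\n".join(group_lines))
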