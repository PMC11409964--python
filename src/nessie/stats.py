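"""Descriptive immunopeptidome comparisons.

Cross-sample sharing (how much of each sample's repertoire recurs in
other samples with the same HLA), pairwise Venn overlaps, ligand length
distributions, C-terminal residue composition, and source-gene
expression profiles of a peptidome (each peptide mapped back to the
proteome by exact substring search, with a kernel density estimate of
log10 TPM for plotting).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .types import ExpressionTable, ProteinRecord, SurrogatePeptidome


@dataclass(frozen=True)
class SharingSummary:
    """Per-sample shared/unique peptide counts across >= 2 samples."""

    sample_counts: Mapping[str, tuple[int, int]]  # name -> (shared, unique)
    occurrence: Mapping[str, int]  # peptide -> number of samples containing it

    def fraction_shared(self, name: str) -> float:
        shared, unique = self.sample_counts[name]
        total = shared + unique
        return shared / total if total else 0.0


def sharing_counts(samples: Sequence[tuple[str, Iterable[str]]]) -> SharingSummary:
    """Count, per sample, peptides shared by >= 2 samples vs unique.

    ``samples`` is an ordered list of (name, peptide collection); each
    collection is deduplicated before counting.
    """
    if len(samples) < 2:
        raise ValueError("sharing analysis requires at least 2 samples")
    sets = [(name, frozenset(peps)) for name, peps in samples]
    names = [name for name, _ in sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample names")
    occurrence: Counter[str] = Counter()
    for _, peps in sets:
        occurrence.update(peps)
    sample_counts = {}
    for name, peps in sets:
        shared = sum(occurrence[p] >= 2 for p in peps)
        sample_counts[name] = (shared, len(peps) - shared)
    return SharingSummary(sample_counts=sample_counts, occurrence=dict(occurrence))


def pairwise_overlap(a: Iterable[str], b: Iterable[str]) -> tuple[int, int, int]:
    """Venn counts (|a only|, |a ∩ b|, |b only|) on deduplicated sets."""
    sa, sb = frozenset(a), frozenset(b)
    return len(sa - sb), len(sa & sb), len(sb - sa)


def source_gene_tpm(
    peptidome: SurrogatePeptidome,
    reference: Iterable[ProteinRecord],
    expr: ExpressionTable,
) -> tuple[list[float], int]:
    """Per-peptide source-gene TPM values for a peptidome.

    Each peptide is mapped to proteins by exact substring search; a
    multi-mapping peptide takes the MAXIMUM TPM over its source genes
    (the most plausible source under abundance bias). Peptides matching
    no protein, or only genes absent from the expression table, are
    excluded from the values and counted as unmapped.
    """
    records = list(reference)
    values: list[float] = []
    n_unmapped = 0
    for peptide in sorted(peptidome.peptides):
        tpms = [
            tpm
            for rec in records
            if peptide in rec.sequence
            and (tpm := expr.get(rec.gene_id)) is not None
        ]
        if tpms:
            values.append(max(tpms))
        else:
            n_unmapped += 1
    return values, n_unmapped


def log_tpm_density(
    tpm_values: Sequence[float],
    eps: float = 0.01,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian KDE of log10(TPM + eps) for density plots.

    Returns (log-values, grid, density). Needs >= 2 distinct values.
    """
    log_values = np.log10(np.asarray(tpm_values, dtype=float) + eps)
    if grid is None:
        pad = 0.5
        grid = np.linspace(log_values.min() - pad, log_values.max() + pad, 256)
    density = gaussian_kde(log_values)(grid)
    return log_values, grid, density


def length_distribution(peptides: Iterable[str]) -> dict[int, int]:
    """Peptide count per length, as a plain sorted dict."""
    counts = Counter(len(p) for p in peptides)
    return dict(sorted(counts.items()))


def cterminal_composition(peptides: Iterable[str]) -> dict[str, int]:
    """Count of each C-terminal residue (anchor-position composition)."""
    counts = Counter(p[-1] for p in peptides if p)
    return dict(sorted(counts.items()))
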