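"""Quartile-stratified expression comparisons.

Genes (or per-gene male/female pairs) are ranked by expression, split into
four contiguous bins — Q4 holds the highest-expression genes, Q1 the lowest
— and male and female expression are compared within each bin by rank-sum
test.  Two binning modes exist: *independent* (each sex's values ranked on
their own, for the within-sample Z:A dataset) and *paired max* (pairs
ranked by max(male, female), keeping each gene's two values in the same
bin, for the M:F dataset).  Because binning keys on ranks, membership is
invariant to any order-preserving transform of the values.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .dosage_stats import mwu_test

__all__ = [
    "QUARTILE_LABELS",
    "QuartileReport",
    "independent_quartiles",
    "paired_max_quartiles",
    "quartile_compare",
]

#: Bin labels from highest to lowest expression.
QUARTILE_LABELS = ("Q4", "Q3", "Q2", "Q1")


def _descending_order(keys: np.ndarray, gene_ids: Sequence[str]) -> np.ndarray:
    """Stable descending sort by value, ties broken by gene id ascending."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    # lexsort: last key is primary; negate values for descending order
    return np.lexsort((gene_ids, -keys))


def _split_sizes(n: int) -> list[int]:
    """Four near-equal contiguous bin sizes; higher-expression bins take the remainder."""
    base, rem = divmod(n, 4)
    return [base + (1 if i < rem else 0) for i in range(4)]


def _bin_indices(order: np.ndarray) -> dict[str, np.ndarray]:
    sizes = _split_sizes(order.size)
    bins: dict[str, np.ndarray] = {}
    start = 0
    for label, size in zip(QUARTILE_LABELS, sizes):
        bins[label] = order[start : start + size]
        start += size
    return bins


def independent_quartiles(values, gene_ids: Sequence[str]) -> dict[str, list[str]]:
    """Split genes into expression quartiles Q4 (high) … Q1 (very low).

    Values are ranked descending (ties broken by gene id, ascending) and cut
    into four contiguous bins as equal as possible, earlier bins taking the
    remainder.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 4:
        raise ValueError(f"need at least 4 values to form quartiles, got {vals.size}")
    if vals.size != len(gene_ids):
        raise ValueError("values and gene_ids differ in length")
    order = _descending_order(vals, gene_ids)
    return {
        label: [gene_ids[i] for i in idx]
        for label, idx in _bin_indices(order).items()
    }


def paired_max_quartiles(male, female, gene_ids: Sequence[str]) -> dict[str, list[str]]:
    """Split per-gene (male, female) pairs into quartiles by max(male, female).

    Each gene's pair stays intact in a single bin, so within-bin sex
    comparisons contrast the same genes.
    """
    m = np.asarray(male, dtype=float)
    f = np.asarray(female, dtype=float)
    if m.shape != f.shape or m.size != len(gene_ids):
        raise ValueError("male, female and gene_ids must have equal length")
    if m.size < 4:
        raise ValueError(f"need at least 4 pairs to form quartiles, got {m.size}")
    order = _descending_order(np.maximum(m, f), gene_ids)
    return {
        label: [gene_ids[i] for i in idx]
        for label, idx in _bin_indices(order).items()
    }


@dataclasses.dataclass
class QuartileBin:
    label: str
    gene_ids: list[str]
    median_log2_male: float
    median_log2_female: float
    p_value: float


@dataclasses.dataclass
class QuartileReport:
    """Per-quartile male-vs-female comparison (rank-sum, two-sided, raw p)."""

    binning_mode: str  # "independent" | "paired_max"
    bins: list[QuartileBin]

    def as_rows(self, label: str = "") -> list[dict]:
        return [
            {
                "label": label,
                "binning_mode": self.binning_mode,
                "quartile": b.label,
                "n_genes": len(b.gene_ids),
                "median_log2_male": b.median_log2_male,
                "median_log2_female": b.median_log2_female,
                "p_value": b.p_value,
            }
            for b in self.bins
        ]


def quartile_compare(
    bins_male: dict[str, Sequence[str]],
    bins_female: dict[str, Sequence[str]],
    male: dict[str, float],
    female: dict[str, float],
    binning_mode: str,
) -> QuartileReport:
    """Rank-sum male-vs-female comparison within each quartile.

    Under *independent* binning each sex contributes its own bin of genes
    (``bins_male`` and ``bins_female`` may differ); under *paired max*
    binning the two bin sets are the same shared partition.  ``male`` /
    ``female`` map gene id → positive linear expression; tests and reported
    medians use log2 values.
    """
    out: list[QuartileBin] = []
    for label in QUARTILE_LABELS:
        genes_m = list(bins_male[label])
        genes_f = list(bins_female[label])
        m = np.log2([male[g] for g in genes_m])
        f = np.log2([female[g] for g in genes_f])
        res = mwu_test(m, f, "two_sided")
        out.append(
            QuartileBin(
                label=label,
                gene_ids=sorted(set(genes_m) | set(genes_f)),
                median_log2_male=float(np.median(m)),
                median_log2_female=float(np.median(f)),
                p_value=res.p_value,
            )
        )
    return QuartileReport(binning_mode=binning_mode, bins=out)
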