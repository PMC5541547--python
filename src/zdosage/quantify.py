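"""Expression quantification: FPKM, replicate averaging, filters and TMM.

The analysis operates on two normalizations of the same raw counts:

* FPKM — fragments per kilobase of transcript per million mapped fragments,
  ``FPKM(g, s) = 1e9 * count(g, s) / (length(g) * N(s))`` with ``N(s)`` the
  library size of sample ``s``.
* TMM — trimmed mean of M-values scaling factors between libraries,
  computed from weighted, doubly trimmed log expression ratios and rescaled
  to geometric mean 1.

Two gene filters precede the ratio statistics: the "true expression" filter
(FPKM ≠ 0, either per sample or jointly in the male and female sample of a
stage) and a minimum-raw-count filter (a gene is kept only when it has at
least ``min_count`` reads in all four libraries of a male/female
technical-replicate quartet), applied before TMM.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expr_io import ExpressionMatrix, SampleMeta

__all__ = [
    "compute_fpkm",
    "average_replicates",
    "filter_true_expression",
    "filter_low_counts",
    "tmm_factors",
    "apply_tmm",
    "TmmFactors",
]

logger = logging.getLogger(__name__)


def compute_fpkm(
    counts: ExpressionMatrix,
    library_sizes: Mapping[str, float] | pd.Series | str = "from column sums",
) -> ExpressionMatrix:
    """Convert raw counts to FPKM using per-gene transcript lengths.

    ``library_sizes`` is either a per-sample mapping of positive totals or
    the string ``"from column sums"`` to use each column's total count.
    Fixed, externally known library sizes preserve genuine global expression
    differences between samples; column sums normalize them away.
    """
    if counts.unit != "raw_counts":
        raise ValueError(f"compute_fpkm expects raw_counts, got unit {counts.unit!r}")
    if counts.gene_lengths is None:
        raise ValueError("gene_lengths are required to compute FPKM")
    if isinstance(library_sizes, str):
        if library_sizes != "from column sums":
            raise ValueError(f"unknown library_sizes spec {library_sizes!r}")
        sizes = counts.values.sum(axis=0)
    else:
        sizes = pd.Series({s: float(library_sizes[s]) for s in counts.sample_ids})
    if (sizes <= 0).any():
        bad = sizes.index[sizes <= 0][0]
        raise ValueError(f"library size for sample {bad!r} must be positive")
    lengths = counts.gene_lengths.astype(float)
    fpkm = counts.values.div(lengths, axis=0).div(sizes, axis=1) * 1e9
    return ExpressionMatrix(fpkm, "fpkm", list(counts.samples), counts.gene_lengths)


def average_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average technical replicates, leaving one column per (sex, stage).

    The merged column is named ``<sex>_<stage>`` (just ``<stage>`` for
    unsexed samples such as cell lines); singleton groups pass through
    unchanged apart from the rename.
    """
    groups: dict[tuple[str, str], list[str]] = {}
    for s in matrix.samples:
        groups.setdefault((s.sex, s.stage), []).append(s.sample_id)
    cols = {}
    metas = []
    for (sex, stage), sample_ids in groups.items():
        if not sample_ids:
            raise ValueError(f"empty replicate group for ({sex}, {stage})")
        name = stage if sex == "none" else f"{sex}_{stage}"
        cols[name] = matrix.values[sample_ids].mean(axis=1)
        metas.append(SampleMeta(name, sex, stage, replicate=1))
    merged = pd.DataFrame(cols, index=matrix.values.index)
    return ExpressionMatrix(merged, matrix.unit, metas, matrix.gene_lengths)


def filter_true_expression(
    matrix: ExpressionMatrix, mode: str
) -> dict[str, ExpressionMatrix]:
    """Restrict to the "true expression dataset" (FPKM ≠ 0).

    mode ``per_sample``
        Returns one single-column matrix per sample, keeping the genes with
        positive FPKM in that sample (the universe for within-sample Z:A
        ratios).
    mode ``both_sexes``
        Returns one two-column (male, female) matrix per stage, keeping the
        genes with positive FPKM in *both* sexes (the universe for M:F
        ratios).  Stages lacking a male or female column are skipped.
    """
    if matrix.unit not in ("fpkm", "raw_counts"):
        raise ValueError(f"true-expression filter expects linear values, got {matrix.unit!r}")
    if mode == "per_sample":
        out: dict[str, ExpressionMatrix] = {}
        for s in matrix.samples:
            col = matrix.subset_samples([s.sample_id])
            keep = col.values.index[col.values[s.sample_id] > 0]
            out[s.sample_id] = col.subset_genes(list(keep))
        return out
    if mode == "both_sexes":
        out = {}
        by_stage: dict[str, dict[str, str]] = {}
        for s in matrix.samples:
            if s.sex in ("male", "female"):
                by_stage.setdefault(s.stage, {})[s.sex] = s.sample_id
        for stage, sexes in by_stage.items():
            if set(sexes) != {"male", "female"}:
                continue
            pair = matrix.subset_samples([sexes["male"], sexes["female"]])
            mask = (pair.values > 0).all(axis=1)
            out[stage] = pair.subset_genes(list(pair.values.index[mask]))
        return out
    raise ValueError(f"unknown true-expression filter mode {mode!r}")


def filter_low_counts(
    counts: ExpressionMatrix,
    comparison_samples: Sequence[str],
    min_count: int = 4,
) -> ExpressionMatrix:
    """Keep genes with at least ``min_count`` raw reads in all four libraries.

    ``comparison_samples`` names the four libraries of one stage (two male
    and two female technical replicates); a gene with fewer than
    ``min_count`` reads in any one of them is removed.
    """
    if counts.unit != "raw_counts":
        raise ValueError("filter_low_counts expects raw counts")
    if len(comparison_samples) != 4:
        raise ValueError(
            f"exactly 4 comparison samples are required, got {len(comparison_samples)}"
        )
    missing = [s for s in comparison_samples if s not in counts.sample_ids]
    if missing:
        raise ValueError(f"comparison samples not in matrix: {missing}")
    keep = (counts.values[list(comparison_samples)] >= min_count).all(axis=1)
    kept = counts.subset_genes(list(counts.values.index[keep]))
    logger.info(
        "low-count filter (min_count=%d): %d of %d genes retained",
        min_count, len(kept.gene_ids), len(counts.gene_ids),
    )
    return kept


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TmmFactors:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1."""

    factors: pd.Series
    reference: str
    logratio_trim: float
    intensity_trim: float

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """1-based mid-ranks (ties share the average of their rank range)."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def _tmm_one(
    x: np.ndarray, ref: np.ndarray, n_x: float, n_ref: float,
    logratio_trim: float, intensity_trim: float,
) -> float:
    """2^(weighted trimmed mean of M) of one library against the reference."""
    both = (x > 0) & (ref > 0)
    if not both.any():
        raise ValueError("sample shares no co-expressed gene with the reference")
    xk, xr = x[both].astype(float), ref[both].astype(float)
    pk, pr = xk / n_x, xr / n_ref
    m = np.log2(pk / pr)
    a = 0.5 * np.log2(pk * pr)
    w = 1.0 / ((n_x - xk) / (n_x * xk) + (n_ref - xr) / (n_ref * xr))
    n = len(m)
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * intensity_trim) + 1
    hi_a = n + 1 - lo_a
    rm = _average_ranks(m)
    ra = _average_ranks(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        logger.warning("TMM: no genes survive trimming; factor set to 1.0")
        return 1.0
    return float(2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))


def tmm_factors(
    counts: ExpressionMatrix,
    reference: str = "auto",
    logratio_trim: float = 0.30,
    intensity_trim: float = 0.05,
) -> TmmFactors:
    """Trimmed-mean-of-M-values scaling factors between libraries.

    For each library k against the reference r, using the genes with
    positive counts in both, the gene-wise log ratio
    ``M_g = log2((x_gk/N_k) / (x_gr/N_r))`` and average intensity
    ``A_g = 0.5 * log2((x_gk/N_k) * (x_gr/N_r))`` are doubly trimmed (the
    most extreme ``logratio_trim`` of genes at each end by M, and
    ``intensity_trim`` by A; survivors are the intersection) and the factor
    is ``2**(sum(w_g M_g)/sum(w_g))`` with inverse-variance precision
    weights ``w_g = 1/((N_k - x_gk)/(N_k x_gk) + (N_r - x_gr)/(N_r x_gr))``.
    Factors are finally rescaled to geometric mean 1.  ``reference="auto"``
    picks the sample whose 75th-percentile count fraction is closest to the
    mean of those fractions across samples.
    """
    if counts.unit != "raw_counts":
        raise ValueError("tmm_factors expects raw counts")
    if len(counts.sample_ids) < 2:
        raise ValueError("TMM needs at least two samples")
    vals = counts.values.to_numpy(dtype=float)
    sizes = vals.sum(axis=0)
    if (sizes <= 0).any():
        raise ValueError("every sample must have at least one positive count")
    if reference == "auto":
        q75 = np.array(
            [np.quantile(vals[:, j][vals[:, j] > 0], 0.75) for j in range(vals.shape[1])]
        ) / sizes
        reference = counts.sample_ids[int(np.argmin(np.abs(q75 - q75.mean())))]
    if reference not in counts.sample_ids:
        raise ValueError(f"reference sample {reference!r} not in matrix")
    r = counts.sample_ids.index(reference)
    raw = np.ones(len(counts.sample_ids))
    for j, sid in enumerate(counts.sample_ids):
        if j == r:
            continue
        raw[j] = _tmm_one(vals[:, j], vals[:, r], sizes[j], sizes[r],
                          logratio_trim, intensity_trim)
    raw /= np.exp(np.mean(np.log(raw)))
    return TmmFactors(
        pd.Series(raw, index=counts.sample_ids), reference, logratio_trim, intensity_trim
    )


def apply_tmm(counts: ExpressionMatrix, factors: TmmFactors) -> ExpressionMatrix:
    """TMM-normalized expression: counts / (library size × factor), per million.

    Returns counts-per-million on TMM-adjusted effective library sizes; the
    unit tag is ``fpkm`` in the loose sense of "normalized linear
    expression" so the downstream ratio statistics accept it (they depend
    only on relative expression).
    """
    if counts.unit != "raw_counts":
        raise ValueError("apply_tmm expects raw counts")
    sizes = counts.values.sum(axis=0)
    eff = sizes * factors.factors.reindex(counts.sample_ids)
    cpm = counts.values.div(eff, axis=1) * 1e6
    return ExpressionMatrix(cpm, "fpkm", list(counts.samples), counts.gene_lengths)
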