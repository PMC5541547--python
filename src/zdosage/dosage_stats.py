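"""Core dosage statistics.

Two estimates together characterise sex-chromosome dosage compensation:

* **Z:A ratio** — average expression of Z-linked genes divided by that of
  autosomal genes *within* one sample.  Values of 0.5 / 1 / 2 correspond to
  half / equal / double Z expression relative to autosomes.
* **M:F ratio** — the per-gene male/female expression ratio; the median of
  its distribution over a gene class summarises the sex bias of that class,
  and the Z-class median divided by the A-class median ("ratio of medians")
  is ≈1 when the Z chromosome is compensated relative to autosomes.

Group comparisons use the Mann–Whitney U (Wilcoxon rank-sum) test, exact by
enumeration for small tie-free samples and normal-approximated with tie and
continuity corrections otherwise.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "DosageSummary",
    "MFSummary",
    "mwu_test",
    "za_summary",
    "mf_ratios",
    "mf_summary",
    "delta_ct_fold",
]

#: Largest min(|x|, |y|) for which the exact U distribution is enumerated.
EXACT_LIMIT = 8


@dataclasses.dataclass(frozen=True)
class TestResult:
    """Outcome of a Mann–Whitney U test."""

    u: float
    p_value: float
    method: str  # "exact" | "normal_approx"
    alternative: str  # "two_sided" | "less" | "greater"


def _mid_ranks(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks of ``values`` and the tie-group sizes."""
    ranks = sps.rankdata(values, method="average")
    _, counts = np.unique(values, return_counts=True)
    return ranks, counts


def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank assignments giving each U value, for tie-free data.

    ``counts[u]`` is the number of n1-subsets of the pooled ranks 1..n1+n2
    whose rank sum W satisfies ``U = W - n1(n1+1)/2 = u``; the counts total
    C(n1+n2, n1).  Computed by a subset-sum dynamic program over the ranks.
    """
    n = n1 + n2
    max_w = sum(range(n2 + 1, n + 1))  # largest possible rank sum of x
    dp = np.zeros((n1 + 1, max_w + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in range(1, n + 1):
        for j in range(min(r, n1), 0, -1):
            dp[j, r:] += dp[j - 1, : max_w + 1 - r]
    min_w = n1 * (n1 + 1) // 2
    return dp[n1, min_w : min_w + n1 * n2 + 1]


def mwu_test(x, y, alternative: str = "two_sided") -> TestResult:
    """Mann–Whitney U test of two independent samples.

    ``U`` counts pairs with x above y (ties counted half).  The exact null
    distribution is enumerated when ``min(|x|, |y|) <= 8`` and the pooled
    data are tie-free; otherwise a normal approximation with tie correction
    and continuity correction is used.  The exact two-sided p-value doubles
    the smaller tail probability, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mwu_test requires non-empty samples")
    if alternative not in ("two_sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks, tie_sizes = _mid_ranks(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0  # pairs with x > y, + half-ties
    has_ties = (tie_sizes > 1).any()

    if min(n1, n2) <= EXACT_LIMIT and not has_ties:
        counts = _exact_u_counts(n1, n2)
        total = counts.sum()
        ui = int(round(u))
        p_le = counts[: ui + 1].sum() / total
        p_ge = counts[ui:].sum() / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(u=float(u), p_value=float(p), method="exact",
                          alternative=alternative)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(np.sum(tie_sizes**3 - tie_sizes)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        return TestResult(u=float(u), p_value=1.0, method="normal_approx",
                          alternative=alternative)
    sd = math.sqrt(var)
    if alternative == "greater":
        z = (u - mu - 0.5) / sd
        p = sps.norm.sf(z)
    elif alternative == "less":
        z = (u - mu + 0.5) / sd
        p = sps.norm.cdf(z)
    else:
        cc = 0.5 if u != mu else 0.0
        z = (u - mu - math.copysign(cc, u - mu)) / sd
        p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(u=float(u), p_value=float(min(1.0, p)),
                      method="normal_approx", alternative=alternative)


# ---------------------------------------------------------------------------
# Z:A summaries (per-sample relative Z expression)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class DosageSummary:
    """Per-sample Z:A expression summary (one table row)."""

    sample: str
    mean_A: float
    mean_Z: float
    mean_za: float
    median_A: float
    median_Z: float
    median_za: float
    n_A: int
    n_Z: int
    p_A_vs_Z: float

    def as_row(self) -> dict:
        return dataclasses.asdict(self)


def za_summary(fpkm_A, fpkm_Z, label: str) -> DosageSummary:
    """Mean- and median-based Z:A ratios within one sample.

    Inputs are the positive FPKM values of autosomal and Z-linked genes in
    the sample (the true-expression dataset).  Means and medians are taken
    on the linear FPKM scale; the A-vs-Z rank-sum test compares the two
    log2-FPKM distributions two-sidedly.
    """
    a = np.asarray(fpkm_A, dtype=float)
    z = np.asarray(fpkm_Z, dtype=float)
    if a.size == 0 or z.size == 0:
        raise ValueError(f"za_summary({label!r}): empty gene class")
    if (a <= 0).any() or (z <= 0).any():
        raise ValueError(
            f"za_summary({label!r}): non-positive FPKM; apply the true-expression filter first"
        )
    mean_a, mean_z = float(a.mean()), float(z.mean())
    med_a, med_z = float(np.median(a)), float(np.median(z))
    p = mwu_test(np.log2(a), np.log2(z), "two_sided").p_value
    return DosageSummary(
        sample=label,
        mean_A=mean_a, mean_Z=mean_z, mean_za=mean_z / mean_a,
        median_A=med_a, median_Z=med_z, median_za=med_z / med_a,
        n_A=int(a.size), n_Z=int(z.size), p_A_vs_Z=p,
    )


# ---------------------------------------------------------------------------
# M:F summaries (sex-biased expression per stage)
# ---------------------------------------------------------------------------


def mf_ratios(male, female) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene male/female ratios and their log2, for genes expressed in both sexes."""
    m = np.asarray(male, dtype=float)
    f = np.asarray(female, dtype=float)
    if m.shape != f.shape:
        raise ValueError(f"male and female vectors differ in length: {m.size} vs {f.size}")
    if (m <= 0).any() or (f <= 0).any():
        raise ValueError("M:F ratios require FPKM > 0 in both sexes; filter first")
    ratio = m / f
    return ratio, np.log2(ratio)


@dataclasses.dataclass
class MFSummary:
    """Per-stage M:F summary for the Z and A gene classes (one table row)."""

    stage: str
    n_Z: int
    n_A: int
    median_mf_Z: float
    median_mf_A: float
    za_ratio_of_medians: float
    p_Z_MvsF: float
    p_A_MvsF: float
    p_AvsZ_dist: float

    def as_row(self) -> dict:
        return dataclasses.asdict(self)


def mf_summary(
    ratios_Z,
    ratios_A,
    stage: str,
    pairs_Z: tuple | None = None,
    pairs_A: tuple | None = None,
) -> MFSummary:
    """Summarise sex-biased expression of the Z and A classes at one stage.

    ``ratios_Z`` / ``ratios_A`` are the per-gene M:F ratio vectors.  The
    ratio of medians (median Z-class M:F over median A-class M:F) is the
    headline compensation statistic.  When ``pairs_Z`` / ``pairs_A`` supply
    the underlying ``(male_fpkm, female_fpkm)`` vectors, the within-class
    male-vs-female rank-sum tests compare the two log2-FPKM distributions
    (unpaired, two-sided); without them those p-values are NaN.  The
    A-vs-Z distribution test always compares the two log2-ratio
    distributions.
    """
    rz = np.asarray(ratios_Z, dtype=float)
    ra = np.asarray(ratios_A, dtype=float)
    if rz.size == 0 or ra.size == 0:
        raise ValueError(f"mf_summary({stage!r}): empty gene class")
    med_z, med_a = float(np.median(rz)), float(np.median(ra))

    def _sex_test(pairs) -> float:
        if pairs is None:
            return float("nan")
        m, f = (np.asarray(v, dtype=float) for v in pairs)
        return mwu_test(np.log2(m), np.log2(f), "two_sided").p_value

    p_avsz = mwu_test(np.log2(rz), np.log2(ra), "two_sided").p_value
    return MFSummary(
        stage=stage, n_Z=int(rz.size), n_A=int(ra.size),
        median_mf_Z=med_z, median_mf_A=med_a,
        za_ratio_of_medians=med_z / med_a,
        p_Z_MvsF=_sex_test(pairs_Z), p_A_MvsF=_sex_test(pairs_A),
        p_AvsZ_dist=p_avsz,
    )


def delta_ct_fold(
    ct_target_m: float, ct_ref_m: float, ct_target_f: float, ct_ref_f: float
) -> float:
    """qRT-PCR relative expression of male vs female by ΔCt analysis.

    ``fold = 2**-(ΔCt_male - ΔCt_female)`` with ``ΔCt = Ct_target - Ct_ref``
    against an endogenous reference gene; the female sample is the
    calibrator (fold 1).
    """
    for v in (ct_target_m, ct_ref_m, ct_target_f, ct_ref_f):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_m - ct_ref_m) - (ct_target_f - ct_ref_f)
    return float(2.0 ** (-ddct))
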