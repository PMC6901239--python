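"""Per-individual variant-allele counts and the bootstrap comparison test.

The comparison framework fixes one cohort (the isolate) and repeatedly
resamples size-matched subsets (with replacement) from the reference
cohort.  Each replicate records the subset median count, the
fixed/subset median ratio and a Wilcoxon rank-sum p-value.  A contrast
is called significant only under a dual rule: at least 95% of subsets
reach the (Bonferroni-corrected) p-value threshold, AND the fixed
cohort's median falls outside the 95% percentile interval of the
subset medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import CohortGenotypes, MISSING

logger = logging.getLogger(__name__)


def per_individual_counts(cohort: CohortGenotypes, site_mask: np.ndarray,
                          region_length_mb: float | None = None) -> np.ndarray:
    """Variant-allele count per individual over the masked sites.

    Alleles, not sites: a heterozygote contributes 1, a hom-alt 2.
    With ``region_length_mb`` the counts are returned per megabase.
    """
    mask = np.asarray(site_mask)
    if mask.dtype == bool:
        cols = np.flatnonzero(mask)
    else:
        cols = mask
    gt = cohort.gt[:, cols]
    counts = np.where(gt == MISSING, 0, gt).sum(axis=1).astype(float)
    if region_length_mb is not None:
        if region_length_mb <= 0:
            raise ValueError("region length must be positive")
        counts = counts / region_length_mb
    return counts


def wilcoxon_rank_sum(a, b, sided: str = "two") -> float:
    """Wilcoxon rank-sum p-value with midrank ties.

    Exact null distribution when both groups have at most 12
    observations and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.

    ``sided``: "two", or "less"/"greater" meaning the first sample's
    distribution is shifted that way.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    alternative = {"two": "two-sided", "less": "less", "greater": "greater"}[sided]
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0  # identical constant samples carry no rank evidence
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (max(a.size, b.size) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.pvalue)


@dataclass
class ComparisonResult:
    """Bootstrap verdict for one variant class/region contrast."""

    fixed_median: float
    subset_medians: np.ndarray
    ratio_median: float
    ratio_ci: tuple[float, float]
    p_median: float
    p_ci: tuple[float, float]
    n_significant: int
    n_subsets: int
    alpha: float
    verdict: bool
    n_infinite_ratio: int = 0


def bootstrap_compare(fixed_counts, pool_counts, n_subsets: int = 10_000,
                      subset_size: int | None = None, alpha: float = 5e-3,
                      seed=None) -> ComparisonResult:
    """Compare a fixed cohort's counts against bootstrap reference subsets.

    Subsets are drawn with replacement from ``pool_counts``; the
    default subset size matches the fixed cohort.  Per subset the
    two-sided Wilcoxon rank-sum p-value (fixed vs subset) and the
    median ratio are recorded.  The verdict requires both
    ``n_significant >= 0.95 * n_subsets`` and the fixed median lying
    outside the [2.5, 97.5] percentile interval of subset medians.
    Subsets with zero median yield an infinite ratio, excluded from the
    ratio CI with a logged count.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fixed = np.asarray(fixed_counts, dtype=float)
    pool = np.asarray(pool_counts, dtype=float)
    if subset_size is None:
        subset_size = fixed.size
    subsets = pool[rng.integers(0, pool.size, size=(n_subsets, subset_size))]
    subset_medians = np.median(subsets, axis=1)
    fixed_median = float(np.median(fixed))

    with np.errstate(divide="ignore"):
        ratios = np.where(subset_medians > 0, fixed_median / np.maximum(subset_medians, 1e-300), np.inf)
    finite = np.isfinite(ratios)
    n_inf = int((~finite).sum())
    if n_inf:
        logger.info("bootstrap_compare: %d subset(s) with zero median excluded "
                    "from the ratio CI", n_inf)

    if np.array_equal(fixed, np.full_like(fixed, fixed[0])) and np.all(subsets == fixed[0]):
        pvals = np.ones(n_subsets)
    else:
        pvals = stats.mannwhitneyu(
            fixed[None, :], subsets, alternative="two-sided",
            method="asymptotic", use_continuity=True, axis=-1,
        ).pvalue
        pvals = np.atleast_1d(np.asarray(pvals, dtype=float))
        pvals[np.isnan(pvals)] = 1.0  # all-tied replicates carry no evidence

    n_sig = int((pvals <= alpha).sum())
    med_lo, med_hi = np.percentile(subset_medians, [2.5, 97.5])
    verdict = (n_sig >= 0.95 * n_subsets) and not (med_lo <= fixed_median <= med_hi)
    fr = ratios[finite]
    ratio_ci = tuple(np.percentile(fr, [2.5, 97.5])) if fr.size else (np.nan, np.nan)
    return ComparisonResult(
        fixed_median=fixed_median,
        subset_medians=subset_medians,
        ratio_median=float(np.median(fr)) if fr.size else np.inf,
        ratio_ci=(float(ratio_ci[0]), float(ratio_ci[1])),
        p_median=float(np.median(pvals)),
        p_ci=(float(np.percentile(pvals, 2.5)), float(np.percentile(pvals, 97.5))),
        n_significant=n_sig,
        n_subsets=n_subsets,
        alpha=alpha,
        verdict=bool(verdict),
        n_infinite_ratio=n_inf,
    )


# Bonferroni-corrected alpha defaults by analysis family
DEFAULT_ALPHAS = {
    "genome_wide": 5e-3,
    "coding_regions": 8e-4,
    "chromatin_states": 2e-4,
    "roh": 0.0125,
}


def bonferroni_alpha(base_alpha: float, family_size: int) -> float:
    """Corrected per-test threshold ``base_alpha / family_size``."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return base_alpha / family_size
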