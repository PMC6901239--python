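"""Hard-filter threshold derivation and variant-level quality control.

Thresholds are derived per cohort (never pooled) as the boundary to the
worst-quality ``tail_fraction`` of each GATK-style site annotation:
lower bounds for QD, MQ, MQRankSum and ReadPosRankSum, upper bounds for
FS and SOR.  Filters use strict inequalities, so a value exactly at the
cutoff passes.  Site-level retention follows KEEP_IF_ANY_UNFILTERED
semantics: a site survives if at least one sample's call passes.

Additional rules: a per-genotype depth floor; exclusion of variants in
fixed 100 bp genome blocks with extreme GC content; and the DP/GQ
carrier checks applied to candidate ultra-rare (panel-absent) variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import CohortGenotypes, VariantSite

logger = logging.getLogger(__name__)

LOW_IS_BAD = ("QD", "MQ", "MQRankSum", "ReadPosRankSum")
HIGH_IS_BAD = ("FS", "SOR")


@dataclass
class HardFilterThresholds:
    """Per-parameter cutoffs; a genotype fails on strict violation only."""

    lower: dict = field(default_factory=dict)  # param -> fail if value < cutoff
    upper: dict = field(default_factory=dict)  # param -> fail if value > cutoff
    dp_floor: int = 10

    def __post_init__(self) -> None:
        if self.dp_floor < 0:
            raise ValueError("dp_floor must be >= 0")
        for d in (self.lower, self.upper):
            for k, v in d.items():
                if not np.isfinite(v):
                    raise ValueError(f"non-finite cutoff for {k}")


def derive_thresholds(annotation_samples: Mapping[str, Sequence[float]],
                      tail_fraction: float = 0.05,
                      dp_floor: int = 10) -> HardFilterThresholds:
    """Quantile-based cutoffs isolating the worst-quality tail.

    For low-is-bad parameters the cutoff is the ``tail_fraction``
    quantile; for high-is-bad the ``1 - tail_fraction`` quantile.
    Quantiles use linear interpolation between order statistics
    (NumPy's default, the classical "type 7") so derived thresholds are
    exactly reproducible.  SNPs and INDELs should be passed in as
    separate collections by the caller.
    """
    if not 0.0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5)")
    lower, upper = {}, {}
    for name, values in annotation_samples.items():
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            raise ValueError(f"no finite values for parameter {name!r}")
        if name in LOW_IS_BAD:
            lower[name] = float(np.quantile(arr, tail_fraction))
        elif name in HIGH_IS_BAD:
            upper[name] = float(np.quantile(arr, 1.0 - tail_fraction))
        else:
            raise KeyError(f"unknown hard-filter parameter {name!r}")
    return HardFilterThresholds(lower=lower, upper=upper, dp_floor=dp_floor)


def site_fails_annotations(site: VariantSite, thr: HardFilterThresholds) -> bool:
    """Strict-inequality check of the site-level annotations.

    A missing annotation is "not evaluated" by that filter, never a
    failure.
    """
    ann = site.site_annotations
    for name, cutoff in thr.lower.items():
        if name in ann and ann[name] < cutoff:
            return True
    for name, cutoff in thr.upper.items():
        if name in ann and ann[name] > cutoff:
            return True
    return False


@dataclass
class HardFilterResult:
    genotype_pass: np.ndarray  # (n_samples, n_sites) bool
    site_keep: np.ndarray      # (n_sites,) bool; any-unfiltered rule


def apply_hard_filters(cohort: CohortGenotypes,
                       thr: HardFilterThresholds) -> HardFilterResult:
    """Genotype-level pass/fail plus the cohort-level keep decision.

    A genotype fails if its site's annotations violate any cutoff or its
    depth is below ``dp_floor``.  A site is kept cohort-wide iff at
    least one sample's call is unfiltered (KEEP_IF_ANY_UNFILTERED).
    Missing genotypes never rescue a site.
    """
    site_bad = np.array(
        [site_fails_annotations(s, thr) for s in cohort.sites], dtype=bool
    )
    gt_called = cohort.gt != -1
    gpass = gt_called & ~site_bad[None, :] & (cohort.dp >= thr.dp_floor)
    return HardFilterResult(genotype_pass=gpass, site_keep=gpass.any(axis=0))


def gc_content_blocks(genome: str, block_size: int = 100) -> np.ndarray:
    """GC fraction of fixed consecutive blocks starting at position 1.

    Ambiguous bases (anything outside ACGT) are excluded from both the
    numerator and the denominator; an all-ambiguous block gets NaN.
    """
    seq = np.frombuffer(genome.upper().encode("ascii"), dtype=np.uint8)
    n_blocks = (seq.size + block_size - 1) // block_size
    padded = np.full(n_blocks * block_size, ord("N"), dtype=np.uint8)
    padded[: seq.size] = seq
    blocks = padded.reshape(n_blocks, block_size)
    gc = ((blocks == ord("G")) | (blocks == ord("C"))).sum(axis=1)
    valid = np.isin(blocks, [ord(b) for b in "ACGT"]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(valid > 0, gc / np.maximum(valid, 1), np.nan)


def gc_window_filter(sites: Sequence[VariantSite], genome: str,
                     block_size: int = 100,
                     lo: float = 0.15, hi: float = 0.75) -> list[VariantSite]:
    """Drop variants in 100 bp blocks of extreme GC content.

    Exclusion is strict (< 15% or > 75%); blocks of entirely ambiguous
    sequence have undefined GC and exclude nothing.
    """
    frac = gc_content_blocks(genome, block_size)
    kept = []
    n_undefined = 0
    for site in sites:
        if site.pos > len(genome):
            raise ValueError(f"site {site.chrom}:{site.pos} beyond genome end")
        f = frac[(site.pos - 1) // block_size]
        if np.isnan(f):
            n_undefined += 1
            kept.append(site)
        elif lo <= f <= hi:
            kept.append(site)
    if n_undefined:
        logger.info("GC filter: %d site(s) in all-ambiguous blocks retained", n_undefined)
    return kept


def gc_keep_mask(positions: np.ndarray, genome: str, block_size: int = 100,
                 lo: float = 0.15, hi: float = 0.75) -> np.ndarray:
    """Vectorised form of :func:`gc_window_filter` over 1-based positions."""
    frac = gc_content_blocks(genome, block_size)
    f = frac[(np.asarray(positions, dtype=np.int64) - 1) // block_size]
    return np.isnan(f) | ((f >= lo) & (f <= hi))


# carrier DP/GQ bounds for candidate ultra-rare variants, by variant type
ULTRA_RARE_BOUNDS = {
    "snp": {"dp_min": 8, "dp_max": 60, "gq_min": 30},
    "indel": {"dp_min": 12, "dp_max": 60, "gq_min": 40},
}


def ultra_rare_qc(site: VariantSite, carrier_dp: Sequence[int],
                  carrier_gq: Sequence[int], cohort_af: float,
                  af_max: float = 0.1) -> bool:
    """Carrier-evidence QC for a panel-absent candidate ultra-rare variant.

    Pass iff the site is biallelic with cohort AF <= 0.1 and every
    carrier genotype satisfies the type-specific depth and quality
    bounds (SNP: 8 <= DP <= 60 and GQ >= 30; INDEL: 12 <= DP <= 60 and
    GQ >= 40), all boundaries inclusive.
    """
    if cohort_af > af_max:
        return False
    b = ULTRA_RARE_BOUNDS["snp" if site.is_snp else "indel"]
    dp = np.asarray(carrier_dp)
    gq = np.asarray(carrier_gq)
    return bool(
        np.all(dp >= b["dp_min"]) and np.all(dp <= b["dp_max"])
        and np.all(gq >= b["gq_min"])
    )


def ultra_rare_qc_mask(cohort: CohortGenotypes, candidate: np.ndarray,
                       af_max: float = 0.1) -> np.ndarray:
    """Apply :func:`ultra_rare_qc` over all candidate sites of a cohort."""
    keep = np.zeros(cohort.n_sites, dtype=bool)
    af = cohort.cohort_af
    carrier = cohort.gt > 0
    snp = cohort.is_snp_mask()
    for j in np.flatnonzero(np.asarray(candidate)):
        if not (af[j] <= af_max):
            continue
        b = ULTRA_RARE_BOUNDS["snp" if snp[j] else "indel"]
        rows = carrier[:, j]
        dp = cohort.dp[rows, j]
        gq = cohort.gq[rows, j]
        keep[j] = bool(
            np.all(dp >= b["dp_min"]) and np.all(dp <= b["dp_max"])
            and np.all(gq >= b["gq_min"])
        )
    return keep
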