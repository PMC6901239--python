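"""Relaxation-of-selection statistics.

Three complementary lines of evidence:

* **LOF/SYN ratio** -- the allele-count ratio of predicted
  loss-of-function variants (stop gained, essential splice, and
  missense with CADD >= 20) to synonymous variants.  Under relaxed
  purifying selection damaging alleles survive longer, inflating the
  ratio; a smaller-Ne isolate is expected to sit above its
  cosmopolitan control.

* **Allelic shift bias (ASB)** -- a region-level test usable outside
  exons.  For panel-known very rare SNPs (MAF_NFE <= 1%) shared by the
  isolate and a bootstrap reference subset, each cohort's constraint
  signal is the drop in mean within-cohort MAF from a neutral
  intergenic baseline (NFIG) to the test region.  Weakened constraint
  shows up as systematically smaller shifts, assessed by a one-sided
  Wilcoxon rank-sum over bootstrap replicates.

* **Fisher enrichment** -- per-variant one-sided Fisher's exact test
  of cohort AC/AN against the panel's POPMAX counts (or a
  coverage-derived AN for panel-absent variants), Bonferroni corrected
  by the candidate family size.

Within-cohort "MAF" is the folded cohort allele frequency
min(AF, 1 - AF) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .compare import wilcoxon_rank_sum
from .core import CohortGenotypes, MISSING, PanelRecord, VariantSite

logger = logging.getLogger(__name__)

LOF_SET = ("stop_gained", "splice_donor", "splice_acceptor")
FUNCTIONAL_CONSEQUENCES = (
    "stop_gained", "splice_acceptor", "splice_donor", "start_lost",
    "stop_lost", "missense", "frameshift", "inframe_insertion",
    "inframe_deletion",
)
NONSENSE_CLASS = ("stop_gained", "splice_acceptor", "splice_donor",
                  "start_lost", "stop_lost", "frameshift")
CADD_LOF_THRESHOLD = 20.0


def categorize_lof_syn(site: VariantSite) -> str:
    """LOF / SYN / OTHER for an exonic SNP.

    LOF: stop gained or essential splice, or missense with
    CADD >= 20.  SYN: synonymous.  Everything else OTHER.
    """
    if site.consequence in LOF_SET:
        return "LOF"
    if site.consequence == "missense":
        if site.cadd is not None and site.cadd >= CADD_LOF_THRESHOLD:
            return "LOF"
        return "OTHER"
    if site.consequence == "synonymous":
        return "SYN"
    return "OTHER"


def lof_syn_ratio_from_counts(n_lof: int, n_syn: int) -> float:
    """Cohort-level ratio of LOF to SYN allele counts."""
    if n_syn <= 0:
        raise ValueError("ratio undefined with zero SYN alleles")
    return n_lof / n_syn


@dataclass
class LofSynResult:
    n_lof: int
    n_syn: int
    ratio: float
    gene_restricted: bool
    per_individual_ratios: np.ndarray
    wilcoxon_p: float | None  # one-sided vs the other cohort, if given


def _scope_mask(cohort: CohortGenotypes, ultra_mask: np.ndarray, scope: str) -> np.ndarray:
    snp = cohort.is_snp_mask()
    base = np.asarray(ultra_mask) & snp
    if scope == "all_ultra_rare":
        return base
    if scope == "singleton":
        carriers = (cohort.gt > 0).sum(axis=0)
        het_only = (cohort.gt == 2).sum(axis=0) == 0
        return base & (carriers == 1) & het_only
    raise ValueError(f"unknown scope {scope!r}")


def lof_syn_ratio(cohort: CohortGenotypes, ultra_mask: np.ndarray,
                  scope: str = "all_ultra_rare", gene_restrict: bool = False,
                  other_cohort: CohortGenotypes | None = None,
                  other_ultra_mask: np.ndarray | None = None) -> LofSynResult:
    """LOF/SYN allele-count ratio over a cohort's ultra-rare exonic SNPs.

    ``scope="singleton"`` keeps only heterozygous sole-carrier sites.
    ``gene_restrict`` keeps genes with at least one LOF or SYN variant
    observed in both cohorts.  Per-individual ratios (individuals with
    >= 1 SYN allele) feed a one-sided Wilcoxon rank-sum against the
    other cohort (alternative: this cohort's ratios larger).
    """
    cats = np.array([categorize_lof_syn(s) for s in cohort.sites])
    mask = _scope_mask(cohort, ultra_mask, scope)
    lof_sites = mask & (cats == "LOF")
    syn_sites = mask & (cats == "SYN")

    other_ratios = None
    if gene_restrict:
        if other_cohort is None:
            raise ValueError("gene_restrict requires the other cohort")
        genes_here = _genes_with_lof_or_syn(cohort, mask, cats)
        o_mask = _scope_mask(other_cohort, other_ultra_mask, scope)
        o_cats = np.array([categorize_lof_syn(s) for s in other_cohort.sites])
        genes_there = _genes_with_lof_or_syn(other_cohort, o_mask, o_cats)
        shared = genes_here & genes_there
        in_shared = np.array([s.gene_id in shared for s in cohort.sites])
        lof_sites &= in_shared
        syn_sites &= in_shared
        o_in_shared = np.array([s.gene_id in shared for s in other_cohort.sites])
        other_ratios = _per_individual_ratios(
            other_cohort, o_mask & (o_cats == "LOF") & o_in_shared,
            o_mask & (o_cats == "SYN") & o_in_shared)
    elif other_cohort is not None:
        o_mask = _scope_mask(other_cohort, other_ultra_mask, scope)
        o_cats = np.array([categorize_lof_syn(s) for s in other_cohort.sites])
        other_ratios = _per_individual_ratios(
            other_cohort, o_mask & (o_cats == "LOF"), o_mask & (o_cats == "SYN"))

    ac = cohort.cohort_ac
    n_lof = int(ac[lof_sites].sum())
    n_syn = int(ac[syn_sites].sum())
    ratios = _per_individual_ratios(cohort, lof_sites, syn_sites)
    p = None
    if other_ratios is not None and ratios.size and other_ratios.size:
        p = wilcoxon_rank_sum(ratios, other_ratios, sided="greater")
    return LofSynResult(
        n_lof=n_lof, n_syn=n_syn,
        ratio=lof_syn_ratio_from_counts(n_lof, n_syn),
        gene_restricted=gene_restrict,
        per_individual_ratios=ratios, wilcoxon_p=p,
    )


def _genes_with_lof_or_syn(cohort, mask, cats) -> set:
    keep = mask & np.isin(cats, ("LOF", "SYN"))
    ac = cohort.cohort_ac
    return {cohort.sites[j].gene_id for j in np.flatnonzero(keep & (ac > 0))
            if cohort.sites[j].gene_id is not None}


def _per_individual_ratios(cohort, lof_sites, syn_sites) -> np.ndarray:
    """LOF/SYN allele ratio per individual; zero-SYN individuals excluded."""
    gt = np.where(cohort.gt == MISSING, 0, cohort.gt)
    lof = gt[:, lof_sites].sum(axis=1)
    syn = gt[:, syn_sites].sum(axis=1)
    ok = syn > 0
    return lof[ok] / syn[ok]


# ---------------------------------------------------------------------------
# Fraction of ultra-rare variants


def fuv(n_ultra: int, n_known: int, region_length_mb: float | None = None) -> dict:
    """Fraction of ultra-rare variants and variant density per Mb."""
    total = n_ultra + n_known
    if total == 0:
        raise ValueError("no variants in region; FUV undefined")
    out = {"fuv": n_ultra / total, "n_ultra": n_ultra, "n_known": n_known}
    if region_length_mb is not None:
        if region_length_mb <= 0:
            raise ValueError("region length must be positive")
        out["density_per_mb"] = total / region_length_mb
    return out


# ---------------------------------------------------------------------------
# Allelic shift bias


@dataclass
class AsbResult:
    region: str
    iso_shifts: np.ndarray
    ref_shifts: np.ndarray
    p_value: float
    n_dropped: int = 0


def asb_test(iso_cohort: CohortGenotypes, ref_cohort: CohortGenotypes,
             eligible: np.ndarray, region_mask: np.ndarray,
             nfig_mask: np.ndarray, n_reps: int = 1000,
             subset_size: int | None = None, seed=None,
             region_label: str = "", chunk: int = 100) -> AsbResult:
    """Allelic shift bias test of one region against the NFIG baseline.

    ``eligible`` marks panel-present SNPs with MAF_NFE <= 1% (plus any
    region-specific consequence/CADD restriction already folded into
    ``region_mask``).  Both cohorts must hold the same site list in the
    same order.  Per replicate a reference subset (with replacement,
    default size = isolate cohort) is drawn; qualifying sites are the
    eligible sites carried in BOTH the isolate and the subset; each
    cohort's shift is mean folded MAF over qualifying NFIG sites minus
    the mean over qualifying region sites.  Replicates with no
    qualifying site in either region are dropped with a logged count.
    The p-value is a one-sided Wilcoxon rank sum with alternative
    "isolate shifts smaller".
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if subset_size is None:
        subset_size = iso_cohort.n_samples
    eligible = np.asarray(eligible, bool)
    region_mask = np.asarray(region_mask, bool) & eligible
    nfig_mask = np.asarray(nfig_mask, bool) & eligible

    iso_af = iso_cohort.cohort_af
    iso_pos = np.nan_to_num(iso_af) > 0
    iso_fold = np.minimum(np.nan_to_num(iso_af), 1.0 - np.nan_to_num(iso_af))

    gt_ref = np.where(ref_cohort.gt == MISSING, 0, ref_cohort.gt).astype(np.float64)
    called = (ref_cohort.gt != MISSING).astype(np.float64)
    n_ref = ref_cohort.n_samples

    iso_shift, ref_shift = [], []
    n_dropped = 0
    done = 0
    while done < n_reps:
        b = min(chunk, n_reps - done)
        picks = rng.integers(0, n_ref, size=(b, subset_size))
        w = np.zeros((b, n_ref))
        for r in range(b):  # tally with-replacement picks into weights
            np.add.at(w[r], picks[r], 1.0)
        ac = w @ gt_ref
        an = 2.0 * (w @ called)
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(an > 0, ac / np.maximum(an, 1), 0.0)
        fold = np.minimum(af, 1.0 - af)
        qual = (ac > 0) & iso_pos[None, :]
        q_reg = qual & region_mask[None, :]
        q_nfig = qual & nfig_mask[None, :]
        n_reg = q_reg.sum(axis=1)
        n_nfig = q_nfig.sum(axis=1)
        ok = (n_reg > 0) & (n_nfig > 0)
        n_dropped += int((~ok).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            iso_nfig = (iso_fold[None, :] * q_nfig).sum(axis=1) / np.maximum(n_nfig, 1)
            iso_reg = (iso_fold[None, :] * q_reg).sum(axis=1) / np.maximum(n_reg, 1)
            ref_nfig = (fold * q_nfig).sum(axis=1) / np.maximum(n_nfig, 1)
            ref_reg = (fold * q_reg).sum(axis=1) / np.maximum(n_reg, 1)
        iso_shift.extend((iso_nfig - iso_reg)[ok])
        ref_shift.extend((ref_nfig - ref_reg)[ok])
        done += b
    if n_dropped:
        logger.info("asb_test(%s): %d replicate(s) without qualifying sites dropped",
                    region_label, n_dropped)
    iso_arr = np.asarray(iso_shift)
    ref_arr = np.asarray(ref_shift)
    if iso_arr.size == 0:
        raise ValueError("every ASB replicate was dropped; no qualifying sites")
    p = wilcoxon_rank_sum(iso_arr, ref_arr, sided="less")
    return AsbResult(region=region_label, iso_shifts=iso_arr,
                     ref_shifts=ref_arr, p_value=p, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Fisher enrichment against the panel


@dataclass
class EnrichmentRecord:
    site: VariantSite
    cohort_ac: int
    cohort_an: int
    baseline_ac: int
    baseline_an: int
    fisher_p: float
    significant: bool


def fisher_enrichment(site: VariantSite, cohort_ac: int, cohort_an: int,
                      panel: PanelRecord, coverage30_individuals: int,
                      family_size: int) -> EnrichmentRecord:
    """One-sided Fisher's exact enrichment of a variant over the panel.

    Baseline counts are the panel POPMAX AC/AN; panel-absent variants
    use AC = 0 with AN = 2 x (individuals covered >= 30x at the
    position).  Significance threshold is 0.05 / ``family_size``.
    """
    if panel.present_in_panel:
        base_ac, base_an = panel.popmax_ac, panel.popmax_an
    else:
        base_ac, base_an = 0, 2 * coverage30_individuals
    if base_an == 0:
        raise ValueError("baseline AN is zero")
    table = [[cohort_ac, cohort_an - cohort_ac], [base_ac, base_an - base_ac]]
    _, p = stats.fisher_exact(table, alternative="greater")
    return EnrichmentRecord(
        site=site, cohort_ac=cohort_ac, cohort_an=cohort_an,
        baseline_ac=base_ac, baseline_an=base_an, fisher_p=float(p),
        significant=bool(p <= 0.05 / family_size),
    )


def functional_exonic_filter(sites: list[VariantSite], cohort_af: np.ndarray,
                             other_af: np.ndarray, panel_records: list[PanelRecord],
                             constraint: "pd.DataFrame") -> np.ndarray:
    """Candidate mask for enriched, predicted-functional exonic variants.

    Keeps sites more frequent in the focal cohort than in the other
    cohort and every panel population, with a qualifying consequence;
    missense/inframe additionally need CADD >= 20; nonsense-class
    variants need gene pLI >= 0.9 and missense gene z-score > 0.
    Sites whose gene is absent from the constraint table are excluded
    with a logged count.
    """
    keep = np.zeros(len(sites), dtype=bool)
    n_missing_gene = 0
    for j, site in enumerate(sites):
        if site.consequence not in FUNCTIONAL_CONSEQUENCES:
            continue
        rec = panel_records[j]
        if cohort_af[j] <= other_af[j] or cohort_af[j] <= rec.max_population_af:
            continue
        if site.consequence in ("missense", "inframe_insertion", "inframe_deletion"):
            if site.cadd is None or site.cadd < CADD_LOF_THRESHOLD:
                continue
        if site.gene_id is None or site.gene_id not in constraint.index:
            n_missing_gene += 1
            continue
        row = constraint.loc[site.gene_id]
        if site.consequence in NONSENSE_CLASS and row["pli"] < 0.9:
            continue
        if site.consequence == "missense" and row["mis_z"] <= 0:
            continue
        keep[j] = True
    if n_missing_gene:
        logger.info("functional_exonic_filter: %d site(s) lacking gene "
                    "constraint excluded", n_missing_gene)
    return keep
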