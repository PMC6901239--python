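"""End-to-end calibration and recovery studies on synthetic cohorts.

These functions wire the simulator into the downstream statistics and
measure operating characteristics: power and type-I behaviour of the
bootstrap load comparison, directional recovery of the Tajima's D
contrast, planted-tract ROH recovery, and calibration/power of the
allelic shift bias test.  They exist so that tests and the
reproduction script exercise exactly the same pipelines.

Null datasets draw both cohorts from the same simulated lineage, so
the two samples are exchangeable by construction; effect datasets use
the two-lineage founder-effect demography.
"""

from __future__ import annotations

import numpy as np

from .compare import bootstrap_compare, per_individual_counts
from .core import CohortGenotypes
from .popgen import (
    aggregate_tajima,
    call_roh,
    subset_aggregate_tajima,
    windowed_tajima,
)
from .selection import asb_test
from .simulate import SimConfig, sample_genotypes, simulate_dataset

GENE_REGIONS = ("five_utr", "exon", "intron", "three_utr", "ncrna", "non_coding")


def small_config(seed: int, **overrides) -> SimConfig:
    """Desk-scale study conditions for repeated-dataset calibrations."""
    base = dict(
        n_sites=6000, genome_length=6_000_000, n_iso=50, n_cosmo=200,
        panel_diploids=4000, N_cosmo=8000, N_iso=800, bottleneck_size=120,
        bottleneck_generations=10, g_split=60, seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def panel_absent_mask(cohort: CohortGenotypes, panel: dict) -> np.ndarray:
    """Ultra-rare candidates: carried in the cohort, absent from the panel."""
    absent = np.array([s.key not in panel for s in cohort.sites])
    return absent & (cohort.cohort_ac > 0)


def sharing_masks(cohort: CohortGenotypes, ultra: np.ndarray):
    """(singleton, doubleton_plus) subdivision of an ultra-rare mask."""
    carriers = (cohort.gt > 0).sum(axis=0)
    return ultra & (carriers == 1), ultra & (carriers >= 2)


def _null_cohorts(config: SimConfig, rng: np.random.Generator):
    """Two exchangeable cohorts sampled from one simulated lineage."""
    ds = simulate_dataset(config)
    positions = ds.cohort_iso.positions()
    iso, _ = sample_genotypes(
        ds.freqs.cosmo, config.n_iso, F=0.0, seed=rng, positions=positions,
        genome_length=config.genome_length, sites=ds.cohort_iso.sites,
        sample_prefix="NIS")
    ref, _ = sample_genotypes(
        ds.freqs.cosmo, config.n_cosmo, F=0.0, seed=rng, positions=positions,
        genome_length=config.genome_length, sites=ds.cohort_cosmo.sites,
        sample_prefix="NRF")
    return iso, ref, ds.panel


def load_comparison_verdicts(n_datasets: int, seed: int, effect: bool,
                             n_subsets: int = 2000, alpha: float = 5e-3) -> np.ndarray:
    """Bootstrap verdicts for the shared (doubleton-plus) ultra-rare class.

    ``effect=True`` uses the founder-effect demography (isolate through
    a bottleneck); ``effect=False`` draws both cohorts from the same
    lineage, an exchangeable null.
    """
    rng = np.random.default_rng(seed)
    verdicts = np.zeros(n_datasets, dtype=bool)
    for d in range(n_datasets):
        cfg = small_config(seed=int(rng.integers(2**31)))
        if effect:
            ds = simulate_dataset(cfg)
            iso, ref, panel = ds.cohort_iso, ds.cohort_cosmo, ds.panel
        else:
            iso, ref, panel = _null_cohorts(cfg, rng)
        _, iso_db = sharing_masks(iso, panel_absent_mask(iso, panel))
        _, ref_db = sharing_masks(ref, panel_absent_mask(ref, panel))
        res = bootstrap_compare(
            per_individual_counts(iso, iso_db),
            per_individual_counts(ref, ref_db),
            n_subsets=n_subsets, alpha=alpha,
            seed=np.random.default_rng(int(rng.integers(2**31))),
        )
        verdicts[d] = res.verdict
    return verdicts


def tajima_region_shifts(seed: int, n_subsets: int = 30) -> dict:
    """Isolate-minus-reference median Tajima's D per functional region.

    Known (panel-present) SNPs only.  The isolate median aggregates all
    windows; the reference median aggregates window medians over
    repeated size-matched subsets, as in the main framework.
    """
    cfg = SimConfig(n_sites=40_000, genome_length=20_000_000, seed=seed)
    ds = simulate_dataset(cfg)
    known = np.array([s.key in ds.panel for s in ds.cohort_iso.sites])
    labels = ds.region_labels
    gene_any = (labels[["five_utr", "exon", "intron", "three_utr", "ncrna"]]
                .to_numpy().any(axis=1))
    rng = np.random.default_rng(seed + 1)
    shifts = {}
    for region in GENE_REGIONS:
        if region == "non_coding":
            in_region = ~gene_any
        else:
            in_region = labels[region].to_numpy()
        mask = known & in_region
        iso_agg = aggregate_tajima(windowed_tajima(ds.cohort_iso, site_mask=mask))
        ref_agg = subset_aggregate_tajima(
            ds.cohort_cosmo, n_subsets=n_subsets, subset_size=cfg.n_iso,
            seed=rng, site_mask=mask)
        shifts[region] = {
            "iso_median": iso_agg["median"],
            "ref_median": ref_agg["median"],
            "shift": iso_agg["median"] - ref_agg["median"],
        }
    return shifts


def _interval_overlap(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def roh_recovery(seed: int, n_samples_checked: int = 10,
                 min_tract_bp: float = 1e6) -> dict:
    """Fraction of planted autozygous tract length recovered by the caller.

    Only planted tracts of at least ``min_tract_bp`` enter the truth
    set (very short tracts carry too few markers to be callable).
    """
    cfg = SimConfig(seed=seed, F_iso=0.08)
    ds = simulate_dataset(cfg)
    cohort = ds.cohort_iso
    af = np.nan_to_num(cohort.cohort_af)
    pos = cohort.positions()
    truth_total = called_overlap = 0
    for sid in cohort.sample_ids[:n_samples_checked]:
        i = cohort.sample_ids.index(sid)
        truth = [(s, e) for s, e in ds.iso_tracts[sid] if e - s >= min_tract_bp]
        if not truth:
            continue
        segs = call_roh(cohort.gt[i], pos, af, gq=cohort.gq[i], sample_id=sid)
        called = [(s.start - 1, s.end) for s in segs]
        truth_total += sum(e - s for s, e in truth)
        called_overlap += _interval_overlap(truth, called)
    return {
        "truth_bp": truth_total,
        "recovered_bp": called_overlap,
        "recovered_fraction": called_overlap / truth_total if truth_total else float("nan"),
    }


def _asb_inputs(iso: CohortGenotypes, ref: CohortGenotypes, panel: dict):
    """Eligibility and region masks for the exonic non-synonymous ASB test."""
    sites = iso.sites
    maf_nfe = np.array([
        panel[s.key].maf_nfe if s.key in panel else np.nan for s in sites
    ])
    eligible = np.isfinite(maf_nfe) & (maf_nfe <= 0.01) & iso.is_snp_mask()
    nonsyn = np.array([
        s.consequence in ("stop_gained", "splice_donor", "splice_acceptor",
                          "missense", "start_lost", "stop_lost")
        for s in sites
    ])
    return eligible, nonsyn


def asb_power_config(seed: int, relaxation_r: float) -> SimConfig:
    """Relaxation-only contrast: identical demography, selection scaled by r.

    Both lineages share size and history; only the isolate's selection
    coefficients are multiplied by ``relaxation_r``, so any rejection
    reflects the constraint contrast alone rather than drift.
    """
    return SimConfig(
        n_sites=20_000, genome_length=20_000_000, n_iso=80, n_cosmo=320,
        panel_diploids=4000, N_cosmo=8000, N_iso=8000, bottleneck_size=8000,
        bottleneck_generations=1, g_split=60, F_iso=0.0,
        relaxation_r=relaxation_r, seed=seed,
    )


def asb_rejection_rate(n_datasets: int, seed: int, relaxation_r: float | None,
                       n_reps: int = 400, alpha: float = 0.05) -> float:
    """ASB rejection rate over simulated datasets.

    ``relaxation_r=None`` runs the exchangeable null (both cohorts from
    one lineage); otherwise the relaxation-only contrast of
    :func:`asb_power_config` with the given factor in the isolate.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for d in range(n_datasets):
        if relaxation_r is None:
            cfg = small_config(seed=int(rng.integers(2**31)))
            iso, ref, panel = _null_cohorts(cfg, rng)
        else:
            cfg = asb_power_config(seed=int(rng.integers(2**31)),
                                   relaxation_r=relaxation_r)
            ds = simulate_dataset(cfg)
            iso, ref, panel = ds.cohort_iso, ds.cohort_cosmo, ds.panel
        eligible, nonsyn = _asb_inputs(iso, ref, panel)
        exonic = np.array([s.consequence != "none" for s in iso.sites])
        nfig_mask = _nfig_site_mask(iso, cfg)
        res = asb_test(iso, ref, eligible, region_mask=exonic & nonsyn,
                       nfig_mask=nfig_mask, n_reps=n_reps,
                       seed=np.random.default_rng(int(rng.integers(2**31))),
                       region_label="exon_nonsyn")
        rejections += res.p_value <= alpha
    return rejections / n_datasets


def _nfig_site_mask(cohort: CohortGenotypes, config: SimConfig) -> np.ndarray:
    """Sites in the neutral intergenic baseline, via the dataset catalog."""
    from .simulate import emit_annotation_layout

    layout = emit_annotation_layout(config, np.random.default_rng(config.seed + 1))
    return layout.catalog.contains("nfig", "1", cohort.positions())
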