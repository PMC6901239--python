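"""Forward-time simulator for an isolate/cosmopolitan cohort contrast.

Two present-day cohorts descend from a shared ancestral population whose
allele-frequency spectrum is neutral-like (density proportional to 1/x).
The cosmopolitan lineage drifts at a large effective size; the isolate
lineage passes through a founding bottleneck and then persists at a much
smaller size, so it experiences stronger drift.  Deleterious site
classes evolve with a per-generation transmission penalty (1 - s), and a
relaxation factor r in [0, 1] multiplies s in the isolate, so r < 1
models relaxed purifying selection there.  A large "panel" sample drawn
from the cosmopolitan lineage plays the role of a gnomAD-like reference:
variants the panel happens to sample zero copies of are the ultra-rare
class downstream.

Linkage is ignored except for autozygosity: isolate genotypes are drawn
inside alternating autozygous / outbred tracts so that runs of
homozygosity have realistic contiguity, with the long-run autozygous
fraction equal to the target inbreeding coefficient F.

Everything is deterministic given the config seed, including the
emitted VCF/BED/TSV side files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    CohortGenotypes,
    PanelRecord,
    RegionCatalog,
    VariantSite,
    write_cohort_vcf,
    write_panel_table,
    write_regions,
)

LOF_CONSEQUENCES = ("stop_gained", "splice_donor", "splice_acceptor")


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults are a desk-scale rendition of a founder-effect contrast: a
    20 Mb genome, an isolate founded ~60 generations ago through a
    narrow bottleneck, a four-fold larger cosmopolitan pool, and a
    15,000-diploid panel sampled from the cosmopolitan lineage.
    """

    n_sites: int = 20_000
    genome_length: int = 20_000_000
    spectrum_af_min: float = 1e-3  # lower truncation of the 1/x ancestral spectrum
    N_cosmo: int = 10_000
    N_iso: int = 1_000
    g_split: int = 60
    bottleneck_size: int = 150
    bottleneck_generations: int = 10
    s_del: float = 0.02
    relaxation_r: float = 1.0  # multiplies s_del in the isolate; 1 = no relaxation
    F_iso: float = 0.05
    F_cosmo: float = 0.0
    n_iso: int = 80
    n_cosmo: int = 320
    panel_diploids: int = 15_000
    mean_tract_bp: float = 1.5e6
    bad_site_fraction: float = 0.05  # planted low-quality mixture component
    exon_lof_mis_syn: tuple = (0.08, 0.57, 0.35)
    frac_missense_cadd20: float = 0.30
    dp_mean: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "genome_length", "N_cosmo", "N_iso", "g_split",
                     "bottleneck_size", "bottleneck_generations", "n_iso",
                     "n_cosmo", "panel_diploids"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.relaxation_r <= 1.0:
            raise ValueError("relaxation_r must be in [0, 1]")
        for name in ("F_iso", "F_cosmo"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")


def ancestral_spectrum(n_sites: int, rng: np.random.Generator,
                       af_min: float = 1e-3, af_max: float = 0.5) -> np.ndarray:
    """Draw ancestral AFs from a truncated 1/x density via inverse CDF."""
    u = rng.random(n_sites)
    return af_min * (af_max / af_min) ** u


def wright_fisher(p0: np.ndarray, N: int, generations: int,
                  s: np.ndarray | float, rng: np.random.Generator) -> np.ndarray:
    """Generation-wise binomial drift at diploid size N with selection s.

    Each generation the deleterious allele's transmission probability is
    p(1-s) / (1 - p s), then 2N gametes are drawn binomially.  Fixed and
    lost alleles are retained (absorbing states).
    """
    p = np.asarray(p0, dtype=float).copy()
    s = np.broadcast_to(np.asarray(s, dtype=float), p.shape)
    two_n = 2 * N
    for _ in range(generations):
        p_sel = p * (1.0 - s) / (1.0 - p * s)
        p = rng.binomial(two_n, p_sel) / two_n
    return p


@dataclass
class FrequencyResult:
    ancestral: np.ndarray
    cosmo: np.ndarray
    iso: np.ndarray
    panel_af: np.ndarray
    panel_ac: np.ndarray
    panel_an: int


def simulate_frequencies(config: SimConfig, s_per_site: np.ndarray | None = None,
                         rng: np.random.Generator | None = None) -> FrequencyResult:
    """Ancestral, cosmopolitan, isolate and panel allele frequencies.

    The isolate lineage runs ``bottleneck_generations`` at
    ``bottleneck_size`` then the remainder of ``g_split`` at ``N_iso``;
    the cosmopolitan lineage runs all of ``g_split`` at ``N_cosmo``.
    The panel is a binomial sample of ``2 * panel_diploids`` chromosomes
    from the cosmopolitan lineage frequency.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    anc = ancestral_spectrum(config.n_sites, rng, config.spectrum_af_min)
    s = np.zeros(config.n_sites) if s_per_site is None else np.asarray(s_per_site, float)
    cosmo = wright_fisher(anc, config.N_cosmo, config.g_split, s, rng)
    s_iso = s * config.relaxation_r
    g_post = max(config.g_split - config.bottleneck_generations, 0)
    iso = wright_fisher(anc, config.bottleneck_size, config.bottleneck_generations, s_iso, rng)
    iso = wright_fisher(iso, config.N_iso, g_post, s_iso, rng)
    panel_an = 2 * config.panel_diploids
    panel_ac = rng.binomial(panel_an, cosmo)
    return FrequencyResult(
        ancestral=anc, cosmo=cosmo, iso=iso,
        panel_af=panel_ac / panel_an, panel_ac=panel_ac, panel_an=panel_an,
    )


def _autozygous_tracts(genome_length: int, F: float, mean_tract_bp: float,
                       rng: np.random.Generator) -> list[tuple[int, int]]:
    """Alternating outbred/autozygous segments with autozygous fraction F."""
    if F <= 0:
        return []
    if F >= 1.0:
        return [(0, genome_length)]
    mean_out = mean_tract_bp * (1.0 - F) / F
    tracts = []
    pos = 0
    while pos < genome_length:
        pos += int(rng.exponential(mean_out)) + 1
        if pos >= genome_length:
            break
        end = pos + int(rng.exponential(mean_tract_bp)) + 1
        tracts.append((pos, min(end, genome_length)))
        pos = end
    return tracts


def sample_genotypes(freqs: np.ndarray, n_samples: int, F: float = 0.0,
                     seed=None, positions: np.ndarray | None = None,
                     genome_length: int | None = None,
                     mean_tract_bp: float = 1.5e6, dp_mean: float = 35.0,
                     sites: list[VariantSite] | None = None,
                     sample_prefix: str = "S"):
    """Draw diploid genotypes (plus DP/GQ) at the given site frequencies.

    Outside autozygous tracts genotypes are Hardy-Weinberg draws; inside
    a tract the two alleles are identical by descent, so
    P(hom-alt) = p and P(het) = 0 there.  Marginally over the genome
    P(hom-alt) = p^2 + F p (1 - p) and P(het) = 2 p (1 - p) (1 - F).

    Returns ``(cohort, tracts)`` where ``tracts`` maps sample id to its
    autozygous (start, end) list -- the ground truth for ROH recovery.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.asarray(freqs, dtype=float)
    n_sites = p.size
    if positions is None:
        positions = np.arange(1, n_sites + 1, dtype=np.int64) * 1000
    if genome_length is None:
        genome_length = int(positions[-1]) + 1000 if n_sites else 1000
    if sites is None:
        sites = [VariantSite(chrom="1", pos=int(x), ref="A", alt="G") for x in positions]

    gt = np.empty((n_samples, n_sites), dtype=np.int8)
    sample_ids = [f"{sample_prefix}{i:04d}" for i in range(n_samples)]
    tracts: dict[str, list[tuple[int, int]]] = {}
    pos0 = positions - 1
    for i, sid in enumerate(sample_ids):
        a1 = rng.random(n_sites) < p
        a2 = rng.random(n_sites) < p
        row = a1.astype(np.int8) + a2.astype(np.int8)
        sample_tracts = _autozygous_tracts(genome_length, F, mean_tract_bp, rng)
        if sample_tracts:
            auto = np.zeros(n_sites, dtype=bool)
            for s, e in sample_tracts:
                auto |= (pos0 >= s) & (pos0 < e)
            row[auto] = 2 * a1[auto].astype(np.int8)
        gt[i] = row
        tracts[sid] = sample_tracts

    dp = rng.poisson(dp_mean, size=gt.shape).astype(np.int32)
    np.clip(dp, 1, None, out=dp)
    gq = np.clip(rng.normal(65, 15, size=gt.shape), 2, 99).astype(np.int32)
    cohort = CohortGenotypes(sample_ids=sample_ids, sites=sites, gt=gt, dp=dp, gq=gq)
    return cohort, tracts


# ---------------------------------------------------------------------------
# Annotation layout


@dataclass
class AnnotationLayout:
    catalog: RegionCatalog
    gene_spans: list[tuple[str, int, int]]  # (gene_id, start0, end0)
    gene_constraint: "pd.DataFrame"


def emit_annotation_layout(config: SimConfig, rng: np.random.Generator | None = None) -> AnnotationLayout:
    """Tile the synthetic genome into genes, ncRNA, chromatin states and masks.

    Genes repeat every 20 kb as 5'UTR / exon / intron / exon / intron /
    exon / 3'UTR; one gene in ten carries a downstream ncRNA block.  Two
    pseudo cell types get chromatin-state tracks: promoters upstream of
    gene starts, transcribed over gene bodies, enhancers and insulators
    sprinkled in intergenic space, heterochromatin over what remains.
    NFIG is the mappable non-coding space minus every chromatin-state
    annotation other than heterochromatin.
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    L = config.genome_length
    chrom = "1"
    gene_pitch = 20_000
    utr5, ex, intr, utr3 = 300, 400, 1500, 600

    five_utr, exon, intron, three_utr, ncrna = [], [], [], [], []
    gene_spans = []
    promoters, transcribed = [], []
    g = 0
    for start in range(2_000, L - gene_pitch, gene_pitch):
        gid = f"G{g:04d}"
        g += 1
        p = start
        five_utr.append((p, p + utr5)); p += utr5
        exon.append((p, p + ex)); p += ex
        intron.append((p, p + intr)); p += intr
        exon.append((p, p + ex)); p += ex
        intron.append((p, p + intr)); p += intr
        exon.append((p, p + ex)); p += ex
        three_utr.append((p, p + utr3)); p += utr3
        gene_spans.append((gid, start, p))
        promoters.append((max(start - 1000, 0), start))
        transcribed.append((start, p))
        if g % 10 == 0:
            ncrna.append((p + 2000, p + 3000))

    catalog = RegionCatalog()
    # mappability: everything except a masked 40 kb block every 2 Mb
    masked = [(m, m + 40_000) for m in range(1_000_000, L, 2_000_000)]
    mappable, cur = [], 0
    for s, e in masked:
        mappable.append((cur, s)); cur = e
    mappable.append((cur, L))
    catalog.add("mappable", {chrom: mappable})
    catalog.add("five_utr", {chrom: five_utr})
    catalog.add("exon", {chrom: exon})
    catalog.add("intron", {chrom: intron})
    catalog.add("three_utr", {chrom: three_utr})
    catalog.add("ncrna", {chrom: ncrna})
    catalog.finalize_non_coding()

    # chromatin states per pseudo cell type; jitter makes the types differ
    for cell in ("cellA", "cellB"):
        jit = lambda iv: [
            (max(0, s + int(rng.integers(-200, 201))), e + int(rng.integers(-200, 201)))
            for s, e in iv
        ]
        prom = jit(promoters)
        trans = jit(transcribed)
        n_enh = max(L // 100_000, 1)
        enh_starts = rng.integers(0, L - 2000, size=n_enh)
        enh = [(int(s), int(s) + 1500) for s in np.sort(enh_starts)]
        ins = [(int(s), int(s) + 800)
               for s in np.sort(rng.integers(0, L - 1000, size=max(n_enh // 4, 1)))]
        rep = [(int(s), int(s) + 3000)
               for s in np.sort(rng.integers(0, L - 4000, size=max(n_enh // 3, 1)))]
        catalog.add(f"promoter:{cell}", {chrom: prom})
        catalog.add(f"enhancer:{cell}", {chrom: enh})
        catalog.add(f"insulator:{cell}", {chrom: ins})
        catalog.add(f"transcribed:{cell}", {chrom: trans})
        catalog.add(f"repressed:{cell}", {chrom: rep})
        functional = merge_all(catalog, [f"{st}:{cell}" for st in
                                         ("promoter", "enhancer", "insulator",
                                          "transcribed", "repressed")], chrom)
        catalog.add_complement(f"heterochromatin:{cell}", "mappable",
                               _tmp_names(catalog, functional, chrom, cell))
    # NFIG: mappable non-coding minus all non-heterochromatin chromatin states
    non_het = [n for n in catalog.chromatin_labels() if not n.startswith("heterochromatin")]
    catalog.add_complement("nfig", "non_coding", non_het)

    pli = rng.beta(0.25, 0.25, size=len(gene_spans))
    mis_z = rng.normal(1.0, 1.5, size=len(gene_spans))
    constraint = pd.DataFrame(
        {"gene_id": [gid for gid, _, _ in gene_spans], "pli": pli, "mis_z": mis_z}
    ).set_index("gene_id")
    return AnnotationLayout(catalog=catalog, gene_spans=gene_spans,
                           gene_constraint=constraint)


def merge_all(catalog: RegionCatalog, names: list[str], chrom: str) -> np.ndarray:
    from .core import merge_intervals
    arrs = [catalog.intervals(n).get(chrom) for n in names]
    arrs = [a for a in arrs if a is not None and len(a)]
    if not arrs:
        return np.empty((0, 2), dtype=np.int64)
    return merge_intervals(np.concatenate(arrs))


def _tmp_names(catalog: RegionCatalog, merged: np.ndarray, chrom: str, cell: str) -> list[str]:
    name = f"_functional:{cell}"
    catalog.add(name, {chrom: merged})
    return [name]


# ---------------------------------------------------------------------------
# Whole-dataset orchestration


@dataclass
class SimulatedDataset:
    config: SimConfig
    cohort_iso: CohortGenotypes
    cohort_cosmo: CohortGenotypes
    panel: dict
    catalog: RegionCatalog
    layout: AnnotationLayout
    freqs: FrequencyResult
    s_per_site: np.ndarray
    bad_sites: np.ndarray  # planted low-quality component (bool per site)
    iso_tracts: dict
    region_labels: "pd.DataFrame"  # per-site gene-structure membership


def _site_positions(config: SimConfig, catalog: RegionCatalog,
                    rng: np.random.Generator) -> np.ndarray:
    """Distinct sorted 1-based positions uniform over the mappable genome."""
    ivals = catalog.intervals("mappable")["1"]
    lens = ivals[:, 1] - ivals[:, 0]
    cum = np.concatenate([[0], np.cumsum(lens)])
    total = int(cum[-1])
    draws = np.unique(rng.integers(0, total, size=config.n_sites * 2))
    rng.shuffle(draws)
    draws = np.sort(draws[: config.n_sites])
    idx = np.searchsorted(cum, draws, side="right") - 1
    pos0 = ivals[idx, 0] + (draws - cum[idx])
    return np.sort(pos0) + 1  # 1-based


def _draw_qc_annotations(n_sites: int, bad: np.ndarray, rng: np.random.Generator) -> dict:
    """Two-component mixture of GATK-style site QC parameters.

    The "bad" component sits >= 3 s.d. into each parameter's failing
    tail so a 5%-tail threshold derivation has a real signal to find.
    """
    good = ~bad
    out = {}
    components = {  # param: ((good_mu, good_sd), (bad_mu, bad_sd))
        "QD": ((20.0, 4.0), (3.0, 1.5)),
        "MQ": ((60.0, 2.0), (40.0, 4.0)),
        "FS": ((3.0, 2.0), (25.0, 5.0)),
        "SOR": ((1.2, 0.3), (3.5, 0.5)),
        "MQRankSum": ((0.0, 1.0), (-5.0, 1.0)),
        "ReadPosRankSum": ((0.0, 1.0), (-5.0, 1.0)),
    }
    for name, ((gm, gs), (bm, bs)) in components.items():
        v = np.empty(n_sites)
        v[good] = rng.normal(gm, gs, good.sum())
        v[bad] = rng.normal(bm, bs, bad.sum())
        if name in ("QD", "FS"):
            np.clip(v, 0.0, None, out=v)
        out[name] = v
    return out


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate the full study: two cohorts, panel, regions, annotations."""
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    layout = emit_annotation_layout(config, np.random.default_rng(config.seed + 1))
    catalog = layout.catalog
    positions = _site_positions(config, catalog, rng)
    n = positions.size

    # region membership and functional annotation of each site
    in_cat = {c: catalog.contains(c, "1", positions)
              for c in ("five_utr", "exon", "intron", "three_utr", "ncrna")}
    exonic = in_cat["exon"]
    promoter_any = np.zeros(n, dtype=bool)
    for name in catalog.chromatin_labels():
        if name.startswith("promoter:"):
            promoter_any |= catalog.contains(name, "1", positions)

    consequence = np.array(["none"] * n, dtype=object)
    cadd = np.full(n, np.nan)
    gene_id = np.array([None] * n, dtype=object)
    gene_starts = np.array([s for _, s, _ in layout.gene_spans])
    gene_ends = np.array([e for _, _, e in layout.gene_spans])
    gene_ids = [gid for gid, _, _ in layout.gene_spans]
    gidx = np.searchsorted(gene_starts, positions - 1, side="right") - 1
    in_gene = (gidx >= 0) & ((positions - 1) < gene_ends[np.maximum(gidx, 0)])
    for i in np.flatnonzero(in_gene):
        gene_id[i] = gene_ids[gidx[i]]

    p_lof, p_mis, p_syn = config.exon_lof_mis_syn
    ex_idx = np.flatnonzero(exonic)
    draws = rng.random(ex_idx.size)
    lof_mask = draws < p_lof
    mis_mask = (draws >= p_lof) & (draws < p_lof + p_mis)
    syn_mask = draws >= p_lof + p_mis
    consequence[ex_idx[lof_mask]] = rng.choice(LOF_CONSEQUENCES, size=lof_mask.sum())
    consequence[ex_idx[mis_mask]] = "missense"
    consequence[ex_idx[syn_mask]] = "synonymous"
    cadd[ex_idx[lof_mask]] = rng.uniform(25, 50, lof_mask.sum())
    high = rng.random(mis_mask.sum()) < config.frac_missense_cadd20
    mis_cadd = np.where(high, rng.uniform(20, 40, mis_mask.sum()),
                        rng.uniform(0, 20, mis_mask.sum()))
    cadd[ex_idx[mis_mask]] = mis_cadd
    cadd[ex_idx[syn_mask]] = rng.uniform(0, 10, syn_mask.sum())
    # non-exonic sites also carry a CADD score; promoters reach higher values
    other = ~exonic
    cadd[other] = rng.uniform(0, 10, other.sum())
    prom_nonex = promoter_any & ~exonic
    cadd[prom_nonex] = rng.uniform(0, 25, prom_nonex.sum())

    # per-site selection coefficients
    s = np.zeros(n)
    is_lof = np.isin(consequence, LOF_CONSEQUENCES)
    is_mis = consequence == "missense"
    s[is_lof] = config.s_del
    s[is_mis & (cadd >= 20)] = config.s_del
    s[is_mis & (cadd < 20)] = config.s_del / 4
    s[prom_nonex & (cadd >= 10)] = config.s_del / 2

    freqs = simulate_frequencies(config, s_per_site=s, rng=rng)

    bad = rng.random(n) < config.bad_site_fraction
    qc = _draw_qc_annotations(n, bad, rng)

    def make_sites():
        out = []
        for i in range(n):
            out.append(VariantSite(
                chrom="1", pos=int(positions[i]), ref="A", alt="G",
                site_annotations={k: float(qc[k][i]) for k in qc},
                consequence=str(consequence[i]),
                cadd=None if np.isnan(cadd[i]) else float(cadd[i]),
                gene_id=gene_id[i],
            ))
        return out

    cohort_iso, iso_tracts = sample_genotypes(
        freqs.iso, config.n_iso, F=config.F_iso, seed=rng, positions=positions,
        genome_length=config.genome_length, mean_tract_bp=config.mean_tract_bp,
        dp_mean=config.dp_mean, sites=make_sites(), sample_prefix="ISO",
    )
    cohort_cosmo, _ = sample_genotypes(
        freqs.cosmo, config.n_cosmo, F=config.F_cosmo, seed=rng, positions=positions,
        genome_length=config.genome_length, mean_tract_bp=config.mean_tract_bp,
        dp_mean=config.dp_mean, sites=make_sites(), sample_prefix="COS",
    )

    panel = {}
    nfe_an = freqs.panel_an // 2  # NFE-like subpopulation is half the panel
    nfe_ac = rng.binomial(freqs.panel_ac, nfe_an / freqs.panel_an)
    other_ac = freqs.panel_ac - nfe_ac
    for i, site in enumerate(cohort_iso.sites):
        ac = int(freqs.panel_ac[i])
        if ac == 0:
            continue
        af_nfe = nfe_ac[i] / nfe_an
        af_other = other_ac[i] / (freqs.panel_an - nfe_an)
        pop_af = {"nfe": af_nfe, "oth": af_other}
        popmax_pop = max(pop_af, key=pop_af.get)
        popmax_an = nfe_an if popmax_pop == "nfe" else freqs.panel_an - nfe_an
        panel[site.key] = PanelRecord(
            present_in_panel=True,
            af_by_population=pop_af,
            maf_nfe=min(af_nfe, 1.0 - af_nfe),
            popmax_ac=int(round(pop_af[popmax_pop] * popmax_an)),
            popmax_an=int(popmax_an),
            panel_filter_pass=True,
        )

    region_labels = pd.DataFrame(
        {c: in_cat[c] for c in in_cat} | {"promoter_any": promoter_any,
                                          "nfig": catalog.contains("nfig", "1", positions)}
    )
    return SimulatedDataset(
        config=config, cohort_iso=cohort_iso, cohort_cosmo=cohort_cosmo,
        panel=panel, catalog=catalog, layout=layout, freqs=freqs,
        s_per_site=s, bad_sites=bad, iso_tracts=iso_tracts,
        region_labels=region_labels,
    )


def write_dataset(ds: SimulatedDataset, out_dir) -> None:
    """Emit cohort VCFs, panel TSV, BED tracks, annotation TSVs, manifest."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort_vcf(ds.cohort_iso, out / "isolate.vcf")
    write_cohort_vcf(ds.cohort_cosmo, out / "cosmopolitan.vcf")
    write_panel_table(ds.panel, out / "panel.tsv")
    for name in ds.catalog.names():
        if name.startswith("_"):
            continue
        write_regions(ds.catalog, name, out / f"{name.replace(':', '_')}.bed")
    rows = [
        {"chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt,
         "consequence": s.consequence, "cadd": s.cadd, "gene_id": s.gene_id}
        for s in ds.cohort_iso.sites
    ]
    pd.DataFrame(rows).to_csv(out / "consequences.tsv", sep="\t", index=False)
    ds.layout.gene_constraint.reset_index().to_csv(
        out / "gene_constraint.tsv", sep="\t", index=False)
    manifest = dataclasses.asdict(ds.config)
    manifest["exon_lof_mis_syn"] = list(manifest["exon_lof_mis_syn"])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
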