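"""Domain types and file IO for cohort variant data.

The package works on three kinds of inputs: multi-sample VCFs holding
biallelic, decomposed SNP/INDEL calls with per-genotype GT/DP/GQ; a
reference-panel frequency table (gnomAD-genomes-like) with per-population
allele frequencies, POPMAX counts and a filter status; and BED interval
tracks describing gene structure, chromatin states, mappability and the
neutral intergenic baseline.

Coordinate conventions
----------------------
Variant positions are 1-based (VCF); intervals are 0-based half-open
(BED).  A variant at 1-based position ``pos`` overlaps interval
``[start, end)`` iff ``start < pos <= end``, equivalently
``start <= pos - 1 < end``.  Strand is ignored throughout: every region
test is purely positional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # genotype code for a missing diploid call

#: maximum REF/ALT length difference accepted for an INDEL (half a read length)
MAX_INDEL_LEN = 75

HARD_FILTER_PARAMS = ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum")

CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "splice_acceptor",
        "splice_donor",
        "start_lost",
        "stop_lost",
        "missense",
        "synonymous",
        "frameshift",
        "inframe_insertion",
        "inframe_deletion",
        "other",
        "none",
    }
)

GENE_STRUCTURE_CATEGORIES = ("five_utr", "exon", "intron", "three_utr", "ncrna")


class VcfParseError(ValueError):
    """Raised when a VCF-like record cannot be interpreted."""


@dataclass
class VariantSite:
    """One biallelic variant site with its QC and functional annotations.

    ``site_annotations`` carries the GATK-style hard-filter parameters
    (QD, MQ, FS, SOR, MQRankSum, ReadPosRankSum); any of them may be
    absent, which downstream filters treat as "not evaluated".
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    site_annotations: dict = field(default_factory=dict)
    consequence: str = "none"
    cadd: float | None = None
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("REF and ALT must be non-empty")
        if abs(len(self.ref) - len(self.alt)) > MAX_INDEL_LEN:
            raise ValueError(
                f"indel length difference exceeds {MAX_INDEL_LEN} bp at "
                f"{self.chrom}:{self.pos}"
            )
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CohortGenotypes:
    """Sample-by-site genotype matrix with per-genotype depth and quality.

    ``gt`` holds the count of alternate alleles per diploid sample
    (0, 1, 2) with :data:`MISSING` (-1) for no-calls.  AC/AN/AF are always
    derived from the matrix, never stored.
    """

    sample_ids: list[str]
    sites: list[VariantSite]
    gt: np.ndarray  # (n_samples, n_sites) int8
    dp: np.ndarray  # (n_samples, n_sites) int32
    gq: np.ndarray  # (n_samples, n_sites) int32

    def __post_init__(self) -> None:
        shape = (len(self.sample_ids), len(self.sites))
        for name in ("gt", "dp", "gq"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {shape}"
                )
            setattr(self, name, arr)
        bad = ~np.isin(self.gt, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, missing}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def cohort_ac(self) -> np.ndarray:
        """Alternate allele count per site over non-missing genotypes."""
        return np.where(self.gt == MISSING, 0, self.gt).sum(axis=0)

    @property
    def cohort_an(self) -> np.ndarray:
        """Called allele number per site (2 x non-missing samples)."""
        return 2 * (self.gt != MISSING).sum(axis=0)

    @property
    def cohort_af(self) -> np.ndarray:
        """AC/AN per site; NaN where no genotype was called."""
        an = self.cohort_an
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, self.cohort_ac / np.maximum(an, 1), np.nan)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CohortGenotypes":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing}")
        rows = [index[s] for s in sample_ids]
        return CohortGenotypes(
            sample_ids=list(sample_ids),
            sites=self.sites,
            gt=self.gt[rows],
            dp=self.dp[rows],
            gq=self.gq[rows],
        )

    def subset_sites(self, mask_or_index) -> "CohortGenotypes":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CohortGenotypes(
            sample_ids=self.sample_ids,
            sites=[self.sites[i] for i in idx],
            gt=self.gt[:, idx],
            dp=self.dp[:, idx],
            gq=self.gq[:, idx],
        )

    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def is_snp_mask(self) -> np.ndarray:
        return np.array([s.is_snp for s in self.sites], dtype=bool)


@dataclass
class PanelRecord:
    """Reference-panel frequency summary for one variant.

    ``maf_nfe`` is the folded (minor) allele frequency in the panel's
    Non-Finnish-European-like population and drives the frequency-class
    boundaries; POPMAX AC/AN come from the population where the variant
    is most prevalent and serve as the Fisher-enrichment baseline.
    """

    present_in_panel: bool
    af_by_population: dict = field(default_factory=dict)
    maf_nfe: float = 0.0
    popmax_ac: int = 0
    popmax_an: int = 0
    panel_filter_pass: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_nfe <= 0.5:
            raise ValueError(f"maf_nfe must be folded (in [0, 0.5]): {self.maf_nfe}")
        if self.popmax_ac > self.popmax_an:
            raise ValueError("popmax_ac cannot exceed popmax_an")

    @property
    def max_population_af(self) -> float:
        if not self.af_by_population:
            return 0.0
        return max(self.af_by_population.values())


ABSENT_PANEL_RECORD = PanelRecord(present_in_panel=False)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    """Sort and merge overlapping/adjacent half-open intervals."""
    arr = np.asarray(list(intervals), dtype=np.int64).reshape(-1, 2)
    if len(arr) == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


class RegionCatalog:
    """Named sets of genomic intervals (0-based, half-open, merged).

    Gene-structure categories (5'UTR, exon, intron, 3'UTR, ncRNA) are
    non-exclusive: a position may belong to several.  ``non_coding`` is
    the mappable complement of their union.  Chromatin-state tracks are
    stored per cell type under names like ``"promoter:cellA"``.
    """

    def __init__(self) -> None:
        self._sets: dict[str, dict[str, np.ndarray]] = {}

    def names(self) -> list[str]:
        return sorted(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def add(self, name: str, intervals_by_chrom: Mapping[str, Iterable[tuple[int, int]]]) -> None:
        merged = {}
        for chrom, ivals in intervals_by_chrom.items():
            arr = merge_intervals(ivals)
            if len(arr):
                if (arr[:, 1] <= arr[:, 0]).any():
                    raise ValueError(f"empty or inverted interval in set {name!r}")
                merged[chrom] = arr
        self._sets[name] = merged

    def intervals(self, name: str) -> dict[str, np.ndarray]:
        return self._sets[name]

    def total_length(self, name: str, unit: str = "bp") -> float:
        """Total (merged) length of a set, in bp or Mb."""
        bp = sum(
            int((arr[:, 1] - arr[:, 0]).sum()) for arr in self._sets[name].values()
        )
        if unit == "bp":
            return float(bp)
        if unit == "Mb":
            return bp / 1e6
        raise ValueError(f"unknown unit {unit!r}")

    def contains(self, name: str, chrom: str, pos: np.ndarray | int) -> np.ndarray | bool:
        """Membership of 1-based position(s) in the named set."""
        scalar = np.isscalar(pos)
        pos0 = np.atleast_1d(np.asarray(pos, dtype=np.int64)) - 1  # to 0-based
        ivals = self._sets[name].get(chrom)
        if ivals is None or len(ivals) == 0:
            out = np.zeros(pos0.shape, dtype=bool)
        else:
            # index of interval whose start is <= pos0 (rightmost)
            idx = np.searchsorted(ivals[:, 0], pos0, side="right") - 1
            ok = idx >= 0
            out = np.zeros(pos0.shape, dtype=bool)
            out[ok] = pos0[ok] < ivals[idx[ok], 1]
        return bool(out[0]) if scalar else out

    def add_complement(self, name: str, universe: str, minus: Sequence[str]) -> None:
        """Define ``name`` = ``universe`` minus the union of ``minus`` sets."""
        result: dict[str, list[tuple[int, int]]] = {}
        for chrom, base in self._sets[universe].items():
            cuts = []
            for m in minus:
                arr = self._sets[m].get(chrom)
                if arr is not None:
                    cuts.append(arr)
            cut = merge_intervals(np.concatenate(cuts)) if cuts else np.empty((0, 2), dtype=np.int64)
            pieces = []
            for s, e in base:
                cur = s
                for cs, ce in cut:
                    if ce <= cur or cs >= e:
                        continue
                    if cs > cur:
                        pieces.append((cur, min(cs, e)))
                    cur = max(cur, ce)
                    if cur >= e:
                        break
                if cur < e:
                    pieces.append((cur, e))
            if pieces:
                result[chrom] = pieces
        self.add(name, result)

    def finalize_non_coding(self) -> None:
        """non_coding = mappable minus the five gene-structure categories."""
        present = [c for c in GENE_STRUCTURE_CATEGORIES if c in self._sets]
        self.add_complement("non_coding", "mappable", present)

    def chromatin_labels(self) -> list[str]:
        return [n for n in self.names() if ":" in n]


def assign_regions(site: VariantSite, catalog: RegionCatalog) -> set[str]:
    """All region labels overlapping one variant position.

    Gene-structure membership is non-exclusive (a 3'UTR of one gene may
    be a 5'UTR of another); ``non_coding`` is returned iff none of the
    five gene categories overlap.  Chromatin-state labels are reported
    per cell type.  A site outside the mappable mask is an error: such
    sites must be removed upstream.
    """
    if "mappable" in catalog and not catalog.contains("mappable", site.chrom, site.pos):
        raise ValueError(f"site {site.chrom}:{site.pos} outside the mappable mask")
    labels: set[str] = set()
    for cat in GENE_STRUCTURE_CATEGORIES:
        if cat in catalog and catalog.contains(cat, site.chrom, site.pos):
            labels.add(cat)
    if not labels:
        labels.add("non_coding")
    for name in catalog.chromatin_labels():
        if catalog.contains(name, site.chrom, site.pos):
            labels.add(name)
    if "nfig" in catalog and catalog.contains("nfig", site.chrom, site.pos):
        labels.add("nfig")
    return labels


# ---------------------------------------------------------------------------
# VCF IO


def read_cohort_vcf(path, sample_subset: Sequence[str] | None = None) -> CohortGenotypes:
    """Read a decomposed biallelic multi-sample VCF into a genotype matrix.

    Multi-allelic records and indels longer than 75 bp are skipped with a
    single summary warning.  Requires GT; DP and GQ default to -1 where
    absent.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    all_samples = list(vcf.samples)
    if sample_subset is not None:
        unknown = [s for s in sample_subset if s not in all_samples]
        if unknown:
            raise KeyError(f"unknown sample id(s): {unknown}")
        keep = [all_samples.index(s) for s in sample_subset]
        samples = list(sample_subset)
    else:
        keep = list(range(len(all_samples)))
        samples = all_samples

    sites: list[VariantSite] = []
    gt_cols, dp_cols, gq_cols = [], [], []
    n_rejected = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_rejected += 1
            continue
        if abs(len(rec.REF) - len(rec.ALT[0])) > MAX_INDEL_LEN:
            n_rejected += 1
            continue
        ann = {}
        for p in HARD_FILTER_PARAMS:
            v = rec.INFO.get(p)
            if v is not None:
                ann[p] = float(v)
        csq = rec.INFO.get("CSQ") or "none"
        cadd = rec.INFO.get("CADD")
        gene = rec.INFO.get("GENE")
        sites.append(
            VariantSite(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                site_annotations=ann,
                consequence=str(csq),
                cadd=float(cadd) if cadd is not None else None,
                gene_id=str(gene) if gene is not None else None,
            )
        )
        g = rec.gt_types[keep].astype(np.int8)  # gts012: 0,1,2, 3=unknown
        g[g == 3] = MISSING
        gt_cols.append(g)
        for key, cols in (("DP", dp_cols), ("GQ", gq_cols)):
            try:
                arr = rec.format(key)
            except KeyError:
                arr = None
            cols.append(
                arr[keep, 0].astype(np.int32) if arr is not None
                else np.full(len(keep), -1, np.int32)
            )
    if n_rejected:
        warnings.warn(
            f"skipped {n_rejected} multi-allelic or over-length record(s)",
            stacklevel=2,
        )
    n = len(samples)
    stack = lambda cols, dt: (
        np.stack(cols, axis=1) if cols else np.empty((n, 0), dtype=dt)
    )
    return CohortGenotypes(
        sample_ids=samples,
        sites=sites,
        gt=stack(gt_cols, np.int8),
        dp=stack(dp_cols, np.int32),
        gq=stack(gq_cols, np.int32),
    )


def write_cohort_vcf(cohort: CohortGenotypes, path) -> None:
    """Write a CohortGenotypes as a VCF 4.2 body with FORMAT GT:DP:GQ.

    Site QC annotations plus consequence/CADD/gene ride in INFO so a
    round trip through :func:`read_cohort_vcf` is lossless.
    """
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for p in HARD_FILTER_PARAMS:
            fh.write(f'##INFO=<ID={p},Number=1,Type=Float,Description="{p}">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n')
        fh.write('##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD phred">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + list(cohort.sample_ids)) + "\n")
        for j, site in enumerate(cohort.sites):
            info = [f"{k}={site.site_annotations[k]:.6g}" for k in HARD_FILTER_PARAMS
                    if k in site.site_annotations]
            if site.consequence != "none":
                info.append(f"CSQ={site.consequence}")
            if site.cadd is not None:
                info.append(f"CADD={site.cadd:.6g}")
            if site.gene_id is not None:
                info.append(f"GENE={site.gene_id}")
            row = [
                site.chrom,
                str(site.pos),
                ".",
                site.ref,
                site.alt,
                ".",
                "PASS",
                ";".join(info) if info else ".",
                "GT:DP:GQ",
            ]
            for i in range(cohort.n_samples):
                row.append(
                    f"{gt_strings[int(cohort.gt[i, j])]}:{int(cohort.dp[i, j])}:{int(cohort.gq[i, j])}"
                )
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# BED / tabular IO


def read_regions(path, label: str, catalog: RegionCatalog | None = None) -> RegionCatalog:
    """Load a BED3+ track into a catalog under ``label`` (merged, sorted)."""
    if catalog is None:
        catalog = RegionCatalog()
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
            by_chrom.setdefault(chrom, []).append((start, end))
    catalog.add(label, by_chrom)
    return catalog


def write_regions(catalog: RegionCatalog, name: str, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(catalog.intervals(name)):
            for s, e in catalog.intervals(name)[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


PANEL_COLUMNS = ["chrom", "pos", "ref", "alt", "present", "maf_nfe",
                 "popmax_ac", "popmax_an", "filter_pass"]


def read_panel_table(path) -> dict[tuple, PanelRecord]:
    """Read the reference-panel TSV into a lookup keyed by variant.

    Columns: chrom, pos, ref, alt, present, maf_nfe, af_<pop>...,
    popmax_ac, popmax_an, filter_pass.  Variants not in the table are
    treated as panel-absent by lookup code.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    af_cols = [c for c in df.columns if c.startswith("af_")]
    records = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        records[(d["chrom"], int(d["pos"]), d["ref"], d["alt"])] = PanelRecord(
            present_in_panel=bool(d["present"]),
            af_by_population={c[3:]: float(d[c]) for c in af_cols},
            maf_nfe=float(d["maf_nfe"]),
            popmax_ac=int(d["popmax_ac"]),
            popmax_an=int(d["popmax_an"]),
            panel_filter_pass=bool(d["filter_pass"]),
        )
    return records


def write_panel_table(records: Mapping[tuple, PanelRecord], path) -> None:
    pops = sorted({p for r in records.values() for p in r.af_by_population})
    rows = []
    for (chrom, pos, ref, alt), r in records.items():
        row = {
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "present": int(r.present_in_panel), "maf_nfe": r.maf_nfe,
            "popmax_ac": r.popmax_ac, "popmax_an": r.popmax_an,
            "filter_pass": int(r.panel_filter_pass),
        }
        for p in pops:
            row[f"af_{p}"] = r.af_by_population.get(p, 0.0)
        rows.append(row)
    cols = PANEL_COLUMNS[:6] + [f"af_{p}" for p in pops] + PANEL_COLUMNS[6:]
    pd.DataFrame(rows).reindex(columns=cols).to_csv(path, sep="\t", index=False)


def lookup_panel(site: VariantSite, panel: Mapping[tuple, PanelRecord]) -> PanelRecord:
    """Panel record for a site; absent variants get the canonical absent record."""
    return panel.get(site.key, ABSENT_PANEL_RECORD)


def drop_panel_failed(cohort: CohortGenotypes, panel: Mapping[tuple, PanelRecord]) -> CohortGenotypes:
    """Remove sites present in the panel but failing its quality filters."""
    keep = np.array(
        [
            (r := lookup_panel(s, panel)).panel_filter_pass or not r.present_in_panel
            for s in cohort.sites
        ],
        dtype=bool,
    )
    return cohort.subset_sites(keep)


def read_consequence_table(path) -> pd.DataFrame:
    """Per-variant consequence + CADD table (chrom, pos, ref, alt, consequence, cadd, gene_id)."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_gene_constraint(path) -> pd.DataFrame:
    """Per-gene constraint table (gene_id, pli, mis_z)."""
    return pd.read_csv(path, sep="\t").set_index("gene_id")


def annotate_sites(cohort: CohortGenotypes, consequences: pd.DataFrame) -> None:
    """Attach consequence/CADD/gene annotations onto cohort sites in place."""
    lut = {
        (r.chrom, int(r.pos), r.ref, r.alt): r
        for r in consequences.itertuples(index=False)
    }
    for site in cohort.sites:
        r = lut.get(site.key)
        if r is None:
            continue
        site.consequence = r.consequence
        site.cadd = None if pd.isna(r.cadd) else float(r.cadd)
        site.gene_id = None if pd.isna(r.gene_id) else str(r.gene_id)
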