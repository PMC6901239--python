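"""Folded SFS, windowed Tajima's D and runs of homozygosity.

Tajima's D contrasts mean pairwise diversity (pi) with Watterson's
estimator (S / a1): negative values indicate an excess of rare alleles
(growth or purifying selection), positive values an excess of shared
intermediate-frequency alleles, as expected after a bottleneck.  pi is
computed from unphased genotype allele counts per site,
pi_site = 2 ac (an - ac) / (an (an - 1)), matching the behaviour of the
standard VCF tooling.  Windows are consecutive 1 Mb bins tiling each
chromosome; windows without segregating sites are undefined and
excluded from aggregation.

ROH calling is a two-state (autozygous / outbred) hidden Markov model
over a sample's genotypes along a chromosome, with het-emission
probability 2 p (1 - p) in the outbred state and a small error rate in
the autozygous state, distance-dependent state switching, and a Viterbi
decode.  Called segments are filtered by marker density and classified
as intermediate (0.5 - 2 Mb) or long (>= 2 Mb).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compare import bootstrap_compare, ComparisonResult
from .core import CohortGenotypes, MISSING


# ---------------------------------------------------------------------------
# Folded site frequency spectrum


@dataclass
class SFSSpectrum:
    """Mean and s.d. of folded minor-allele-count bin proportions."""

    bins: np.ndarray          # minor allele count 1..n_chrom//2
    mean_proportion: np.ndarray
    sd_proportion: np.ndarray
    per_replicate: np.ndarray  # (reps, n_bins)


def folded_sfs(cohort: CohortGenotypes, subsample_n: int = 50, reps: int = 100,
               seed=None, site_mask: np.ndarray | None = None) -> SFSSpectrum:
    """Folded SFS over repeated subsamples of distinct individuals.

    Per replicate: draw ``subsample_n`` distinct individuals (without
    replacement within a replicate, with replacement across
    replicates), drop sites with any missing genotype, fold allele
    counts to the minor allele, and tabulate proportions over
    polymorphic sites.
    """
    if subsample_n > cohort.n_samples:
        raise ValueError("subsample_n exceeds cohort size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gt = cohort.gt if site_mask is None else cohort.gt[:, np.asarray(site_mask)]
    n_chrom = 2 * subsample_n
    n_bins = n_chrom // 2
    out = np.zeros((reps, n_bins))
    for r in range(reps):
        rows = rng.choice(cohort.n_samples, size=subsample_n, replace=False)
        sub = gt[rows]
        complete = ~(sub == MISSING).any(axis=0)
        ac = sub[:, complete].astype(np.int64).sum(axis=0)
        mac = np.minimum(ac, n_chrom - ac)
        mac = mac[(mac > 0)]
        if mac.size:
            counts = np.bincount(mac, minlength=n_bins + 1)[1:n_bins + 1]
            out[r] = counts / mac.size
    return SFSSpectrum(
        bins=np.arange(1, n_bins + 1),
        mean_proportion=out.mean(axis=0),
        sd_proportion=out.std(axis=0, ddof=0),
        per_replicate=out,
    )


# ---------------------------------------------------------------------------
# Tajima's D


@dataclass
class TajimaWindow:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # inclusive
    n_segregating: int
    pi: float
    d: float | None  # None when S = 0


def tajima_constants(n: int) -> dict:
    """Normalising constants for n sampled chromosomes."""
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2}


def tajimas_d(ac: np.ndarray, an: np.ndarray, n_chromosomes: int) -> tuple[float, float, int]:
    """(D, pi, S) from per-site allele counts within one window.

    pi is the sum over segregating sites of 2 ac (an - ac) / (an (an-1));
    S counts sites with 0 < ac < an.  D is NaN when S = 0.
    """
    ac = np.asarray(ac, dtype=float)
    an = np.asarray(an, dtype=float)
    seg = (ac > 0) & (ac < an) & (an > 1)
    s_count = int(seg.sum())
    if s_count == 0:
        return float("nan"), 0.0, 0
    a = ac[seg]
    n = an[seg]
    pi = float(np.sum(2.0 * a * (n - a) / (n * (n - 1.0))))
    k = tajima_constants(n_chromosomes)
    theta_w = s_count / k["a1"]
    var = k["e1"] * s_count + k["e2"] * s_count * (s_count - 1)
    d = (pi - theta_w) / np.sqrt(var)
    return float(d), pi, s_count


def windowed_tajima(cohort: CohortGenotypes, window_bp: int = 1_000_000,
                    site_mask: np.ndarray | None = None,
                    sample_rows: np.ndarray | None = None) -> list[TajimaWindow]:
    """Tajima's D in consecutive fixed windows tiling each chromosome.

    ``n_chromosomes`` per window is twice the number of samples used;
    sites with missing genotypes contribute their called alleles only,
    through the per-site pi formula.
    """
    gt = cohort.gt if sample_rows is None else cohort.gt[sample_rows]
    n_chrom = 2 * gt.shape[0]
    mask = np.ones(cohort.n_sites, bool) if site_mask is None else np.asarray(site_mask)
    chroms = np.array([s.chrom for s in cohort.sites])
    positions = cohort.positions()
    ac_all = np.where(gt == MISSING, 0, gt).sum(axis=0)
    an_all = 2 * (gt != MISSING).sum(axis=0)
    windows = []
    for chrom in sorted(set(chroms)):
        sel = (chroms == chrom) & mask
        if not sel.any():
            continue
        pos = positions[sel]
        ac = ac_all[sel]
        an = an_all[sel]
        last = int(pos.max())
        for w0 in range(1, last + 1, window_bp):
            w1 = w0 + window_bp - 1
            in_w = (pos >= w0) & (pos <= w1)
            if not in_w.any():
                continue
            d, pi, s = tajimas_d(ac[in_w], an[in_w], n_chrom)
            windows.append(TajimaWindow(
                chrom=chrom, start=w0, end=w1, n_segregating=s, pi=pi,
                d=None if s == 0 else d,
            ))
    return windows


def aggregate_tajima(windows: list[TajimaWindow]) -> dict:
    """Median and 95% percentile interval over defined windows."""
    vals = np.array([w.d for w in windows if w.d is not None], dtype=float)
    if vals.size == 0:
        return {"n_windows": 0, "median": float("nan"),
                "ci": (float("nan"), float("nan"))}
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return {"n_windows": int(vals.size), "median": float(np.median(vals)),
            "ci": (float(lo), float(hi))}


def subset_aggregate_tajima(cohort: CohortGenotypes, n_subsets: int,
                            subset_size: int, seed=None,
                            window_bp: int = 1_000_000,
                            site_mask: np.ndarray | None = None) -> dict:
    """Median over window medians of repeated cohort subsets.

    Subsets are distinct individuals within a draw, with replacement
    across draws -- the reference-cohort aggregation recipe.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    medians = []
    for _ in range(n_subsets):
        rows = rng.choice(cohort.n_samples, size=subset_size, replace=False)
        wins = windowed_tajima(cohort, window_bp=window_bp,
                               site_mask=site_mask, sample_rows=rows)
        agg = aggregate_tajima(wins)
        if agg["n_windows"]:
            medians.append(agg["median"])
    arr = np.asarray(medians, dtype=float)
    if arr.size == 0:
        return {"n_subsets": 0, "median": float("nan"),
                "ci": (float("nan"), float("nan"))}
    lo, hi = np.percentile(arr, [2.5, 97.5])
    return {"n_subsets": int(arr.size), "median": float(np.median(arr)),
            "ci": (float(lo), float(hi))}


# ---------------------------------------------------------------------------
# Runs of homozygosity


@dataclass
class ROHSegment:
    sample_id: str
    chrom: str
    start: int  # 1-based position of first marker
    end: int    # 1-based position of last marker
    n_markers: int
    length_class: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def density(self) -> float:
        """Markers per kb of segment length."""
        return self.n_markers / (max(self.length, 1) / 1000.0)


def call_roh(genotypes: np.ndarray, positions: np.ndarray, afs: np.ndarray,
             gq: np.ndarray | None = None, gq_floor: int = 30,
             sample_id: str = "", chrom: str = "1",
             het_error: float = 5e-3, switch_rate: float = 5e-7) -> list[ROHSegment]:
    """Two-state HMM autozygosity caller for one sample and chromosome.

    Emissions: P(het | outbred) = 2 p (1 - p), P(het | autozygous) =
    ``het_error``.  Transition probability between consecutive markers
    at distance d bp is ``1 - exp(-switch_rate * d)`` in each
    direction.  Markers with GQ below ``gq_floor`` are ignored.
    Returns maximal Viterbi-autozygous runs with their marker counts.
    """
    g = np.asarray(genotypes)
    pos = np.asarray(positions, dtype=np.int64)
    p = np.asarray(afs, dtype=float)
    use = (g != MISSING)
    if gq is not None:
        use &= np.asarray(gq) >= gq_floor
    use &= (p > 0) & (p < 1)
    g, pos, p = g[use], pos[use], p[use]
    m = g.size
    if m == 0:
        return []

    het = g == 1
    p_het_out = 2.0 * p * (1.0 - p)
    eps = 1e-12
    log_e = np.empty((m, 2))
    log_e[:, 0] = np.where(het, np.log(p_het_out + eps), np.log1p(-p_het_out + eps))
    log_e[:, 1] = np.where(het, np.log(het_error), np.log1p(-het_error))

    d = np.diff(pos).astype(float)
    p_switch = 1.0 - np.exp(-switch_rate * d)
    np.clip(p_switch, 1e-12, 0.5, out=p_switch)
    log_sw = np.log(p_switch)
    log_st = np.log1p(-p_switch)

    # Viterbi in log space; state 0 = outbred, 1 = autozygous
    v = np.array([np.log(0.9), np.log(0.1)]) + log_e[0]
    back = np.zeros((m, 2), dtype=np.int8)
    for t in range(1, m):
        stay0 = v[0] + log_st[t - 1]
        from1 = v[1] + log_sw[t - 1]
        stay1 = v[1] + log_st[t - 1]
        from0 = v[0] + log_sw[t - 1]
        if stay0 >= from1:
            new0, back[t, 0] = stay0, 0
        else:
            new0, back[t, 0] = from1, 1
        if stay1 >= from0:
            new1, back[t, 1] = stay1, 1
        else:
            new1, back[t, 1] = from0, 0
        v = np.array([new0, new1]) + log_e[t]
    states = np.empty(m, dtype=np.int8)
    states[-1] = int(v[1] > v[0])
    for t in range(m - 1, 0, -1):
        states[t - 1] = back[t, states[t]]

    segments = []
    in_run = False
    for t in range(m):
        if states[t] == 1 and not in_run:
            run_start, run_markers, in_run = t, 1, True
        elif states[t] == 1:
            run_markers += 1
        elif in_run:
            segments.append(ROHSegment(sample_id, chrom, int(pos[run_start]),
                                       int(pos[t - 1]), run_markers))
            in_run = False
    if in_run:
        segments.append(ROHSegment(sample_id, chrom, int(pos[run_start]),
                                   int(pos[m - 1]), run_markers))
    return segments


def filter_classify_roh(segments: list[ROHSegment], density_cutoff: float,
                        bounds: tuple[float, float] = (0.5e6, 2e6)) -> list[ROHSegment]:
    """Length classification plus the per-cohort marker-density filter.

    short (< 0.5 Mb) segments are discarded; intermediate is
    [0.5, 2) Mb and long >= 2 Mb, and both are dropped when their
    marker density falls strictly below ``density_cutoff`` per kb.
    """
    lo, hi = bounds
    out = []
    for seg in segments:
        if seg.length < lo:
            continue
        if seg.density < density_cutoff:
            continue
        seg.length_class = "intermediate" if seg.length < hi else "long"
        out.append(seg)
    return out


def density_antimode(densities, bins: int = 40) -> float:
    """Suggested density cutoff: the antimode of the histogram.

    ROH marker densities are typically bimodal (well-covered vs poorly
    covered segments); the histogram minimum between the two modes is a
    natural per-cohort cutoff.
    """
    arr = np.asarray(densities, dtype=float)
    hist, edges = np.histogram(arr, bins=bins)
    peaks = np.flatnonzero(
        (hist >= np.roll(hist, 1)) & (hist >= np.roll(hist, -1)) & (hist > 0)
    )
    if peaks.size < 2:
        return float(np.median(arr))
    left, right = peaks[0], peaks[-1]
    valley = left + int(np.argmin(hist[left:right + 1]))
    return float((edges[valley] + edges[valley + 1]) / 2.0)


def roh_per_individual(segments: list[ROHSegment], length_class: str) -> dict:
    """Per-sample (count, total length) summaries for one length class."""
    out: dict[str, list[float]] = {}
    for seg in segments:
        if seg.length_class != length_class:
            continue
        rec = out.setdefault(seg.sample_id, [0, 0.0])
        rec[0] += 1
        rec[1] += seg.length
    return {k: tuple(v) for k, v in out.items()}


def compare_roh(iso_segments: list[ROHSegment], ref_segments: list[ROHSegment],
                length_class: str, n_subsets: int = 10_000,
                alpha: float = 0.0125, seed=None) -> dict[str, ComparisonResult]:
    """Bootstrap count and total-length comparisons for one length class.

    Only individuals carrying at least one segment of the class enter
    the comparison; the subset size equals the number of such isolate
    individuals.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    iso = roh_per_individual(iso_segments, length_class)
    ref = roh_per_individual(ref_segments, length_class)
    if not iso or not ref:
        raise ValueError(f"no individuals with {length_class} ROH in one cohort")
    iso_counts = np.array([v[0] for v in iso.values()], dtype=float)
    ref_counts = np.array([v[0] for v in ref.values()], dtype=float)
    iso_len = np.array([v[1] for v in iso.values()], dtype=float)
    ref_len = np.array([v[1] for v in ref.values()], dtype=float)
    size = iso_counts.size
    return {
        "count": bootstrap_compare(iso_counts, ref_counts, n_subsets=n_subsets,
                                   subset_size=size, alpha=alpha, seed=rng),
        "total_length": bootstrap_compare(iso_len, ref_len, n_subsets=n_subsets,
                                          subset_size=size, alpha=alpha, seed=rng),
    }
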