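"""Panel-based frequency stratification and founder/drift enrichment.

Variants are classified against the reference panel: ultra-rare means
absent from the panel entirely; panel-present variants fall into
very rare (MAF_NFE <= 1%), rare (1% < MAF_NFE <= 5%), common
(5% < MAF_NFE <= 10%) and very common (MAF_NFE > 10%), upper bounds
inclusive.  Ultra-rare variants subdivide by within-cohort sharing:
singleton (exactly one carrier individual, regardless of zygosity) or
doubleton-plus.

Fold enrichment measures drift: the focal cohort AF over the maximum AF
seen in the other cohort and any panel population (panel-absent
variants use the other cohort alone).  Variants absent from both the
panel and the other cohort are cohort-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CohortGenotypes, PanelRecord, VariantSite, lookup_panel

FREQUENCY_CLASSES = ("ultra_rare", "very_rare", "rare", "common", "very_common")
CLASS_BOUNDS = (0.01, 0.05, 0.10)  # very_rare | rare | common | very_common


def classify_frequency(site: VariantSite, panel: PanelRecord) -> str:
    """Frequency class from panel presence and folded NFE MAF.

    Panel-present variants with MAF_NFE = 0 (seen only in other panel
    populations) fall in very_rare, since MAF_NFE <= 1% holds.
    """
    if not panel.present_in_panel:
        return "ultra_rare"
    m = panel.maf_nfe
    if m <= CLASS_BOUNDS[0]:
        return "very_rare"
    if m <= CLASS_BOUNDS[1]:
        return "rare"
    if m <= CLASS_BOUNDS[2]:
        return "common"
    return "very_common"


def classify_sharing(site_index: int, cohort: CohortGenotypes) -> str:
    """singleton vs doubleton_plus by carrier individuals, not alleles.

    A sole hom-alt carrier (AC = 2 in one individual) is a singleton.
    """
    carriers = int((cohort.gt[:, site_index] > 0).sum())
    if carriers == 0:
        raise ValueError(f"site index {site_index} has no carriers")
    return "singleton" if carriers == 1 else "doubleton_plus"


@dataclass
class DriftCategory:
    fold_enrichment: float  # may be inf when the baseline AF is zero
    ge2x: bool
    ge5x: bool
    ge10x: bool
    cohort_specific: bool


def drift_category(site: VariantSite, cohort_af: float, other_cohort_af: float,
                   panel: PanelRecord) -> DriftCategory:
    """Fold enrichment of the focal cohort AF over its drift baseline.

    Baseline = max(other cohort AF, max panel-population AF) when the
    variant is panel-present, else the other cohort AF alone.
    Cohort-specific iff panel-absent and unseen in the other cohort.
    """
    if cohort_af <= 0:
        raise ValueError("drift_category requires cohort_af > 0")
    if panel.present_in_panel:
        baseline = max(other_cohort_af, panel.max_population_af)
        specific = False
    else:
        baseline = other_cohort_af
        specific = other_cohort_af == 0
    fold = np.inf if baseline == 0 else cohort_af / baseline
    return DriftCategory(
        fold_enrichment=float(fold),
        ge2x=fold >= 2, ge5x=fold >= 5, ge10x=fold >= 10,
        cohort_specific=specific,
    )


def classify_cohort(cohort: CohortGenotypes, panel: Mapping[tuple, PanelRecord],
                    other_cohort: CohortGenotypes | None = None) -> pd.DataFrame:
    """Per-site table: frequency class, sharing, drift category.

    Sites with zero alternate alleles in the cohort are marked absent
    and excluded from class counts.
    """
    ac = cohort.cohort_ac
    af = cohort.cohort_af
    other_af = np.zeros(cohort.n_sites)
    if other_cohort is not None:
        lut = {s.key: j for j, s in enumerate(other_cohort.sites)}
        oaf = other_cohort.cohort_af
        for j, s in enumerate(cohort.sites):
            k = lut.get(s.key)
            if k is not None and np.isfinite(oaf[k]):
                other_af[j] = oaf[k]
    rows = []
    for j, site in enumerate(cohort.sites):
        if ac[j] == 0:
            rows.append({"freq_class": "absent", "sharing": "", "fold": np.nan,
                         "ge2x": False, "ge5x": False, "ge10x": False,
                         "cohort_specific": False, "is_snp": site.is_snp})
            continue
        rec = lookup_panel(site, panel)
        fc = classify_frequency(site, rec)
        sharing = classify_sharing(j, cohort) if fc == "ultra_rare" else ""
        d = drift_category(site, float(af[j]), float(other_af[j]), rec)
        rows.append({"freq_class": fc, "sharing": sharing,
                     "fold": d.fold_enrichment, "ge2x": d.ge2x, "ge5x": d.ge5x,
                     "ge10x": d.ge10x, "cohort_specific": d.cohort_specific,
                     "is_snp": site.is_snp})
    return pd.DataFrame(rows)


def drift_summary(classified: pd.DataFrame) -> dict:
    """Per-frequency-class drift percentages plus aggregate fractions.

    ``per_class`` rows give, within each panel frequency class, the
    percentage of variants in each fold bin and the percentage that are
    cohort-specific.  Aggregates (over all cohort variants): the
    cohort-specific fraction, and cohort-specific plus >= 10x enriched.
    """
    df = classified[classified["freq_class"] != "absent"]
    total = len(df)
    per_class = {}
    for fc in FREQUENCY_CLASSES:
        sub = df[df["freq_class"] == fc]
        n = len(sub)
        if n == 0:
            per_class[fc] = {"n": 0, "pct_ge2x": 0.0, "pct_ge5x": 0.0,
                             "pct_ge10x": 0.0, "pct_specific": 0.0}
            continue
        nonspec = sub[~sub["cohort_specific"]]
        per_class[fc] = {
            "n": n,
            "pct_ge2x": 100.0 * (nonspec["ge2x"]).sum() / n,
            "pct_ge5x": 100.0 * (nonspec["ge5x"]).sum() / n,
            "pct_ge10x": 100.0 * (nonspec["ge10x"]).sum() / n,
            "pct_specific": 100.0 * sub["cohort_specific"].sum() / n,
        }
    n_specific = int(df["cohort_specific"].sum())
    n_drifted = int((df["ge10x"] & ~df["cohort_specific"]).sum())
    return {
        "per_class": per_class,
        "n_total": total,
        "n_cohort_specific": n_specific,
        "pct_cohort_specific": 100.0 * n_specific / total if total else 0.0,
        "pct_specific_or_10x": 100.0 * (n_specific + n_drifted) / total if total else 0.0,
    }


def drift_percentages(n_specific: int, n_ge10x: int, n_total: int) -> dict:
    """Aggregate drift fractions from externally tabulated counts.

    Reproduces the published arithmetic: cohort-specific / total, and
    (cohort-specific + >=10x-enriched) / total, as percentages.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return {
        "pct_cohort_specific": 100.0 * n_specific / n_total,
        "pct_specific_or_10x": 100.0 * (n_specific + n_ge10x) / n_total,
    }


def frequency_class_counts(classified: pd.DataFrame) -> pd.DataFrame:
    """Counts per frequency class (and sharing split for ultra-rare)."""
    df = classified[classified["freq_class"] != "absent"]
    rows = []
    for fc in FREQUENCY_CLASSES:
        sub = df[df["freq_class"] == fc]
        row = {"freq_class": fc, "n": len(sub)}
        if fc == "ultra_rare":
            row["n_singleton"] = int((sub["sharing"] == "singleton").sum())
            row["n_doubleton_plus"] = int((sub["sharing"] == "doubleton_plus").sum())
        rows.append(row)
    return pd.DataFrame(rows)
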