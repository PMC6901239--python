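"""LOF/SYN categorisation and ratios, FUV, ASB baseline, Fisher oracle."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from isodrift.core import CohortGenotypes, PanelRecord, VariantSite
from isodrift.selection import (
    asb_test,
    categorize_lof_syn,
    fisher_enrichment,
    functional_exonic_filter,
    fuv,
    lof_syn_ratio,
    lof_syn_ratio_from_counts,
)


def site(consequence="none", cadd=None, gene="G1", pos=1):
    return VariantSite("1", pos, "A", "G", consequence=consequence,
                       cadd=cadd, gene_id=gene)


class TestCategorize:
    @pytest.mark.parametrize("csq,cadd,expected", [
        ("stop_gained", None, "LOF"),
        ("splice_donor", None, "LOF"),
        ("splice_acceptor", None, "LOF"),
        ("missense", 20.0, "LOF"),
        ("missense", 19.9, "OTHER"),
        ("missense", None, "OTHER"),
        ("synonymous", None, "SYN"),
        ("start_lost", 30.0, "OTHER"),
        ("none", None, "OTHER"),
    ])
    def test_consequence_and_cadd_rules(self, csq, cadd, expected):
        assert categorize_lof_syn(site(csq, cadd)) == expected


class TestCohortRatios:
    def test_printed_cohort_level_ratios(self):
        assert round(lof_syn_ratio_from_counts(211_761, 158_077), 2) == 1.34
        assert round(lof_syn_ratio_from_counts(23_787, 17_122), 2) == 1.39
        assert round(lof_syn_ratio_from_counts(3_655, 2_501), 2) == 1.46

    def test_equal_counts_give_unit_ratio(self):
        assert lof_syn_ratio_from_counts(10, 10) == pytest.approx(1.0)

    def test_zero_syn_is_an_error(self):
        with pytest.raises(ValueError):
            lof_syn_ratio_from_counts(5, 0)


def build_cohort(gt, sites):
    gt = np.asarray(gt, np.int8)
    n, m = gt.shape
    return CohortGenotypes([f"S{i}" for i in range(n)], sites, gt,
                           np.full((n, m), 30, np.int32),
                           np.full((n, m), 60, np.int32))


class TestLofSynRatio:
    def cohorts(self):
        sites_a = [site("stop_gained", gene="G1", pos=1),
                   site("synonymous", gene="G1", pos=2),
                   site("missense", cadd=25.0, gene="G2", pos=3),
                   site("synonymous", gene="G3", pos=4)]
        a = build_cohort([[1, 1, 2, 1], [1, 1, 0, 0]], sites_a)
        sites_b = [site("stop_gained", gene="G1", pos=11),
                   site("synonymous", gene="G1", pos=12),
                   site("synonymous", gene="G2", pos=13)]
        b = build_cohort([[1, 1, 1], [0, 1, 1], [1, 0, 0]], sites_b)
        ultra_a = np.ones(4, bool)
        ultra_b = np.ones(3, bool)
        return a, ultra_a, b, ultra_b

    def test_allele_counts_and_ratio(self):
        a, ua, _, _ = self.cohorts()
        res = lof_syn_ratio(a, ua)
        assert res.n_lof == 2 + 2  # stop_gained AC=2, high-CADD missense AC=2
        assert res.n_syn == 2 + 1
        assert res.ratio == pytest.approx(4 / 3)

    def test_gene_restriction_never_increases_counts(self):
        a, ua, b, ub = self.cohorts()
        full = lof_syn_ratio(a, ua, other_cohort=b, other_ultra_mask=ub)
        restricted = lof_syn_ratio(a, ua, gene_restrict=True,
                                   other_cohort=b, other_ultra_mask=ub)
        assert restricted.n_lof <= full.n_lof
        assert restricted.n_syn <= full.n_syn
        # G3 has no LOF-or-SYN in cohort b, so its SYN allele drops out
        assert restricted.n_syn == full.n_syn - 1

    def test_singleton_scope_keeps_het_sole_carriers_only(self):
        sites = [site("stop_gained", pos=1), site("synonymous", pos=2),
                 site("stop_gained", pos=3)]
        # site 1: het singleton; site 2: het singleton; site 3: hom sole carrier
        cohort = build_cohort([[1, 1, 2], [0, 0, 0]], sites)
        res = lof_syn_ratio(cohort, np.ones(3, bool), scope="singleton")
        assert res.n_lof == 1 and res.n_syn == 1

    def test_per_individual_ratios_exclude_zero_syn(self):
        a, ua, _, _ = self.cohorts()
        res = lof_syn_ratio(a, ua)
        # S0: LOF = 1 + 2 = 3 alleles, SYN = 2 -> 1.5; S1: LOF = 1, SYN = 1 -> 1.0
        assert sorted(res.per_individual_ratios) == pytest.approx([1.0, 1.5])

    def test_one_sided_p_against_other_cohort(self):
        a, ua, b, ub = self.cohorts()
        res = lof_syn_ratio(a, ua, other_cohort=b, other_ultra_mask=ub)
        assert res.wilcoxon_p is not None
        assert 0.0 < res.wilcoxon_p <= 1.0


class TestFUV:
    def test_bounds_and_arithmetic(self):
        assert fuv(0, 20)["fuv"] == 0.0
        assert fuv(20, 0)["fuv"] == 1.0
        assert fuv(5, 15)["fuv"] == pytest.approx(0.25)

    def test_density_per_mb(self):
        assert fuv(5, 15, region_length_mb=4.0)["density_per_mb"] == pytest.approx(5.0)

    def test_empty_region_undefined(self):
        with pytest.raises(ValueError):
            fuv(0, 0)


class TestASB:
    def make_pair(self, rng, n_sites=400):
        af = rng.uniform(0.001, 0.05, n_sites)
        iso = build_cohort(rng.binomial(2, af, size=(30, n_sites)),
                           [site(pos=i + 1) for i in range(n_sites)])
        ref = build_cohort(rng.binomial(2, af, size=(80, n_sites)),
                           [site(pos=i + 1) for i in range(n_sites)])
        return iso, ref

    def test_region_equal_to_baseline_gives_zero_shifts(self, rng):
        iso, ref = self.make_pair(rng)
        mask = np.ones(iso.n_sites, bool)
        res = asb_test(iso, ref, eligible=mask, region_mask=mask,
                       nfig_mask=mask, n_reps=50, seed=1, region_label="self")
        assert np.allclose(res.iso_shifts, 0.0)
        assert np.allclose(res.ref_shifts, 0.0)
        assert res.p_value >= 0.99

    def test_replicates_without_qualifying_sites_dropped(self, rng):
        iso, ref = self.make_pair(rng, n_sites=20)
        eligible = np.zeros(20, bool)
        eligible[:2] = True
        region = eligible.copy()
        with pytest.raises(ValueError):
            # no NFIG sites at all: every replicate drops
            asb_test(iso, ref, eligible, region, np.zeros(20, bool),
                     n_reps=10, seed=2)

    def test_equal_replicate_counts_across_cohorts(self, rng):
        iso, ref = self.make_pair(rng)
        half = np.zeros(iso.n_sites, bool)
        half[::2] = True
        res = asb_test(iso, ref, np.ones(iso.n_sites, bool),
                       region_mask=half, nfig_mask=~half, n_reps=40, seed=3)
        assert res.iso_shifts.size == res.ref_shifts.size


def fisher_oracle_greater(table):
    """One-sided hypergeometric tail summed exactly with Fractions."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    p = Fraction(0)
    for k in range(a, hi + 1):
        p += Fraction(comb(row1, k) * comb(n - row1, col1 - k), comb(n, col1))
    return float(p)


class TestFisherEnrichment:
    def panel(self, ac, an):
        return PanelRecord(True, {"nfe": ac / an}, maf_nfe=min(ac / an, 1 - ac / an),
                           popmax_ac=ac, popmax_an=an)

    def test_matches_hypergeometric_enumeration(self, rng):
        for _ in range(40):
            a, b = int(rng.integers(0, 30)), int(rng.integers(1, 40))
            c, d = int(rng.integers(0, 30)), int(rng.integers(1, 40))
            rec = fisher_enrichment(site(), a, a + b, self.panel(c, c + d),
                                    coverage30_individuals=0, family_size=100)
            assert rec.fisher_p == pytest.approx(
                fisher_oracle_greater([[a, b], [c, d]]), abs=1e-12)

    def test_identical_proportions_not_significant(self):
        rec = fisher_enrichment(site(), 5, 100, self.panel(50, 1000),
                                coverage30_individuals=0, family_size=1)
        assert rec.fisher_p >= 0.5

    def test_panel_absent_uses_coverage_derived_an(self):
        rec = fisher_enrichment(site(), 3, 100, PanelRecord(False),
                                coverage30_individuals=7500, family_size=1)
        assert rec.baseline_ac == 0
        assert rec.baseline_an == 15_000

    def test_zero_baseline_an_errors(self):
        with pytest.raises(ValueError):
            fisher_enrichment(site(), 1, 10, PanelRecord(False),
                              coverage30_individuals=0, family_size=1)

    def test_bonferroni_family_threshold_applied(self):
        rec = fisher_enrichment(site(), 30, 100, self.panel(1, 15_000),
                                coverage30_individuals=0, family_size=153_381)
        assert rec.significant == (rec.fisher_p <= 0.05 / 153_381)


class TestFunctionalExonicFilter:
    constraint = pd.DataFrame(
        {"gene_id": ["HI", "LO"], "pli": [0.95, 0.5], "mis_z": [3.1, -1.0]}
    ).set_index("gene_id")

    def run(self, s, cohort_af=0.02, other_af=0.001, panel_af=0.0):
        rec = PanelRecord(panel_af > 0, {"nfe": panel_af} if panel_af else {},
                          maf_nfe=min(panel_af, 1 - panel_af) if panel_af else 0.0)
        return functional_exonic_filter([s], np.array([cohort_af]),
                                        np.array([other_af]), [rec],
                                        self.constraint)[0]

    def test_high_cadd_missense_in_constrained_gene_kept(self):
        assert self.run(site("missense", cadd=25.0, gene="HI"))

    def test_enrichment_direction_required(self):
        assert not self.run(site("missense", cadd=25.0, gene="HI"),
                            cohort_af=0.001, other_af=0.01)

    def test_low_cadd_missense_dropped(self):
        assert not self.run(site("missense", cadd=15.0, gene="HI"))

    def test_nonsense_in_tolerant_gene_dropped(self):
        assert not self.run(site("stop_gained", gene="LO"))
        assert self.run(site("stop_gained", gene="HI"))

    def test_missense_needs_positive_z(self):
        assert not self.run(site("missense", cadd=25.0, gene="LO"))

    def test_unknown_gene_excluded(self):
        assert not self.run(site("stop_gained", gene="NOPE"))
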