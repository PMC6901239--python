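"""Domain types, coordinate conventions and file round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isodrift.core import (
    CohortGenotypes,
    PanelRecord,
    RegionCatalog,
    VariantSite,
    assign_regions,
    merge_intervals,
    read_cohort_vcf,
    read_panel_table,
    read_regions,
    write_cohort_vcf,
    write_panel_table,
)


def make_cohort(gt, dp=None, dq=None, annotations=None):
    gt = np.asarray(gt, dtype=np.int8)
    n, m = gt.shape
    sites = []
    for j in range(m):
        ann = annotations[j] if annotations else {}
        sites.append(VariantSite(chrom="1", pos=100 * (j + 1), ref="A", alt="G",
                                 site_annotations=ann))
    return CohortGenotypes(
        sample_ids=[f"S{i}" for i in range(n)],
        sites=sites,
        gt=gt,
        dp=np.full((n, m), 30, np.int32) if dp is None else np.asarray(dp, np.int32),
        gq=np.full((n, m), 60, np.int32) if dq is None else np.asarray(dq, np.int32),
    )


class TestVariantSite:
    def test_snp_iff_single_base_alleles(self):
        assert VariantSite("1", 5, "A", "G").is_snp
        assert not VariantSite("1", 5, "A", "AG").is_snp
        assert not VariantSite("1", 5, "AT", "A").is_snp

    def test_rejects_invalid_coordinates_and_indels(self):
        with pytest.raises(ValueError):
            VariantSite("1", 0, "A", "G")
        with pytest.raises(ValueError):
            VariantSite("1", 5, "A", "G" * 77)  # > 75 bp length difference

    def test_panel_record_invariants(self):
        with pytest.raises(ValueError):
            PanelRecord(present_in_panel=True, maf_nfe=0.6)
        with pytest.raises(ValueError):
            PanelRecord(present_in_panel=True, popmax_ac=5, popmax_an=4)


class TestCohortDerivedValues:
    def test_ac_an_af_recomputed_from_genotypes(self):
        cohort = make_cohort([[0, 1, 2], [1, -1, 2]])
        assert list(cohort.cohort_ac) == [1, 1, 4]
        assert list(cohort.cohort_an) == [4, 2, 4]
        assert np.allclose(cohort.cohort_af, [0.25, 0.5, 1.0])

    def test_one_missing_diploid_of_two_leaves_an_two(self):
        cohort = make_cohort([[1], [-1]])
        assert cohort.cohort_an[0] == 2


class TestVcfRoundTrip:
    def test_round_trip_preserves_everything(self, tmp_path):
        ann = [{"QD": 12.5, "FS": 3.25}, {}, {"SOR": 1.5, "MQRankSum": -0.75}]
        cohort = make_cohort([[0, 1, 2], [2, -1, 0]], annotations=ann)
        cohort.sites[0].consequence = "missense"
        cohort.sites[0].cadd = 23.1
        cohort.sites[0].gene_id = "G1"
        path = tmp_path / "c.vcf"
        write_cohort_vcf(cohort, path)
        back = read_cohort_vcf(path)
        assert back.sample_ids == cohort.sample_ids
        assert np.array_equal(back.gt, cohort.gt)
        assert np.array_equal(back.dp, cohort.dp)
        assert np.array_equal(back.gq, cohort.gq)
        for a, b in zip(back.sites, cohort.sites):
            assert a.key == b.key
            assert a.consequence == b.consequence
            assert a.site_annotations == pytest.approx(b.site_annotations)

    def test_hom_alt_serialises_as_1_slash_1(self, tmp_path):
        cohort = make_cohort([[2]])
        path = tmp_path / "c.vcf"
        write_cohort_vcf(cohort, path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert body[0].split("\t")[9].startswith("1/1")

    def test_empty_site_list_writes_header_only(self, tmp_path):
        cohort = CohortGenotypes(["S0"], [], np.empty((1, 0), np.int8),
                                 np.empty((1, 0), np.int32), np.empty((1, 0), np.int32))
        path = tmp_path / "c.vcf"
        write_cohort_vcf(cohort, path)
        assert all(l.startswith("#") for l in path.read_text().splitlines())

    def test_multiallelic_records_skipped_with_warning(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\n"
            "1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\n"
            "1\t200\t.\tA\tG\t.\tPASS\t.\tGT\t1/1\n"
        )
        with pytest.warns(UserWarning, match="multi-allelic"):
            cohort = read_cohort_vcf(path)
        assert cohort.n_sites == 1
        assert cohort.gt[0, 0] == 2

    def test_unknown_sample_subset_errors(self, tmp_path):
        cohort = make_cohort([[0, 1]])
        path = tmp_path / "c.vcf"
        write_cohort_vcf(cohort, path)
        with pytest.raises(KeyError):
            read_cohort_vcf(path, sample_subset=["nope"])

    @settings(max_examples=25, deadline=None)
    @given(n=st.integers(1, 4), m=st.integers(1, 6), seed=st.integers(0, 10_000))
    def test_round_trip_random_matrices(self, tmp_path_factory, n, m, seed):
        r = np.random.default_rng(seed)
        gt = r.integers(-1, 3, size=(n, m)).astype(np.int8)
        dp = r.integers(0, 80, size=(n, m)).astype(np.int32)
        gq = r.integers(0, 99, size=(n, m)).astype(np.int32)
        cohort = make_cohort(gt, dp, gq)
        path = tmp_path_factory.mktemp("rt") / "c.vcf"
        write_cohort_vcf(cohort, path)
        back = read_cohort_vcf(path)
        assert np.array_equal(back.gt, cohort.gt)
        assert np.array_equal(back.dp, cohort.dp)
        assert np.array_equal(back.gq, cohort.gq)


class TestRegions:
    def test_overlapping_intervals_merge(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("1\t0\t10\n1\t5\t15\n")
        cat = read_regions(bed, "x")
        assert np.array_equal(cat.intervals("x")["1"], [[0, 15]])

    def test_empty_file_gives_empty_set(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("")
        cat = read_regions(bed, "x")
        assert cat.total_length("x") == 0.0

    def test_megabase_length(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("1\t0\t1000000\n")
        cat = read_regions(bed, "x")
        assert cat.total_length("x", "Mb") == 1.0

    def test_inverted_interval_reports_line(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("1\t0\t10\n1\t20\t20\n")
        with pytest.raises(ValueError, match=":2"):
            read_regions(bed, "x")

    def test_merge_intervals_idempotent_and_sorted(self, rng):
        ivals = [(int(s), int(s) + int(l) + 1)
                 for s, l in zip(rng.integers(0, 1000, 50), rng.integers(0, 50, 50))]
        once = merge_intervals(ivals)
        twice = merge_intervals(once)
        assert np.array_equal(once, twice)
        assert np.all(np.diff(once[:, 0]) > 0)
        assert np.all(once[1:, 0] > once[:-1, 1])  # strictly disjoint


class TestAssignRegions:
    @pytest.fixture()
    def catalog(self):
        cat = RegionCatalog()
        cat.add("mappable", {"1": [(0, 10_000)]})
        cat.add("exon", {"1": [(100, 200)]})
        cat.add("three_utr", {"1": [(150, 250)]})
        cat.add("intron", {"1": [(300, 400)]})
        cat.finalize_non_coding()
        return cat

    def test_variant_at_interval_start_is_inside(self, catalog):
        # interval (100, 200) 0-based half-open: 1-based positions 101..200
        assert "exon" in assign_regions(VariantSite("1", 101, "A", "G"), catalog)
        assert "exon" not in assign_regions(VariantSite("1", 100, "A", "G"), catalog)
        assert "exon" in assign_regions(VariantSite("1", 200, "A", "G"), catalog)
        assert "exon" not in assign_regions(VariantSite("1", 201, "A", "G"), catalog)

    def test_overlapping_categories_are_non_exclusive(self, catalog):
        labels = assign_regions(VariantSite("1", 180, "A", "G"), catalog)
        assert {"exon", "three_utr"} <= labels
        assert "non_coding" not in labels

    def test_position_in_no_gene_category_is_non_coding(self, catalog):
        assert assign_regions(VariantSite("1", 5000, "A", "G"), catalog) == {"non_coding"}

    def test_outside_mappable_mask_raises(self, catalog):
        with pytest.raises(ValueError, match="mappable"):
            assign_regions(VariantSite("1", 10_001, "A", "G"), catalog)

    def test_non_coding_is_exact_complement(self, catalog):
        gene_len = sum(catalog.total_length(c) for c in ("exon", "three_utr", "intron"))
        overlap = 50  # exon and three_utr share (150, 200)
        assert catalog.total_length("non_coding") == (
            catalog.total_length("mappable") - (gene_len - overlap)
        )
        # every position is in a gene category xor non-coding
        pos = np.arange(1, 10_001)
        in_gene = np.zeros(pos.shape, bool)
        for c in ("exon", "three_utr", "intron"):
            in_gene |= catalog.contains(c, "1", pos)
        assert np.array_equal(catalog.contains("non_coding", "1", pos), ~in_gene)


class TestPanelTable:
    def test_round_trip(self, tmp_path):
        records = {
            ("1", 100, "A", "G"): PanelRecord(True, {"nfe": 0.004, "oth": 0.2},
                                              maf_nfe=0.004, popmax_ac=40,
                                              popmax_an=200, panel_filter_pass=True),
            ("1", 250, "C", "T"): PanelRecord(True, {"nfe": 0.3, "oth": 0.1},
                                              maf_nfe=0.3, popmax_ac=60,
                                              popmax_an=200, panel_filter_pass=False),
        }
        path = tmp_path / "panel.tsv"
        write_panel_table(records, path)
        back = read_panel_table(path)
        assert set(back) == set(records)
        for k in records:
            assert back[k].maf_nfe == pytest.approx(records[k].maf_nfe)
            assert back[k].popmax_ac == records[k].popmax_ac
            assert back[k].panel_filter_pass == records[k].panel_filter_pass
            assert back[k].af_by_population == pytest.approx(records[k].af_by_population)
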