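"""VCF parsing, writing round-trips, and the hard-filter expressions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from popvcf import (
    GenotypeMatrix,
    SiteRecord,
    apply_filters,
    filter_summary,
    pass_sites,
    read_vcf,
    write_vcf,
)
from popvcf.vcfio import MISSING, VcfParseError

HEADER = """##fileformat=VCFv4.2
##contig=<ID=1,length=100000>
##FILTER=<ID=lowDP,Description="x">
##INFO=<ID=DP,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsA\tsB\tsC
"""


def _write(tmp_path, body):
    path = tmp_path / "in.vcf"
    path.write_text(HEADER + body)
    return str(path)


class TestReadVcf:
    def test_dosages_and_missing(self, tmp_path):
        path = _write(
            tmp_path,
            "1\t100\t.\tA\tG\t60\tPASS\tDP=30\tGT\t0/1\t0/0\t0/0\n"
            "1\t200\t.\tC\tT\t60\tPASS\tDP=30\tGT\t1/1\t0/1\t./.\n",
        )
        sites, matrix = read_vcf(path)
        assert [s.pos for s in sites] == [100, 200]
        assert matrix.gt.tolist() == [[1, 0, 0], [2, 1, MISSING]]
        assert matrix.sample_ids == ["sA", "sB", "sC"]

    def test_multiallelic_and_indel_skipped(self, tmp_path):
        path = _write(
            tmp_path,
            "1\t100\t.\tA\tG,T\t60\tPASS\tDP=30\tGT\t0/1\t0/0\t0/0\n"
            "1\t200\t.\tAT\tA\t60\tPASS\tDP=30\tGT\t0/1\t0/0\t0/0\n"
            "1\t300\t.\tA\tC\t60\tPASS\tDP=30\tGT\t0/0\t0/1\t0/0\n",
        )
        sites, matrix = read_vcf(path)
        assert [s.pos for s in sites] == [300]
        assert matrix.n_sites == 1

    def test_filter_labels_parsed(self, tmp_path):
        path = _write(tmp_path, "1\t100\t.\tA\tG\t60\tlowDP\tDP=5\tGT\t0/1\t0/0\t0/0\n")
        sites, _ = read_vcf(path)
        assert sites[0].filters == {"lowDP"}

    def test_malformed_raises(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("this is not a vcf\n")
        with pytest.raises(VcfParseError):
            read_vcf(str(path))


class TestWriteVcf:
    def test_roundtrip_identity(self, tiny_params, tiny_sim, tmp_path):
        sites, matrix, _, _ = tiny_sim
        out = tmp_path / "rt.vcf"
        write_vcf(sites, matrix, str(out), chrom_lengths=tiny_params.chrom_lengths)
        sites2, matrix2 = read_vcf(str(out))
        assert sites == sites2
        assert np.array_equal(matrix.gt, matrix2.gt)
        assert np.array_equal(matrix.depth, matrix2.depth)

    def test_unsorted_input_written_sorted(self, tmp_path):
        sites = [
            SiteRecord(chrom="2", pos=5, ref="A", alt="G", qual=60.0),
            SiteRecord(chrom="1", pos=9, ref="C", alt="T", qual=60.0),
            SiteRecord(chrom="1", pos=3, ref="G", alt="A", qual=60.0),
        ]
        matrix = GenotypeMatrix(sample_ids=["a", "b"], gt=np.array([[0, 1], [1, 1], [2, 0]]))
        out = tmp_path / "sorted.vcf"
        write_vcf(sites, matrix, str(out))
        sites2, matrix2 = read_vcf(str(out))
        assert [(s.chrom, s.pos) for s in sites2] == [("1", 3), ("1", 9), ("2", 5)]
        assert matrix2.gt.tolist() == [[2, 0], [1, 1], [0, 1]]

    def test_empty_site_list_header_only(self, tmp_path):
        out = tmp_path / "empty.vcf"
        write_vcf([], GenotypeMatrix(sample_ids=["a"], gt=np.empty((0, 1))), str(out),
                  chrom_lengths={"1": 1000})
        sites, matrix = read_vcf(str(out))
        assert sites == [] and matrix.n_sites == 0

    def test_dimension_mismatch(self, tmp_path):
        sites = [SiteRecord(chrom="1", pos=1, ref="A", alt="G")]
        with pytest.raises(ValueError):
            write_vcf(sites, GenotypeMatrix(sample_ids=["a"], gt=np.empty((0, 1))), str(tmp_path / "x.vcf"))


def _benign(**kw):
    defaults = dict(chrom="1", pos=1000, ref="A", alt="G", qual=100.0,
                    info_dp=500.0, info_qd=10.0, info_mq0=0.0, info_sb=-1.0)
    defaults.update(kw)
    return SiteRecord(**defaults)


class TestHardFilters:
    @pytest.mark.parametrize(
        "kw,expected",
        [
            ({"info_dp": 9.0}, {"lowDP"}),
            ({"qual": 49.9}, {"lowQUAL"}),
            ({"info_qd": 1.49}, {"lowQD"}),
            ({"info_sb": -0.09}, {"highSB"}),
            ({"info_mq0": 4.0, "info_dp": 30.0}, {"highMQ0"}),  # 4/30 > 0.1
            ({"info_mq0": 4.0, "info_dp": 50.0}, set()),  # ratio 0.08, conjunction fails
            ({"info_mq0": 3.0, "info_dp": 10.0}, set()),  # MQ0 < 4, conjunction fails
        ],
    )
    def test_single_criteria(self, kw, expected):
        site = _benign(**kw)
        apply_filters([site])
        assert site.filters == expected

    def test_boundaries_are_strict(self):
        site = _benign(qual=50.0, info_qd=1.5, info_sb=-0.1, info_dp=10.0)
        apply_filters([site])
        assert site.passes

    def test_absent_metric_skips_criterion(self):
        site = _benign(info_dp=None)
        apply_filters([site])
        assert site.passes  # lowDP and highMQ0 both need DP

    def test_snp_cluster_examples(self):
        trio = [_benign(pos=p) for p in (100, 105, 109)]
        apply_filters(trio)
        assert all(s.filters == {"snpCluster"} for s in trio)
        spread = [_benign(pos=p) for p in (100, 105, 120)]
        apply_filters(spread)
        assert all(s.passes for s in spread)

    def test_cluster_respects_chromosomes(self):
        sites = [_benign(pos=100), _benign(pos=105), _benign(chrom="2", pos=109)]
        apply_filters(sites)
        assert all(s.passes for s in sites)

    @given(st.lists(st.integers(1, 300), min_size=1, max_size=40, unique=True),
           st.integers(2, 25), st.integers(2, 5))
    def test_cluster_matches_bruteforce_window_scan(self, positions, window, cluster_size):
        positions = sorted(positions)
        sites = [_benign(pos=p) for p in positions]
        apply_filters(sites, window=window, cluster_size=cluster_size)
        # oracle: a site fails iff some window [w, w+window-1] holds it plus
        # >= cluster_size sites in total
        expect = set()
        pos_set = positions
        for w in range(1, max(positions) + 1):
            inside = [p for p in pos_set if w <= p <= w + window - 1]
            if len(inside) >= cluster_size:
                expect.update(inside)
        got = {s.pos for s in sites if "snpCluster" in s.filters}
        assert got == expect

    def test_idempotent(self, tiny_sim):
        sites, _, _, _ = tiny_sim
        apply_filters(sites)
        once = [set(s.filters) for s in sites]
        apply_filters(sites)
        assert [set(s.filters) for s in sites] == once

    def test_pass_sites_subset_ordered(self, tiny_sim):
        sites, _, _, _ = tiny_sim
        apply_filters(sites)
        passed = pass_sites(sites)
        assert len(passed) <= len(sites)
        it = iter(sites)
        assert all(any(s is t for t in it) for s in passed)  # order preserved

    def test_pass_count_matches_bruteforce(self, study_sim):
        """Filter evaluation agrees with an independent re-evaluation."""
        sites, _, _, _ = study_sim
        sub = sites[:10_000]
        apply_filters(sub)
        # independent re-check of the numeric criteria, plain python
        n_pass_numeric = 0
        for s in sub:
            fail = (
                (s.info_dp is not None and s.info_dp < 10)
                or (s.qual is not None and s.qual < 50)
                or (s.info_qd is not None and s.info_qd < 1.5)
                or (s.info_sb is not None and s.info_sb > -0.1)
                or (s.info_mq0 is not None and s.info_dp is not None
                    and s.info_mq0 >= 4 and s.info_mq0 / s.info_dp > 0.1)
            )
            if not fail and "snpCluster" not in s.filters:
                n_pass_numeric += 1
        assert len(pass_sites(sub)) == n_pass_numeric
        summary = filter_summary(sub)
        assert summary["n_pass"] + summary["n_fail"] == len(sub)
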