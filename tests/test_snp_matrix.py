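import numpy as np
import pytest

import radpop as rp
from radpop.snp_matrix import (
    MISSING,
    SiteFilterSpec,
    allele_frequencies,
    filter_sites,
    read_vcf,
    write_vcf,
)

from conftest import make_matrix

VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\ts2
"""


def write_test_vcf(tmp_path, body, popmap=None):
    vcf = tmp_path / "test.vcf"
    vcf.write_text(VCF_HEADER + body)
    pm = tmp_path / "popmap.tsv"
    pm.write_text(popmap or "s0\tp1\ns1\tp1\ns2\tp2\n")
    return vcf, pm


class TestReadVcf:
    def test_gt_semantics(self, tmp_path):
        body = "chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT:DP\t0/1:9\t1|1:8\t./.:.\n"
        vcf, pm = write_test_vcf(tmp_path, body)
        gm = read_vcf(vcf, pm)
        assert gm.dosage[0, 0] == 1      # 0/1
        assert gm.dosage[0, 1] == 2      # 1|1 (phasing irrelevant)
        assert gm.dosage[0, 2] == MISSING

    def test_multiallelic_and_indels_skipped(self, tmp_path):
        lines = [
            f"chr1\t{100 + i}\t.\tA\tC\t.\tPASS\t.\tGT:DP\t0/1:9\t0/0:8\t1/1:7\n"
            for i in range(9)
        ]
        lines.insert(4, "chr1\t99\t.\tA\tC,G\t.\tPASS\t.\tGT:DP\t0/1:9\t0/0:8\t1/1:7\n")
        vcf, pm = write_test_vcf(tmp_path, "".join(lines))
        gm = read_vcf(vcf, pm)
        assert gm.n_sites == 9

    def test_sample_missing_from_popmap_raises(self, tmp_path):
        body = "chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT:DP\t0/1:9\t0/0:8\t1/1:7\n"
        vcf, pm = write_test_vcf(tmp_path, body, popmap="s0\tp1\ns1\tp1\n")
        with pytest.raises(ValueError, match="s2"):
            read_vcf(vcf, pm)

    def test_round_trip_preserves_dosage_and_depth(self, tmp_path, small_matrix):
        sub = small_matrix.take_sites(np.arange(50))
        path = tmp_path / "rt.vcf"
        write_vcf(sub, path)
        pm = tmp_path / "pm.tsv"
        pm.write_text("".join(f"{s}\t{p}\n" for s, p in sub.popmap.items()))
        back = read_vcf(path, pm)
        np.testing.assert_array_equal(back.dosage, sub.dosage)
        np.testing.assert_array_equal(back.depth, sub.depth)
        assert back.samples == sub.samples


def brute_force_filter(gm, spec):
    """Independent re-implementation of the filter rules, site by site."""
    keep = []
    depth_masked = np.where(
        (gm.depth != MISSING) & (gm.depth < spec.dp_min), MISSING, gm.dosage
    )
    dp_called = gm.depth != MISSING
    overall_mean_depth = gm.depth[dp_called].mean() if dp_called.any() else 0.0
    for i in range(gm.n_sites):
        row = depth_masked[i]
        called = row != MISSING
        if called.sum() / gm.n_samples < spec.call_rate_min:
            continue
        alt = row[called].sum()
        total = 2 * called.sum()
        if total == 0:
            continue
        maf = min(alt / total, 1 - alt / total)
        if maf < spec.maf_min:
            continue
        het = (row == 1).sum() / called.sum()
        d_row = gm.depth[i][gm.depth[i] != MISSING]
        mean_d = d_row.mean() if len(d_row) else 0.0
        if het > spec.dup_het_max or mean_d > spec.dup_depth_factor * overall_mean_depth:
            continue
        keep.append(i)
    return keep


class TestFilterSites:
    def test_call_rate_boundary_inclusive(self):
        # 10/14 samples called = 0.714 >= 0.7 -> kept
        row = [2] * 5 + [0] * 5 + [MISSING] * 4
        gm = make_matrix([row, [2] * 7 + [0] * 7])
        out, counts = filter_sites(gm, SiteFilterSpec(maf_min=0.0, call_rate_min=0.7))
        assert out.n_sites == 2 and counts["removed_call_rate"] == 0

    def test_call_rate_below_threshold_removed(self):
        row = [2] * 5 + [0] * 4 + [MISSING] * 5  # 0.643 < 0.7
        gm = make_matrix([row, [2] * 7 + [0] * 7])
        out, counts = filter_sites(gm, SiteFilterSpec(maf_min=0.0, call_rate_min=0.7))
        assert out.n_sites == 1 and counts["removed_call_rate"] == 1

    def test_maf_boundary_exact_count(self):
        # 50 diploids: 1 alt copy of 100 -> maf 0.01 kept at threshold 0.01
        site_keep = [1] + [0] * 49
        site_drop = [0] * 50  # maf 0 -> removed
        gm = make_matrix([site_keep, site_drop])
        out, counts = filter_sites(gm, SiteFilterSpec(maf_min=0.01, call_rate_min=0.0))
        assert out.n_sites == 1 and counts["removed_maf"] == 1

    def test_depth_masking_before_site_rules(self):
        dosage = [[1, 1, 1, 1]]
        depth = [[1, 1, 9, 9]]  # two genotypes below dp_min=2 get masked
        gm = make_matrix(dosage, depth)
        out, counts = filter_sites(
            gm, SiteFilterSpec(maf_min=0.0, call_rate_min=0.6, dp_min=2)
        )
        assert counts["genotypes_depth_masked"] == 2
        assert counts["removed_call_rate"] == 1  # call rate 0.5 < 0.6

    def test_duplicate_proxy_excess_heterozygosity(self):
        all_het = [1] * 10
        normal = [0, 0, 1, 2, 0, 1, 0, 0, 2, 1]
        gm = make_matrix([all_het, normal])
        out, counts = filter_sites(gm, SiteFilterSpec(maf_min=0.0, call_rate_min=0.0))
        assert counts["removed_duplicate_proxy"] == 1
        assert out.n_sites == 1

    def test_matches_brute_force_oracle_on_crafted_sites(self):
        rng = np.random.default_rng(23)
        dosage = rng.choice([0, 1, 2, MISSING], size=(20, 14), p=[0.4, 0.2, 0.2, 0.2])
        depth = rng.choice([0, 1, 2, 5, 30, 80], size=(20, 14))
        gm = make_matrix(dosage, depth)
        spec = SiteFilterSpec()
        out, _ = filter_sites(gm, spec)
        expected = brute_force_filter(gm, spec)
        np.testing.assert_array_equal(
            out.sites["pos"].to_numpy(), gm.sites["pos"].to_numpy()[expected]
        )

    def test_filtering_idempotent(self, small_matrix):
        spec = SiteFilterSpec()
        once, _ = filter_sites(small_matrix, spec)
        twice, counts = filter_sites(once, spec)
        assert twice.n_sites == once.n_sites
        np.testing.assert_array_equal(once.dosage, twice.dosage)

    def test_retained_sites_satisfy_thresholds_post_hoc(self, small_matrix):
        spec = SiteFilterSpec()
        out, _ = filter_sites(small_matrix, spec)
        called = out.dosage != MISSING
        call_rate = called.mean(axis=1)
        alt = np.where(called, out.dosage, 0).sum(axis=1)
        p = alt / (2 * called.sum(axis=1))
        maf = np.minimum(p, 1 - p)
        assert (call_rate >= spec.call_rate_min).all()
        assert (maf >= spec.maf_min).all()

    def test_empty_matrix_passes_through(self):
        gm = make_matrix(np.empty((0, 4), dtype=np.int8))
        out, counts = filter_sites(gm)
        assert out.n_sites == 0 and counts["kept"] == 0


class TestAlleleFrequencies:
    def test_simple_dosage_arithmetic(self):
        gm = make_matrix([[0, 1, 2]], pops=["p1", "p1", "p1"])
        freqs = allele_frequencies(gm)
        assert freqs.freq[0, 0] == pytest.approx(0.5)
        assert freqs.n_alleles[0, 0] == 6

    def test_all_missing_population_is_nan(self):
        gm = make_matrix(
            [[MISSING, MISSING, 1]], pops=["p1", "p1", "p2"]
        )
        freqs = allele_frequencies(gm)
        i = freqs.populations.index("p1")
        assert np.isnan(freqs.freq[0, i])
        assert freqs.n_alleles[0, i] == 0

    def test_matches_per_sample_loop_oracle(self, small_matrix):
        freqs = allele_frequencies(small_matrix)
        rng = np.random.default_rng(0)
        for i in rng.integers(0, small_matrix.n_sites, 50):
            for j, pop in enumerate(freqs.populations):
                alt = n = 0
                for k, s in enumerate(small_matrix.samples):
                    if small_matrix.popmap[s] != pop:
                        continue
                    d = small_matrix.dosage[i, k]
                    if d != MISSING:
                        alt += d
                        n += 2
                if n == 0:
                    assert np.isnan(freqs.freq[i, j])
                else:
                    assert freqs.freq[i, j] == pytest.approx(alt / n)

    def test_adding_alt_allele_never_decreases_freq(self):
        gm1 = make_matrix([[0, 1, 0]], pops=["p1"] * 3)
        gm2 = make_matrix([[0, 2, 0]], pops=["p1"] * 3)
        assert allele_frequencies(gm2).freq[0, 0] >= allele_frequencies(gm1).freq[0, 0]
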