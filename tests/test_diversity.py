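import itertools
import math

import numpy as np
import pytest
from scipy import stats

from poolsweep import diversity as d
from poolsweep import io as psio


def brute_force_pi(counts):
    """Oracle: average pairwise difference by explicit pair counting."""
    reads = []
    for base, n in zip("ATCG", counts):
        reads.extend([base] * n)
    c = len(reads)
    if c < 2:
        return float("nan")
    diff = sum(
        1 for a, b in itertools.combinations(reads, 2) if a != b
    )
    return diff / math.comb(c, 2)


class TestTajimaConstants:
    def test_a1_for_c50(self):
        # direct-summation oracle
        assert d.tajima_constants(50).a1 == pytest.approx(4.479205, abs=1e-6)

    def test_all_constants_small_n(self):
        n = 10
        k = d.tajima_constants(n)
        a1 = sum(1.0 / i for i in range(1, n))
        a2 = sum(1.0 / i**2 for i in range(1, n))
        assert k.a1 == pytest.approx(a1)
        assert k.a2 == pytest.approx(a2)
        assert k.b1 == pytest.approx((n + 1) / (3 * (n - 1)))
        assert k.e1 == pytest.approx((k.b1 - 1 / a1) / a1)

    def test_rejects_n1(self):
        with pytest.raises(ValueError):
            d.tajima_constants(1)


class TestSitePi:
    def test_25_25(self):
        # 625 discordant pairs out of C(50,2)=1225
        assert d.site_pi([25, 0, 25, 0]) == pytest.approx(625 / 1225)

    def test_monomorphic(self):
        assert d.site_pi([50, 0, 0, 0]) == 0.0

    def test_min_count_zeroes_rare_allele(self):
        assert d.site_pi([49, 0, 0, 1], min_count=2) == 0.0

    def test_below_two_reads_nan(self):
        assert math.isnan(d.site_pi([1, 0, 0, 0]))

    def test_exhaustive_oracle_up_to_c20(self):
        # every count vector over 4 alleles with 2 <= coverage <= 20
        for c in range(2, 21):
            for a in range(c + 1):
                for t in range(c - a + 1):
                    for g in range(c - a - t + 1):
                        counts = [a, t, g, c - a - t - g]
                        assert d.site_pi(counts, min_count=1) == pytest.approx(
                            brute_force_pi(counts)
                        ), counts


class TestSubsampleSite:
    params = d.SubsampleParams(target_coverage=50, max_coverage=100, seed=0)

    def test_insufficient(self):
        status, out = d.subsample_site([30, 0, 0, 0], self.params)
        assert status == d.SubsampleStatus.INSUFFICIENT and out is None

    def test_excluded_above_max(self):
        status, out = d.subsample_site([150, 0, 0, 0], self.params)
        assert status == d.SubsampleStatus.EXCLUDED and out is None

    def test_exact_target_passthrough(self):
        status, out = d.subsample_site([20, 30, 0, 0], self.params)
        assert status == d.SubsampleStatus.OK
        assert list(out) == [20, 30, 0, 0]

    def test_total_preserved_and_mean(self, rng):
        totals, a_vals = [], []
        for _ in range(2000):
            status, out = d.subsample_site([60, 40, 0, 0], self.params, rng=rng)
            assert status == d.SubsampleStatus.OK
            totals.append(out.sum())
            a_vals.append(out[0])
        assert set(totals) == {50}
        # hypergeometric mean 50*60/100 = 30, sd ~ 2.46
        assert np.mean(a_vals) == pytest.approx(30.0, abs=0.2)

    def test_chi2_goodness_of_fit(self, rng):
        # empirical distribution of drawn A-counts vs hypergeometric pmf
        n_rep = 10_000
        draws = np.empty(n_rep, dtype=int)
        for i in range(n_rep):
            _, out = d.subsample_site([60, 40, 0, 0], self.params, rng=rng)
            draws[i] = out[0]
        ks = np.arange(10, 51)
        pmf = stats.hypergeom.pmf(ks, 100, 60, 50)
        obs = np.bincount(draws, minlength=51)[10:51]
        keep = pmf * n_rep >= 5
        chi2, p = stats.chisquare(obs[keep], pmf[keep] / pmf[keep].sum() * obs[keep].sum())
        assert p > 0.001

    def test_deterministic_under_seed(self):
        s1 = d.subsample_site([60, 40, 0, 0], self.params)[1]
        s2 = d.subsample_site([60, 40, 0, 0], self.params)[1]
        assert np.array_equal(s1, s2)


class TestSubsamplePopulation:
    def test_statuses_and_totals(self, rng):
        counts = np.zeros((4, 1, 6), dtype=np.int64)
        counts[0, 0, 0] = 30     # insufficient
        counts[1, 0, 0] = 150    # excluded
        counts[2, 0, :4] = [20, 20, 5, 5]   # exact
        counts[3, 0, :4] = [40, 30, 20, 10]  # subsampled
        mat = psio.SyncMatrix(
            chroms=np.array(["s"] * 4, dtype=object),
            pos=np.arange(1, 5), ref=np.array(list("ACGT"), dtype=object),
            counts=counts,
        )
        params = d.SubsampleParams(seed=4)
        sub, status = d.subsample_population(mat, 0, params, rng=rng)
        assert list(status) == [
            d.SubsampleStatus.INSUFFICIENT, d.SubsampleStatus.EXCLUDED,
            d.SubsampleStatus.OK, d.SubsampleStatus.OK,
        ]
        assert sub[2].sum() == 50 and sub[3].sum() == 50
        assert (sub[3] <= counts[3, 0, :4]).all()

    def test_matches_marginal_hypergeometric(self):
        # vectorised path agrees with the scalar contract in distribution
        counts = np.zeros((5000, 1, 6), dtype=np.int64)
        counts[:, 0, :4] = [60, 40, 0, 0]
        mat = psio.SyncMatrix(
            chroms=np.array(["s"] * 5000, dtype=object),
            pos=np.arange(1, 5001),
            ref=np.array(["A"] * 5000, dtype=object),
            counts=counts,
        )
        sub, status = d.subsample_population(
            mat, 0, d.SubsampleParams(seed=8))
        assert (sub.sum(axis=1) == 50).all()
        assert sub[:, 0].mean() == pytest.approx(30.0, abs=0.15)
        assert sub[:, 0].std() == pytest.approx(
            math.sqrt(50 * 0.6 * 0.4 * 50 / 99), rel=0.1)


class TestWindowStats:
    def make_mat(self, site_counts, start_pos=1):
        n = len(site_counts)
        counts = np.zeros((n, 1, 6), dtype=np.int64)
        counts[:, 0, :4] = site_counts
        return psio.SyncMatrix(
            chroms=np.array(["s"] * n, dtype=object),
            pos=np.arange(start_pos, start_pos + n),
            ref=np.array(["A"] * n, dtype=object),
            counts=counts,
        )

    def test_zero_snps(self):
        mat = self.make_mat([[50, 0, 0, 0]] * 10)
        params = d.SubsampleParams(min_covered_fraction=0.001, seed=0)
        ws = d.window_stats(mat.pos, mat.counts[:, 0, :4],
                            np.zeros(10, dtype=np.int8), "s", 1, 10, params)
        assert ws.pi == 0.0 and ws.thetaW == 0.0
        assert math.isnan(ws.tajd)
        assert ws.n_snps == 0

    def test_manual_small_window(self):
        # 3 covered sites, one segregating (25A/25T)
        sites = [[50, 0, 0, 0], [25, 25, 0, 0], [50, 0, 0, 0]]
        mat = self.make_mat(sites)
        params = d.SubsampleParams(min_covered_fraction=0.001, seed=0)
        ws = d.window_stats(mat.pos, mat.counts[:, 0, :4],
                            np.zeros(3, dtype=np.int8), "s", 1, 3, params)
        k = d.tajima_constants(50)
        pi_site = 625 / 1225
        assert ws.pi == pytest.approx(pi_site / 3)
        assert ws.thetaW == pytest.approx(1 / (k.a1 * 3))
        expected_d = (pi_site - 1 / k.a1) / math.sqrt(k.e1)
        assert ws.tajd == pytest.approx(expected_d)

    def test_vectorised_agrees_with_scalar(self, small_sim):
        cfg, (mat, genes, ref, truth) = small_sim
        params = d.SubsampleParams(seed=13)
        rng = np.random.default_rng(13)
        sub, status = d.subsample_population(mat, 0, params, rng=rng)
        table = d.windowed_diversity(mat, 0, params, window=5000,
                                     sub=sub, status=status)
        for _, row in table.iterrows():
            ws = d.window_stats(mat.pos, sub, status, "scaffold_1",
                                int(row["start"]), int(row["end"]), params)
            assert ws.pi == pytest.approx(row["pi"])
            assert ws.thetaW == pytest.approx(row["thetaW"])
            assert ws.n_snps == row["snps"]
            if math.isnan(ws.tajd):
                assert math.isnan(row["tajd"])
            else:
                assert ws.tajd == pytest.approx(row["tajd"])

    def test_invalid_flag_below_covered_fraction(self):
        mat = self.make_mat([[50, 0, 0, 0]] * 3)
        params = d.SubsampleParams(min_covered_fraction=0.6, seed=0)
        ws = d.window_stats(mat.pos, mat.counts[:, 0, :4],
                            np.zeros(3, dtype=np.int8), "s", 1, 10, params)
        assert not ws.valid   # 3/10 covered < 0.6


class TestGenePi:
    def make_mat(self, length, snp_positions, coverage=60):
        counts = np.zeros((length, 1, 6), dtype=np.int64)
        counts[:, 0, 0] = coverage
        for p in snp_positions:
            counts[p - 1, 0, :4] = [coverage // 2, coverage - coverage // 2, 0, 0]
        return psio.SyncMatrix(
            chroms=np.array(["s"] * length, dtype=object),
            pos=np.arange(1, length + 1),
            ref=np.array(["A"] * length, dtype=object),
            counts=counts,
        )

    def test_no_snps_in_cds_pi_zero(self):
        mat = self.make_mat(120, snp_positions=[])
        gene = psio.GeneModel("g", "s", "+", [(1, 60)])
        gp = d.gene_pi(mat, 0, gene, d.SubsampleParams(seed=0))
        assert gp.pi == 0.0
        assert gp.usable

    def test_low_coverage_not_usable(self):
        mat = self.make_mat(120, snp_positions=[], coverage=40)
        gene = psio.GeneModel("g", "s", "+", [(1, 60)])
        gp = d.gene_pi(mat, 0, gene, d.SubsampleParams(
            target_coverage=30, seed=0))
        assert gp.mean_coverage == 40.0
        assert not gp.usable

    def test_two_exon_equals_concatenation(self):
        # coverage == target makes subsampling a deterministic passthrough
        params = d.SubsampleParams(seed=5)
        mat = self.make_mat(300, snp_positions=[10, 110], coverage=50)
        two_exon = psio.GeneModel("g2", "s", "+", [(1, 30), (101, 130)])
        single = psio.GeneModel("g1", "s", "+", [(1, 60)])
        gp2 = d.gene_pi(mat, 0, two_exon, params)
        mat_c = self.make_mat(300, snp_positions=[10, 50], coverage=50)
        gp1 = d.gene_pi(mat_c, 0, single, params)
        assert gp2.n_snps == gp1.n_snps == 2
        assert gp2.pi == pytest.approx(gp1.pi, rel=1e-12)

    def test_gene_outside_data_unusable(self):
        mat = self.make_mat(50, snp_positions=[])
        gene = psio.GeneModel("g", "s", "+", [(1000, 1059)])
        gp = d.gene_pi(mat, 0, gene, d.SubsampleParams(seed=0))
        assert not gp.usable
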