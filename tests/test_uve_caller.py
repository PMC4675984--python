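"""Beta-binomial HMM UVE caller: f_UV, training, emissions, segmentation."""

import itertools

import numpy as np
import pytest
from scipy import stats

from bruuv.annotations_io import (
    BinnedTrack,
    GeneModel,
    GeneSet,
    GenomicInterval,
)
from bruuv.uve_caller import (
    BetaParams,
    UveHmmConfig,
    UVEPeak,
    beta_binomial_log_pmf,
    collect_training_fuv,
    compute_fuv,
    filter_intergenic,
    fit_beta_by_moments,
    reflect_beta,
    segment_uve,
)


def pair(mock_vals, uv_vals, bin_width=250, total=None):
    m = np.asarray(mock_vals, float)
    u = np.asarray(uv_vals, float)
    mt = BinnedTrack(bin_width, {"chr1": m}, total or max(m.sum(), 1.0))
    ut = BinnedTrack(bin_width, {"chr1": u}, total or max(u.sum(), 1.0))
    return mt, ut


class TestComputeFuv:
    def test_basic_fractions(self):
        mt, ut = pair([8, 4, 3, 0], [0, 4, 9, 0])
        p = compute_fuv(mt, ut)
        f = p.fuv["chr1"]
        assert f[0] == 0.0
        assert f[1] == 0.5
        assert f[2] == pytest.approx(0.75)
        assert np.isnan(f[3])
        assert p.k["chr1"][2] == 9 and p.n["chr1"][2] == 12

    def test_rounding_keeps_k_le_n(self):
        mt, ut = pair([0.4, 0.5], [0.5, 0.4])
        p = compute_fuv(mt, ut)
        assert (p.k["chr1"] <= p.n["chr1"]).all()

    def test_mismatched_grids_rejected(self):
        mt, _ = pair([1, 2], [1, 2])
        _, ut = pair([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            compute_fuv(mt, ut)


class TestTrainingFuv:
    def _gene(self, length=40_000, start=0, strand="+", gid="g"):
        iv = GenomicInterval("chr1", start, start + length, strand)
        return GeneModel(gid, iv, iv.start if strand == "+" else iv.end - 1)

    def test_pooled_fraction_example(self):
        # two qualifying bins past 20 kb with (uv, mock) = (1,9) and (3,7)
        n_bins = 160  # 40 kb
        mock = np.zeros(n_bins)
        uv = np.zeros(n_bins)
        mock[:80] = 10.0  # keeps RPKM above threshold
        mock[100], uv[100] = 9.0, 1.0
        mock[101], uv[101] = 7.0, 3.0
        mt, ut = pair(mock, uv, total=1e5)
        p = compute_fuv(mt, ut)
        gs = GeneSet([self._gene()])
        vals = collect_training_fuv(p, gs, mt)
        assert vals == pytest.approx([4.0 / 20.0])

    def test_short_gene_contributes_nothing(self):
        mock = np.full(160, 5.0)
        mt, ut = pair(mock, mock, total=1e4)
        p = compute_fuv(mt, ut)
        gs = GeneSet([self._gene(length=15_000)])
        with pytest.raises(ValueError, match="cannot train"):
            collect_training_fuv(p, gs, mt)

    def test_low_rpkm_gene_excluded(self):
        mock = np.full(160, 5.0)
        mt, ut = pair(mock, mock, total=1e9)  # huge library -> tiny RPKM
        p = compute_fuv(mt, ut)
        gs = GeneSet([self._gene()])
        with pytest.raises(ValueError, match="cannot train"):
            collect_training_fuv(p, gs, mt)

    def test_minus_strand_uses_far_upstream_coordinates(self):
        # minus-strand gene: the 3' body lies at LOW coordinates
        n_bins = 200
        mock = np.zeros(n_bins)
        uv = np.zeros(n_bins)
        mock[:160] = 8.0
        uv[:80] = 2.0  # low-coordinate (3' body) bins carry some UV signal
        mt, ut = pair(mock, uv, total=1e5)
        p = compute_fuv(mt, ut)
        gs = GeneSet([self._gene(length=40_000, strand="-")])
        vals = collect_training_fuv(p, gs, mt)
        assert vals[0] == pytest.approx(2.0 / 10.0)


class TestBetaMoments:
    def test_symmetric_example(self):
        d = np.sqrt(0.025)
        p = fit_beta_by_moments([0.5 - d, 0.5, 0.5 + d])
        assert p.alpha == pytest.approx(4.5)
        assert p.beta == pytest.approx(4.5)
        # verify against the analytic beta mean/variance
        assert stats.beta.mean(p.alpha, p.beta) == pytest.approx(0.5)
        assert stats.beta.var(p.alpha, p.beta) == pytest.approx(0.025)

    def test_asymmetric_example(self):
        d = np.sqrt(0.016)
        p = fit_beta_by_moments([0.2 - d, 0.2, 0.2 + d])
        assert p.alpha == pytest.approx(1.8)
        assert p.beta == pytest.approx(7.2)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(42)
        draws = rng.beta(3.0, 7.0, 100_000)
        p = fit_beta_by_moments(draws)
        assert p.alpha == pytest.approx(3.0, rel=0.05)
        assert p.beta == pytest.approx(7.0, rel=0.05)

    def test_variance_bound_enforced(self):
        with pytest.raises(ValueError, match="Bernoulli"):
            fit_beta_by_moments([0.001, 0.999, 0.001, 0.999])
        with pytest.raises(ValueError):
            fit_beta_by_moments([0.3, 0.3, 0.3])


class TestReflection:
    def test_swap_and_fixed_point(self):
        assert reflect_beta(BetaParams(1.8, 7.2)) == BetaParams(7.2, 1.8)
        assert reflect_beta(BetaParams(4.5, 4.5)) == BetaParams(4.5, 4.5)

    def test_involution(self, rng):
        for _ in range(20):
            p = BetaParams(rng.uniform(0.1, 10), rng.uniform(0.1, 10))
            assert reflect_beta(reflect_beta(p)) == p


class TestBetaBinomialPmf:
    def test_uniform_case(self):
        p = BetaParams(1.0, 1.0)
        assert beta_binomial_log_pmf(1, 2, p) == pytest.approx(np.log(1 / 3))

    def test_empty_bin_probability_one(self):
        assert beta_binomial_log_pmf(0, 0, BetaParams(2.0, 3.0)) == 0.0

    @pytest.mark.parametrize("n,a,b", [(12, 1.8, 7.2), (5, 0.5, 0.5), (30, 4.5, 4.5)])
    def test_normalized(self, n, a, b):
        p = BetaParams(a, b)
        total = np.exp([beta_binomial_log_pmf(k, n, p) for k in range(n + 1)]).sum()
        assert total == pytest.approx(1.0)

    def test_matches_scipy_betabinom(self):
        p = BetaParams(1.8, 7.2)
        for n in (1, 7, 20):
            for k in range(n + 1):
                assert beta_binomial_log_pmf(k, n, p) == pytest.approx(
                    stats.betabinom.logpmf(k, n, p.alpha, p.beta)
                )

    def test_reflection_identity_exhaustive(self):
        for a, b in [(1.8, 7.2), (0.7, 3.1), (4.5, 4.5), (9.0, 0.4)]:
            p = BetaParams(a, b)
            r = reflect_beta(p)
            for n in range(31):
                ks = np.arange(n + 1)
                lhs = beta_binomial_log_pmf(ks, np.full(n + 1, n), r)
                rhs = beta_binomial_log_pmf(n - ks, np.full(n + 1, n), p)
                np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            beta_binomial_log_pmf(5, 3, BetaParams(1, 1))


def two_state_oracle(log_em, p):
    """Best score over all 2^L paths (uniform initial, symmetric transitions)."""
    L = log_em.shape[0]
    stay, switch = np.log1p(-p), np.log(p)
    best = -np.inf
    for path in itertools.product((0, 1), repeat=L):
        s = np.log(0.5) + log_em[0, path[0]]
        for t in range(1, L):
            s += (stay if path[t] == path[t - 1] else switch) + log_em[t, path[t]]
        best = max(best, s)
    return best


def path_log_prob(log_em, p, path):
    stay, switch = np.log1p(-p), np.log(p)
    s = np.log(0.5) + log_em[0, path[0]]
    for t in range(1, len(path)):
        s += (stay if path[t] == path[t - 1] else switch) + log_em[t, path[t]]
    return s


def make_paired(uv_counts, mock_counts, bin_width=250):
    from bruuv.uve_caller import PairedBinSeries

    u = np.asarray(uv_counts, float)
    m = np.asarray(mock_counts, float)
    tot = u + m
    f = np.full(u.shape, np.nan)
    f[tot > 0] = u[tot > 0] / tot[tot > 0]
    k = np.floor(u + 0.5).astype(np.int64)
    n = k + np.floor(m + 0.5).astype(np.int64)
    return PairedBinSeries(bin_width, {"chr1": m}, {"chr1": u}, {"chr1": f},
                           {"chr1": k}, {"chr1": n})


class TestSegmentation:
    uvr = BetaParams(1.8, 7.2)  # mean f_UV = 0.2

    def test_background_yields_no_peaks(self):
        uv = np.full(30, 2.0)
        mock = np.full(30, 8.0)  # f = 0.2 everywhere, the UVR mean
        paired = make_paired(uv, mock)
        _, peaks = segment_uve(paired, self.uvr, reflect_beta(self.uvr), 0.005)
        assert peaks == []

    def test_high_block_becomes_single_peak(self):
        uv = np.full(30, 2.0)
        mock = np.full(30, 8.0)
        uv[10:20], mock[10:20] = 18.0, 2.0  # f = 0.9 block
        paired = make_paired(uv, mock)
        _, peaks = segment_uve(paired, self.uvr, reflect_beta(self.uvr), 0.005)
        assert len(peaks) == 1
        assert (peaks[0].interval.start, peaks[0].interval.end) == (2500, 5000)
        assert peaks[0].n_bins == 10
        assert peaks[0].mean_fuv == pytest.approx(0.9)

    def test_two_blocks_two_peaks(self):
        uv = np.full(40, 2.0)
        mock = np.full(40, 8.0)
        for sl in (slice(5, 10), slice(20, 26)):
            uv[sl], mock[sl] = 18.0, 2.0
        paired = make_paired(uv, mock)
        _, peaks = segment_uve(paired, self.uvr, reflect_beta(self.uvr), 0.005)
        assert len(peaks) == 2
        assert peaks[0].interval.end <= peaks[1].interval.start

    def test_viterbi_matches_exhaustive_enumeration(self, rng):
        for _ in range(60):
            L = int(rng.integers(2, 13))
            n = rng.integers(5, 25, L)
            k = rng.binomial(n, rng.uniform(0.05, 0.95, L))
            paired = make_paired(k.astype(float), (n - k).astype(float))
            paths, _ = segment_uve(paired, self.uvr, reflect_beta(self.uvr), 0.005)
            log_em = np.stack(
                [
                    beta_binomial_log_pmf(k, n, self.uvr),
                    beta_binomial_log_pmf(k, n, reflect_beta(self.uvr)),
                ],
                axis=1,
            )
            assert path_log_prob(log_em, 0.005, paths["chr1"]) == pytest.approx(
                two_state_oracle(log_em, 0.005), abs=1e-9
            )

    def test_swapping_samples_complements_segmentation(self, rng):
        n = 2 * rng.integers(5, 20, 50) + 1  # odd totals: no tied emissions
        k = rng.binomial(n, np.where(rng.random(50) < 0.3, 0.9, 0.2))
        fwd = make_paired(k.astype(float), (n - k).astype(float))
        rev = make_paired((n - k).astype(float), k.astype(float))
        p_fwd, _ = segment_uve(fwd, self.uvr, reflect_beta(self.uvr), 0.005)
        # with the labels swapped the reflection identity makes the UVR
        # emissions of the swapped data equal the UVE emissions of the
        # original, so the same parameters segment it complementarily
        p_rev, _ = segment_uve(rev, self.uvr, reflect_beta(self.uvr), 0.005)
        np.testing.assert_array_equal(p_fwd["chr1"], 1 - p_rev["chr1"])

    def test_peaks_disjoint_ordered_grid_aligned(self, rng):
        n = rng.integers(5, 30, 200)
        k = rng.binomial(n, np.where(rng.random(200) < 0.2, 0.85, 0.15))
        paired = make_paired(k.astype(float), (n - k).astype(float))
        _, peaks = segment_uve(paired, self.uvr, reflect_beta(self.uvr), 0.005)
        prev_end = -1
        for p in peaks:
            assert p.interval.start % 250 == 0 and p.interval.end % 250 == 0
            assert p.interval.start >= prev_end
            prev_end = p.interval.end


class TestFilterIntergenic:
    def _peak(self, start, end):
        return UVEPeak(GenomicInterval("chr1", start, end), (end - start) // 250, 0.8)

    def test_overlap_rules(self):
        genes = [GenomicInterval("chr1", 10_000, 50_000)]
        peaks = [
            self._peak(20_000, 21_000),  # inside gene body
            self._peak(80_000, 81_000),  # far away
            self._peak(49_750, 50_750),  # shares 250 bp
            self._peak(50_000, 51_000),  # abuts: half-open, no overlap
        ]
        out = filter_intergenic(peaks, genes)
        assert [p.intergenic for p in out] == [False, True, False, True]

    def test_single_bp_overlap(self):
        peaks = [self._peak(999_750, 1_000_000)]
        excl = [GenomicInterval("chr1", 999_999, 1_050_000)]
        assert filter_intergenic(peaks, excl)[0].intergenic is False

    def test_intergenic_only_flag(self):
        peaks = [self._peak(0, 250), self._peak(1000, 1250)]
        excl = [GenomicInterval("chr1", 0, 500)]
        only = filter_intergenic(peaks, excl, intergenic_only=True)
        assert len(only) == 1 and only[0].interval.start == 1000
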