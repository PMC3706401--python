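import numpy as np
import pytest
from scipy import optimize

from epiqtl.core_map import kosambi_r_from_d
from epiqtl.sdl_model import ViabilityParams, genotype_frequencies
from epiqtl.sdl_scan import (SdlCountTable, correct_pairwise_r,
                             em_fit_sdl_at_markers, em_fit_sdl_interval,
                             epistasis_test_profiled, scan_pairs,
                             tabulate_counts)
from epiqtl.sdl_scan import test_distortion as distortion_lrt
from epiqtl.sdl_scan import test_epistasis as epistasis_lrt
from epiqtl.simulator import SimDesign, simulate_f2

from conftest import oracle_multinomial_negll


def expected_counts(u, v, x, r, N):
    return SdlCountTable(genotype_frequencies(
        ViabilityParams(u, v, x, r)).collapsed * N)


def oracle_mle(counts, r):
    """Direct numerical MLE of (u, v, x) on the observed-data multinomial
    likelihood, built on the enumeration oracle."""
    negll = oracle_multinomial_negll(counts.counts)
    best = None
    for start in ([1.0, 1.0, 1.0], [0.5, 0.5, 0.5], [2.0, 0.5, 1.0]):
        res = optimize.minimize(lambda th: negll(np.exp(th), r),
                                np.log(start), method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-13,
                                         "maxiter": 8000})
        if best is None or res.fun < best.fun:
            best = res
    return np.exp(best.x), -best.fun


class TestEmAtMarkers:
    def test_mendelian_expected_counts_recover_unity(self):
        counts = expected_counts(1, 1, 1, 0.25, 1600)
        fit = em_fit_sdl_at_markers(counts, r=0.25)
        assert fit.converged
        for val in (fit.u, fit.v, fit.x):
            assert val == pytest.approx(1.0, abs=1e-6)

    def test_recovers_generating_viabilities(self):
        counts = expected_counts(0.3615, 0.3615, 0.3615, 0.0906, 1e5)
        fit = em_fit_sdl_at_markers(counts, r=0.0906)
        assert fit.u == pytest.approx(0.3615, abs=1e-3)
        assert fit.v == pytest.approx(0.3615, abs=1e-3)
        assert fit.x == pytest.approx(0.3615, abs=1e-3)

    def test_monotone_loglik_trace(self, rng):
        for _ in range(10):
            n = rng.integers(0, 60, size=9).astype(float)
            if n.sum() == 0:
                continue
            fit = em_fit_sdl_at_markers(SdlCountTable(n), r=0.2,
                                        init=tuple(rng.uniform(0.2, 3, 3)))
            assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_matches_numeric_oracle_on_random_tables(self, rng):
        """EM estimates agree with a direct MLE of the observed-data
        multinomial likelihood (independent enumeration-based oracle)."""
        for _ in range(12):
            r = float(rng.uniform(0.05, 0.45))
            truth = rng.uniform(0.2, 2.0, 3)
            pi = genotype_frequencies(ViabilityParams(*truth, r)).collapsed
            n = rng.multinomial(400, pi).astype(float)
            if np.any(n.reshape(3, 3).sum(0) == 0) or \
               np.any(n.reshape(3, 3).sum(1) == 0):
                continue
            fit = em_fit_sdl_at_markers(SdlCountTable(n), r=r, tol=1e-12)
            est, ll_oracle = oracle_mle(SdlCountTable(n), r)
            if max(est.max(), fit.u, fit.v, fit.x) > 50:
                continue  # boundary table; both sit on the same boundary
            assert fit.loglik == pytest.approx(ll_oracle, abs=1e-4)
            assert np.array([fit.u, fit.v, fit.x]) == pytest.approx(
                est, abs=1e-3)

    def test_zero_double_homozygote_pushes_x_to_boundary(self):
        counts = expected_counts(1, 1, 1, 0.25, 400).counts
        counts[8] = 0.0  # remove every aabb individual
        fit = em_fit_sdl_at_markers(SdlCountTable(counts), r=0.25)
        est, _ = oracle_mle(SdlCountTable(counts), 0.25)
        assert fit.x == pytest.approx(est[2], abs=1e-3)
        assert fit.x < 0.9

    def test_relabelling_loci_swaps_u_v(self):
        counts = expected_counts(0.4, 0.8, 0.6, 0.15, 900)
        a = em_fit_sdl_at_markers(counts, r=0.15)
        b = em_fit_sdl_at_markers(counts.swapped_loci(), r=0.15)
        assert a.u == pytest.approx(b.v, abs=1e-6)
        assert a.v == pytest.approx(b.u, abs=1e-6)
        assert a.x == pytest.approx(b.x, abs=1e-6)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-8)

    def test_zero_total_count_rejected(self):
        with pytest.raises(ValueError):
            SdlCountTable(np.zeros(9))


class TestDistortionTest:
    def test_mendelian_counts_give_null_result(self):
        fit = em_fit_sdl_at_markers(expected_counts(1, 1, 1, 0.25, 1600),
                                    r=0.25)
        lrt, p = distortion_lrt(fit)
        assert lrt == pytest.approx(0.0, abs=1e-6)
        assert p > 0.99

    def test_selection_detected_at_n300(self):
        fit = em_fit_sdl_at_markers(
            expected_counts(0.3615, 0.3615, 0.3615, 0.0906, 300), r=0.0906)
        lrt, p = distortion_lrt(fit)
        assert p < 0.05


class TestEpistasisTest:
    def test_no_selection_gives_zero_lrt(self):
        fit = em_fit_sdl_at_markers(expected_counts(1, 1, 1, 0.2, 1000),
                                    r=0.2)
        lrt, _ = epistasis_lrt(fit)
        assert lrt == pytest.approx(0.0, abs=1e-4)

    def test_multiplicative_viabilities_give_zero_lrt(self):
        # x = u*v exactly: the constrained model contains the truth
        fit = em_fit_sdl_at_markers(
            expected_counts(0.5, 0.8, 0.4, 0.2, 5000), r=0.2)
        lrt, _ = epistasis_lrt(fit)
        assert lrt == pytest.approx(0.0, abs=1e-3)

    def test_type_one_error_near_nominal(self, rng):
        """Fixed-r epistasis LRT under a multiplicative-viability null."""
        pi = genotype_frequencies(ViabilityParams(0.7, 0.8, 0.56, 0.2)).collapsed
        rejections = 0
        trials = 120
        for _ in range(trials):
            n = rng.multinomial(300, pi).astype(float)
            fit = em_fit_sdl_at_markers(SdlCountTable(n), r=0.2)
            _, p = epistasis_lrt(fit)
            rejections += p < 0.05
        # binomial 99% band around 0.05 for 120 trials: [0, ~0.11]
        assert rejections / trials < 0.12

    def test_power_exceeds_size_for_epistatic_truth(self, rng):
        pi_alt = genotype_frequencies(ViabilityParams(1.0, 1.0, 0.2, 0.2)).collapsed
        rej = 0
        for _ in range(60):
            n = rng.multinomial(300, pi_alt).astype(float)
            fit = em_fit_sdl_at_markers(SdlCountTable(n), r=0.2)
            _, p = epistasis_lrt(fit)
            rej += p < 0.05
        assert rej / 60 > 0.3

    def test_profiled_variant_detects_strong_epistasis(self):
        # profiling r out of both hypotheses trades power for robustness
        # to map errors: the signal is attenuated but still present
        counts = expected_counts(1.0, 1.0, 0.2, 0.2, 2000)
        lrt, p = epistasis_test_profiled(counts, r_init=0.2)
        assert p < 0.01
        fixed_r_fit = em_fit_sdl_at_markers(counts, r=0.2)
        lrt_fixed, _ = epistasis_lrt(fixed_r_fit)
        assert lrt_fixed > lrt  # known r is strictly more informative


class TestJointRem:
    def test_mendelian_reduction_to_two_point(self):
        counts = expected_counts(1, 1, 1, 0.2, 10_000)
        fit = correct_pairwise_r(counts, r_init=0.35)
        assert fit.r == pytest.approx(0.2, abs=1e-6)
        for val in (fit.u, fit.v, fit.x):
            assert val == pytest.approx(1.0, abs=1e-4)

    def test_recovers_all_four_parameters(self):
        counts = expected_counts(0.5, 0.5, 0.5, 0.2, 1e6)
        fit = correct_pairwise_r(counts, r_init=0.3)
        assert fit.r == pytest.approx(0.2, abs=1e-3)
        assert fit.u == pytest.approx(0.5, abs=1e-3)
        assert fit.v == pytest.approx(0.5, abs=1e-3)
        assert fit.x == pytest.approx(0.5, abs=1e-3)

    def test_fix_viabilities_reduces_to_standard_em(self):
        counts = expected_counts(1, 1, 1, 0.12, 5000)
        fit = correct_pairwise_r(counts, r_init=0.3, fix_viabilities=True)
        assert fit.r == pytest.approx(0.12, abs=1e-6)
        assert fit.u == fit.v == fit.x == 1.0

    def test_unlinked_loci_flagged(self, rng):
        d = SimDesign(n=2000, n_markers=2, marker_spacing=1000.0,
                      qtl_pos=0.0, qtl_h2=0.0, sdl_pos=None, sdl_h2=None)
        g, y, lmap, _ = simulate_f2(d, seed=5)
        counts, _ = tabulate_counts(g, "m1", "m2")
        fit = correct_pairwise_r(counts, r_init=0.3)
        assert fit.r >= 0.49

    def test_monotone_loglik_trace(self, rng):
        for _ in range(5):
            n = rng.integers(1, 80, size=9).astype(float)
            fit = correct_pairwise_r(SdlCountTable(n), r_init=0.4)
            assert np.all(np.diff(fit.loglik_trace) >= -1e-8)


class TestIntervalEm:
    def test_matches_count_em_on_two_marker_map(self):
        """With no flanking markers the multipoint pair posterior carries
        exactly the information of the tabulated counts, so the interval
        EM and the count EM coincide."""
        d = SimDesign(n=400, n_markers=2, marker_spacing=10.0, qtl_pos=0.0,
                      qtl_h2=0.0, sdl_pos=(0.0, 10.0), sdl_h2=0.10)
        g, y, lmap, _ = simulate_f2(d, seed=23)
        counts, dropped = tabulate_counts(g, "m1", "m2")
        assert dropped == 0
        r = kosambi_r_from_d(10.0)
        at = em_fit_sdl_at_markers(counts, r=r)
        inter = em_fit_sdl_interval(g, lmap, "1", 0.0, 10.0)
        assert inter.u == pytest.approx(at.u, abs=1e-4)
        assert inter.v == pytest.approx(at.v, abs=1e-4)
        assert inter.x == pytest.approx(at.x, abs=1e-4)

    def test_close_to_count_em_with_flanking_markers(self, distorted_dataset):
        # flanking markers add phase information about the heterozygote
        # orders, so the interval EM is close to, but not identical to,
        # the marginal count EM
        g, y, lmap, truth = distorted_dataset
        counts, dropped = tabulate_counts(g, "m5", "m7")
        assert dropped == 0
        at = em_fit_sdl_at_markers(counts, r=kosambi_r_from_d(10.0))
        inter = em_fit_sdl_interval(g, lmap, "1", 20.0, 30.0)
        assert inter.u == pytest.approx(at.u, abs=0.05)
        assert inter.v == pytest.approx(at.v, abs=0.05)
        assert inter.x == pytest.approx(at.x, abs=0.05)

    def test_off_marker_fit_recovers_selection(self):
        g, y, lmap, truth = simulate_f2(SimDesign(n=2000, sdl_h2=0.10),
                                        seed=31)
        fit = em_fit_sdl_interval(g, lmap, "1", 21.0, 29.0)
        # selection at 20/30 seen from 21/29: strong viability deficit
        assert fit.converged
        assert fit.u < 0.7 and fit.v < 0.7 and fit.x < 0.7
        lrt = 2 * (fit.loglik - fit.loglik_null)
        assert lrt > 20

    def test_positions_outside_span_rejected(self, distorted_dataset):
        g, y, lmap, _ = distorted_dataset
        with pytest.raises(ValueError, match="span"):
            em_fit_sdl_interval(g, lmap, "1", 20.0, 150.0)
        with pytest.raises(ValueError, match="strictly less"):
            em_fit_sdl_interval(g, lmap, "1", 30.0, 30.0)

    def test_all_missing_individual_is_uninformative(self):
        g, y, lmap, _ = simulate_f2(SimDesign(n=120, sdl_h2=0.10), seed=17)
        codes = g.codes.copy()
        codes[0, :] = 5  # first individual fully missing
        from epiqtl.core_map import GenotypeMatrix
        g2 = GenotypeMatrix(codes, g.individuals, g.markers)
        f_all = em_fit_sdl_interval(g2, lmap, "1", 22.0, 28.0)
        g3 = GenotypeMatrix(codes[1:], g.individuals[1:], g.markers)
        f_rest = em_fit_sdl_interval(g3, lmap, "1", 22.0, 28.0)
        assert f_all.u == pytest.approx(f_rest.u, abs=5e-2)
        assert f_all.x == pytest.approx(f_rest.x, abs=5e-2)


class TestScanPairs:
    def test_significant_pairs_cover_sdl_region(self, distorted_dataset):
        g, y, lmap, truth = distorted_dataset
        scan = scan_pairs(g, lmap)
        sig = scan.table[scan.table["significant"]]
        assert len(sig) > 0
        # some significant pair straddles or touches the 20-30 cM region
        near = sig[(sig["posA"] <= 32.0) & (sig["posB"] >= 18.0)]
        assert len(near) > 0

    def test_single_marker_chromosome_skipped(self):
        from epiqtl.core_map import ChromosomeMap, GenotypeMatrix, LinkageMap
        lmap = LinkageMap([ChromosomeMap("1", ["only"], [0.0])])
        g = GenotypeMatrix(np.zeros((10, 1), dtype=np.int8),
                           [f"i{k}" for k in range(10)], ["only"])
        scan = scan_pairs(g, lmap)
        assert len(scan.table) == 0

    def test_unknown_adjustment_rejected(self, distorted_dataset):
        g, y, lmap, _ = distorted_dataset
        with pytest.raises(ValueError):
            scan_pairs(g, lmap, adjust="fancy")
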