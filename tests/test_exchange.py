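"""Exchange statistics: constructed examples, brute-force oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import poisson

from antiphony.exchange import (count_answers, cross_correlogram,
                                detect_antiphony, directionality_index,
                                overlap_rate, poisson_limits,
                                summarize_exchange)


def brute_correlogram(focal, partner, half=2.0, n_bins=100):
    """O(n·m) double-loop oracle with the half-open [left, right) convention."""
    edges = np.linspace(-half, half, n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    for t in focal:
        for u in partner:
            d = u - t
            if -half <= d < half:
                counts[np.searchsorted(edges, d, side="right") - 1] += 1
    return counts


class TestCorrelogram:
    def test_single_pair_lands_in_correct_bin(self):
        cg = cross_correlogram([10.0], [10.2])
        assert cg.counts.sum() == 1
        i = int(np.flatnonzero(cg.counts)[0])
        assert cg.bin_edges[i] == pytest.approx(0.20)
        assert cg.bin_edges[i + 1] == pytest.approx(0.24)

    def test_empty_partner_stream(self):
        cg = cross_correlogram([1.0, 2.0], [])
        assert cg.counts.sum() == 0 and cg.n_focal == 2

    def test_empty_focal_stream(self):
        cg = cross_correlogram([], [1.0, 2.0])
        assert cg.n_focal == 0 and cg.counts.sum() == 0

    def test_matches_brute_force_on_random_streams(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            f = np.sort(rng.uniform(0, 60, rng.integers(50, 200)))
            p = np.sort(rng.uniform(0, 60, rng.integers(50, 200)))
            cg = cross_correlogram(f, p)
            assert np.array_equal(cg.counts, brute_correlogram(f, p))

    def test_mirror_symmetry_under_role_swap(self):
        """cc(A, B) at lag τ equals cc(B, A) at −τ for generic (tie-free) times."""
        rng = np.random.default_rng(7)
        a = np.sort(rng.uniform(0, 50, 80))
        b = np.sort(rng.uniform(0, 50, 90))
        assert np.array_equal(cross_correlogram(a, b).counts,
                              cross_correlogram(b, a).counts[::-1])

    def test_edge_convention(self):
        # lag +2.0 excluded, −2.0 included
        assert cross_correlogram([0.0], [2.0]).counts.sum() == 0
        cg = cross_correlogram([2.0], [0.0])
        assert cg.counts.sum() == 1 and cg.counts[0] == 1

    def test_baseline_flanks(self):
        # lags −3 and +3 fall in the flanks, not the main window
        cg = cross_correlogram([10.0], [7.0, 13.0])
        assert cg.counts.sum() == 0
        assert cg.baseline_counts.sum() == 2
        assert cg.baseline_counts.size == 100


class TestCountAnswers:
    def test_answer_after_focal(self):
        assert count_answers([1.0], [1.3]) == (1, 0)

    def test_answered_before_focal(self):
        assert count_answers([1.0], [0.7]) == (0, 1)

    def test_zero_lag_counts_as_answered(self):
        assert count_answers([1.0], [1.0]) == (0, 1)

    def test_partner_call_assigned_to_nearest_focal_only(self):
        # partner at 1.4 is 0.4 after focal 1.0 and 0.1 before focal 1.5:
        # nearest is 1.5, so it is an answered call, counted once
        assert count_answers([1.0, 1.5], [1.4]) == (0, 1)

    def test_literal_all_pairs_mode_double_counts(self):
        assert count_answers([1.0, 1.5], [1.4], dedupe=False) == (1, 1)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation_each_partner_call_counted_at_most_once(self, seed):
        rng = np.random.default_rng(seed)
        f = np.sort(rng.uniform(0, 30, 40))
        p = np.sort(rng.uniform(0, 30, 40))
        n_ans, n_ansd = count_answers(f, p)
        assert n_ans + n_ansd <= p.size

    def test_recovers_configured_answer_probability(self):
        from antiphony.simulate import SimConfig, simulate_pair_calling
        cfg = SimConfig(duration_s=5000, base_rate_f=0.05, base_rate_m=0.05,
                        p_answer_f=0.0, p_answer_m=0.3, seed=11)
        s = simulate_pair_calling(cfg)
        f = s.female_events.onset_s.to_numpy()
        m = s.male_events.onset_s.to_numpy()
        n_ans, _ = count_answers(f, m)
        phat = n_ans / f.size
        tol = 3 * np.sqrt(0.3 * 0.7 / f.size)
        # chance coincidences add ≈ base_rate × window on top of p_answer
        assert phat == pytest.approx(0.3, abs=tol + 0.05 * 0.5)


class TestDirectionality:
    def test_equal_counts_give_zero(self):
        assert directionality_index(10, 10) == 0.0

    def test_simple_arithmetic(self):
        assert directionality_index(3, 1) == pytest.approx(0.5)

    def test_boundaries(self):
        assert directionality_index(0, 5) == -1.0
        assert directionality_index(5, 0) == 1.0

    def test_undefined_is_nan_not_zero(self):
        assert np.isnan(directionality_index(0, 0))

    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    def test_bounds_and_antisymmetry(self, a, b):
        if a + b == 0:
            return
        d = directionality_index(a, b)
        assert -1.0 <= d <= 1.0
        assert d == pytest.approx(-directionality_index(b, a))
        assert (d > 0) == (a > b)

    def test_role_swap_negates_index_on_event_streams(self):
        """Exact antisymmetry holds pair-for-pair in all-pairs counting mode
        (nearest-focal assignment depends on which stream is focal)."""
        rng = np.random.default_rng(3)
        f = np.sort(rng.uniform(0, 200, 150))
        m = np.sort(rng.uniform(0, 200, 140))
        s1 = summarize_exchange(f, m, dedupe=False)
        s2 = summarize_exchange(m, f, dedupe=False)
        assert s1.n_answers == s2.n_answered and s1.n_answered == s2.n_answers
        assert s1.directionality == pytest.approx(-s2.directionality)
        assert s1.directionality_display == pytest.approx(100 * s1.directionality)


class TestPoissonLimits:
    def test_degenerate_zero_rate(self):
        with pytest.warns(UserWarning):
            lo, up, lam = poisson_limits(np.zeros(100))
        assert (lo, up, lam) == (0, 0, 0.0)

    @pytest.mark.parametrize("lam", [0.5, 4.0, 18.0])
    @pytest.mark.parametrize("alpha", [0.05, 0.01])
    def test_limits_match_pmf_summation_oracle(self, lam, alpha):
        lo, up, lam_out = poisson_limits(np.full(50, lam), alpha=alpha)
        assert lam_out == pytest.approx(lam)
        # oracle: accumulate the pmf directly
        k, cdf = 0, poisson.pmf(0, lam)
        while cdf < 1 - alpha / 2:
            k += 1
            cdf += poisson.pmf(k, lam)
        assert up == k
        k, cdf = 0, poisson.pmf(0, lam)
        while cdf < alpha / 2:
            k += 1
            cdf += poisson.pmf(k, lam)
        assert lo == k

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            poisson_limits([])


class TestDetectAntiphony:
    def test_coupled_pair_detected_with_plausible_latency(self):
        from antiphony.simulate import SimConfig, simulate_pair_calling
        cfg = SimConfig(duration_s=3600, p_answer_f=0.4, p_answer_m=0.4, seed=5)
        s = simulate_pair_calling(cfg)
        cg = cross_correlogram(s.female_events.onset_s.to_numpy(),
                               s.male_events.onset_s.to_numpy())
        det = detect_antiphony(cg, alpha=0.01)
        assert det.is_antiphonal
        # latency distribution Gamma(4, 0.05) has its mode near 0.15 s
        assert 0.1 <= det.peak_latency_s <= 0.25

    def test_single_over_threshold_bin_gives_its_center(self):
        cg = cross_correlogram([10.0], [10.22])
        cg.baseline_counts = np.zeros(100, dtype=int)
        cg.baseline_counts[:50] = 0
        with pytest.warns(UserWarning):
            det = detect_antiphony(cg)
        assert det.is_antiphonal
        assert det.peak_latency_s == pytest.approx(0.22, abs=0.021)

    def test_all_zero_correlogram_is_not_antiphonal(self):
        cg = cross_correlogram([], [])
        cg.baseline_counts = np.full(100, 2)
        det = detect_antiphony(cg)
        assert not det.is_antiphonal and np.isnan(det.peak_latency_s)


class TestOverlapRate:
    def test_disjoint_and_identical(self):
        assert overlap_rate([0.0], [0.1], [1.0], [0.1]) == 0.0
        on = [0.0, 2.0, 4.0]
        dur = [0.5, 0.5, 0.5]
        assert overlap_rate(on, dur, on, dur) == 1.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        f_on = np.sort(rng.uniform(0, 50, 120))
        f_du = rng.uniform(0.05, 0.3, 120)
        p_on = np.sort(rng.uniform(0, 50, 130))
        p_du = rng.uniform(0.05, 0.3, 130)
        got = overlap_rate(f_on, f_du, p_on, p_du)
        brute = np.mean([
            any(a < po + pd_ and po < a + ad for po, pd_ in zip(p_on, p_du))
            for a, ad in zip(f_on, f_du)])
        assert got == pytest.approx(brute)

    def test_missing_durations_error(self):
        with pytest.raises(ValueError, match="onset-only"):
            overlap_rate([1.0], [np.nan], [2.0], [0.1])
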