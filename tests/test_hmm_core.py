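import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import (
    oracle_expected_stats,
    oracle_log_Z,
    oracle_map_path,
    oracle_posteriors,
    path_posterior_score,
)
from squigseg.errors import BandError, InfeasibleReadError, InputError, NumericalConsistencyError
from squigseg.hmm_core import (
    TransitionParams,
    backward_pass,
    emission_logpdf,
    forward_backward,
    forward_pass,
    make_band,
    map_segmentation,
    posterior,
)
from squigseg.pore_model import SignalRead


def _random_instance(rng, model, n_max=3, T_max=8):
    n = int(rng.integers(1, n_max + 1))
    T = int(rng.integers(2 * n, T_max + 1))
    kmers = rng.integers(0, model.n_kmers, size=n)
    samples = rng.normal(rng.choice(model.means[kmers], size=T), 3.0)
    params = TransitionParams(float(rng.uniform(0.1, 0.9)))
    return SignalRead("r", samples, normalized=True), kmers, params


class TestTransitionParams:
    def test_e2_is_complement_of_a1(self):
        p = TransitionParams(0.3)
        assert math.isclose(p.a1 + p.e2, 1.0, abs_tol=1e-12)
        assert p.e1 == 1.0

    @pytest.mark.parametrize("a1", [0.0, 1.5, -0.1])
    def test_out_of_range_rejected(self, a1):
        with pytest.raises(InputError):
            TransitionParams(a1)

    def test_inconsistent_e2_rejected(self):
        with pytest.raises(InputError):
            TransitionParams(0.3, e2=0.5)


class TestEmission:
    def test_mode_value(self, toy1):
        # at t = mu with sigma 1 the log-density is -0.5*ln(2*pi)
        assert math.isclose(
            emission_logpdf(0.0, 0, toy1), -0.5 * math.log(2 * math.pi), abs_tol=1e-12
        )

    def test_one_sigma_identity(self, toy1):
        mode = emission_logpdf(10.0, 1, toy1)
        assert math.isclose(emission_logpdf(11.0, 1, toy1), mode - 0.5, abs_tol=1e-12)

    def test_hand_substitution(self):
        # t=0, mu=2, sigma=2: ln(phi) = -0.5 - ln(2*sqrt(2*pi))
        from squigseg.pore_model import KmerModel

        model = KmerModel(
            k=1, kmers=("A", "C", "G", "T"),
            means=np.array([2.0, 0.0, 0.0, 0.0]), stdvs=np.array([2.0, 1, 1, 1]),
        )
        expected = -0.5 - math.log(2 * math.sqrt(2 * math.pi))
        assert math.isclose(emission_logpdf(0.0, 0, model), expected, abs_tol=1e-12)

    def test_non_finite_sample_rejected(self, toy1):
        with pytest.raises(InputError):
            emission_logpdf(float("nan"), 0, toy1)


class TestForwardPass:
    def test_single_kmer_two_samples_closed_form(self, toy1):
        # unique path A,E at the mode: log_Z = 2 * (-0.5 ln 2pi) = -ln(2pi)
        sig = SignalRead("r", np.array([0.0, 0.0]), normalized=True)
        res = forward_pass(sig, np.array([0]), TransitionParams(0.5), toy1)
        assert math.isclose(res.log_Z, -math.log(2 * math.pi), abs_tol=1e-12)

    def test_two_kmer_instance_matches_enumeration(self, toy1):
        sig = SignalRead("r", np.array([0.0, 0.0, 10.0, 10.0]), normalized=True)
        kmers = np.array([0, 1])
        params = TransitionParams(0.5)
        res = forward_pass(sig, kmers, params, toy1)
        assert math.isclose(
            res.log_Z, oracle_log_Z(sig.samples, kmers, params, toy1), abs_tol=1e-9
        )

    def test_infeasible_signal_rejected(self, toy1):
        sig = SignalRead("r", np.zeros(3), normalized=True)
        with pytest.raises(InfeasibleReadError):
            forward_pass(sig, np.array([0, 1]), TransitionParams(0.5), toy1)

    @pytest.mark.parametrize("trial", range(20))
    def test_log_Z_matches_enumeration_on_random_instances(self, toy1_noisy, trial):
        rng = np.random.default_rng(1000 + trial)
        sig, kmers, params = _random_instance(rng, toy1_noisy)
        res = forward_pass(sig, kmers, params, toy1_noisy)
        expected = oracle_log_Z(sig.samples, kmers, params, toy1_noisy)
        assert math.isclose(res.log_Z, expected, abs_tol=1e-9)


class TestBackwardPass:
    def test_single_path_origin_score(self, toy1):
        # beta at the origin is the total path log-probability minus the
        # origin emission; log_Z* adds it back
        sig = SignalRead("r", np.array([0.0, 0.0]), normalized=True)
        params = TransitionParams(0.5)
        res = backward_pass(sig, np.array([0]), params, toy1)
        em0 = emission_logpdf(0.0, 0, toy1)
        total = -math.log(2 * math.pi)  # from the forward closed form
        assert math.isclose(res.log_backward_A[0, 0], total - em0, abs_tol=1e-12)
        assert math.isclose(res.log_Z_star, total, abs_tol=1e-12)

    @pytest.mark.parametrize("trial", range(10))
    def test_forward_backward_scores_agree(self, toy1_noisy, trial):
        rng = np.random.default_rng(2000 + trial)
        sig, kmers, params = _random_instance(rng, toy1_noisy)
        res = forward_backward(sig, kmers, params, toy1_noisy)
        assert abs(res.log_Z - res.log_Z_star) <= 1e-6

    def test_out_of_band_cells_are_neg_inf(self, toy1):
        sig = SignalRead("r", np.array([0.0, 0.0, 10.0, 10.0]), normalized=True)
        kmers = np.array([0, 1])
        band = make_band(4, 2, 0)
        res = forward_backward(sig, kmers, TransitionParams(0.5), toy1, band)
        mask = band.as_mask()
        for mat in (res.log_forward_A, res.log_forward_E,
                    res.log_backward_A, res.log_backward_E):
            assert np.all(np.isneginf(mat[~mask]))


class TestPosterior:
    def test_single_path_posteriors_are_indicator(self, toy1):
        sig = SignalRead("r", np.array([0.0, 0.0]), normalized=True)
        res = forward_backward(sig, np.array([0]), TransitionParams(0.5), toy1)
        post = posterior(res)
        assert math.isclose(post.post_A[0, 0], 1.0, abs_tol=1e-9)
        assert math.isclose(post.post_E[0, 1], 1.0, abs_tol=1e-9)
        assert post.post_A[0, 1] < 1e-12 and post.post_E[0, 0] < 1e-12

    def test_cells_match_enumerated_path_weights(self, toy1):
        sig = SignalRead("r", np.array([0.0, 0.0, 10.0, 10.0]), normalized=True)
        kmers = np.array([0, 1])
        params = TransitionParams(0.5)
        post = posterior(forward_backward(sig, kmers, params, toy1))
        pA, pE, _ = oracle_posteriors(sig.samples, kmers, params, toy1)
        assert np.allclose(post.post_A, pA, atol=1e-9)
        assert np.allclose(post.post_E, pE, atol=1e-9)

    @pytest.mark.parametrize("trial", range(10))
    def test_column_sums_and_A_mass(self, toy1_noisy, trial):
        rng = np.random.default_rng(3000 + trial)
        sig, kmers, params = _random_instance(rng, toy1_noisy, n_max=4, T_max=16)
        post = posterior(forward_backward(sig, kmers, params, toy1_noisy))
        col = (post.post_A + post.post_E).sum(axis=0)
        assert np.allclose(col, 1.0, atol=1e-6)
        # every path visits A exactly once per k-mer
        assert math.isclose(post.post_A.sum(), kmers.size, abs_tol=1e-6)

    def test_large_drift_is_an_error(self, toy1):
        sig = SignalRead("r", np.array([0.0, 0.0]), normalized=True)
        res = forward_backward(sig, np.array([0]), TransitionParams(0.5), toy1)
        res.log_Z -= 1.0  # corrupt the normalizer
        with pytest.raises(NumericalConsistencyError):
            posterior(res)


class TestMapSegmentation:
    def test_single_kmer_forced_path(self, toy1):
        sig = SignalRead("r", np.zeros(5), normalized=True)
        post = posterior(forward_backward(sig, np.array([0]), TransitionParams(0.5), toy1))
        seg = map_segmentation(post, model=toy1)
        assert len(seg) == 1
        assert (seg.segments[0].signal_start, seg.segments[0].signal_end) == (0, 5)

    def test_two_kmer_boundary_matches_oracle(self, toy1):
        sig = SignalRead("r", np.array([0.0, 0.0, 10.0, 10.0]), normalized=True)
        kmers = np.array([0, 1])
        params = TransitionParams(0.5)
        post = posterior(forward_backward(sig, kmers, params, toy1))
        seg = map_segmentation(post, model=toy1)
        assert seg.segments[1].signal_start == 2
        best, _ = oracle_map_path(sig.samples, kmers, params, toy1)
        assert tuple(len(s) for s in seg) == best

    @pytest.mark.parametrize("trial", range(25))
    def test_decode_attains_oracle_optimum(self, toy1_noisy, trial):
        rng = np.random.default_rng(4000 + trial)
        sig, kmers, params = _random_instance(rng, toy1_noisy)
        post = posterior(forward_backward(sig, kmers, params, toy1_noisy))
        seg = map_segmentation(post, model=toy1_noisy)
        dwells = tuple(len(s) for s in seg)
        pA, pE, _ = oracle_posteriors(sig.samples, kmers, params, toy1_noisy)
        _, best_score = oracle_map_path(sig.samples, kmers, params, toy1_noisy)
        assert path_posterior_score(dwells, pA, pE) >= best_score - 1e-9

    def test_tie_break_prefers_extending(self, toy1):
        # two identical k-mers on a symmetric signal: (4,3) and (3,4) tie;
        # prefer-extend keeps the first segment longer (later boundary)
        sig = SignalRead("r", np.zeros(7), normalized=True)
        kmers = np.array([0, 0])
        params = TransitionParams(0.5)
        post = posterior(forward_backward(sig, kmers, params, toy1))
        seg = map_segmentation(post, model=toy1)
        dwells = tuple(len(s) for s in seg)
        best, _ = oracle_map_path(sig.samples, kmers, params, toy1)
        assert dwells == best
        assert dwells[0] >= dwells[1]  # later boundary, not the mirror path

    @pytest.mark.parametrize("trial", range(15))
    def test_minimum_segment_length_two(self, toy1_noisy, trial):
        rng = np.random.default_rng(5000 + trial)
        sig, kmers, params = _random_instance(rng, toy1_noisy, n_max=4, T_max=20)
        post = posterior(forward_backward(sig, kmers, params, toy1_noisy))
        seg = map_segmentation(post, model=toy1_noisy)
        assert all(len(s) >= 2 for s in seg)
        # contiguity and coverage
        assert seg.segments[0].signal_start == 0
        assert seg.segments[-1].signal_end == len(sig)
        for a, b in zip(seg.segments, seg.segments[1:]):
            assert a.signal_end == b.signal_start


class TestBand:
    def test_full_band_admits_everything(self):
        band = make_band(10, 5, "full")
        assert band.as_mask().all()

    def test_zero_width_follows_rounded_diagonal(self):
        band = make_band(10, 5, 0)
        # round(i*4/9) for i = 0..9 (half-even; no halves occur here)
        expected = [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]
        assert band.lo.tolist() == expected
        assert band.hi.tolist() == expected

    def test_wide_band_clamps_to_full(self):
        band = make_band(10, 5, 5)
        assert band.is_full

    def test_band_contains_origin_and_terminal(self, rng):
        for _ in range(20):
            T = int(rng.integers(2, 50))
            n = int(rng.integers(1, 20))
            w = int(rng.integers(0, 4))
            band = make_band(T, n, w)
            assert band.contains(0, 0)
            assert band.contains(n - 1, T - 1)

    def test_full_band_bit_identical_to_unbanded(self, toy1_noisy):
        rng = np.random.default_rng(77)
        sig, kmers, params = _random_instance(rng, toy1_noisy, n_max=3, T_max=12)
        res_none = forward_backward(sig, kmers, params, toy1_noisy)
        res_full = forward_backward(
            sig, kmers, params, toy1_noisy, make_band(len(sig), kmers.size, "full")
        )
        assert np.array_equal(res_none.log_forward_E, res_full.log_forward_E)
        assert res_none.log_Z == res_full.log_Z

    @pytest.mark.parametrize("trial", range(10))
    def test_log_Z_monotone_in_band_width(self, toy1_noisy, trial):
        rng = np.random.default_rng(6000 + trial)
        sig, kmers, params = _random_instance(rng, toy1_noisy, n_max=4, T_max=16)
        prev = -np.inf
        for w in range(0, kmers.size + 1):
            res = forward_pass(
                sig, kmers, params, toy1_noisy, make_band(len(sig), kmers.size, w)
            )
            assert res.log_Z >= prev - 1e-12
            prev = res.log_Z

    def test_band_excluding_terminal_rejected(self, toy1):
        band = make_band(4, 2, 0)
        object.__setattr__(band, "hi", np.array([0, 0, 0, 0]))
        sig = SignalRead("r", np.zeros(4), normalized=True)
        with pytest.raises(BandError):
            forward_pass(sig, np.array([0, 1]), TransitionParams(0.5), toy1, band)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_forward_backward_consistency_property(seed):
    """|log_Z - log_Z*| <= 1e-6 over randomized feasible instances."""
    from squigseg.pore_model import toy_model

    model = toy_model(1, level_min=0.0, spacing=5.0, stdv=2.0)
    rng = np.random.default_rng(seed)
    sig, kmers, params = _random_instance(rng, model, n_max=5, T_max=24)
    res = forward_backward(sig, kmers, params, model)
    assert abs(res.log_Z - res.log_Z_star) <= 1e-6


def test_expected_transition_stats_match_enumeration(toy1):
    """Posterior-weighted transition expectations equal the enumeration's
    path-weighted counts on the two-k-mer instance."""
    from squigseg.train import expected_counts

    sig = SignalRead("r", np.array([0.0, 0.0, 10.0, 10.0]), normalized=True)
    kmers = np.array([0, 1])
    params = TransitionParams(0.5)
    res = forward_backward(sig, kmers, params, toy1)
    post = posterior(res)
    stats = expected_counts(post, res, params, toy1, sig)
    expected = oracle_expected_stats(sig.samples, kmers, params, toy1)
    assert math.isclose(stats.exp_a1_uses, expected["a1_uses"], abs_tol=1e-9)
    assert math.isclose(stats.exp_e2_uses, expected["e2_uses"], abs_tol=1e-9)
    assert math.isclose(stats.exp_E_occupancy, expected["E_occupancy"], abs_tol=1e-9)
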