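"""Core model: kernels, stimulus trains, history filtering, design, intensity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import acuglm as a
from acuglm.glm import conditional_intensity
from acuglm.kernels import kernels_from_meta, make_kernels


def brute_force_history(counts, kernel):
    """Independent O(n*m) double-loop convolution oracle."""
    out = np.zeros(len(counts))
    for t in range(len(counts)):
        for tau in range(1, len(kernel)):
            if t - tau >= 0:
                out[t] += kernel[tau] * counts[t - tau]
    return out


class TestKernels:
    def test_history_kernel_is_strictly_causal(self, kernels):
        assert kernels.hist[0] == 0.0

    def test_history_kernel_net_inhibitory(self, kernels):
        # refractory area twice the facilitation area by construction
        assert kernels.hist.sum() < 0
        assert kernels.hist.max() > 0  # facilitation lobe present

    def test_stim_kernel_shape(self, kernels):
        assert kernels.stim[0] == kernels.stim.max()  # fast lobe peaks at lag 0
        assert kernels.stim.min() < 0  # depletion window
        # depletion has recovered by the end of the support
        assert abs(kernels.stim[-1]) < 0.05

    def test_meta_round_trip(self, kernels):
        rebuilt = kernels_from_meta(kernels.meta)
        np.testing.assert_array_equal(rebuilt.stim, kernels.stim)
        np.testing.assert_array_equal(rebuilt.hist, kernels.hist)

    def test_nonzero_lag0_rejected(self):
        with pytest.raises(ValueError, match="lag-0"):
            a.KernelSet(dt=1e-3, stim=np.ones(3), hist=np.ones(3))


class TestStimulusTrain:
    @pytest.mark.parametrize(
        "freq,duration,expected_events",
        [(100, 60, 100), (0, 60, 0), (30, 60, 30), (150, 60, 150), (120, 60, 120)],
    )
    def test_periodic_event_counts(self, kernels, freq, duration, expected_events):
        stim = a.make_stimulus_train(freq, duration, 1e-3, kernels)
        assert stim.event_bins.size == expected_events
        if freq == 0:
            assert not stim.x.any()

    def test_event_spacing(self, kernels):
        stim = a.make_stimulus_train(30, 60, 1e-3, kernels)
        assert (np.diff(stim.event_bins) == 2000).all()  # 2 s spacing at 1 ms bins

    def test_covariate_is_kernel_convolution(self, kernels):
        stim = a.make_stimulus_train(60, 10, 1e-3, kernels)
        ind = np.zeros(stim.grid.n_bins)
        ind[stim.event_bins] = 1
        np.testing.assert_allclose(stim.x, np.convolve(ind, kernels.stim)[: ind.size])

    @pytest.mark.parametrize("bad", [dict(duration_s=0), dict(dt=0), dict(freq_per_min=-5)])
    def test_invalid_arguments(self, kernels, bad):
        kw = dict(freq_per_min=100, duration_s=60, dt=1e-3)
        kw.update(bad)
        with pytest.raises(ValueError):
            a.make_stimulus_train(kernels=kernels, **kw)

    def test_aliasing_rejected(self, kernels):
        # period shorter than one bin
        with pytest.raises(ValueError, match="period"):
            a.make_stimulus_train(120000, 1.0, 1e-3, kernels)


class TestFilterHistory:
    def test_zero_counts_zero_covariate(self, kernels):
        assert not a.filter_history(np.zeros(50), kernels.hist).any()

    def test_impulse_response(self, kernels):
        counts = np.zeros(200)
        counts[30] = 1
        out = a.filter_history(counts, kernels.hist)
        expect = np.zeros(200)
        m = min(kernels.hist.size - 1, 200 - 31)
        expect[31 : 31 + m] = kernels.hist[1 : 1 + m]
        np.testing.assert_allclose(out, expect)
        assert out[30] == 0.0  # no same-bin feedback

    def test_output_starts_at_zero(self, kernels):
        counts = np.ones(10)
        assert a.filter_history(counts, kernels.hist)[0] == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(min_value=0, max_value=3), min_size=5, max_size=50),
        kern=st.lists(
            st.floats(min_value=-2, max_value=2, allow_nan=False), min_size=2, max_size=12
        ),
    )
    def test_matches_double_loop_oracle(self, counts, kern):
        kern = np.array([0.0] + kern)
        counts = np.array(counts, dtype=float)
        np.testing.assert_allclose(
            a.filter_history(counts, kern), brute_force_history(counts, kern), atol=1e-12
        )

    def test_rejects_instantaneous_feedback(self):
        with pytest.raises(ValueError, match="causality"):
            a.filter_history(np.ones(5), np.array([0.5, 0.2]))


class TestDesignMatrix:
    def test_column_layout(self, toy_problem, tiny_kernels):
        stim, spikes, design = toy_problem
        assert design.X.shape == (20, 4)
        np.testing.assert_array_equal(design.X[:, 0], stim.x)
        for j in range(3):
            np.testing.assert_allclose(
                design.X[:, j + 1], brute_force_history(spikes.counts[j], tiny_kernels.hist)
            )

    def test_empty_spikes_give_zero_history(self, kernels):
        stim = a.make_stimulus_train(60, 1, 1e-3, kernels)
        spikes = a.SpikeTrainSet(grid=stim.grid, counts=np.zeros((2, 1000), dtype=np.int64))
        design = a.build_design(stim, spikes, kernels)
        assert not design.X[:, 1:].any()
        np.testing.assert_array_equal(design.X[:, 0], stim.x)

    def test_single_neuron_two_columns(self, kernels):
        stim = a.make_stimulus_train(60, 1, 1e-3, kernels)
        spikes = a.SpikeTrainSet(grid=stim.grid, counts=np.ones((1, 1000), dtype=np.int64))
        assert a.build_design(stim, spikes, kernels).X.shape == (1000, 2)

    def test_grid_mismatch_rejected(self, kernels):
        stim = a.make_stimulus_train(60, 1, 1e-3, kernels)
        other = a.TimeGrid(dt=1e-3, n_bins=500)
        spikes = a.SpikeTrainSet(grid=other, counts=np.zeros((1, 500), dtype=np.int64))
        with pytest.raises(ValueError, match="grid"):
            a.build_design(stim, spikes, kernels)

    def test_causality_under_perturbation(self, toy_problem, tiny_kernels):
        stim, spikes, design = toy_problem
        t = 10
        bumped = spikes.counts.copy()
        bumped[1, t] += 1
        design2 = a.build_design(
            stim, a.SpikeTrainSet(grid=spikes.grid, counts=bumped), tiny_kernels
        )
        np.testing.assert_array_equal(design.X[: t + 1], design2.X[: t + 1])
        assert (design.X[t + 1 :] != design2.X[t + 1 :]).any()


class TestConditionalIntensity:
    def test_zero_parameters_give_unit_rate(self, toy_problem):
        _, _, design = toy_problem
        params = a.CouplingParams(k=np.zeros(3), H=np.zeros((3, 3)))
        np.testing.assert_array_equal(conditional_intensity(params, design, 0), np.ones(20))

    def test_log2_stimulus_doubles_rate(self, tiny_kernels):
        # constant unit covariate via a direct design
        from acuglm.glm import DesignMatrix

        X = np.column_stack([np.ones(5), np.zeros(5)])
        design = DesignMatrix(grid=a.TimeGrid(1e-3, 5), X=X, target=0)
        params = a.CouplingParams(k=[np.log(2.0)], H=[[0.0]])
        np.testing.assert_allclose(conditional_intensity(params, design, 0), 2.0)

    def test_matches_scalar_recomputation(self, toy_problem, reference_params):
        _, _, design = toy_problem
        lam = conditional_intensity(reference_params, design, 1)
        for t in range(20):
            eta = reference_params.k[1] * design.X[t, 0] + sum(
                reference_params.H[1, j] * design.X[t, j + 1] for j in range(3)
            )
            assert lam[t] == pytest.approx(np.exp(eta), rel=1e-12)

    def test_strictly_positive(self, toy_problem):
        _, _, design = toy_problem
        params = a.CouplingParams(k=np.full(3, -50.0), H=np.full((3, 3), -50.0))
        assert (conditional_intensity(params, design, 0) > 0).all()

    def test_lnp_special_case(self, toy_problem, reference_params):
        # zero history weights reduce the coupled model to the LNP cascade
        _, _, design = toy_problem
        params = a.CouplingParams(k=reference_params.k, H=np.zeros((3, 3)))
        np.testing.assert_allclose(
            conditional_intensity(params, design, 0),
            np.exp(reference_params.k[0] * design.X[:, 0]),
        )

    def test_self_history_special_case(self, toy_problem, reference_params):
        # zero cross-coupling leaves only the stimulus and own-history terms
        _, _, design = toy_problem
        H = np.diag(np.diag(reference_params.H))
        params = a.CouplingParams(k=reference_params.k, H=H)
        expect = np.exp(
            reference_params.k[1] * design.X[:, 0] + H[1, 1] * design.X[:, 2]
        )
        np.testing.assert_allclose(conditional_intensity(params, design, 1), expect)


class TestHistoryEffectCurves:
    def test_zero_weight_flat_curves(self, kernels):
        params = a.CouplingParams(k=np.zeros(2), H=np.zeros((2, 2)))
        curves = a.history_effect_curves(params, kernels, 0)
        assert not curves["raw"].any()
        np.testing.assert_array_equal(curves["exp"], np.ones_like(curves["exp"]))

    def test_linear_in_weight(self, kernels):
        p1 = a.CouplingParams(k=[0.0], H=[[0.5]])
        p2 = a.CouplingParams(k=[0.0], H=[[1.0]])
        c1 = a.history_effect_curves(p1, kernels, 0)["raw"]
        c2 = a.history_effect_curves(p2, kernels, 0)["raw"]
        np.testing.assert_allclose(c2, 2 * c1)

    def test_reference_peak_ordering(self, kernels, reference_params):
        # neuron 1: cross-coupling from neuron 2 (1.4) > self (1.0) > neuron 3 (0.8)
        curves = a.history_effect_curves(reference_params, kernels, 0)
        peaks = curves["exp"].max(axis=1)
        assert peaks[1] > peaks[0] > peaks[2]
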