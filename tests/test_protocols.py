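"""Protocol runners: tetanus, conditioning, recall, freezing statistics."""

import numpy as np
import pytest

from thetafear import ParamSet
from thetafear.protocols import (
    COMPARTMENTS,
    _conditioning_epoch,
    _threshold_scan,
    freezing_probability,
    run_conditioning,
    run_recall,
    run_tetanus,
)
from thetafear._fast import HAVE_NUMBA


class TestTetanus:
    def test_low_frequency_limit_leaves_weight_unchanged(self, params):
        """Widely spaced spikes: calcium stays tiny, eta ~ 1e-4, no change."""
        w = run_tetanus(0.2, 3, params, train="regular")
        assert w == pytest.approx(1.0, abs=0.01)

    def test_high_beats_low_frequency(self, params):
        assert run_tetanus(9.0, 100, params) > run_tetanus(4.0, 100, params)

    def test_baseline_theta_beats_anxiolytic_theta(self, params):
        assert run_tetanus(6.0, 100, params) > run_tetanus(5.5, 100, params)

    def test_deterministic_given_seed(self, params):
        a = run_tetanus(7.0, 100, params)
        b = run_tetanus(7.0, 100, params)
        assert a == b

    def test_invalid_frequency(self, params):
        with pytest.raises(ValueError):
            run_tetanus(0.0, 100, params)


class TestConditioning:
    def test_weights_nonnegative_and_shaped(self, tiny_params):
        cond = run_conditioning(6.0, tiny_params, 1)
        assert cond.weights.shape == (2, 2, 3)
        assert np.all(cond.weights >= 0)
        assert np.all(cond.relative >= 0)

    def test_symmetry_when_fear_rates_equal(self, tiny_params):
        """With r_threat -> r_safe the compartments are statistically
        exchangeable; over seeds the mean weight difference is ~0."""
        p = tiny_params.replace(r_safe=1.0, r_threat=1.0 + 1e-9)
        diffs = []
        for s in np.random.SeedSequence(99).spawn(30):
            cond = run_conditioning(6.0, p, s)
            diffs.append(
                cond.mean_relative("threat") - cond.mean_relative("safe")
            )
        diffs = np.asarray(diffs)
        t_stat = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(diffs.size))
        assert abs(t_stat) < 3.5  # alpha ~ 0.001 two-sided

    def test_threat_beats_safe_at_defaults(self, params):
        cond = run_conditioning(6.0, params, 7)
        assert cond.mean_relative("threat") > cond.mean_relative("safe")

    def test_deterministic_bit_identical(self, tiny_params):
        a = run_conditioning(6.0, tiny_params, 123)
        b = run_conditioning(6.0, tiny_params, 123)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_to_frame_layout(self, tiny_params):
        df = run_conditioning(6.0, tiny_params, 1).to_frame()
        assert set(df.columns) >= {
            "fear_cell_id", "place_cell_id", "compartment", "w", "w_rel"
        }
        assert len(df) == 2 * 2 * 3
        assert set(df["compartment"]) == set(COMPARTMENTS)

    @pytest.mark.skipif(not HAVE_NUMBA, reason="numba not installed")
    def test_fast_kernel_matches_numpy_reference(self, tiny_params):
        fast = run_conditioning(6.0, tiny_params, 321, use_fast=True)
        ref = run_conditioning(6.0, tiny_params, 321, use_fast=False)
        np.testing.assert_allclose(fast.weights, ref.weights, rtol=1e-4)


class TestConditioningTrace:
    def test_trace_reproduces_the_simulated_synapse(self, tiny_params):
        """The designated synapse's trace ends at (approximately) the weight
        the full conditioning run assigns it; the zero-calcium drift of the
        other epoch accounts for a sub-1e-3 offset."""
        from thetafear.protocols import conditioning_trace

        cond = run_conditioning(6.0, tiny_params, 11)
        trace = conditioning_trace(
            6.0, tiny_params, 11, compartment="threat", fear_cell=1, place_cell=2
        )
        assert list(trace.columns) == ["t_ms", "v_spine_mv", "ca_um", "w"]
        c = COMPARTMENTS.index("threat")
        assert trace["w"].iloc[-1] == pytest.approx(
            cond.weights[1, c, 2], abs=5e-3
        )
        assert np.all(trace["ca_um"] >= 0)
        assert trace["v_spine_mv"].min() >= tiny_params.v_rest - tiny_params.a_theta


class TestThresholdScan:
    def test_no_crossing_no_spikes(self):
        drive = np.full(1000, -70.0)
        relax = np.zeros(1000)
        assert _threshold_scan(drive, relax, -55.0, 20).size == 0

    def test_single_crossing_with_reset_suppression(self):
        drive = np.full(1000, -54.0)  # permanently above threshold
        relax = np.full(1000, -100.0)  # reset clamps far below threshold
        relax[:900] = -100.0
        spikes = _threshold_scan(drive, relax, -55.0, 20)
        assert spikes.size == 1 and spikes[0] == 0

    def test_refractory_spacing(self):
        drive = np.full(1000, -54.0)
        relax = np.zeros(1000)  # no reset effect: fires at refractory rate
        spikes = _threshold_scan(drive, relax, -55.0, 20)
        assert np.all(np.diff(spikes) == 20)


class TestRecall:
    def test_zero_weights_and_flat_theta_are_silent(self, tiny_params):
        p = tiny_params.replace(a_theta=0.0)
        cond = run_conditioning(6.0, p, 5)
        silent = np.zeros_like(cond.weights)
        rec = run_recall(cond, p, 6, weights_override=silent)
        assert rec.mean_rate == {"safe": 0.0, "threat": 0.0}
        assert rec.froze == {"safe": False, "threat": False}

    def test_rate_and_freeze_flag_consistent(self, tiny_params):
        cond = run_conditioning(6.0, tiny_params, 5)
        rec = run_recall(cond, tiny_params, 6)
        for comp in COMPARTMENTS:
            assert rec.froze[comp] == (rec.mean_rate[comp] > tiny_params.r_freeze)
            assert rec.mean_rate[comp] >= 0

    def test_threat_drive_exceeds_safe_after_conditioning(self, params):
        cond = run_conditioning(6.0, params, 41)
        rec = run_recall(cond, params, 42, compute_spectra=False)
        assert rec.mean_rate["threat"] > rec.mean_rate["safe"]

    def test_shape_mismatch_rejected(self, tiny_params, params):
        cond = run_conditioning(6.0, tiny_params, 5)
        with pytest.raises(ValueError):
            run_recall(cond, params, 6)

    def test_deterministic_bit_identical(self, tiny_params):
        cond = run_conditioning(6.0, tiny_params, 5)
        a = run_recall(cond, tiny_params, 6)
        b = run_recall(cond, tiny_params, 6)
        assert a.mean_rate == b.mean_rate
        for comp in COMPARTMENTS:
            for ta, tb in zip(a.fear_spike_trains[comp], b.fear_spike_trains[comp]):
                np.testing.assert_array_equal(ta.times, tb.times)


class TestFreezingProbability:
    def test_fraction_bounds_and_reproducibility(self, tiny_params):
        fr1 = freezing_probability(6.0, 4, tiny_params, 77)
        fr2 = freezing_probability(6.0, 4, tiny_params, 77)
        assert fr1 == fr2
        for comp in COMPARTMENTS:
            assert 0.0 <= fr1[comp] <= 1.0

    def test_monotone_in_freezing_threshold(self, tiny_params):
        """Raising r_freeze can only lower the freezing fraction."""
        _, rates = freezing_probability(
            6.0, 6, tiny_params, 88, return_rates=True
        )
        fracs = [
            np.mean(rates["threat"] > thr) for thr in (0.5, 1.0, 1.5, 2.0, 3.0)
        ]
        assert all(b <= a for a, b in zip(fracs, fracs[1:]))

    def test_requires_at_least_one_simulation(self, tiny_params):
        with pytest.raises(ValueError):
            freezing_probability(6.0, 0, tiny_params, 1)
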