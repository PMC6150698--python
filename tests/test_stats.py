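"""Statistic hierarchy: closed forms, hand-enumerated oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cxscreen.stats import (
    pair_stats,
    repeat_stats,
    run_stats,
    scale_integrals,
    scale_values,
    compute_screen_stats,
)
from cxscreen.synth import (
    GroundTruthConnectome,
    Repeat,
    ResponseClass,
    ResponseKind,
    StimulationProtocol,
    simulate_experiment,
    simulate_repeat,
)

PROTO = StimulationProtocol(1, onset_time=4.0)
T10 = np.arange(160) / 10.0  # 16 s at 10 Hz


def make_repeat(values, proto=PROTO, fs=10.0):
    values = np.asarray(values, dtype=float)
    return Repeat(time=np.arange(values.size) / fs, values=values,
                  protocol=proto, sampling_rate=fs)


class TestRepeatStats:
    def test_flat_zero_trace(self):
        rs = repeat_stats(make_repeat(np.zeros(160)))
        assert rs.Fpeak == 0 and rs.ItoPeak == 0 and rs.Fbase == 0
        assert np.isnan(rs.tau_half)

    def test_exponential_decay_closed_form(self):
        """Instant rise to 1 at onset, exp(−t) decay: Fpeak = 1,
        tau_half = ln 2, each within one 10 Hz sampling interval."""
        vals = np.where(T10 >= 4.0, np.exp(-(T10 - 4.0)), 0.0)
        rs = repeat_stats(make_repeat(vals))
        assert rs.Fpeak == pytest.approx(1.0)
        assert rs.Tpeak == pytest.approx(0.0, abs=0.1)
        assert rs.tau_half == pytest.approx(np.log(2), abs=0.1)

    def test_inhibition_yields_negative_excursion(self):
        """A planted dip from baseline 1.0 to 0.2: Fpeak ≈ 0.2, negative
        integral (closed-form kernel, no noise)."""
        cls = ResponseClass(ResponseKind.INHIBITION, peak_amplitude=-0.8,
                            baseline_level=1.0, reliability=1.0,
                            amplitude_jitter=0.0)
        rep = simulate_repeat(cls, StimulationProtocol(20), sampling_rate=20,
                              seed=0)
        rs = repeat_stats(rep)
        assert rs.Fpeak == pytest.approx(0.2, abs=0.02)
        assert rs.ItoPeak < 0

    def test_baseline_floor_binds_near_zero_baseline(self):
        vals = np.where(T10 >= 4.0, 1.0, 0.0)
        rs = repeat_stats(make_repeat(vals), fbase_floor=0.05)
        assert rs.base_floored
        assert rs.Fpeak_norm == pytest.approx(1.0 / 0.05)

    def test_no_post_onset_samples_rejected(self):
        proto = StimulationProtocol(1, onset_time=20.0)
        with pytest.raises(ValueError, match="onset"):
            repeat_stats(make_repeat(np.zeros(160), proto=proto))


class TestRunStats:
    def test_identical_repeats(self, rng):
        vals = rng.random(160)
        reps = [repeat_stats(make_repeat(vals)) for _ in range(4)]
        rn = run_stats(reps, [vals] * 4)
        assert rn.Fpeak == reps[0].Fpeak
        assert rn.Rwithin_flies == pytest.approx(1.0)

    def test_median_of_four(self):
        reps = []
        for peak in (1.0, 2.0, 3.0, 4.0):
            vals = np.where(T10 >= 4.0, peak, 0.0)
            reps.append(repeat_stats(make_repeat(vals)))
        rn = run_stats(reps, [np.where(T10 >= 4.0, p, 0.0)
                              for p in (1.0, 2.0, 3.0, 4.0)])
        assert rn.Fpeak == pytest.approx(2.5)

    def test_sign_flipped_traces_hand_enumerated(self, rng):
        """Traces a, −a, 2a, −2a: six pairwise correlations are
        {+1, +1, −1, −1, −1, −1}, mean −1/3."""
        a = rng.standard_normal(160)
        traces = [a, -a, 2 * a, -2 * a]
        reps = [repeat_stats(make_repeat(t)) for t in traces]
        rn = run_stats(reps, traces)
        assert rn.Rwithin_flies == pytest.approx(-1 / 3)

    def test_undefined_tau_half_excluded_from_median(self):
        vals_decay = np.where(T10 >= 4.0, np.exp(-(T10 - 4.0)), 0.0)
        vals_flat = np.where(T10 >= 4.0, 1.0, 0.0)  # never re-crosses
        reps = [repeat_stats(make_repeat(v))
                for v in (vals_decay, vals_decay, vals_flat, vals_flat)]
        rn = run_stats(reps, [vals_decay, vals_decay, vals_flat, vals_flat])
        assert rn.tau_half == pytest.approx(np.log(2), abs=0.1)

    def test_constant_traces_leave_correlation_undefined(self):
        vals = np.zeros(160)
        reps = [repeat_stats(make_repeat(vals)) for _ in range(4)]
        rn = run_stats(reps, [vals] * 4)
        assert np.isnan(rn.Rwithin_flies)

    def test_short_run_warns(self, rng):
        vals = rng.random(160)
        reps = [repeat_stats(make_repeat(vals)) for _ in range(3)]
        with pytest.warns(UserWarning, match="3 repeats"):
            run_stats(reps, [vals] * 3)


class TestPairStats:
    def _run(self, vals):
        reps = [repeat_stats(make_repeat(vals)) for _ in range(4)]
        return run_stats(reps, [vals] * 4)

    def test_identical_flies(self, rng):
        vals = rng.random(160)
        rn = self._run(vals)
        ps = pair_stats({0: rn, 1: rn, 2: rn}, {f: vals for f in range(3)})
        assert ps.Fpeak == rn.Fpeak
        assert ps.Rbetween_flies == pytest.approx(1.0)

    def test_two_flies_single_pairwise_correlation(self, rng):
        a, b = rng.standard_normal(160), rng.standard_normal(160)
        ps = pair_stats({0: self._run(a), 1: self._run(b)}, {0: a, 1: b})
        assert ps.Rbetween_flies == pytest.approx(np.corrcoef(a, b)[0, 1])

    def test_single_fly_leaves_correlations_undefined(self, rng):
        vals = rng.random(160)
        ps = pair_stats({0: self._run(vals)}, {0: vals})
        assert np.isnan(ps.Rbetween_flies) and np.isnan(ps.Rstate)

    def test_planted_brain_state_coupling(self):
        """Response amplitude proportional to baseline across repeats gives a
        strong positive ItoPeak–Fbase correlation, matching the direct
        correlation of the planted values."""
        cls = ResponseClass(ResponseKind.STRONG_EXCITATION, peak_amplitude=1.0,
                            reliability=1.0, baseline_level=0.5,
                            baseline_jitter_sd=0.3, baseline_drift_sd=0.02,
                            noise_sd=0.02, amplitude_jitter=0.0,
                            state_coupling=1.5)
        gt = GroundTruthConnectome(cell_types=["A", "B"],
                                   edges={("A", "B"): cls},
                                   overlap_labels={("A", "B"): True})
        ds = simulate_experiment(gt, n_flies=8,
                                 protocols=[StimulationProtocol(30)], seed=7)
        _, run_df, pair_df = compute_screen_stats(ds)
        planted = np.corrcoef(run_df["ItoPeak"], run_df["Fbase"])[0, 1]
        assert planted > 0.8
        assert pair_df["Rstate"].iloc[0] > 0.8


class TestScaling:
    def test_scaling_rule_by_hand(self):
        np.testing.assert_allclose(scale_values(np.array([-2.0, 1.0, 4.0])),
                                   [-1.0, 0.25, 1.0])

    def test_single_positive_value_scales_to_one(self):
        np.testing.assert_allclose(scale_values(np.array([0.37])), [1.0])

    def test_all_zero_batch(self):
        np.testing.assert_allclose(scale_values(np.zeros(5)), 0.0)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=200)
    def test_scaled_batch_covers_unit_range(self, values):
        x = np.array(values)
        scaled = scale_values(x)
        assert np.all(scaled >= -1 - 1e-12) and np.all(scaled <= 1 + 1e-12)
        if (x > 0).any():
            assert scaled.max() == pytest.approx(1.0)
        if (x < 0).any():
            assert scaled.min() == pytest.approx(-1.0)
        # idempotent once the extrema sit at ±1
        np.testing.assert_allclose(scale_values(scaled), scaled, rtol=1e-12)

    def test_matches_explicit_max_min_oracle(self, rng):
        x = rng.standard_normal(40) * 3
        scaled = scale_values(x)
        oracle = np.where(x > 0, x / x.max(), np.where(x < 0, x / abs(x.min()), 0.0))
        np.testing.assert_allclose(scaled, oracle)


class TestInvariants:
    def test_permutation_invariance(self, rng):
        """Repeat order within a run and fly order within a pair never change
        any statistic."""
        traces = [rng.standard_normal(160) for _ in range(4)]
        reps = [repeat_stats(make_repeat(t)) for t in traces]
        rn1 = run_stats(reps, traces)
        order = [2, 0, 3, 1]
        rn2 = run_stats([reps[i] for i in order], [traces[i] for i in order])
        for field in ("Fpeak", "Tpeak", "ItoPeak", "Fbase", "Rwithin_flies"):
            assert getattr(rn1, field) == pytest.approx(getattr(rn2, field),
                                                        rel=1e-12)

        flies = {f: self_run(rng) for f in range(4)}
        tr = {f: rng.standard_normal(160) for f in range(4)}
        ps1 = pair_stats(flies, tr)
        shuffled = {f: flies[f] for f in (3, 1, 0, 2)}
        ps2 = pair_stats(shuffled, tr)
        assert ps1 == ps2

    def test_monotonicity_in_planted_amplitude(self):
        """Increasing a planted excitatory amplitude (fixed seed and noise)
        never decreases the pair-level normalised integral."""
        vals = []
        for amp in (0.3, 0.8, 1.5, 2.5):
            cls = ResponseClass(ResponseKind.STRONG_EXCITATION,
                                peak_amplitude=amp, reliability=1.0,
                                noise_sd=0.05, baseline_drift_sd=0.05,
                                amplitude_jitter=0.0)
            gt = GroundTruthConnectome(cell_types=["A", "B"],
                                       edges={("A", "B"): cls},
                                       overlap_labels={("A", "B"): True})
            ds = simulate_experiment(gt, n_flies=3,
                                     protocols=[StimulationProtocol(30)],
                                     seed=11)
            _, _, pair_df = compute_screen_stats(ds)
            vals.append(pair_df["ItoPeak_norm"].iloc[0])
        assert np.all(np.diff(vals) >= 0)

    def test_medians_within_repeat_range_and_correlations_bounded(self, rng):
        traces = [rng.standard_normal(160) * 0.3 + 0.2 for _ in range(4)]
        reps = [repeat_stats(make_repeat(t)) for t in traces]
        rn = run_stats(reps, traces)
        peaks = [r.Fpeak for r in reps]
        assert min(peaks) <= rn.Fpeak <= max(peaks)
        assert -1 <= rn.Rwithin_flies <= 1


def self_run(rng):
    traces = [rng.standard_normal(160) for _ in range(4)]
    reps = [repeat_stats(make_repeat(t)) for t in traces]
    return run_stats(reps, traces)
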