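"""Simulator contracts: pulse trains, response kernels, determinism, movies."""

import numpy as np
import pytest

from cxscreen.synth import (
    GroundTruthConnectome,
    Repeat,
    ResponseClass,
    ResponseKind,
    StimulationProtocol,
    default_response_classes,
    make_pulse_train,
    response_kernel,
    simulate_experiment,
    simulate_movie,
    simulate_repeat,
)

from conftest import make_fixture_connectome


class TestPulseTrain:
    def test_single_pulse_train_duration(self):
        p = StimulationProtocol(1)
        assert p.train_duration == pytest.approx(0.002)
        train = make_pulse_train(p, sampling_rate=1000, duration=16.0)
        edges = np.sum(np.diff(np.concatenate(([0], train))) == 1)
        assert edges == 1

    def test_thirty_pulse_train_spans_under_a_second(self):
        p = StimulationProtocol(30)
        assert p.train_duration == pytest.approx(29 / 30 + 0.002)
        train = make_pulse_train(p, sampling_rate=1000, duration=16.0)
        edges = np.sum(np.diff(np.concatenate(([0], train))) == 1)
        assert edges == 30

    @pytest.mark.parametrize("n_pulses", [1, 5, 10, 20, 30])
    def test_rising_edge_count_and_spacing(self, n_pulses):
        p = StimulationProtocol(n_pulses)
        train = make_pulse_train(p, sampling_rate=300, duration=16.0)
        starts = np.flatnonzero(np.diff(np.concatenate(([0], train))) == 1)
        assert starts.size == n_pulses
        if n_pulses > 1:
            # spacing 1/30 s at 300 Hz sampling = 10 samples
            assert np.all(np.diff(starts) == 10)

    def test_undersampled_train_is_rejected(self):
        with pytest.raises(ValueError, match="sampling"):
            make_pulse_train(StimulationProtocol(5), sampling_rate=10,
                             duration=16.0)

    def test_overflowing_train_is_rejected(self):
        p = StimulationProtocol(30, onset_time=15.5)
        with pytest.raises(ValueError, match="beyond the repeat duration"):
            make_pulse_train(p, sampling_rate=1000, duration=16.0)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            StimulationProtocol(0)


class TestSimulateRepeat:
    def test_no_response_no_noise_is_flat(self):
        cls = ResponseClass(ResponseKind.NONE, baseline_level=0.3)
        rep = simulate_repeat(cls, StimulationProtocol(20), seed=0)
        assert np.allclose(rep.values, 0.3)

    def test_excitation_peak_matches_analytic_kernel_extremum(self):
        """With zero noise and full reliability the trace extremum equals the
        planted amplitude (the kernel is unit-peak) within one sample."""
        cls = ResponseClass(ResponseKind.STRONG_EXCITATION, peak_amplitude=1.2,
                            reliability=1.0, amplitude_jitter=0.0)
        proto = StimulationProtocol(20)
        rep = simulate_repeat(cls, proto, sampling_rate=20.0, seed=1)
        assert rep.values.max() == pytest.approx(1.2, abs=0.02)
        peak_t = rep.time[np.argmax(rep.values)]
        # analytic extremum from a fine-grid evaluation of the same kernel
        fine_t = np.arange(0, 16, 1e-3)
        kern = response_kernel(proto, fine_t, cls.rise_tau, cls.decay_tau)
        assert abs(peak_t - fine_t[np.argmax(kern)]) <= 1 / 20.0
        # post-peak decay is exponential with decay_tau
        post = rep.values[np.argmax(rep.values):]
        t_post = np.arange(post.size) / 20.0
        mask = post > 0.05
        fit = np.polyfit(t_post[mask], np.log(post[mask]), 1)
        assert -1.0 / fit[0] == pytest.approx(cls.decay_tau, rel=0.15)

    def test_inhibition_dips_to_analytic_minimum(self):
        """Baseline 1.0 with amplitude −0.8 bottoms out at 0.2."""
        cls = ResponseClass(ResponseKind.INHIBITION, peak_amplitude=-0.8,
                            baseline_level=1.0, reliability=1.0,
                            amplitude_jitter=0.0)
        rep = simulate_repeat(cls, StimulationProtocol(20),
                              sampling_rate=50.0, seed=2)
        assert rep.values.min() == pytest.approx(0.2, abs=0.01)

    def test_rebound_peaks_after_train_offset(self):
        cls = ResponseClass(ResponseKind.REBOUND, peak_amplitude=0.9,
                            reliability=1.0, amplitude_jitter=0.0)
        proto = StimulationProtocol(30)
        rep = simulate_repeat(cls, proto, sampling_rate=20.0, seed=3)
        peak_t = rep.time[np.argmax(rep.values)]
        assert peak_t > proto.offset_time + cls.decay_tau

    def test_inhibition_requires_elevated_baseline(self):
        with pytest.raises(ValueError, match="excited state"):
            ResponseClass(ResponseKind.INHIBITION, peak_amplitude=-0.5,
                          baseline_level=0.0)

    def test_saturation_caps_response(self):
        base = ResponseClass(ResponseKind.STRONG_EXCITATION, peak_amplitude=3.0,
                             reliability=1.0, amplitude_jitter=0.0)
        capped = ResponseClass(ResponseKind.STRONG_EXCITATION, peak_amplitude=3.0,
                               reliability=1.0, amplitude_jitter=0.0,
                               saturation=1.0)
        proto = StimulationProtocol(30)
        r0 = simulate_repeat(base, proto, seed=4)
        r1 = simulate_repeat(capped, proto, seed=4)
        assert r1.values.max() < r0.values.max()
        assert r1.values.max() <= 1.0 + 1e-9


class TestSimulateExperiment:
    def test_counts(self):
        gt = make_fixture_connectome()
        protocols = [StimulationProtocol(n) for n in (1, 5, 10, 20, 30)]
        ds = simulate_experiment(gt, n_flies=2, protocols=protocols, seed=0)
        n_pairs = len(gt.pairs())
        assert len(ds.runs) == n_pairs * 2 * 5
        assert len(ds.metadata) == n_pairs * 2 * 5 * 4

    def test_same_seed_is_bit_identical(self):
        gt = make_fixture_connectome()
        a = simulate_experiment(gt, n_flies=2,
                                protocols=[StimulationProtocol(30)], seed=9)
        b = simulate_experiment(gt, n_flies=2,
                                protocols=[StimulationProtocol(30)], seed=9)
        assert a.metadata.equals(b.metadata)
        for key in a.runs:
            for ra, rb in zip(a.runs[key], b.runs[key]):
                np.testing.assert_array_equal(ra.values, rb.values)

    def test_empty_connectome_rejected(self):
        gt = GroundTruthConnectome(cell_types=["A"], edges={}, overlap_labels={})
        with pytest.raises(ValueError, match="no pairs"):
            simulate_experiment(gt, seed=0)

    def test_planted_edge_must_be_overlapping(self):
        cls = default_response_classes()[ResponseKind.STRONG_EXCITATION]
        with pytest.raises(ValueError, match="non-overlapping"):
            GroundTruthConnectome(cell_types=["A", "B"],
                                  edges={("A", "B"): cls},
                                  overlap_labels={("A", "B"): False})

    def test_disk_round_trip(self, tmp_path):
        gt = make_fixture_connectome()
        ds = simulate_experiment(gt, n_flies=1,
                                 protocols=[StimulationProtocol(30)], seed=3)
        ds.to_disk(tmp_path / "data")
        from cxscreen.synth import ScreenDataset
        back = ScreenDataset.from_disk(tmp_path / "data")
        assert set(back.runs) == set(ds.runs)
        key = next(iter(ds.runs))
        np.testing.assert_allclose(back.runs[key][0].values,
                                   ds.runs[key][0].values, rtol=1e-12)


class TestSimulateMovie:
    def test_two_level_mean_image_without_noise(self):
        mv = simulate_movie(np.zeros(5), drift=(0, 0), poisson_noise=False)
        mean = mv.frames.mean(axis=0)
        levels = np.unique(mean)
        assert levels.size == 2
        assert mean[mv.true_mask].min() > mean[~mv.true_mask].max()

    def test_ground_truth_shift_is_recorded(self):
        mv = simulate_movie(np.zeros(3), drift=(2.0, -3.0), seed=0)
        assert mv.true_shift == (2.0, -3.0)

    def test_drift_out_of_frame_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_movie(np.zeros(3), frame_shape=(32, 32), drift=(30, 0))
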