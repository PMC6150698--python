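"""Synthetic optogenetic-screen data with a planted ground-truth connectome.

Emulates the structure of an all-optical functional-connectivity screen:
a presynaptic cell type expressing a red-shifted channelrhodopsin is driven
with brief LED pulse trains while a candidate postsynaptic type is imaged
with a genetically encoded calcium indicator.  The screen is organised as

    experiment (one cell-type pair, one fly)
      -> runs (one stimulation protocol each)
        -> 4 repeats (~16 s ΔF/F0 traces)

with at least six flies per pair.  Pulse trains are delivered at 30 Hz with
2 ms pulses and 1, 5, 10, 20 or 30 pulses per train.

Responses are phenomenological: a difference-of-exponentials calcium kernel
per pulse, linearly summed over the train with an optional soft saturation
ceiling, gated per repeat by a Bernoulli reliability draw.  Inhibition is a
dip from an elevated baseline (only visible from an excited state); rebound
is a delayed positive transient after train offset.  Slow "brain-state"
baseline fluctuations and white noise are superimposed.  No biophysics
(indicator kinetics, opsin photocycle) is modelled.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import fourier_shift, gaussian_filter1d, shift as nd_shift

__all__ = [
    "StimulationProtocol",
    "ResponseKind",
    "ResponseClass",
    "GroundTruthConnectome",
    "Repeat",
    "ScreenDataset",
    "MovieStack",
    "make_pulse_train",
    "response_kernel",
    "simulate_repeat",
    "simulate_experiment",
    "simulate_movie",
    "simulate_run_movie",
    "default_response_classes",
    "repeat_seed",
]

#: Default protocol pulse counts used across the screen.
DEFAULT_PULSE_COUNTS = (1, 5, 10, 20, 30)

#: Fine grid step (s) used to locate the analytic kernel extremum.
_FINE_DT = 1e-3


@dataclass(frozen=True)
class StimulationProtocol:
    """An optogenetic pulse-train protocol within one repeat.

    Parameters
    ----------
    n_pulses:
        Number of LED pulses in the train (the screen uses 1, 5, 10, 20, 30).
    pulse_rate:
        Pulse repetition rate in Hz (default 30).
    pulse_duration:
        Duration of a single pulse in seconds (default 2 ms).
    onset_time:
        Time of the first pulse within the repeat, in seconds.  The window
        before it is the pre-stimulus baseline.
    """

    n_pulses: int
    pulse_rate: float = 30.0
    pulse_duration: float = 0.002
    onset_time: float = 4.0

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.pulse_rate <= 0 or self.pulse_duration <= 0:
            raise ValueError("pulse_rate and pulse_duration must be positive")
        if self.onset_time < 0:
            raise ValueError("onset_time must be non-negative")

    @property
    def train_duration(self) -> float:
        """Total train duration: (n_pulses - 1)/pulse_rate + pulse_duration."""
        return (self.n_pulses - 1) / self.pulse_rate + self.pulse_duration

    @property
    def offset_time(self) -> float:
        """Time at which the last pulse ends."""
        return self.onset_time + self.train_duration

    def pulse_onsets(self) -> np.ndarray:
        """Onset times of the individual pulses, in seconds."""
        return self.onset_time + np.arange(self.n_pulses) / self.pulse_rate


class ResponseKind(str, enum.Enum):
    STRONG_EXCITATION = "strong_excitation"
    WEAK_EXCITATION = "weak_excitation"
    INHIBITION = "inhibition"
    REBOUND = "rebound"
    NONE = "none"


@dataclass(frozen=True)
class ResponseClass:
    """Phenomenological response of a postsynaptic type to stimulation.

    ``peak_amplitude`` is the signed ΔF/F0 excursion of the noiseless,
    fully reliable response at its extremum (negative for inhibition).
    ``baseline_level`` is the resting ΔF/F0; inhibition requires it to be
    positive, since a dip is only visible from an excited state.
    ``reliability`` is the probability that a given repeat responds at all.
    ``baseline_drift_sd`` sets the amplitude of the slow brain-state
    fluctuation; ``state_coupling`` scales the response amplitude with the
    pre-stimulus drift level, emulating brain-state-dependent responses.
    ``saturation`` is an optional soft ceiling (ΔF/F0) applied to the summed
    response, emulating saturation at strong stimulation.
    """

    kind: ResponseKind
    peak_amplitude: float = 0.0
    rise_tau: float = 0.15
    decay_tau: float = 1.0
    reliability: float = 1.0
    baseline_level: float = 0.0
    baseline_drift_sd: float = 0.0
    baseline_jitter_sd: float = 0.0
    noise_sd: float = 0.0
    amplitude_jitter: float = 0.1
    state_coupling: float = 0.0
    saturation: float | None = None
    rebound_delay: float | None = None

    def __post_init__(self) -> None:
        kind = ResponseKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if not 0.0 <= self.reliability <= 1.0:
            raise ValueError("reliability must lie in [0, 1]")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("rise_tau and decay_tau must be positive")
        if kind is ResponseKind.INHIBITION:
            if self.baseline_level <= 0:
                raise ValueError(
                    "inhibition requires baseline_level > 0: a dip is only "
                    "visible from an excited state"
                )
            if self.peak_amplitude >= 0:
                raise ValueError("inhibition requires a negative peak_amplitude")
        if self.saturation is not None and self.saturation <= 0:
            raise ValueError("saturation ceiling must be positive")


def default_response_classes() -> dict[ResponseKind, ResponseClass]:
    """Response classes emulating the phenomenology seen in the screen.

    Amplitudes are in ΔF/F0 units; noise and drift levels approximate a
    moderately noisy two-photon recording over a large ROI.
    """
    common = dict(baseline_drift_sd=0.05, noise_sd=0.05)
    return {
        ResponseKind.STRONG_EXCITATION: ResponseClass(
            ResponseKind.STRONG_EXCITATION, peak_amplitude=1.5,
            reliability=0.9, **common),
        ResponseKind.WEAK_EXCITATION: ResponseClass(
            ResponseKind.WEAK_EXCITATION, peak_amplitude=0.3,
            reliability=0.6, **common),
        ResponseKind.INHIBITION: ResponseClass(
            ResponseKind.INHIBITION, peak_amplitude=-0.8, baseline_level=1.0,
            decay_tau=2.0, reliability=0.9, **common),
        ResponseKind.REBOUND: ResponseClass(
            ResponseKind.REBOUND, peak_amplitude=0.8, reliability=0.8,
            **common),
        ResponseKind.NONE: ResponseClass(
            ResponseKind.NONE, peak_amplitude=0.0, reliability=0.0, **common),
    }


def make_pulse_train(
    protocol: StimulationProtocol, sampling_rate: float, duration: float
) -> np.ndarray:
    """Binary stimulus vector for ``protocol`` sampled at ``sampling_rate``.

    The vector has exactly ``protocol.n_pulses`` rising edges.  Raises if the
    train does not fit in ``duration`` or if the sampling rate is too low to
    resolve individual pulses.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if protocol.offset_time >= duration:
        raise ValueError(
            f"pulse train ends at {protocol.offset_time:.3f} s, beyond the "
            f"repeat duration {duration:.3f} s "
            f"(overflow {protocol.offset_time - duration:.3f} s)"
        )
    if protocol.n_pulses > 1 and sampling_rate <= protocol.pulse_rate:
        raise ValueError(
            f"sampling rate {sampling_rate} Hz cannot resolve pulses at "
            f"{protocol.pulse_rate} Hz (pulse spacing shorter than the "
            "sampling interval)"
        )
    n = int(round(duration * sampling_rate))
    train = np.zeros(n, dtype=np.int8)
    for start in protocol.pulse_onsets():
        # epsilon guards against fp error flipping the containing sample
        i0 = int(np.floor(start * sampling_rate + 1e-9))
        i1 = int(np.ceil((start + protocol.pulse_duration) * sampling_rate - 1e-9))
        train[i0:max(i1, i0 + 1)] = 1
    edges = int(np.sum(np.diff(np.concatenate(([0], train))) == 1))
    if edges != protocol.n_pulses:
        raise ValueError(
            f"sampling rate {sampling_rate} Hz merges adjacent pulses: "
            f"{edges} rising edges instead of {protocol.n_pulses}"
        )
    return train


def _doe(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials kernel, zero for t < 0."""
    if rise_tau >= decay_tau:
        # swap so the kernel stays a rise-then-decay shape
        rise_tau, decay_tau = min(rise_tau, decay_tau) * 0.999, max(rise_tau, decay_tau)
    out = np.where(
        t >= 0,
        np.exp(-np.maximum(t, 0.0) / decay_tau) - np.exp(-np.maximum(t, 0.0) / rise_tau),
        0.0,
    )
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    return out / peak


def response_kernel(
    protocol: StimulationProtocol,
    t: np.ndarray,
    rise_tau: float,
    decay_tau: float,
    *,
    start_offset: float = 0.0,
) -> np.ndarray:
    """Unit-peak summed response kernel of the pulse train, evaluated at ``t``.

    Each pulse contributes a difference-of-exponentials transient; the
    contributions are summed linearly over the train and the sum is
    normalised so its maximum over a fine time grid equals 1.  With
    ``start_offset`` the whole kernel is delayed (used for rebound).
    """
    onsets = protocol.pulse_onsets() + start_offset

    def evaluate(tt: np.ndarray) -> np.ndarray:
        acc = np.zeros_like(tt, dtype=float)
        for t0 in onsets:
            acc += _doe(tt - t0, rise_tau, decay_tau)
        return acc

    horizon = onsets[-1] + 10 * decay_tau
    fine = np.arange(onsets[0], horizon, _FINE_DT)
    peak = evaluate(fine).max()
    return evaluate(np.asarray(t, dtype=float)) / peak


@dataclass
class Repeat:
    """One ~16 s trace (ΔF/F0 units when simulated directly) with its timing."""

    time: np.ndarray
    values: np.ndarray
    protocol: StimulationProtocol
    sampling_rate: float
    responded: bool = True

    @property
    def onset_time(self) -> float:
        return self.protocol.onset_time


def _slow_drift(rng: np.random.Generator, n: int, sampling_rate: float,
                sd: float) -> np.ndarray:
    """Slow baseline fluctuation: a random walk smoothed over ~2 s, scaled to
    standard deviation ``sd`` and centred on zero."""
    walk = np.cumsum(rng.standard_normal(n))
    smooth = gaussian_filter1d(walk, sigma=2.0 * sampling_rate, mode="nearest")
    smooth -= smooth.mean()
    s = smooth.std()
    if sd <= 0 or s == 0:
        return np.zeros(n)
    return smooth * (sd / s)


def simulate_repeat(
    cls: ResponseClass,
    protocol: StimulationProtocol,
    sampling_rate: float = 10.0,
    duration: float = 16.0,
    seed: int | np.random.Generator | None = None,
) -> Repeat:
    """Simulate one repeat trace in ΔF/F0 units.

    trace = baseline + slow drift + (reliability-gated response kernel)
            + white noise.
    """
    if protocol.offset_time >= duration:
        raise ValueError(
            f"pulse train ends at {protocol.offset_time:.3f} s, beyond the "
            f"repeat duration {duration:.3f} s"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate

    drift = _slow_drift(rng, n, sampling_rate, cls.baseline_drift_sd)
    # draws below happen unconditionally so the stream layout is stable
    responded = bool(rng.random() < cls.reliability)
    jitter = 1.0 + cls.amplitude_jitter * rng.standard_normal()
    baseline_offset = cls.baseline_jitter_sd * rng.standard_normal()
    noise = rng.normal(0.0, cls.noise_sd, n) if cls.noise_sd > 0 else np.zeros(n)

    onset_idx = int(np.searchsorted(t, protocol.onset_time))
    state = baseline_offset + (drift[:onset_idx].mean() if onset_idx > 0 else 0.0)
    amplitude = cls.peak_amplitude * max(jitter, 0.0) * (1.0 + cls.state_coupling * state)

    resp = np.zeros(n)
    if cls.kind is not ResponseKind.NONE and responded and amplitude != 0.0:
        if cls.kind is ResponseKind.REBOUND:
            delay = cls.rebound_delay if cls.rebound_delay is not None else cls.decay_tau
            kern = response_kernel(
                protocol, t, cls.rise_tau, cls.decay_tau,
                start_offset=protocol.train_duration + delay)
        else:
            kern = response_kernel(protocol, t, cls.rise_tau, cls.decay_tau)
        resp = amplitude * kern
        if cls.saturation is not None:
            resp = cls.saturation * np.tanh(resp / cls.saturation)

    values = cls.baseline_level + baseline_offset + drift + resp + noise
    return Repeat(time=t, values=values, protocol=protocol,
                  sampling_rate=sampling_rate, responded=responded)


@dataclass
class GroundTruthConnectome:
    """A planted connectome: cell types, response classes and overlap labels.

    Every pair with a non-``none`` response must be anatomically overlapping;
    non-overlapping pairs are the controls the null model is built from and
    carry no response (optionally a small unreliable "indirect" one when
    ``allow_indirect`` is set).
    """

    cell_types: list[str]
    edges: dict[tuple[str, str], ResponseClass]
    overlap_labels: dict[tuple[str, str], bool]
    allow_indirect: bool = False

    def __post_init__(self) -> None:
        known = set(self.cell_types)
        for pair in list(self.edges) + list(self.overlap_labels):
            for name in pair:
                if name not in known:
                    raise ValueError(f"unknown cell type {name!r} in pair {pair}")
        for pair, cls in self.edges.items():
            if pair not in self.overlap_labels:
                raise ValueError(f"pair {pair} has no overlap label")
            if cls.kind is not ResponseKind.NONE and not self.overlap_labels[pair]:
                if not self.allow_indirect:
                    raise ValueError(
                        f"non-overlapping pair {pair} carries a planted "
                        f"response of kind {cls.kind.value}"
                    )

    def pairs(self) -> list[tuple[str, str]]:
        return list(self.overlap_labels)

    def response_for(self, pair: tuple[str, str]) -> ResponseClass:
        if pair in self.edges:
            return self.edges[pair]
        return default_response_classes()[ResponseKind.NONE]


def repeat_seed(master_seed: int, pair_index: int, fly: int,
                protocol_index: int, repeat: int) -> np.random.SeedSequence:
    """Stable per-repeat seed derived from the master seed and indices."""
    return np.random.SeedSequence(
        [int(master_seed), pair_index, fly, protocol_index, repeat])


@dataclass
class ScreenDataset:
    """A full synthetic screen: traces plus tidy metadata.

    ``runs`` maps (pre, post, fly, n_pulses) to the list of 4 repeats.
    ``metadata`` has one row per repeat.
    """

    runs: dict[tuple[str, str, int, int], list[Repeat]]
    metadata: "pandas.DataFrame"  # noqa: F821 - imported lazily
    ground_truth: GroundTruthConnectome
    sampling_rate: float
    duration: float
    seed: int
    n_repeats: int = 4

    def run_keys(self) -> list[tuple[str, str, int, int]]:
        return list(self.runs)

    def to_disk(self, outdir: str | Path) -> None:
        """Write one CSV per run (time, repeat1..repeatN) plus a JSON manifest."""
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tracedir = outdir / "traces"
        tracedir.mkdir(exist_ok=True)
        index = []
        for (pre, post, fly, n_pulses), reps in self.runs.items():
            fname = f"{pre}__{post}__fly{fly}__p{n_pulses}.csv"
            cols = {"time": reps[0].time}
            for i, rep in enumerate(reps, 1):
                cols[f"repeat{i}"] = rep.values
            pd.DataFrame(cols).to_csv(tracedir / fname, index=False)
            index.append({"pre": pre, "post": post, "fly": fly,
                          "n_pulses": n_pulses, "file": f"traces/{fname}",
                          "onset_time": reps[0].protocol.onset_time,
                          "pulse_rate": reps[0].protocol.pulse_rate,
                          "pulse_duration": reps[0].protocol.pulse_duration})
        gt = self.ground_truth
        manifest = {
            "sampling_rate": self.sampling_rate,
            "duration": self.duration,
            "seed": self.seed,
            "n_repeats": self.n_repeats,
            "cell_types": gt.cell_types,
            "overlap_labels": [
                {"pre": a, "post": b, "overlapping": bool(v)}
                for (a, b), v in gt.overlap_labels.items()],
            "planted_edges": [
                {"pre": a, "post": b, "kind": cls.kind.value,
                 "peak_amplitude": cls.peak_amplitude}
                for (a, b), cls in gt.edges.items()],
            "runs": index,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        self.metadata.to_csv(outdir / "metadata.csv", index=False)

    @staticmethod
    def from_disk(outdir: str | Path) -> "ScreenDataset":
        import pandas as pd

        outdir = Path(outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        fs = manifest["sampling_rate"]
        runs: dict[tuple[str, str, int, int], list[Repeat]] = {}
        for entry in manifest["runs"]:
            df = pd.read_csv(outdir / entry["file"])
            protocol = StimulationProtocol(
                n_pulses=entry["n_pulses"], pulse_rate=entry["pulse_rate"],
                pulse_duration=entry["pulse_duration"],
                onset_time=entry["onset_time"])
            reps = [
                Repeat(time=df["time"].to_numpy(), values=df[c].to_numpy(),
                       protocol=protocol, sampling_rate=fs)
                for c in df.columns if c.startswith("repeat")
            ]
            runs[(entry["pre"], entry["post"], entry["fly"], entry["n_pulses"])] = reps
        overlap = {(d["pre"], d["post"]): d["overlapping"]
                   for d in manifest["overlap_labels"]}
        edges = {
            (d["pre"], d["post"]): ResponseClass(
                ResponseKind(d["kind"]), peak_amplitude=d["peak_amplitude"],
                baseline_level=1.0 if d["kind"] == "inhibition" else 0.0)
            for d in manifest["planted_edges"]
        }
        gt = GroundTruthConnectome(
            cell_types=manifest["cell_types"], edges=edges,
            overlap_labels=overlap, allow_indirect=True)
        metadata = pd.read_csv(outdir / "metadata.csv")
        return ScreenDataset(
            runs=runs, metadata=metadata, ground_truth=gt,
            sampling_rate=fs, duration=manifest["duration"],
            seed=manifest["seed"], n_repeats=manifest["n_repeats"])


def simulate_experiment(
    gt: GroundTruthConnectome,
    n_flies: int = 6,
    protocols: Sequence[StimulationProtocol] | None = None,
    sampling_rate: float = 10.0,
    duration: float = 16.0,
    seed: int = 0,
    n_repeats: int = 4,
) -> ScreenDataset:
    """Simulate the full screen: every pair x fly x protocol run.

    Per-repeat randomness is derived by stable hashing of the master seed
    with (pair index, fly, protocol index, repeat index), so the dataset is
    bit-identical under a fixed seed and insensitive to iteration order.
    """
    import pandas as pd

    if not gt.pairs():
        raise ValueError("ground-truth connectome contains no pairs")
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    if protocols is None:
        protocols = [StimulationProtocol(n) for n in DEFAULT_PULSE_COUNTS]

    runs: dict[tuple[str, str, int, int], list[Repeat]] = {}
    rows = []
    for pair_index, pair in enumerate(gt.pairs()):
        cls = gt.response_for(pair)
        for fly in range(n_flies):
            for proto_index, protocol in enumerate(protocols):
                reps = []
                for r in range(n_repeats):
                    ss = repeat_seed(seed, pair_index, fly, proto_index, r)
                    rep = simulate_repeat(
                        cls, protocol, sampling_rate=sampling_rate,
                        duration=duration, seed=np.random.default_rng(ss))
                    reps.append(rep)
                    rows.append({
                        "pre": pair[0], "post": pair[1], "fly": fly,
                        "n_pulses": protocol.n_pulses, "repeat": r,
                        "responded": rep.responded,
                        "overlapping": gt.overlap_labels[pair],
                        "kind": cls.kind.value,
                    })
                runs[(pair[0], pair[1], fly, protocol.n_pulses)] = reps
    metadata = pd.DataFrame(rows)
    return ScreenDataset(runs=runs, metadata=metadata, ground_truth=gt,
                         sampling_rate=sampling_rate, duration=duration,
                         seed=seed, n_repeats=n_repeats)


@dataclass
class MovieStack:
    """A simulated movie with its ground truth for testing preprocessing."""

    frames: np.ndarray  # (time, height, width), uint16
    true_shift: tuple[float, float]
    true_mask: np.ndarray
    trace: np.ndarray


def _disk_mask(shape: tuple[int, int], center: tuple[float, float],
               radius: float) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def simulate_movie(
    trace: np.ndarray,
    frame_shape: tuple[int, int] = (32, 32),
    roi_center: tuple[float, float] | None = None,
    roi_radius: float = 6.0,
    drift: tuple[float, float] = (0.0, 0.0),
    seed: int | np.random.Generator | None = None,
    base_intensity: float = 200.0,
    gain: float = 150.0,
    background_intensity: float = 30.0,
    poisson_noise: bool = True,
) -> MovieStack:
    """Render a ΔF/F0-like trace as a drifting fluorescence movie.

    Foreground (a disk ROI) intensity follows ``base + gain * trace`` with
    optional Poisson noise; the background is dimmer.  The whole stack is
    translated by ``drift`` (pixels), recorded as ground truth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = frame_shape
    if roi_center is None:
        roi_center = ((h - 1) / 2.0, (w - 1) / 2.0)
    dy, dx = drift
    cy, cx = roi_center[0] + dy, roi_center[1] + dx
    if not (roi_radius <= cy <= h - 1 - roi_radius
            and roi_radius <= cx <= w - 1 - roi_radius):
        raise ValueError(
            f"drift {drift} pushes the ROI (center {roi_center}, radius "
            f"{roi_radius}) outside the {frame_shape} frame")

    mask = _disk_mask((h, w), roi_center, roi_radius)
    trace = np.asarray(trace, dtype=float)
    frames = np.empty((trace.size, h, w), dtype=np.uint16)
    for i, v in enumerate(trace):
        img = np.full((h, w), background_intensity, dtype=float)
        img[mask] = max(background_intensity, base_intensity + gain * v)
        if any(abs(d) > 0 for d in drift):
            if float(dy).is_integer() and float(dx).is_integer():
                img = np.roll(img, (int(dy), int(dx)), axis=(0, 1))
            else:
                img = np.fft.ifftn(fourier_shift(np.fft.fftn(img), (dy, dx))).real
        if poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        frames[i] = np.clip(img, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return MovieStack(frames=frames, true_shift=(float(dy), float(dx)),
                      true_mask=mask, trace=trace)


def simulate_run_movie(
    repeats: Sequence[Repeat],
    drift: tuple[float, float] = (0.0, 0.0),
    seed: int | np.random.Generator | None = None,
    **movie_kwargs,
) -> MovieStack:
    """One movie per run: the 4 repeat traces concatenated, one shared drift."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trace = np.concatenate([r.values for r in repeats])
    return simulate_movie(trace, drift=drift, seed=rng, **movie_kwargs)
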