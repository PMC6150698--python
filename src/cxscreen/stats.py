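"""Three-level response statistics: per repeat, per run, per cell-type pair.

Per repeat (one ~16 s ΔF/F0 trace):

* ``Fbase`` — mean ΔF/F0 over the pre-stimulus window.
* ``Fpeak``/``Tpeak`` — value and post-onset latency of the sample with the
  largest absolute deviation from ``Fbase`` (sign preserved, so inhibition
  shows up as a negative excursion).
* ``ItoPeak`` — trapezoidal integral of (trace − Fbase) from stimulation
  onset to the peak.
* ``tau_half`` — time after the peak at which the deviation first falls to
  half its peak value (undefined when the trace never re-crosses).
* ``Fpeak_norm``/``ItoPeak_norm`` — baseline-normalised versions, with the
  divisor floored at a small epsilon because Fbase can sit near zero by
  construction of the baseline estimate.

Per run (4 repeats, one fly): field-wise medians plus ``Rwithin_flies``, the
mean pairwise Pearson correlation of the repeat traces.  Per pair (across
flies, one stimulation protocol): medians of the run medians, plus
``Rbetween_flies`` (mean pairwise correlation of the per-run average
transients — the screen's reliability measure) and ``Rstate`` (correlation
of ItoPeak with Fbase across flies — brain-state dependence).

Finally, the integral statistics are scaled dataset-wide to [−1, 1]:
positive values are divided by the batch maximum and negative values by the
magnitude of the batch minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields as dc_fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid

from .synth import Repeat, ScreenDataset, StimulationProtocol

__all__ = [
    "RepeatStats",
    "RunStats",
    "PairStats",
    "repeat_stats",
    "run_stats",
    "pair_stats",
    "scale_values",
    "scale_integrals",
    "compute_screen_stats",
]

#: Floor on Fbase when normalising (ΔF/F0 units).
DEFAULT_FBASE_FLOOR = 0.05

_MEDIAN_FIELDS = ("Fpeak", "Tpeak", "ItoPeak", "tau_half", "Fbase",
                  "Fpeak_norm", "ItoPeak_norm")


@dataclass(frozen=True)
class RepeatStats:
    Fpeak: float
    Tpeak: float
    ItoPeak: float
    tau_half: float  # NaN when the trace never re-crosses half-peak
    Fbase: float
    Fpeak_norm: float
    ItoPeak_norm: float
    base_floored: bool = False


@dataclass(frozen=True)
class RunStats:
    """Medians of the repeat statistics across the repeats of one run."""
    Fpeak: float
    Tpeak: float
    ItoPeak: float
    tau_half: float
    Fbase: float
    Fpeak_norm: float
    ItoPeak_norm: float
    Rwithin_flies: float  # mean pairwise correlation of the repeat traces


@dataclass(frozen=True)
class PairStats:
    """Medians across flies of the run statistics, plus reliability measures."""
    Fpeak: float
    Tpeak: float
    ItoPeak: float
    tau_half: float
    Fbase: float
    Fpeak_norm: float
    ItoPeak_norm: float
    Rwithin_flies: float
    Rbetween_flies: float
    Rstate: float
    n_flies: int


def repeat_stats(
    trace: Repeat | np.ndarray,
    protocol: StimulationProtocol | None = None,
    *,
    time: np.ndarray | None = None,
    fbase_floor: float = DEFAULT_FBASE_FLOOR,
) -> RepeatStats:
    """Compute the per-repeat statistics of one ΔF/F0 trace.

    ``trace`` is either a :class:`~cxscreen.synth.Repeat` or a plain array,
    in which case ``time`` and ``protocol`` must be given.  The trace must
    include a pre-stimulus window and at least one post-onset sample.
    """
    if isinstance(trace, Repeat):
        values = np.asarray(trace.values, dtype=float)
        time = trace.time
        protocol = trace.protocol if protocol is None else protocol
    else:
        values = np.asarray(trace, dtype=float)
        if time is None or protocol is None:
            raise ValueError("plain-array traces require time and protocol")
    time = np.asarray(time, dtype=float)
    onset = protocol.onset_time

    pre = time < onset
    post = ~pre
    if not post.any():
        raise ValueError("trace has no samples after stimulation onset")
    if not pre.any():
        raise ValueError("trace has no pre-stimulus window before onset")

    fbase = float(values[pre].mean())
    dev = values - fbase
    post_idx = np.flatnonzero(post)
    ipk = post_idx[int(np.argmax(np.abs(dev[post_idx])))]
    fpeak = float(values[ipk])
    tpeak = float(time[ipk] - onset)
    i0 = post_idx[0]
    itopeak = float(trapezoid(dev[i0: ipk + 1], time[i0: ipk + 1])) if ipk > i0 else 0.0

    peak_dev = abs(dev[ipk])
    tau_half = float("nan")
    if peak_dev > 0:
        after = np.flatnonzero(np.abs(dev) <= peak_dev / 2.0)
        after = after[after > ipk]
        if after.size:
            tau_half = float(time[after[0]] - onset - tpeak)

    floored = fbase < fbase_floor
    denom = max(fbase, fbase_floor)
    return RepeatStats(
        Fpeak=fpeak, Tpeak=tpeak, ItoPeak=itopeak, tau_half=tau_half,
        Fbase=fbase, Fpeak_norm=fpeak / denom, ItoPeak_norm=itopeak / denom,
        base_floored=bool(floored))


def _mean_pairwise_correlation(traces: Sequence[np.ndarray]) -> float:
    """Mean Pearson correlation over all trace pairs; NaN-variance traces are
    skipped.  NaN when fewer than two usable traces remain."""
    usable = [np.asarray(t, dtype=float) for t in traces]
    usable = [t for t in usable if np.std(t) > 0]
    if len(usable) < 2:
        return float("nan")
    corr = np.corrcoef(np.vstack(usable))
    iu = np.triu_indices_from(corr, k=1)
    return float(np.mean(corr[iu]))


def run_stats(repeats: Sequence[RepeatStats],
              traces: Sequence[np.ndarray | Repeat]) -> RunStats:
    """Aggregate one run: field-wise medians over its repeats plus the
    within-fly trace correlation.  Undefined tau_half values are excluded
    from the median rather than zero-filled."""
    if len(repeats) != 4:
        warnings.warn(
            f"run has {len(repeats)} repeats instead of 4", stacklevel=2)
    arrays = [t.values if isinstance(t, Repeat) else np.asarray(t)
              for t in traces]
    med = {}
    for name in _MEDIAN_FIELDS:
        vals = np.array([getattr(r, name) for r in repeats], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN tau_half
            med[name] = float(np.nanmedian(vals)) if np.isfinite(vals).any() else float("nan")
    return RunStats(Rwithin_flies=_mean_pairwise_correlation(arrays), **med)


def pair_stats(
    runs_by_fly: Mapping[int, RunStats],
    transients_by_fly: Mapping[int, np.ndarray],
) -> PairStats:
    """Aggregate one (pair, protocol) cell across flies.

    ``transients_by_fly`` holds each fly's average transient (mean of its 4
    repeat traces); their mean pairwise correlation is ``Rbetween_flies``.
    ``Rstate`` correlates each fly's median ItoPeak with its median Fbase.
    Both are undefined (NaN) with a single fly.
    """
    flies = sorted(runs_by_fly)
    if not flies:
        raise ValueError("pair_stats requires at least one fly")
    med = {}
    for name in _MEDIAN_FIELDS + ("Rwithin_flies",):
        vals = np.array([getattr(runs_by_fly[f], name) for f in flies], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med[name] = float(np.nanmedian(vals)) if np.isfinite(vals).any() else float("nan")

    r_between = _mean_pairwise_correlation([transients_by_fly[f] for f in flies])

    r_state = float("nan")
    if len(flies) >= 2:
        x = np.array([runs_by_fly[f].ItoPeak for f in flies])
        y = np.array([runs_by_fly[f].Fbase for f in flies])
        if np.std(x) > 0 and np.std(y) > 0:
            r_state = float(np.corrcoef(x, y)[0, 1])
    return PairStats(Rbetween_flies=r_between, Rstate=r_state,
                     n_flies=len(flies), **med)


def scale_values(values: np.ndarray) -> np.ndarray:
    """Scale a batch of signed values to cover [−1, 1].

    Positive values are divided by the batch maximum, negative values by the
    magnitude of the batch minimum; zeros are unchanged.  An all-zero batch
    returns zeros.  NaNs propagate.
    """
    x = np.asarray(values, dtype=float).copy()
    finite = np.isfinite(x)
    if not finite.any():
        return x
    hi = np.nanmax(x[finite]) if finite.any() else 0.0
    lo = np.nanmin(x[finite]) if finite.any() else 0.0
    pos = finite & (x > 0)
    neg = finite & (x < 0)
    if hi > 0:
        x[pos] = x[pos] / hi
    if lo < 0:
        x[neg] = x[neg] / abs(lo)
    return x


def scale_integrals(run_df: pd.DataFrame, pair_df: pd.DataFrame
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add the four dataset-scaled integral columns.

    Scaling is applied independently to each of ItoPeak and ItoPeak_norm at
    the run level and the pair level, each over its own analysis batch.
    """
    run_df = run_df.copy()
    pair_df = pair_df.copy()
    for col in ("ItoPeak", "ItoPeak_norm"):
        run_df[f"{col}_scaled"] = scale_values(run_df[col].to_numpy())
        pair_df[f"{col}_scaled"] = scale_values(pair_df[col].to_numpy())
    return run_df, pair_df


def compute_screen_stats(
    dataset: ScreenDataset,
    *,
    fbase_floor: float = DEFAULT_FBASE_FLOOR,
    pulse_filter: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the full hierarchy over a screen dataset.

    Returns tidy (repeat_df, run_df, pair_df) frames.  ``pulse_filter``
    restricts the analysis to the given pulse counts.  The scaled integral
    columns are computed over the returned batch.
    """
    repeat_rows, run_rows = [], []
    per_pair: dict[tuple[str, str, int], dict[int, RunStats]] = {}
    per_pair_tr: dict[tuple[str, str, int], dict[int, np.ndarray]] = {}

    for (pre, post, fly, n_pulses), reps in dataset.runs.items():
        if pulse_filter is not None and n_pulses not in pulse_filter:
            continue
        rstats = [repeat_stats(r, fbase_floor=fbase_floor) for r in reps]
        for i, rs in enumerate(rstats):
            repeat_rows.append({"pre": pre, "post": post, "fly": fly,
                                "n_pulses": n_pulses, "repeat": i,
                                **_asdict(rs)})
        rn = run_stats(rstats, reps)
        run_rows.append({"pre": pre, "post": post, "fly": fly,
                         "n_pulses": n_pulses, **_asdict(rn)})
        key = (pre, post, n_pulses)
        per_pair.setdefault(key, {})[fly] = rn
        per_pair_tr.setdefault(key, {})[fly] = np.mean(
            [r.values for r in reps], axis=0)

    pair_rows = []
    for (pre, post, n_pulses), by_fly in per_pair.items():
        ps = pair_stats(by_fly, per_pair_tr[(pre, post, n_pulses)])
        pair_rows.append({"pre": pre, "post": post, "n_pulses": n_pulses,
                          **_asdict(ps)})

    repeat_df = pd.DataFrame(repeat_rows)
    run_df = pd.DataFrame(run_rows)
    pair_df = pd.DataFrame(pair_rows)
    run_df, pair_df = scale_integrals(run_df, pair_df)
    return repeat_df, run_df, pair_df


def _asdict(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dc_fields(obj)}
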