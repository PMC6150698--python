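"""Pipeline configuration: one YAML file drives every stage.

Defaults match the analysis choices documented in ``docs/methods.md``
(sampling rate 10 Hz, 16 s repeats, onset at 4 s, Fbase floor 0.05 ΔF/F0,
MCD support fraction 0.75, B = 10,000 bootstrap replicates at α = 0.01,
classification on the 30-pulse protocol).  The config round-trips to YAML
losslessly; unknown keys raise, naming the key.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synth import (
    GroundTruthConnectome,
    ResponseClass,
    ResponseKind,
    StimulationProtocol,
    default_response_classes,
)

__all__ = ["PipelineConfig", "connectome_from_pairs"]

#: ResponseClass fields that a config pair entry may override.
_CLASS_OVERRIDES = ("peak_amplitude", "rise_tau", "decay_tau", "reliability",
                    "baseline_level", "baseline_drift_sd", "baseline_jitter_sd",
                    "noise_sd", "amplitude_jitter", "state_coupling",
                    "saturation")


@dataclass
class PipelineConfig:
    seed: int = 0
    sampling_rate: float = 10.0
    duration: float = 16.0
    onset_time: float = 4.0
    n_flies: int = 6
    n_repeats: int = 4
    pulse_counts: list[int] = field(default_factory=lambda: [1, 5, 10, 20, 30])
    pulse_rate: float = 30.0
    pulse_duration: float = 0.002
    analysis_pulses: int = 30
    fbase_floor: float = 0.05
    upsample_factor: int = 10
    support_fraction: float = 0.75
    bootstrap_B: int = 10_000
    alpha: float = 0.01
    bootstrap_refit: bool = True
    mcd_seed: int = 0
    pairs: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.analysis_pulses not in self.pulse_counts:
            raise ValueError(
                f"analysis_pulses {self.analysis_pulses} is not among the "
                f"simulated pulse_counts {self.pulse_counts}")

    # -- (de)serialisation -------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(
                f"unknown configuration key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    # -- derived objects ---------------------------------------------------
    def protocols(self) -> list[StimulationProtocol]:
        return [StimulationProtocol(n, pulse_rate=self.pulse_rate,
                                    pulse_duration=self.pulse_duration,
                                    onset_time=self.onset_time)
                for n in self.pulse_counts]

    def connectome(self) -> GroundTruthConnectome:
        if not self.pairs:
            raise KeyError("missing configuration key: pairs")
        return connectome_from_pairs(self.pairs)


def connectome_from_pairs(pairs: list[dict]) -> GroundTruthConnectome:
    """Build a planted connectome from config pair entries.

    Each entry needs ``pre``, ``post``, ``kind`` and ``overlapping``; any
    response-class field may be overridden per pair.
    """
    defaults = default_response_classes()
    cell_types: list[str] = []
    edges: dict[tuple[str, str], ResponseClass] = {}
    overlap: dict[tuple[str, str], bool] = {}
    for entry in pairs:
        entry = dict(entry)
        try:
            pre, post = entry.pop("pre"), entry.pop("post")
            kind = ResponseKind(entry.pop("kind", "none"))
            overlapping = bool(entry.pop("overlapping"))
        except KeyError as err:
            raise KeyError(f"pair entry missing key: {err.args[0]}") from None
        overrides = {k: entry.pop(k) for k in list(entry)
                     if k in _CLASS_OVERRIDES}
        if entry:
            raise KeyError(
                f"unknown pair entry key(s): {', '.join(sorted(entry))}")
        cls = defaults[kind]
        if overrides:
            cls = dataclasses.replace(cls, **overrides)
        for name in (pre, post):
            if name not in cell_types:
                cell_types.append(name)
        edges[(pre, post)] = cls
        overlap[(pre, post)] = overlapping
    return GroundTruthConnectome(cell_types=cell_types, edges=edges,
                                 overlap_labels=overlap)
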