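"""Shared fixtures: small synthetic screens with known ground truth."""

from pathlib import Path

import numpy as np
import pytest

from cxscreen.synth import (
    GroundTruthConnectome,
    ResponseKind,
    StimulationProtocol,
    default_response_classes,
    simulate_experiment,
)

REPO_ROOT = Path(__file__).resolve().parent.parent

#: The packaged fixture screen: 4 strong excitatory, 2 inhibitory and 4
#: unconnected overlapping pairs, plus 20 non-overlapping controls.
FIXTURE_KINDS = ([("strong_excitation", True)] * 4
                 + [("inhibition", True)] * 2
                 + [("none", True)] * 4
                 + [("none", False)] * 20)


def make_fixture_connectome() -> GroundTruthConnectome:
    defaults = default_response_classes()
    edges, overlap, types = {}, {}, []
    for i, (kind, overlapping) in enumerate(FIXTURE_KINDS):
        pre, post = f"T{2 * i + 1:02d}", f"T{2 * i + 2:02d}"
        types += [pre, post]
        edges[(pre, post)] = defaults[ResponseKind(kind)]
        overlap[(pre, post)] = overlapping
    return GroundTruthConnectome(cell_types=types, edges=edges,
                                 overlap_labels=overlap)


def make_null_connectome(n_pairs: int) -> GroundTruthConnectome:
    types = [f"N{i:02d}" for i in range(n_pairs + 1)]
    return GroundTruthConnectome(
        cell_types=types, edges={},
        overlap_labels={(types[i], types[i + 1]): False
                        for i in range(n_pairs)})


@pytest.fixture(scope="session")
def fixture_dataset():
    """The packaged fixture screen, simulated once per session."""
    return simulate_experiment(
        make_fixture_connectome(), n_flies=6,
        protocols=[StimulationProtocol(30)], seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
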