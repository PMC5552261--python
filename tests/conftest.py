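import warnings

import numpy as np
import pytest

from polyphone.raster import Presentation, SpikeRaster

# the tiny decoder MLPs routinely hit the iteration cap on degenerate
# shuffled-label controls; that is expected and not a test signal
warnings.filterwarnings("ignore", message=".*lbfgs failed to converge.*")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_raster(events, presentations):
    """events: (pid, layer, neuron, t); presentations: (pid, cls, dur)."""
    pres = [
        Presentation(pid, cls, exemplar=0, repetition=0, duration_ms=dur)
        for pid, cls, dur in presentations
    ]
    return SpikeRaster.from_events(events, pres)


@pytest.fixture
def micro_config():
    """One input fibre feeding one output neuron, no inhibition."""

    def build(weight=1000.0, delay=None, plastic=False, stdp=None,
              preset="excitatory_subcortical", n_in=1, n_out=1):
        proj = {
            "source": "IN",
            "target": "OUT",
            "kind": "full" if (n_in > 1 or n_out > 1) else "one_to_one",
            "weight": weight,
        }
        if delay is not None:
            proj["delay"] = delay
        if plastic:
            proj["plastic"] = True
            proj["stdp"] = stdp or {}
        return {
            "name": "micro",
            "input_layer": "IN",
            "layers": [
                {"name": "IN", "n_excitatory": n_in, "n_inhibitory": 0},
                {
                    "name": "OUT",
                    "n_excitatory": n_out,
                    "n_inhibitory": 0,
                    "excitatory_preset": preset,
                    "w_EI": 0.0,
                    "w_IE": 0.0,
                },
            ],
            "projections": [proj],
        }

    return build
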