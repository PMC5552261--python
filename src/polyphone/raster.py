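"""Spike-raster container and delimited-file IO.

A :class:`SpikeRaster` is the universal currency between the simulator,
the synthetic input generator and the two measurement procedures: timed
spike events per neuron, grouped into stimulus presentations, each
presentation carrying a class label, an exemplar (speaker) index, a
repetition index and a duration.

Times are in ms relative to presentation onset; neuron indices are
0-based within a layer.  On disk a raster is a pair of delimited tables:

``<stem>.events.csv``        presentation_id, layer, neuron, time_ms
``<stem>.presentations.csv`` presentation_id, stimulus_class, exemplar,
                             repetition, duration_ms
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

EVENT_COLUMNS = ["presentation_id", "layer", "neuron", "time_ms"]
PRESENTATION_COLUMNS = [
    "presentation_id",
    "stimulus_class",
    "exemplar",
    "repetition",
    "duration_ms",
]


@dataclass
class Presentation:
    """Metadata for one stimulus presentation."""

    presentation_id: int
    stimulus_class: int
    exemplar: int
    repetition: int
    duration_ms: float


@dataclass
class SpikeRaster:
    """Spike events for one or more layers over a presentation schedule."""

    events: pd.DataFrame
    presentations: pd.DataFrame

    def __post_init__(self) -> None:
        self.events = self.events.reindex(columns=EVENT_COLUMNS)
        self.presentations = self.presentations.reindex(
            columns=PRESENTATION_COLUMNS
        )

    # -- constructors -------------------------------------------------

    @classmethod
    def from_events(
        cls,
        events: list[tuple[int, str, int, float]],
        presentations: list[Presentation],
    ) -> "SpikeRaster":
        ev = pd.DataFrame(events, columns=EVENT_COLUMNS)
        pres = pd.DataFrame(
            [
                (
                    p.presentation_id,
                    p.stimulus_class,
                    p.exemplar,
                    p.repetition,
                    p.duration_ms,
                )
                for p in presentations
            ],
            columns=PRESENTATION_COLUMNS,
        )
        return cls(ev, pres)

    # -- accessors ----------------------------------------------------

    @property
    def layers(self) -> list[str]:
        return sorted(self.events["layer"].unique())

    @property
    def presentation_ids(self) -> np.ndarray:
        return self.presentations["presentation_id"].to_numpy()

    def layer_events(self, layer: str) -> pd.DataFrame:
        return self.events[self.events["layer"] == layer]

    def presentation_events(self, presentation_id: int, layer: str) -> pd.DataFrame:
        ev = self.events
        return ev[
            (ev["presentation_id"] == presentation_id) & (ev["layer"] == layer)
        ]

    def class_of(self, presentation_id: int) -> int:
        row = self.presentations[
            self.presentations["presentation_id"] == presentation_id
        ]
        if row.empty:
            raise KeyError(f"unknown presentation {presentation_id}")
        return int(row["stimulus_class"].iloc[0])

    def duration_of(self, presentation_id: int) -> float:
        row = self.presentations[
            self.presentations["presentation_id"] == presentation_id
        ]
        if row.empty:
            raise KeyError(f"unknown presentation {presentation_id}")
        return float(row["duration_ms"].iloc[0])

    def validate(self, layer_sizes: dict[str, int] | None = None) -> None:
        """Check raster invariants; raise ValueError on breach."""
        known = set(self.presentations["presentation_id"])
        if not set(self.events["presentation_id"]).issubset(known):
            raise ValueError("event references unknown presentation")
        dur = self.presentations.set_index("presentation_id")["duration_ms"]
        ev_dur = self.events["presentation_id"].map(dur)
        if ((self.events["time_ms"] < 0) | (self.events["time_ms"] > ev_dur)).any():
            raise ValueError("event time outside presentation duration")
        if (self.events["neuron"] < 0).any():
            raise ValueError("negative neuron index")
        if layer_sizes is not None:
            for layer, size in layer_sizes.items():
                ev = self.layer_events(layer)
                if (ev["neuron"] >= size).any():
                    raise ValueError(f"neuron index out of bounds in layer {layer}")

    # -- IO -----------------------------------------------------------

    def save(self, stem: str | Path) -> None:
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        self.events.to_csv(stem.with_suffix(".events.csv"), index=False)
        self.presentations.to_csv(
            stem.with_suffix(".presentations.csv"), index=False
        )

    @classmethod
    def load(cls, stem: str | Path) -> "SpikeRaster":
        stem = Path(stem)
        events = pd.read_csv(stem.with_suffix(".events.csv"))
        presentations = pd.read_csv(stem.with_suffix(".presentations.csv"))
        return cls(events, presentations)


def merge_rasters(rasters: list[SpikeRaster]) -> SpikeRaster:
    """Concatenate rasters that share a presentation schedule."""
    base = rasters[0].presentations
    for r in rasters[1:]:
        if not base.equals(r.presentations):
            raise ValueError("rasters disagree on the presentation schedule")
    events = pd.concat([r.events for r in rasters], ignore_index=True)
    return SpikeRaster(events, base.copy())
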