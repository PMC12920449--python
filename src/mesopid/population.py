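"""Neuron populations: identities and 2-D positions inside a field of view.

Positions are in micrometres within a rectangular field, mirroring the
layout of a mesoscope recording (a few millimetres on a side, thousands of
cells). Pairwise Euclidean distances computed here are the spatial axis of
every downstream profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


@dataclass(frozen=True)
class NeuronPopulation:
    """Neuron coordinates (µm) inside a rectangular field of view.

    Neuron ids are the implicit 0-based row indices of ``x_um``/``y_um``.
    """

    x_um: np.ndarray
    y_um: np.ndarray
    field_width_um: float
    field_height_um: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x_um, dtype=float)
        y = np.asarray(self.y_um, dtype=float)
        object.__setattr__(self, "x_um", x)
        object.__setattr__(self, "y_um", y)
        if x.ndim != 1 or y.shape != x.shape:
            raise ValueError("x_um and y_um must be 1-D arrays of equal length")
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ValueError("field dimensions must be positive")
        if x.size and (
            x.min() < 0
            or y.min() < 0
            or x.max() > self.field_width_um
            or y.max() > self.field_height_um
        ):
            raise ValueError("positions must lie inside the field of view")

    @property
    def n_neurons(self) -> int:
        return self.x_um.size

    @property
    def neuron_ids(self) -> np.ndarray:
        return np.arange(self.n_neurons)

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of positions."""
        return np.column_stack([self.x_um, self.y_um])

    def distance_matrix(self) -> np.ndarray:
        """Full symmetric matrix of pairwise Euclidean distances (µm)."""
        return squareform(pdist(self.coordinates()))

    def pair_distances(self) -> pd.DataFrame:
        """Unordered pairs (i < j) with their distances, lexicographic order."""
        n = self.n_neurons
        i, j = np.triu_indices(n, k=1)
        d = pdist(self.coordinates())
        return pd.DataFrame({"i": i, "j": j, "distance_um": d})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"neuron_id": self.neuron_ids, "x_um": self.x_um, "y_um": self.y_um}
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, field_width_um: float, field_height_um: float
    ) -> "NeuronPopulation":
        for col in ("neuron_id", "x_um", "y_um"):
            if col not in df.columns:
                raise ValueError(f"missing coordinate column: {col!r}")
        df = df.sort_values("neuron_id")
        ids = df["neuron_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("neuron_id must be contiguous from 0")
        return cls(
            x_um=df["x_um"].to_numpy(float),
            y_um=df["y_um"].to_numpy(float),
            field_width_um=field_width_um,
            field_height_um=field_height_um,
        )
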