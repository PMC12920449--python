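"""Reading and writing of dataset artifacts.

Formats: neuron positions as CSV (neuron_id,x_um,y_um); activity and trace
matrices as HDF5 (dataset ``"activity"``, time x neurons) or CSV; pair
tables and edge lists as TSV; fits, summaries and generation parameters as
JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd

from .population import NeuronPopulation

PathLike = Union[str, Path]


def write_population(pop: NeuronPopulation, path: PathLike) -> None:
    pop.to_frame().to_csv(path, index=False)


def read_population(
    path: PathLike, field_width_um: float, field_height_um: float
) -> NeuronPopulation:
    return NeuronPopulation.from_frame(
        pd.read_csv(path), field_width_um, field_height_um
    )


def write_matrix(matrix: np.ndarray, path: PathLike) -> None:
    """Write a (time x neurons) matrix as HDF5 (.h5/.hdf5) or CSV."""
    path = Path(path)
    matrix = np.asarray(matrix)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("activity", data=matrix)
    else:
        pd.DataFrame(matrix).to_csv(path, index=False, header=False)


def read_matrix(path: PathLike) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return f["activity"][...]
    return pd.read_csv(path, header=None).to_numpy()


def is_binary(matrix: np.ndarray) -> bool:
    return bool(np.isin(matrix, (0, 1)).all())


def validate_binary(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix)
    if not is_binary(matrix):
        bad = matrix[~np.isin(matrix, (0, 1))]
        raise ValueError(
            f"matrix declared binary contains non-binary values (e.g. {bad.flat[0]!r})"
        )
    return matrix.astype(np.int8)


def read_dataset(
    positions_path: PathLike,
    matrix_path: PathLike,
    field_width_um: float,
    field_height_um: float,
    mode: str = "auto",
) -> tuple[NeuronPopulation, np.ndarray, str]:
    """Load a dataset and auto-detect binary states vs continuous traces.

    ``mode`` is 'auto', 'binary' or 'traces'; 'binary' enforces a {0,1}
    value support. Returns ``(population, matrix, resolved_mode)``.
    """
    pop = read_population(positions_path, field_width_um, field_height_um)
    matrix = read_matrix(matrix_path)
    if matrix.ndim != 2:
        raise ValueError("activity matrix must be 2-D (time x neurons)")
    if matrix.shape[1] != pop.n_neurons:
        raise ValueError(
            f"ingest error: matrix has {matrix.shape[1]} neuron columns but "
            f"positions list {pop.n_neurons} neurons"
        )
    if mode == "auto":
        mode = "binary" if is_binary(matrix) else "traces"
    if mode == "binary":
        matrix = validate_binary(matrix)
    elif mode != "traces":
        raise ValueError(f"unknown mode {mode!r}")
    return pop, matrix, mode


def write_json(obj: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def read_json(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
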