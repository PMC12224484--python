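"""On-disk layout: cohort tables, connectome matrices, manifests.

The canonical layout written by ``connclass generate``::

    out/
      cohort.csv              one row per subject, fixed header
      manifest.json           config + seed + package version
      corr/S000001.tsv ...    per-subject square matrices (optional)
      pcorr/...
      struct_c0/...

Connectomes can alternatively go into one HDF5 container with a
``subjects x nodes x nodes`` dataset per modality.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortConfig, SubjectRecord, cohort_to_frame, frame_to_cohort

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_matrix",
    "read_matrix",
    "write_matrix_dir",
    "write_hdf5",
    "write_manifest",
    "read_manifest",
]


def write_cohort(subjects: Iterable[SubjectRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort_to_frame(subjects).to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    return frame_to_cohort(pd.read_csv(path))


def write_matrix(matrix: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.asarray(matrix), delimiter="\t")
    return path


def read_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")


def write_matrix_dir(
    subject_ids: Sequence[str],
    matrices: Sequence[np.ndarray],
    directory: str | Path,
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sid, m in zip(subject_ids, matrices):
        write_matrix(m, directory / f"{sid}.tsv")
    return directory


def write_hdf5(
    path: str | Path,
    subject_ids: Sequence[str],
    modalities: dict,
) -> Path:
    """Write one ``subjects x nodes x nodes`` dataset per modality."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("subject_ids", data=np.array(subject_ids, dtype="S"))
        for name, stack in modalities.items():
            f.create_dataset(name, data=np.asarray(stack))
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_manifest(path: str | Path, config: CohortConfig | dict, **extra) -> Path:
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"version": __version__, "config": _jsonable(config), **_jsonable(extra)}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
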