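"""Reading and writing acoustic volumes and clam position tables.

Volumes round-trip through HDF5 (dataset ``"intensity"`` with metadata in
attributes) or through ``.npy`` with a JSON sidecar for metadata. Position
tables are plain CSV with columns ``bucket_id, x, y[, z, kind]``, mirroring
the supplementary ground-truth tables of bucket-scan studies.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .volume import AcousticVolume

_META_KEYS = ("bucket_id", "bucket_type", "scan_pitch_mm", "provenance")

#: Default layout for HDF5 volumes written by this package. A user-supplied
#: layout can adapt externally deposited archives: ``dataset`` names the HDF5
#: dataset holding the grid, ``axes`` maps stored axes onto (x, y, z) order,
#: and ``metadata`` supplies values missing from the file's attributes.
DEFAULT_LAYOUT = {"dataset": "intensity", "axes": (0, 1, 2), "metadata": {}}


def write_volume(vol: AcousticVolume, path: str | Path) -> None:
    """Write a volume to ``.h5``/``.hdf5`` or ``.npy`` (+ ``.json`` sidecar)."""
    path = Path(path)
    meta = {k: getattr(vol, k) for k in _META_KEYS}
    meta.update(vol.attrs)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("intensity", data=vol.intensity)
            for k, v in meta.items():
                ds.attrs[k] = v
    elif path.suffix == ".npy":
        np.save(path, vol.intensity)
        path.with_suffix(".json").write_text(json.dumps(meta))
    else:
        raise ValueError(f"unsupported volume container: {path.suffix!r}")


def read_volume(path: str | Path, layout: dict | None = None) -> AcousticVolume:
    """Read a volume written by :func:`write_volume` or an external archive.

    Parameters
    ----------
    layout
        Optional mapping with keys ``dataset`` (HDF5 dataset name), ``axes``
        (permutation of stored axes onto (x, y, z)) and ``metadata``
        (fallbacks for attributes the file lacks). Defaults to this
        package's own layout.
    """
    path = Path(path)
    lay = dict(DEFAULT_LAYOUT, **(layout or {}))
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            if lay["dataset"] not in fh:
                raise KeyError(
                    f"dataset {lay['dataset']!r} not found in {path.name}; "
                    "pass a layout mapping for external archives"
                )
            ds = fh[lay["dataset"]]
            grid = np.asarray(ds)
            meta = {k: ds.attrs[k] for k in ds.attrs}
    elif path.suffix == ".npy":
        grid = np.load(path)
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    else:
        raise ValueError(f"unsupported volume container: {path.suffix!r}")

    grid = np.transpose(grid, lay["axes"])
    meta = {**lay["metadata"], **meta}
    missing = [k for k in ("bucket_id", "bucket_type") if k not in meta]
    if missing:
        raise KeyError(f"volume metadata missing keys {missing}; supply them "
                       "via layout['metadata']")
    extra = {k: v for k, v in meta.items() if k not in _META_KEYS}
    return AcousticVolume(
        intensity=grid,
        bucket_id=str(meta["bucket_id"]),
        bucket_type=str(meta["bucket_type"]),
        scan_pitch_mm=float(meta.get("scan_pitch_mm", 2.0)),
        provenance=str(meta.get("provenance", "measured")),
        attrs=extra,
    )


def read_positions(path: str | Path) -> pd.DataFrame:
    """Read a clam position table (CSV: bucket_id, x, y[, z, kind])."""
    df = pd.read_csv(path, dtype={"bucket_id": str})
    required = {"bucket_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"position table must have columns {sorted(required)}; "
            f"got {list(df.columns)}"
        )
    return df


def write_positions(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
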