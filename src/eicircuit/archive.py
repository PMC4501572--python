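"""Named-matrix archive: a single HDF5 file holding dense arrays plus scalar metadata.

Every matrix product of the package (dictionaries, factorizations, solver
results, trajectories) round-trips through this one layout: datasets for
arrays, root attributes for scalars/strings, and a ``format_version`` stamp.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import h5py
import numpy as np

from .errors import FormatError

FORMAT_VERSION = "1"


def save_arrays(path: str | Path, arrays: dict[str, np.ndarray],
                meta: dict | None = None) -> None:
    """Write named arrays and scalar metadata to ``path``, overwriting it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        for name, arr in arrays.items():
            f.create_dataset(name, data=np.asarray(arr))
        for key, val in (meta or {}).items():
            f.attrs[key] = val


def load_arrays(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Read back ``(arrays, meta)``; warns on a version mismatch."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with h5py.File(path, "r") as f:
            meta = dict(f.attrs)
            arrays = {name: np.asarray(f[name]) for name in f.keys()}
    except OSError as exc:  # not an HDF5 file / truncated
        raise FormatError(f"cannot read archive {path}: {exc}") from exc
    version = meta.pop("format_version", None)
    if version != FORMAT_VERSION:
        warnings.warn(
            f"archive {path} has format version {version!r}, expected "
            f"{FORMAT_VERSION!r}; attempting to read anyway", stacklevel=2)
    return arrays, meta
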