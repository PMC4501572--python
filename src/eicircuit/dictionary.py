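"""Feature dictionaries and their Gram (recurrent connectivity) matrices.

The dictionary Φ is an N × M matrix whose columns are unit-norm visual
features on a square pixel patch (N = patch_edge², row-major pixels, origin
at the top-left).  Columns play the role of principal-cell receptive fields.
The recurrent interactions of every network in this package are governed by
the Gram matrix G = ΦᵀΦ.

Because learned natural-image dictionaries are well described as Gabor
wavelets, the generator here synthesizes random Gabor columns directly:
an oriented sinusoid under an elongated Gaussian envelope, with parameters
drawn uniformly over configurable ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .archive import load_arrays, save_arrays
from .errors import FormatError, GeometryError, ParameterError

logger = logging.getLogger(__name__)

#: Default uniform sampling ranges for Gabor parameters.  Frequencies span
#: the band where 16-pixel patches resolve several cycles without aliasing;
#: the envelope is elongated along the bar (aspect 1.5–2), mimicking the
#: qualitative statistics of sparse-coding-learned dictionaries.
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "center_x": (0.15, 0.85),      # fraction of patch_edge
    "center_y": (0.15, 0.85),
    "orientation": (0.0, np.pi),   # radians
    "frequency": (0.08, 0.35),     # cycles / pixel
    "phase": (0.0, 2 * np.pi),
    "sigma_factor": (0.25, 0.45),  # envelope width across stripes, in periods
    "aspect": (1.5, 2.0),          # elongation along the bar
}

_NORM_TOL = 1e-10


@dataclass
class Dictionary:
    """Unit-norm feature dictionary Φ (N pixels × M elements)."""

    phi: np.ndarray
    patch_edge: int
    element_params: pd.DataFrame | None = None

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 2:
            raise FormatError("phi must be a 2-D array")
        n, m = self.phi.shape
        if n != self.patch_edge ** 2:
            raise GeometryError(
                f"phi has {n} rows but patch_edge={self.patch_edge} implies "
                f"{self.patch_edge ** 2}")
        if m < 1:
            raise ParameterError("dictionary needs at least one element")
        norms = np.linalg.norm(self.phi, axis=0)
        if np.any(np.abs(norms - 1.0) > _NORM_TOL):
            raise ParameterError("dictionary columns must have unit l2 norm")

    @property
    def n_pixels(self) -> int:
        return self.phi.shape[0]

    @property
    def n_elements(self) -> int:
        return self.phi.shape[1]

    def element_image(self, j: int) -> np.ndarray:
        """Column ``j`` reshaped to a patch_edge × patch_edge image."""
        return self.phi[:, j].reshape(self.patch_edge, self.patch_edge)


@dataclass
class ConnectivityMatrix:
    """Symmetric PSD recurrent connectivity matrix G (M × M)."""

    g: np.ndarray
    source_tag: str = "gram"

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        if self.g.ndim != 2 or self.g.shape[0] != self.g.shape[1]:
            raise FormatError("connectivity matrix must be square")
        if np.max(np.abs(self.g - self.g.T)) > 1e-10:
            raise ParameterError("connectivity matrix must be symmetric")

    @property
    def m(self) -> int:
        return self.g.shape[0]


def _gabor_column(patch_edge: int, cx: float, cy: float, theta: float,
                  freq: float, phase: float, sigma_par: float,
                  sigma_perp: float) -> np.ndarray:
    """Discretized Gabor: oriented cosine grating × elongated Gaussian."""
    coords = np.arange(patch_edge, dtype=float)
    # row-major pixel order: x = column index, y = row index
    y, x = np.meshgrid(coords, coords, indexing="ij")
    dx, dy = x - cx, y - cy
    # x' runs across the stripes (carrier direction), y' along the bar
    xp = dx * np.cos(theta) + dy * np.sin(theta)
    yp = -dx * np.sin(theta) + dy * np.cos(theta)
    envelope = np.exp(-0.5 * ((xp / sigma_par) ** 2 + (yp / sigma_perp) ** 2))
    carrier = np.cos(2 * np.pi * freq * xp + phase)
    return (envelope * carrier).ravel()


def generate_gabor_dictionary(patch_edge: int, n_elements: int, seed: int,
                              param_ranges: dict | None = None) -> Dictionary:
    """Sample ``n_elements`` random Gabor features on a ``patch_edge``² patch.

    Parameters are drawn uniformly over ``param_ranges`` (see
    :data:`DEFAULT_PARAM_RANGES`); columns are normalized to unit l2 norm.
    Deterministic for a fixed ``seed``.
    """
    if patch_edge < 3:
        raise GeometryError("patch_edge must be at least 3")
    if n_elements < 1:
        raise ParameterError("n_elements must be >= 1")
    ranges = dict(DEFAULT_PARAM_RANGES)
    ranges.update(param_ranges or {})
    for key, (lo, hi) in ranges.items():
        if hi < lo:
            raise ParameterError(f"degenerate range for {key}: ({lo}, {hi})")

    rng = np.random.default_rng(seed)
    n = patch_edge ** 2
    phi = np.empty((n, n_elements))
    rows = []
    j = 0
    while j < n_elements:
        draw = {k: rng.uniform(lo, hi) for k, (lo, hi) in ranges.items()}
        cx = draw["center_x"] * (patch_edge - 1)
        cy = draw["center_y"] * (patch_edge - 1)
        period = 1.0 / draw["frequency"]
        sigma_par = draw["sigma_factor"] * period
        sigma_perp = draw["aspect"] * sigma_par
        col = _gabor_column(patch_edge, cx, cy, draw["orientation"],
                            draw["frequency"], draw["phase"],
                            sigma_par, sigma_perp)
        norm = np.linalg.norm(col)
        if norm < 1e-8:  # phase landed on a node; resample
            continue
        phi[:, j] = col / norm
        rows.append({"center_x": cx, "center_y": cy,
                     "orientation": draw["orientation"],
                     "frequency": draw["frequency"], "phase": draw["phase"],
                     "sigma_par": sigma_par, "sigma_perp": sigma_perp})
        j += 1
    params = pd.DataFrame(rows)
    return Dictionary(phi=phi, patch_edge=patch_edge, element_params=params)


def save_dictionary(d: Dictionary, path: str | Path) -> None:
    """Persist a dictionary to the named-matrix archive."""
    arrays = {"phi": d.phi}
    if d.element_params is not None:
        for col in d.element_params.columns:
            arrays[f"param_{col}"] = d.element_params[col].to_numpy()
    save_arrays(path, arrays, meta={"patch_edge": d.patch_edge,
                                    "kind": "dictionary"})


def load_dictionary(path: str | Path) -> Dictionary:
    """Load a dictionary archive, re-normalizing columns if needed.

    Columns whose norm deviates from 1 by more than 1e-6 are renormalized
    with a logged warning; zero columns are a format error.
    """
    arrays, meta = load_arrays(path)
    if "phi" not in arrays:
        raise FormatError(f"archive {path} has no 'phi' array")
    phi = np.asarray(arrays["phi"], dtype=float)
    if phi.ndim != 2:
        raise FormatError("'phi' must be 2-D")
    if "patch_edge" in meta:
        patch_edge = int(meta["patch_edge"])
    else:
        patch_edge = int(round(np.sqrt(phi.shape[0])))
    if patch_edge ** 2 != phi.shape[0]:
        raise FormatError(
            f"pixel count {phi.shape[0]} is not a square patch")
    norms = np.linalg.norm(phi, axis=0)
    if np.any(norms < 1e-12):
        raise FormatError("archive contains an all-zero dictionary column")
    if np.any(np.abs(norms - 1.0) > 1e-6):
        logger.warning("renormalizing %d dictionary column(s) with non-unit "
                       "norm in %s", int(np.sum(np.abs(norms - 1.0) > 1e-6)),
                       path)
        phi = phi / norms
    else:
        phi = phi / norms  # tighten to exact unit norm
    param_cols = {k[len("param_"):]: v for k, v in arrays.items()
                  if k.startswith("param_")}
    params = pd.DataFrame(param_cols) if param_cols else None
    return Dictionary(phi=phi, patch_edge=patch_edge, element_params=params)


def gram_matrix(d: Dictionary) -> ConnectivityMatrix:
    """Recurrent connectivity G = ΦᵀΦ of a dictionary (symmetrized to kill
    round-off skew; unit diagonal for unit-norm columns)."""
    g = d.phi.T @ d.phi
    g = 0.5 * (g + g.T)
    np.fill_diagonal(g, 1.0)
    return ConnectivityMatrix(g=g, source_tag="gram")
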