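"""Deterministic synthetic inputs: planted low-rank + column-sparse models
and standard Gabor fixtures at two scales.

Planted models provide exact ground truth for the robust-PCA solver: a PSD
low-rank part (matching the Gram-matrix structure of real inputs) plus a
known set of nonzero columns.  The standard fixtures mirror the study's
network geometry: ``full`` is a 16×16-patch, 2048-element dictionary;
``small`` is an 8×8-patch, 128-element dictionary for fast tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dictionary import (ConnectivityMatrix, Dictionary,
                         generate_gabor_dictionary, gram_matrix,
                         load_dictionary, save_dictionary)
from .errors import ParameterError

FIXTURE_SCALES = {
    "full": {"patch_edge": 16, "n_elements": 2048},
    "small": {"patch_edge": 8, "n_elements": 128},
}


@dataclass
class PlantedModel:
    """Ground-truth decomposition g = l_true + s_true (exact)."""

    g: np.ndarray
    l_true: np.ndarray
    s_true: np.ndarray
    rank: int
    support: np.ndarray  # indices of the planted nonzero columns
    seed: int


def make_planted(m: int, rank: int, n_sparse_cols: int,
                 magnitude: float = 0.5, seed: int = 0) -> PlantedModel:
    """Plant a rank-``rank`` PSD matrix plus ``n_sparse_cols`` dense columns.

    The low-rank part is AAᵀ (A random Gaussian, m × rank) scaled to unit
    spectral norm; each planted column of the sparse part has entries of
    typical size ``magnitude`` with mixed signs.  Sizes obey the
    incoherence heuristic rank ≤ m/10 and n_sparse_cols ≤ m/10.
    """
    if m < 10:
        raise ParameterError("planted models need m >= 10")
    if rank < 0 or n_sparse_cols < 0:
        raise ParameterError("rank and n_sparse_cols must be >= 0")
    if rank > m / 10 or n_sparse_cols > m / 10:
        raise ParameterError(
            "infeasible sizes: need rank <= m/10 and n_sparse_cols <= m/10")
    rng = np.random.default_rng(seed)
    if rank > 0:
        a = rng.standard_normal((m, rank))
        l = a @ a.T
        l /= np.linalg.norm(l, 2)
    else:
        l = np.zeros((m, m))
    s = np.zeros((m, m))
    support = np.sort(rng.choice(m, size=n_sparse_cols, replace=False)) \
        if n_sparse_cols else np.array([], dtype=int)
    for j in support:
        signs = rng.choice([-1.0, 1.0], size=m)
        s[:, j] = signs * rng.uniform(0.5, 1.5, size=m) * magnitude
    return PlantedModel(g=l + s, l_true=l, s_true=s, rank=rank,
                        support=support, seed=seed)


def make_standard_fixture(scale: str = "full", seed: int = 0,
                          cache_dir: str | Path | None = None,
                          ) -> tuple[Dictionary, ConnectivityMatrix]:
    """The standard Gabor dictionary and its Gram matrix at a named scale.

    With ``cache_dir`` the generated dictionary is stored in (and reloaded
    from) a named-matrix archive keyed by scale and seed.
    """
    if scale not in FIXTURE_SCALES:
        raise ParameterError(
            f"unknown scale {scale!r}; choose from {sorted(FIXTURE_SCALES)}")
    spec = FIXTURE_SCALES[scale]
    if cache_dir is not None:
        path = Path(cache_dir) / f"dictionary_{scale}_seed{seed}.h5"
        if path.exists():
            d = load_dictionary(path)
            return d, gram_matrix(d)
    d = generate_gabor_dictionary(spec["patch_edge"], spec["n_elements"],
                                  seed=seed)
    if cache_dir is not None:
        save_dictionary(d, path)
    return d, gram_matrix(d)
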