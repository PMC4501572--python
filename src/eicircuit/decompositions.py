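"""Dale's-law factorizations of the recurrent connectivity matrix.

The recurrent matrix splits entrywise into inhibitory and excitatory
effects, G = G₊ + G₋ = G^Inhib + G^Excite: positive entries are recurrent
inhibition (routed through interneurons), negative entries are direct E→E
excitation.  Four interneuron implementations of G^Inhib are built here:

* ``direct``   — one interneuron per principal cell: G^Inhib = I·G₊ (M cells);
* ``gramian``  — pixel-indexed interneurons from G = ΦᵀΦ:
                 G^Inhib = Φ₊ᵀΦ₊ + Φ₋ᵀΦ₋ (N pixel units, each bundling an
                 ON and an OFF channel);
* ``svd``      — truncated eigendecomposition G ≈ UΣVᵀ, sign-split into two
                 populations with inputs ΣV₊ᵀ and Σ(−V₋ᵀ), outputs U₊ and
                 −U₋ (2r cells);
* ``rpca``     — the svd scheme applied to the low-rank part L of an
                 adaptive robust-PCA decomposition G = L + S, plus one
                 selectively-connected interneuron per retained nonzero
                 column of S (input row of the 0/1 diagonal D, output the
                 corresponding column of S₊).

Every interneuron weight stored here is nonnegative; the inhibitory sign is
applied when the network is assembled (the drive enters with a minus sign).
The excitatory recurrent term I − G^Excite is likewise entrywise
nonnegative by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .arpca import ARPCAResult
from .dictionary import ConnectivityMatrix, Dictionary
from .errors import AssemblyError, ParameterError, UndefinedStatisticError

#: Columns of S with l2 norm below this fraction of the largest column norm
#: are treated as zero.  The uncapped-mu ADMM schedule leaves ~1e-3-scale
#: numerical residue in priced-out columns, so the cut sits well above
#: that floor; genuinely surviving columns are orders of magnitude larger.
SPARSE_COLUMN_TOL = 1e-2


@dataclass
class SignSplit:
    """Entrywise split G = g_plus + g_minus with disjoint supports."""

    g_plus: np.ndarray
    g_minus: np.ndarray


@dataclass
class EIFactorization:
    """A network-ready interneuron implementation of G^Inhib.

    ``inhib_in[k]`` holds the synases from principal cells onto population
    k (one row per interneuron), ``inhib_gain[k]`` the per-cell gains, and
    ``inhib_out[k]`` the projections back (one column per interneuron), so
    the population's inhibitory contribution is out·diag(gain)·in.
    ``g_excite_direct`` is the direct E→E matrix I − G^Excite (entrywise
    ≥ 0).  ``counts`` tallies interneurons after pruning zero rows/columns.
    """

    scheme: str
    population_names: list[str]
    inhib_in: list[np.ndarray]
    inhib_gain: list[np.ndarray]
    inhib_out: list[np.ndarray]
    g_excite_direct: np.ndarray
    counts: dict[str, int]
    rank_r: int | None = None
    sparse_in_selector: np.ndarray | None = None  # diagonal of D (0/1)
    sparse_col_indices: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, w_in, gain, w_out in zip(self.population_names,
                                           self.inhib_in, self.inhib_gain,
                                           self.inhib_out):
            for label, w in (("input", w_in), ("gain", gain),
                             ("output", w_out)):
                if np.any(np.asarray(w) < 0):
                    raise AssemblyError(
                        f"negative {label} weight in population {name}")
        if np.any(self.g_excite_direct < 0):
            raise AssemblyError("negative entry in the E->E weight matrix")

    @property
    def m(self) -> int:
        return self.g_excite_direct.shape[0]

    def population_sizes(self) -> dict[str, int]:
        return {name: w.shape[0] for name, w in
                zip(self.population_names, self.inhib_in)}


def sign_split(g: ConnectivityMatrix) -> SignSplit:
    """Entrywise positive/negative split of the recurrent matrix."""
    gm = g.g
    return SignSplit(g_plus=np.maximum(gm, 0.0), g_minus=np.minimum(gm, 0.0))


def _prune(w_in: np.ndarray, gain: np.ndarray, w_out: np.ndarray):
    """Drop interneurons whose input row, gain, or output column is zero."""
    keep = ~((np.all(w_in == 0, axis=1)) | (gain == 0)
             | np.all(w_out == 0, axis=0))
    return w_in[keep], gain[keep], w_out[:, keep], keep


def direct_factorization(g: ConnectivityMatrix) -> EIFactorization:
    """One interneuron per principal cell: G^Inhib = I·G₊."""
    split = sign_split(g)
    m = g.m
    return EIFactorization(
        scheme="direct",
        population_names=["direct"],
        inhib_in=[split.g_plus.copy()],
        inhib_gain=[np.ones(m)],
        inhib_out=[np.eye(m)],
        g_excite_direct=np.eye(m) - split.g_minus,
        counts={"low_rank": 0, "sparse": 0, "direct": m, "total": m},
    )


def gramian_factorization(d: Dictionary) -> EIFactorization:
    """Pixel-indexed interneurons from the Gramian structure of G = ΦᵀΦ.

    G^Inhib = Φ₊ᵀΦ₊ + Φ₋ᵀΦ₋ is carried by one interneuron unit per pixel,
    each bundling an ON channel (weights = that pixel's row of Φ₊) and an
    OFF channel (weights = that pixel's row of −Φ₋); the count is N units.
    Internally the two channels are kept as separate weight rows (2N rows)
    with pixel-pairing metadata, since a single scalar-activity unit cannot
    carry two distinct weight patterns.  G^Excite = Φ₊ᵀΦ₋ + Φ₋ᵀΦ₊ ≤ 0 goes
    to the direct E→E matrix.
    """
    phi_plus = np.maximum(d.phi, 0.0)
    phi_minus = np.minimum(d.phi, 0.0)
    n, m = d.phi.shape
    on_in, on_gain, on_out, on_keep = _prune(
        phi_plus.copy(), np.ones(n), phi_plus.T.copy())
    off_in, off_gain, off_out, off_keep = _prune(
        -phi_minus, np.ones(n), -phi_minus.T)
    g_excite = phi_plus.T @ phi_minus + phi_minus.T @ phi_plus
    g_excite = np.minimum(g_excite, 0.0)  # clip +0. round-off
    np.fill_diagonal(g_excite, np.minimum(np.diag(g_excite), 0.0))
    n_units = int(np.count_nonzero(on_keep | off_keep))
    return EIFactorization(
        scheme="gramian",
        population_names=["on", "off"],
        inhib_in=[on_in, off_in],
        inhib_gain=[on_gain, off_gain],
        inhib_out=[on_out, off_out],
        g_excite_direct=np.eye(m) - g_excite,
        counts={"low_rank": 0, "sparse": 0, "pixel_units": n_units,
                "total": n_units},
        meta={"on_pixels": np.flatnonzero(on_keep),
              "off_pixels": np.flatnonzero(off_keep)},
    )


def _top_eigh(gm: np.ndarray, rank_r: int):
    """Top-``rank_r`` eigenpairs of a symmetric matrix, descending order."""
    m = gm.shape[0]
    vals, vecs = scipy.linalg.eigh(
        gm, subset_by_index=[m - rank_r, m - 1])
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def _split_uv(u: np.ndarray, sigma: np.ndarray, v: np.ndarray):
    """Sign-split populations for L = UΣVᵀ: inputs ΣV₊ᵀ / Σ(−V₋ᵀ),
    outputs U₊ / −U₋, gains Σ."""
    u_plus, u_minus = np.maximum(u, 0.0), np.minimum(u, 0.0)
    v_plus, v_minus = np.maximum(v, 0.0), np.minimum(v, 0.0)
    pop1 = (v_plus.T.copy(), sigma.copy(), u_plus.copy())
    pop2 = ((-v_minus).T.copy(), sigma.copy(), (-u_minus).copy())
    g_excite = u_minus @ np.diag(sigma) @ v_plus.T \
        + u_plus @ np.diag(sigma) @ v_minus.T
    g_excite = np.minimum(g_excite, 0.0)
    return pop1, pop2, g_excite


def svd_factorization(g: ConnectivityMatrix, rank_r: int) -> EIFactorization:
    """Truncated eigendecomposition of the symmetric PSD matrix G.

    Because G is symmetric PSD its truncated singular triplets coincide
    with its top eigenpairs, so L = UΣUᵀ with Σ the top eigenvalues.  Two
    interneuron populations implement the sign-split of L.
    """
    m = g.m
    if not (1 <= rank_r <= m):
        raise ParameterError(f"rank_r must lie in [1, {m}]")
    vals, vecs = _top_eigh(g.g, rank_r)
    sigma = np.clip(vals, 0.0, None)
    pop1, pop2, g_excite = _split_uv(vecs, sigma, vecs)
    in1, gain1, out1, _ = _prune(*pop1)
    in2, gain2, out2, _ = _prune(*pop2)
    total = in1.shape[0] + in2.shape[0]
    return EIFactorization(
        scheme="svd",
        population_names=["low_rank_1", "low_rank_2"],
        inhib_in=[in1, in2],
        inhib_gain=[gain1, gain2],
        inhib_out=[out1, out2],
        g_excite_direct=np.eye(m) - g_excite,
        counts={"low_rank": total, "sparse": 0, "total": total},
        rank_r=rank_r,
    )


def variance_explained(g_or_l: ConnectivityMatrix | np.ndarray,
                       rank_r: int) -> float:
    """Fraction of eigenvalue mass captured by the top ``rank_r``
    eigenvalues (eigenvalues clipped at 0; G is PSD up to round-off)."""
    gm = g_or_l.g if isinstance(g_or_l, ConnectivityMatrix) else \
        np.asarray(g_or_l)
    if rank_r < 1:
        raise ParameterError("rank_r must be >= 1")
    sym = 0.5 * (gm + gm.T)
    vals = np.clip(scipy.linalg.eigvalsh(sym), 0.0, None)[::-1]
    total = float(np.sum(vals))
    if total == 0:
        raise UndefinedStatisticError("all-zero matrix has no variance")
    return float(np.sum(vals[:rank_r]) / total)


def rpca_factorization(arpca: ARPCAResult, rank_r: int,
                       column_tol: float = SPARSE_COLUMN_TOL,
                       ) -> EIFactorization:
    """Low-rank + sparse interneuron network from an ARPCA result.

    The low-rank part L is factored exactly as in :func:`svd_factorization`
    at ``rank_r`` (via SVD of L, which may be slightly nonsymmetric after
    ADMM).  Each retained nonzero column j of S (column l2 norm above
    ``column_tol`` × the largest column norm) becomes one sparse-population
    interneuron receiving a unit-weight connection from principal cell j
    (a row of the 0/1 diagonal D) and projecting back with the positive
    part of that column; S₋ joins the direct E→E matrix.
    """
    l_mat, s_mat = arpca.l, arpca.s
    m = l_mat.shape[0]
    u_full, sigma_full, vt_full = np.linalg.svd(l_mat, full_matrices=False)
    eff_rank = int(np.sum(sigma_full > max(1e-12, 1e-10 * sigma_full[0])))
    if rank_r > eff_rank:
        raise ParameterError(
            f"rank_r={rank_r} exceeds the effective rank {eff_rank} of L")
    u = u_full[:, :rank_r]
    sigma = sigma_full[:rank_r]
    v = vt_full[:rank_r].T
    pop1, pop2, g_excite_lr = _split_uv(u, sigma, v)
    in1, gain1, out1, _ = _prune(*pop1)
    in2, gain2, out2, _ = _prune(*pop2)

    col_norms = np.linalg.norm(s_mat, axis=0)
    max_norm = col_norms.max() if col_norms.size else 0.0
    if max_norm <= 0:
        retained = np.zeros(m, dtype=bool)
    else:
        retained = col_norms > column_tol * max_norm
    cols = np.flatnonzero(retained)
    if cols.size == 0:
        warnings.warn("sparse part S has no nonzero columns; the sparse "
                      "interneuron population is empty", stacklevel=2)
    s_plus = np.maximum(s_mat, 0.0)
    s_minus = np.minimum(s_mat, 0.0)
    # sparse population: input = rows of D (unit weight from cell j),
    # output = S₊ column j
    sparse_in = np.zeros((cols.size, m))
    sparse_in[np.arange(cols.size), cols] = 1.0
    sparse_out = s_plus[:, cols].copy()
    sparse_gain = np.ones(cols.size)

    g_excite = np.minimum(g_excite_lr + s_minus, 0.0)
    n_low = in1.shape[0] + in2.shape[0]
    d_diag = retained.astype(float)
    return EIFactorization(
        scheme="rpca",
        population_names=["low_rank_1", "low_rank_2", "sparse"],
        inhib_in=[in1, in2, sparse_in],
        inhib_gain=[gain1, gain2, sparse_gain],
        inhib_out=[out1, out2, sparse_out],
        g_excite_direct=np.eye(m) - g_excite,
        counts={"low_rank": n_low, "sparse": int(cols.size),
                "total": n_low + int(cols.size)},
        rank_r=rank_r,
        sparse_in_selector=d_diag,
        sparse_col_indices=cols,
    )


def assemble_gi_ge(f: EIFactorization) -> tuple[np.ndarray, np.ndarray]:
    """Assemble (G^Inhib, I − G^Excite) from the factor matrices.

    G^Inhib = Σ over populations of out·diag(gain)·in (which includes the
    S₊D term for the rpca scheme).  Both returned matrices are entrywise
    nonnegative; any negative entry raises an assembly error.
    """
    m = f.m
    g_inhib = np.zeros((m, m))
    for w_in, gain, w_out in zip(f.inhib_in, f.inhib_gain, f.inhib_out):
        if w_in.shape[0] == 0:
            continue
        g_inhib += (w_out * gain[np.newaxis, :]) @ w_in
    if np.any(g_inhib < 0) or np.any(f.g_excite_direct < 0):
        raise AssemblyError("assembled network violates Dale's law")
    return g_inhib, f.g_excite_direct
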