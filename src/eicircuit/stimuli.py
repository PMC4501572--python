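"""Stimulus patches: gratings, single-pixel dots, and factorial test grids.

All stimuli are N-vectors over the same row-major pixel layout as the
dictionary module (N = patch_edge², origin top-left).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .errors import AliasingError, ParameterError

#: Default factorial grating grid used by the equivalence analyses:
#: 12 orientations on [0, π), two spatial frequencies, two phases,
#: unit contrast, full-field.
DEFAULT_GRATING_GRID = {
    "n_orientations": 12,
    "frequencies": (0.1, 0.2),
    "phases": (0.0, np.pi / 2),
    "contrasts": (1.0,),
}


@dataclass
class Stimulus:
    """A pixel patch: the input vector s of the coding model."""

    s: np.ndarray
    kind: str = "custom"  # grating | dot | custom
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float).ravel()
        if not np.all(np.isfinite(self.s)):
            raise ParameterError("stimulus contains non-finite pixels")


def make_grating(patch_edge: int, orientation: float, frequency: float,
                 phase: float = 0.0, contrast: float = 1.0,
                 center: tuple[float, float] | None = None,
                 windowed: bool = False,
                 envelope_radius: float | None = None,
                 normalize: bool = False) -> Stimulus:
    """Sinusoidal luminance grating, optionally under a Gaussian window.

    ``frequency`` is in cycles/pixel and must not exceed the Nyquist limit
    0.5.  The carrier is ``contrast * cos(2π f (x cosθ + y sinθ) + phase)``
    with its phase origin at pixel (0, 0), or at ``center`` when one is
    given; when ``windowed`` a Gaussian envelope of scale
    ``envelope_radius`` (default patch_edge/4) centered at ``center``
    (default patch middle) multiplies the carrier.

    With ``normalize`` the patch is rescaled to unit l2 norm after the
    contrast scaling (contrast then acts as a relative weight between
    stimuli rather than an absolute amplitude).  The sparse-coding
    threshold λ is calibrated against unit-scale inputs, so the
    equivalence and tuning protocols use normalized patches.
    """
    if frequency <= 0:
        raise ParameterError("grating frequency must be positive")
    if frequency > 0.5:
        raise AliasingError(
            f"frequency {frequency} exceeds the Nyquist limit 0.5 c/px")
    coords = np.arange(patch_edge, dtype=float)
    y, x = np.meshgrid(coords, coords, indexing="ij")
    mid = (patch_edge - 1) / 2.0
    if center is None:
        ox = oy = 0.0          # carrier phase origin
        ex, ey = mid, mid      # envelope center
    else:
        ox, oy = center
        ex, ey = center
    carrier = np.cos(2 * np.pi * frequency
                     * ((x - ox) * np.cos(orientation)
                        + (y - oy) * np.sin(orientation)) + phase)
    patch = contrast * carrier
    if windowed:
        radius = envelope_radius if envelope_radius is not None \
            else patch_edge / 4.0
        patch = patch * np.exp(-((x - ex) ** 2 + (y - ey) ** 2)
                               / (2.0 * radius ** 2))
    patch = patch.ravel()
    if normalize:
        norm = np.linalg.norm(patch)
        if norm > 0:
            patch = patch / norm
    return Stimulus(s=patch, kind="grating",
                    params={"orientation": orientation,
                            "frequency": frequency, "phase": phase,
                            "contrast": contrast, "center": center,
                            "windowed": windowed, "normalized": normalize})


def make_dot(patch_edge: int, pixel: int, polarity: int = 1,
             amplitude: float = 1.0) -> Stimulus:
    """Single-pixel (sparse-dot) stimulus: polarity·amplitude at one pixel."""
    n = patch_edge ** 2
    if not (0 <= pixel < n):
        raise IndexError(f"pixel {pixel} out of range [0, {n})")
    if polarity not in (-1, 1):
        raise ParameterError("polarity must be +1 or -1")
    s = np.zeros(n)
    s[pixel] = polarity * amplitude
    return Stimulus(s=s, kind="dot",
                    params={"pixel": pixel, "polarity": polarity,
                            "amplitude": amplitude})


def grating_test_set(patch_edge: int, n_orientations: int,
                     frequencies, phases, contrasts,
                     seed: int = 0, normalize: bool = True) -> list[Stimulus]:
    """Full factorial grid of full-field gratings in deterministic order
    (orientation-major, then frequency, phase, contrast), normalized to
    unit l2 norm by default."""
    if n_orientations < 1 or not len(frequencies) or not len(phases) \
            or not len(contrasts):
        raise ParameterError("grating grid must be non-empty")
    orientations = np.arange(n_orientations) * np.pi / n_orientations
    stimuli = []
    for theta, f, ph, c in product(orientations, frequencies, phases,
                                   contrasts):
        stimuli.append(make_grating(patch_edge, theta, f, ph, c,
                                    normalize=normalize))
    return stimuli


def default_grating_set(patch_edge: int) -> list[Stimulus]:
    """The standard 48-stimulus grating grid of the equivalence analyses."""
    grid = DEFAULT_GRATING_GRID
    return grating_test_set(patch_edge, grid["n_orientations"],
                            grid["frequencies"], grid["phases"],
                            grid["contrasts"])
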