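"""Sensory map of projected Vegfr activations and AP signature measures.

The sensory map is a fixed cylindrical-surface grid covering the whole
vessel (one bin per 0.5 x 0.5 um surface patch: axial bins along x,
circumferential bins around the cross-section).  Every activated receptor
— including those carried into space on filopodia — is projected radially
back onto the surface: the displacement from the activation to the axis is
normalised and scaled to the vessel radius, preserving the axial
coordinate and azimuth.  Activations over a neighbour cell's territory are
credited to the bin under them, not to the owning cell's base: the map is
a vessel-level representation of sensing.

Two signature measures are computed per time step:

* intensity ``I`` — the total activation count over the map,
* Shannon entropy ``H`` (bits) of the spatial activation distribution,
  inferred with Laplace smoothing:
  ``p_i = (v_i + alpha) / (sum v + N alpha)``, ``H = -sum p_i log2 p_i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .lattice import GRID_UM


class ProjectionError(ValueError):
    """Raised for points on the cylinder axis (undefined azimuth)."""


@dataclass
class CylinderGeometry:
    """Fixed surface grid of the vessel used by the sensory map."""

    n_axial: int
    n_circ: int
    radius_um: float
    y_center_um: float
    z_center_um: float

    @property
    def n_bins(self) -> int:
        return self.n_axial * self.n_circ


def project_activation(point, geom: CylinderGeometry) -> int:
    """Map a 3-D activation position (um) to its surface bin index.

    Radial projection: the azimuth of the displacement from the axis and
    the axial coordinate are preserved; the radial distance is discarded.
    Points already on the surface map to their own bin (idempotent).
    """
    x, y, z = float(point[0]), float(point[1]), float(point[2])
    dy = y - geom.y_center_um
    dz = z - geom.z_center_um
    if dy == 0.0 and dz == 0.0:
        raise ProjectionError("point on the cylinder axis has no azimuth")
    ax = int(math.floor(x / GRID_UM)) % geom.n_axial
    phi = math.atan2(dy, dz) % (2 * math.pi)
    circ = int(phi / (2 * math.pi) * geom.n_circ) % geom.n_circ
    return ax * geom.n_circ + circ


def project_activation_array(points: np.ndarray, geom: CylinderGeometry) -> np.ndarray:
    """Vectorised :func:`project_activation` for an (n, 3) position array."""
    dy = points[:, 1] - geom.y_center_um
    dz = points[:, 2] - geom.z_center_um
    if np.any((dy == 0) & (dz == 0)):
        raise ProjectionError("point on the cylinder axis has no azimuth")
    ax = np.floor(points[:, 0] / GRID_UM).astype(np.int64) % geom.n_axial
    phi = np.mod(np.arctan2(dy, dz), 2 * math.pi)
    circ = (phi / (2 * math.pi) * geom.n_circ).astype(np.int64) % geom.n_circ
    return ax * geom.n_circ + circ


@dataclass
class SensoryMap:
    """Per-step accumulation of projected activation counts."""

    geom: CylinderGeometry
    counts: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.zeros(self.geom.n_bins, dtype=np.int64)

    def reset(self) -> None:
        self.counts[:] = 0

    def add(self, bins: np.ndarray, activations: np.ndarray) -> None:
        """Credit ``activations[k]`` receptor activations to ``bins[k]``."""
        np.add.at(self.counts, bins, activations)

    def add_binned(self, bins: np.ndarray, activations: np.ndarray) -> None:
        # bincount route, faster for large agent counts
        self.counts += np.bincount(
            bins, weights=activations, minlength=self.geom.n_bins
        ).astype(np.int64)


def intensity(counts: np.ndarray) -> float:
    """Total Vegfr activations across the sensory map."""
    return float(np.sum(counts))


def entropy(counts: np.ndarray, alpha: float = 1.0) -> float:
    """Shannon entropy (bits) of the Laplace-smoothed map distribution.

    ``p_i = (v_i + alpha)/(sum v + N alpha)`` with ``alpha > 0``; the
    smoothed distribution is always proper, so H is well defined even for
    an empty map (where it attains its maximum, log2 N).
    """
    if alpha <= 0:
        raise ValueError("Laplace smoothing parameter alpha must be > 0")
    v = np.asarray(counts, dtype=float)
    p = (v + alpha) / (v.sum() + alpha * v.size)
    return float(-np.sum(p * np.log2(p)))


@dataclass
class APMeasureSeries:
    """Per-step intensity and entropy for one run, plus the pattern marker."""

    t: np.ndarray
    intensity: np.ndarray
    entropy: np.ndarray
    seed: int
    patterned: bool = False
    pattern_time: float = float("nan")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "I": self.intensity,
                "H": self.entropy,
                "patterned_flag": self.patterned,
                "seed": self.seed,
            }
        )
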