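"""Discrete 3-D lattice environment holding the VEGF field.

The simulation world is a grid of 0.5 x 0.5 x 0.5 micron cubic sites.
Membrane agents live in continuous space but are snapped to sites so that
local interaction rules (sensing, occupancy, filopodia stepping) are
discrete.  The VEGF field is static: either a linear gradient anchored at
zero at the lattice floor (``I_g = V * y``) or a uniform concentration.

The lattice is periodic along x (the vessel axis) and bounded in y and z.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

#: physical edge length of one grid site, in microns
GRID_UM = 0.5

#: the 26 Moore-neighbourhood offsets in 3-D
MOORE_OFFSETS = np.array(
    [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)],
    dtype=np.int64,
)


class DomainError(ValueError):
    """Raised for positions or sites outside the simulated volume."""


@dataclass
class VegfField:
    """Static VEGF concentration field.

    Parameters
    ----------
    mode : {"gradient", "uniform"}
        ``gradient`` gives a linear ramp ``I = V * y`` along the y axis
        (``y`` in grid-site units, anchored at 0 at the lattice floor);
        ``uniform`` gives the flat value ``V`` everywhere.
    V : float
        Gradient slope (per site) or flat concentration.  Non-negative.
    """

    mode: str = "gradient"
    V: float = 0.04

    def __post_init__(self) -> None:
        if self.mode not in ("gradient", "uniform"):
            raise ValueError(f"unknown vegf mode {self.mode!r}")
        if self.V < 0:
            raise ValueError("VEGF parameter V must be >= 0")

    def value_at_y(self, y):
        """Concentration at grid row(s) ``y`` (vectorised)."""
        y = np.asarray(y, dtype=float)
        if self.mode == "gradient":
            return self.V * y
        return np.full_like(y, self.V)


@dataclass
class Lattice:
    """Bounded grid with per-site occupancy and ownership bookkeeping.

    ``owner[x, y, z]`` holds the id of the cell occupying the site, or -1.
    x wraps periodically (ring vessel); y and z are hard walls.
    """

    nx: int
    ny: int
    nz: int
    occupancy: np.ndarray = field(init=False, repr=False)
    owner: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.occupancy = np.zeros((self.nx, self.ny, self.nz), dtype=bool)
        self.owner = np.full((self.nx, self.ny, self.nz), -1, dtype=np.int16)

    # -- geometry ----------------------------------------------------

    def in_bounds(self, site) -> bool:
        x, y, z = site
        return 0 <= y < self.ny and 0 <= z < self.nz and 0 <= x < self.nx

    def wrap_x(self, x):
        return np.mod(x, self.nx)

    def site_center(self, site) -> np.ndarray:
        """Continuous position (um) of the centre of ``site``."""
        return (np.asarray(site, dtype=float) + 0.5) * GRID_UM

    def neighbors(self, site) -> np.ndarray:
        """The Moore neighbours of ``site`` that lie inside the volume.

        x is wrapped; neighbours falling outside the y/z walls are dropped.
        Returns an (m, 3) integer array, m <= 26.
        """
        cand = MOORE_OFFSETS + np.asarray(site, dtype=np.int64)
        cand[:, 0] = self.wrap_x(cand[:, 0])
        ok = (
            (cand[:, 1] >= 0)
            & (cand[:, 1] < self.ny)
            & (cand[:, 2] >= 0)
            & (cand[:, 2] < self.nz)
        )
        return cand[ok]

    # -- occupancy ---------------------------------------------------

    def occupy(self, site, cell_id: int) -> None:
        x, y, z = site
        self.occupancy[x, y, z] = True
        self.owner[x, y, z] = cell_id

    def release(self, site) -> None:
        x, y, z = site
        self.occupancy[x, y, z] = False
        self.owner[x, y, z] = -1


def snap_to_grid(position, lattice: Lattice):
    """Snap a continuous position (um) to the grid site containing it.

    Sites are half-open cubes ``[k*0.5, (k+1)*0.5)`` so the mapping is
    simply ``floor(position / 0.5)`` and is deterministic.

    Raises
    ------
    DomainError
        If the position lies outside the simulated volume.
    """
    site = tuple(int(v) for v in np.floor(np.asarray(position, dtype=float) / GRID_UM))
    if not lattice.in_bounds(site):
        raise DomainError(f"position {position} outside lattice")
    return site


def vegf_at(site, fieldspec: VegfField, lattice: Lattice | None = None) -> float:
    """VEGF concentration at a grid site.

    Gradient mode returns ``V * y`` of the site (y in site units, exactly 0
    at the floor); uniform mode returns ``V`` everywhere.
    """
    if lattice is not None and not lattice.in_bounds(site):
        raise DomainError(f"site {site} outside lattice")
    return float(fieldspec.value_at_y(site[1]))


def sensing_input(site, fieldspec: VegfField, lattice: Lattice, cell_id: int,
                  scale: float = 1.0) -> float:
    """Ligand input available to a membrane agent sitting at ``site``.

    Receptors face extracellular space, so the input aggregates the VEGF of
    the agent's own site and of its Moore neighbours that are not occupied
    by the same cell's body, normalised by the full neighbourhood size (27).
    The normalisation keeps the magnitude on the per-site scale ``V * y``
    while letting occlusion by the cell's own surface reduce exposure.
    """
    total = float(fieldspec.value_at_y(site[1]))
    nb = lattice.neighbors(site)
    own = lattice.owner[nb[:, 0], nb[:, 1], nb[:, 2]] == cell_id
    free = nb[~own]
    if len(free):
        total += float(np.sum(fieldspec.value_at_y(free[:, 1])))
    return total / (27.0 * scale)


def dump_field_csv(fieldspec: VegfField, lattice: Lattice, path) -> None:
    """Write the per-site field as CSV (x,y,z,vegf) for inspection."""
    import pandas as pd

    xs, ys, zs = np.meshgrid(
        np.arange(lattice.nx), np.arange(lattice.ny), np.arange(lattice.nz),
        indexing="ij",
    )
    df = pd.DataFrame(
        {
            "x": xs.ravel(),
            "y": ys.ravel(),
            "z": zs.ravel(),
            "vegf": fieldspec.value_at_y(ys.ravel()),
        }
    )
    df.to_csv(path, index=False)
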