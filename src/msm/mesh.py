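"""Cylindrical vessel surfaces of memAgents connected by Hookean springs.

A vessel is a ring of cells, each spanning one full cross-section of a
cylinder (radius 3 um, cell width 10 um by default).  The surface of each
cell is a quad ring-lattice of membrane agents ("memAgents"): ``n_axial``
rings of ``n_circ`` agents.  At the default mesh density this gives
20 x 60 = 1200 agents per cell.

Cells are positionally fixed in this constrained model; springs exist to
carry tension in filopodia-neighbouring membrane and are relaxed by damped
iteration.  Receptor and ligand pools are re-distributed over the current
surface every step: Vegfr equally over all agents, Dll4 equally over
junction agents only (agents whose site has a Moore neighbour occupied by
another cell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .lattice import GRID_UM, Lattice, VegfField, sensing_input, snap_to_grid


class NumericalStabilityError(RuntimeError):
    """Spring relaxation diverged (energy increased over a full pass)."""


@dataclass
class Springs:
    """Hookean springs as parallel arrays over agent-index endpoint pairs."""

    a: np.ndarray  # (n_springs,) first endpoint agent index
    b: np.ndarray  # (n_springs,) second endpoint agent index
    rest_length: np.ndarray  # um, > 0
    stiffness: np.ndarray  # force/um, > 0

    def energy(self, positions: np.ndarray) -> float:
        d = positions[self.b] - positions[self.a]
        length = np.linalg.norm(d, axis=1)
        return float(0.5 * np.sum(self.stiffness * (length - self.rest_length) ** 2))


@dataclass
class Cell:
    """One endothelial cell: surface geometry plus signalling pools."""

    cell_id: int
    positions: np.ndarray  # (n, 3) um
    sites: np.ndarray  # (n, 3) int grid sites
    mesh_coords: np.ndarray  # (n, 2) int (axial ring, circumferential index)
    springs: Springs
    is_junction: np.ndarray = field(default=None)  # (n,) bool
    partner_cell: np.ndarray = field(default=None)  # (n,) int, -1 if none
    partner_idx: np.ndarray = field(default=None)  # (n,) int
    ell: np.ndarray = field(default=None)  # (n,) cached sensing input
    # signalling pools
    vegfr_total: float = 0.0
    dll4_total: float = 0.0
    notch_active_total: float = 0.0
    actin_pool: float = 0.0
    fixed: bool = True  # cells do not migrate in this constrained model
    # per-agent views, refreshed each step by distribution
    vegfr: np.ndarray = field(default=None)
    vegfr_active: np.ndarray = field(default=None)
    dll4: np.ndarray = field(default=None)

    @property
    def n_agents(self) -> int:
        return len(self.positions)


@dataclass
class Vessel:
    """Ring of cells on a shared lattice; periodic along the axis."""

    cells: list
    lattice: Lattice
    radius_um: float
    cell_width_um: float
    n_axial_per_cell: int
    n_circ: int
    y_center_um: float
    z_center_um: float
    periodic: bool = True

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def neighbors_of(self, cell_id: int):
        n = self.n_cells
        return ((cell_id - 1) % n, (cell_id + 1) % n)


def build_vessel(
    n_cells: int,
    mesh_density: Optional[float] = None,
    radius_um: float = 3.0,
    cell_width_um: float = 10.0,
    headroom_um: float = 44.0,
) -> Vessel:
    """Construct the cylindrical vessel mesh.

    The mesh is deterministic given its arguments.  Axial spacing is one
    grid site (0.5 um); the circumferential agent count follows the mesh
    density (default ~6.4 agents/um^2, which yields 60 agents per ring and
    hence ~1200 agents per 10 um cell).  The vessel rests on the lattice
    floor (y = 0 at its lowest surface) so the VEGF gradient is anchored
    at the bottom of the vessel.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2: lateral inhibition undefined")
    if mesh_density is None:
        mesh_density = 1200.0 / (math.pi * 2 * radius_um * cell_width_um)

    n_axial = int(round(cell_width_um / GRID_UM))
    circumference = 2 * math.pi * radius_um
    n_circ = int(round(mesh_density * circumference * GRID_UM))

    nx = n_cells * n_axial
    y_center = radius_um
    ny = int(round((2 * radius_um + headroom_um) / GRID_UM)) + 1
    z_half = radius_um + 5.0  # lateral wander margin for filopodia
    z_center = z_half
    nz = int(round(2 * z_half / GRID_UM)) + 1
    lattice = Lattice(nx=nx, ny=ny, nz=nz)

    cells = []
    for c in range(n_cells):
        n = n_axial * n_circ
        positions = np.empty((n, 3))
        mesh_coords = np.empty((n, 2), dtype=np.int64)
        k = 0
        for i in range(n_axial):
            x = (c * n_axial + i + 0.5) * GRID_UM
            for j in range(n_circ):
                phi = 2 * math.pi * (j + 0.5) / n_circ
                y = y_center + radius_um * math.sin(phi)
                z = z_center + radius_um * math.cos(phi)
                positions[k] = (x, y, z)
                mesh_coords[k] = (i, j)
                k += 1
        sites = np.floor(positions / GRID_UM).astype(np.int64)
        springs = _quad_springs(positions, mesh_coords, n_axial, n_circ)
        cells.append(
            Cell(
                cell_id=c,
                positions=positions,
                sites=sites,
                mesh_coords=mesh_coords,
                springs=springs,
            )
        )

    vessel = Vessel(
        cells=cells,
        lattice=lattice,
        radius_um=radius_um,
        cell_width_um=cell_width_um,
        n_axial_per_cell=n_axial,
        n_circ=n_circ,
        y_center_um=y_center,
        z_center_um=z_center,
    )
    _register_occupancy(vessel)
    _flag_junctions(vessel)
    return vessel


def _quad_springs(positions, mesh_coords, n_axial, n_circ) -> Springs:
    """Quad ring-lattice springs: axial and circumferential neighbours."""
    idx = {(i, j): k for k, (i, j) in enumerate(map(tuple, mesh_coords))}
    a, b = [], []
    for (i, j), k in idx.items():
        if (i + 1, j) in idx:
            a.append(k)
            b.append(idx[(i + 1, j)])
        a.append(k)
        b.append(idx[(i, (j + 1) % n_circ)])
    a = np.asarray(a)
    b = np.asarray(b)
    rest = np.linalg.norm(positions[b] - positions[a], axis=1)
    return Springs(a=a, b=b, rest_length=rest, stiffness=np.ones_like(rest))


def _register_occupancy(vessel: Vessel) -> None:
    lat = vessel.lattice
    for cell in vessel.cells:
        s = cell.sites
        lat.occupancy[s[:, 0], s[:, 1], s[:, 2]] = True
        lat.owner[s[:, 0], s[:, 1], s[:, 2]] = cell.cell_id


def _flag_junctions(vessel: Vessel) -> None:
    """Mark agents whose site has a Moore neighbour owned by another cell,
    and pair each junction agent with its nearest apposed agent."""
    lat = vessel.lattice
    from .lattice import MOORE_OFFSETS

    # site -> list of (cell, agent) for partner lookup
    site_map: dict = {}
    for cell in vessel.cells:
        for k, s in enumerate(map(tuple, cell.sites)):
            site_map.setdefault(s, []).append((cell.cell_id, k))

    for cell in vessel.cells:
        n = cell.n_agents
        # vectorised junction test over all agents' Moore neighbourhoods
        nb = cell.sites[:, None, :] + MOORE_OFFSETS[None, :, :]  # (n, 26, 3)
        xw = np.mod(nb[..., 0], lat.nx)
        yc = np.clip(nb[..., 1], 0, lat.ny - 1)
        zc = np.clip(nb[..., 2], 0, lat.nz - 1)
        inb = (nb[..., 1] >= 0) & (nb[..., 1] < lat.ny) & (nb[..., 2] >= 0) & (
            nb[..., 2] < lat.nz
        )
        owner = lat.owner[xw, yc, zc]
        foreign = inb & (owner >= 0) & (owner != cell.cell_id)
        junction = foreign.any(axis=1)

        pcell = np.full(n, -1, dtype=np.int64)
        pidx = np.full(n, -1, dtype=np.int64)
        for k in np.nonzero(junction)[0]:
            best = None
            for m in np.nonzero(foreign[k])[0]:
                s = (int(xw[k, m]), int(nb[k, m, 1]), int(nb[k, m, 2]))
                for oc, ok in site_map.get(s, ()):
                    if oc == cell.cell_id:
                        continue
                    d = np.linalg.norm(
                        vessel.cells[oc].positions[ok] - cell.positions[k]
                    )
                    if best is None or d < best[0]:
                        best = (d, oc, ok)
            if best is not None:
                pcell[k] = best[1]
                pidx[k] = best[2]
        cell.is_junction = junction
        cell.partner_cell = pcell
        cell.partner_idx = pidx


def compute_sensing_inputs(
    vessel: Vessel, fieldspec: VegfField, scale: float = 1.0
) -> None:
    """Cache each body agent's ligand input (static geometry, static field)."""
    for cell in vessel.cells:
        ell = np.empty(cell.n_agents)
        for k in range(cell.n_agents):
            ell[k] = sensing_input(
                tuple(cell.sites[k]), fieldspec, vessel.lattice, cell.cell_id,
                scale=scale,
            )
        cell.ell = ell


def distribute_receptors(cell: Cell, rng: np.random.Generator, n_extra: int = 0):
    """Split the cell's Vegfr pool equally over its current agents.

    Every agent receives ``floor(total / n)``; the integer remainder goes
    to uniformly random agents (one extra receptor each) so no surface
    region is systematically favoured.  ``n_extra`` counts filopodium
    agents beyond the body mesh.  Returns the per-agent integer array
    (body agents first); the sum is exactly the (floored) pool.
    """
    n = cell.n_agents + n_extra
    total = int(cell.vegfr_total)
    base, rem = divmod(total, n)
    out = np.full(n, base, dtype=np.int64)
    if rem:
        out[rng.permutation(n)[:rem]] += 1
    return out


def distribute_dll4(cell: Cell, junction_idx: np.ndarray) -> np.ndarray:
    """Equal split of the Dll4 pool over junction agents only.

    Non-junction agents hold zero ligand.  Returns a per-junction-agent
    float array aligned with ``junction_idx``; conservation is exact.
    """
    m = len(junction_idx)
    if m == 0:
        return np.zeros(0)
    return np.full(m, cell.dll4_total / m)


def relax_springs(
    positions: np.ndarray,
    springs: Springs,
    fixed_mask: np.ndarray,
    n_iterations: int = 5,
    damping: float = 0.5,
) -> np.ndarray:
    """Damped iterative spring relaxation.

    Each pass moves every free agent by ``damping *`` its net Hookean
    force.  Agents flagged fixed (vessel body, adhesion anchors) do not
    move.  Raises ``NumericalStabilityError`` if the total spring energy
    increases over a pass, which indicates the damping factor is too
    large for the mesh.
    """
    pos = positions.copy()
    energy = springs.energy(pos)
    for _ in range(n_iterations):
        d = pos[springs.b] - pos[springs.a]
        length = np.linalg.norm(d, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(length[:, None] > 0, d / np.maximum(length, 1e-12)[:, None], 0.0)
        f = (springs.stiffness * (length - springs.rest_length))[:, None] * unit
        force = np.zeros_like(pos)
        np.add.at(force, springs.a, f)
        np.add.at(force, springs.b, -f)
        force[fixed_mask] = 0.0
        pos += damping * force
        new_energy = springs.energy(pos)
        if new_energy > energy + 1e-9:
            raise NumericalStabilityError(
                "spring energy increased during relaxation; reduce damping"
            )
        energy = new_energy
    return pos


# ----------------------------------------------------------------------
# Template cache: the body mesh and its cached sensing inputs are static
# given the geometry and field, so repeated simulations clone a template
# instead of re-meshing.

_TEMPLATE_CACHE: dict = {}


def fresh_vessel(
    n_cells: int,
    fieldspec: VegfField,
    mesh_density: Optional[float] = None,
    radius_um: float = 3.0,
    cell_width_um: float = 10.0,
    headroom_um: float = 44.0,
    sensing_scale: float = 1.0,
) -> Vessel:
    """A vessel with cached static geometry but private mutable state.

    Geometry arrays (positions, sites, springs, junction flags, sensing
    inputs) are shared read-only with the template; the lattice occupancy
    and the per-cell pools are fresh per call.
    """
    key = (n_cells, mesh_density, radius_um, cell_width_um, headroom_um,
           fieldspec.mode, fieldspec.V, sensing_scale)
    if key not in _TEMPLATE_CACHE:
        vessel = build_vessel(
            n_cells,
            mesh_density=mesh_density,
            radius_um=radius_um,
            cell_width_um=cell_width_um,
            headroom_um=headroom_um,
        )
        compute_sensing_inputs(vessel, fieldspec, scale=sensing_scale)
        _TEMPLATE_CACHE[key] = vessel
    tpl = _TEMPLATE_CACHE[key]

    lattice = Lattice(nx=tpl.lattice.nx, ny=tpl.lattice.ny, nz=tpl.lattice.nz)
    lattice.occupancy[:] = tpl.lattice.occupancy
    lattice.owner[:] = tpl.lattice.owner
    cells = [
        Cell(
            cell_id=c.cell_id,
            positions=c.positions,
            sites=c.sites,
            mesh_coords=c.mesh_coords,
            springs=c.springs,
            is_junction=c.is_junction,
            partner_cell=c.partner_cell,
            partner_idx=c.partner_idx,
            ell=c.ell,
        )
        for c in tpl.cells
    ]
    return Vessel(
        cells=cells,
        lattice=lattice,
        radius_um=tpl.radius_um,
        cell_width_um=tpl.cell_width_um,
        n_axial_per_cell=tpl.n_axial_per_cell,
        n_circ=tpl.n_circ,
        y_center_um=tpl.y_center_um,
        z_center_um=tpl.z_center_um,
    )


def export_mesh(vessel: Vessel, path) -> None:
    """OBJ-style vertex/edge dump of the body mesh plus per-agent CSV."""
    import pandas as pd

    rows = []
    with open(str(path) + ".obj", "w") as fh:
        offset = 0
        for cell in vessel.cells:
            for p in cell.positions:
                fh.write(f"v {p[0]:.3f} {p[1]:.3f} {p[2]:.3f}\n")
            for a, b in zip(cell.springs.a, cell.springs.b):
                fh.write(f"l {a + 1 + offset} {b + 1 + offset}\n")
            offset += cell.n_agents
            for k in range(cell.n_agents):
                rows.append(
                    {
                        "cell_id": cell.cell_id,
                        "agent": k,
                        "x": cell.positions[k, 0],
                        "y": cell.positions[k, 1],
                        "z": cell.positions[k, 2],
                        "is_junction": bool(cell.is_junction[k]),
                    }
                )
    pd.DataFrame(rows).to_csv(str(path) + ".csv", index=False)
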