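"""Per-step simulation engine for the constrained MSM vessel.

Update order within a time step (fixed):

1. distribute pools — Vegfr equally over all of the cell's current agents
   (body mesh + filopodia), Dll4 equally over junction agents;
2. activate Vegfr against the local ligand input;
3. bind Notch at junctions (consuming neighbour Dll4);
4. filopodia dynamics — established chains first (tip extension attempts,
   with one retraction burst for still-idle retracting chains), then new
   initiations (established protrusions get first claim on free actin);
5. spring mechanics — the constrained vessel is at its spring equilibrium
   by construction (body agents are anchored, chain agents are created at
   rest length), so the relaxation pass is the identity and is skipped;
6. delayed gene regulation of the cell pools.

Junction binding reduces to scalar bookkeeping: Dll4 is split equally
over a cell's junction agents and the per-agent Notch ceiling is uniform,
so the amount bound across an interface is ``pairs * min(alloc,
notch_max)`` with the 1-1 agent pairing established at mesh build.

All stochastic draws (receptor-remainder placement, binomial activation,
extension and direction draws) consume a single seeded Generator in a
fixed documented order, making runs bit-reproducible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .active_perception import (
    CylinderGeometry,
    entropy,
    intensity,
    project_activation,
)
from .config import SimConfig
from .filopodia import Filopodium
from .lattice import GRID_UM, MOORE_OFFSETS, VegfField
from .mesh import Vessel, fresh_vessel
from .signalling import DelayBuffer


@dataclass
class Trace:
    """Per-step per-cell state log of one run."""

    t: np.ndarray = None
    vegfr: np.ndarray = None  # (T, n_cells)
    vegfr_active: np.ndarray = None
    dll4: np.ndarray = None
    notch_active: np.ndarray = None
    n_filopodia: np.ndarray = None
    fil_agents: np.ndarray = None
    ap_intensity: Optional[np.ndarray] = None
    ap_entropy: Optional[np.ndarray] = None
    seed: int = 0

    def to_frame(self):
        import pandas as pd

        T, n = self.dll4.shape
        rows = {
            "t": np.repeat(self.t, n),
            "cell_id": np.tile(np.arange(n), T),
            "vegfr_cell": self.vegfr.ravel(),
            "vegfr_active_cell": self.vegfr_active.ravel(),
            "d_cell": self.dll4.ravel(),
            "notch_active_cell": self.notch_active.ravel(),
            "n_filopodia": self.n_filopodia.ravel(),
            "fil_agents": self.fil_agents.ravel(),
        }
        return pd.DataFrame(rows)


class Simulation:
    """One seeded run of the constrained MSM.

    Parameters
    ----------
    config : SimConfig
    seed : int
        Seed for the single per-run random generator.
    frozen_cells : tuple of int
        Cells acting as non-responsive Dll4 sources (hysteresis testbed):
        they present a clamped external Dll4 level at interfaces with
        active cells, consume neighbour Dll4 through their Notch, and
        never update their own state or extend filopodia.
    """

    def __init__(self, config: SimConfig, seed: int, frozen_cells: tuple = ()):
        self.config = config
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.field = VegfField(mode=config.vegf.mode, V=config.vegf.V)
        self.vessel: Vessel = fresh_vessel(
            config.vessel.n_cells,
            self.field,
            mesh_density=config.vessel.mesh_density,
            radius_um=config.vessel.radius_um,
            cell_width_um=config.vessel.cell_width_um,
            headroom_um=config.vessel.headroom_um,
            sensing_scale=config.vegf.sensing_scale,
        )
        self.frozen = frozenset(frozen_cells)
        self.d_ext_total = 0.0
        self.t = 0

        sig = config.signalling
        fil = config.filopodia
        n_body = self.vessel.cells[0].n_agents
        if fil.p_cap is not None:
            self.p_cap = fil.p_cap
        else:
            # rest per-agent receptor count, scaled so control-condition
            # tip extension sits well above the filtipmax persistence knee
            self.p_cap = fil.p_cap_rest_multiple * sig.vegfr_max / n_body
        self.step_cost = GRID_UM * fil.token_strength  # actin per extension
        self.adhesion_every = max(1, int(round(fil.adhesion_spacing_um / GRID_UM)))

        self.geom = CylinderGeometry(
            n_axial=self.vessel.lattice.nx,
            n_circ=self.vessel.n_circ,
            radius_um=self.vessel.radius_um,
            y_center_um=self.vessel.y_center_um,
            z_center_um=self.vessel.z_center_um,
        )

        # per-cell dynamic state
        n = self.vessel.n_cells
        self.vegfr_cell = np.full(n, sig.vegfr_max)
        self.dll4_cell = np.zeros(n)
        self.actin = np.full(n, fil.actin_pool_um)
        self.fils: list[list[Filopodium]] = [[] for _ in range(n)]
        self.base_coords: list[set] = [set() for _ in range(n)]
        self.vstar_buf = [DelayBuffer(sig.delay_steps) for _ in range(n)]
        self.nstar_buf = [DelayBuffer(sig.delay_steps) for _ in range(n)]
        # most recent step's totals (filled by step())
        self.vstar_cell = np.zeros(n)
        self.nstar_cell = np.zeros(n)
        self._veg_fil = [np.zeros(0, dtype=np.int64) for _ in range(n)]

        self._prepare_static()

    # -- static precomputation ---------------------------------------

    def _prepare_static(self) -> None:
        lat = self.vessel.lattice
        self._body_bins = []
        self._jcount = []  # junction agent count per cell
        for cell in self.vessel.cells:
            bins = np.array(
                [project_activation(p, self.geom) for p in cell.positions],
                dtype=np.int64,
            )
            self._body_bins.append(bins)
            self._jcount.append(int(np.sum(cell.is_junction)))
        # interface pair counts: pairs[c][p] = junction agents of c paired to p
        n = self.vessel.n_cells
        self.pairs = np.zeros((n, n), dtype=np.int64)
        for cell in self.vessel.cells:
            pc = cell.partner_cell[cell.is_junction]
            for p in np.unique(pc):
                self.pairs[cell.cell_id, p] = int(np.sum(pc == p))
        if not np.array_equal(self.pairs, self.pairs.T):
            raise RuntimeError("junction pairing is not symmetric")
        # body VEGF per site, for guidance; neighbour candidate cache
        self._lat = lat
        self._V = self.field.V
        self._uniform = self.field.mode == "uniform"
        self._sens_scale = self.config.vegf.sensing_scale
        # flat-index fast path for tip stepping (sites away from walls)
        self._occ_flat = lat.occupancy.ravel()
        self._own_flat = lat.owner.ravel()
        self._nyz = lat.ny * lat.nz
        self._nz = lat.nz
        d = MOORE_OFFSETS
        self._deltas26 = (d[:, 0] * lat.ny + d[:, 1]) * lat.nz + d[:, 2]
        self._dy26 = d[:, 1].astype(np.int64)

    # -- hysteresis support ------------------------------------------

    def set_external_dll4(self, total: float) -> None:
        """Clamp the summed external Dll4 presented by frozen cells."""
        if not self.frozen:
            raise RuntimeError("no frozen cells in this simulation")
        self.d_ext_total = float(total)

    # -- helpers ------------------------------------------------------

    def _site_vegf(self, ys):
        if self._uniform:
            return np.full_like(np.asarray(ys, dtype=float), self._V)
        return self._V * np.asarray(ys, dtype=float)

    def _sensing_input_fast(self, site, cell_id: int) -> float:
        """Ligand input for a (new) filopodium agent at ``site``: neighbour
        VEGF averaged over the full 27-neighbourhood, own-cell-occupied
        sites excluded (occlusion)."""
        lat = self._lat
        nb = MOORE_OFFSETS + np.asarray(site, dtype=np.int64)
        nb[:, 0] %= lat.nx
        ok = (nb[:, 1] >= 0) & (nb[:, 1] < lat.ny) & (nb[:, 2] >= 0) & (nb[:, 2] < lat.nz)
        nb = nb[ok]
        own = lat.owner[nb[:, 0], nb[:, 1], nb[:, 2]] == cell_id
        free = nb[~own]
        total = float(self._site_vegf(site[1]))
        if len(free):
            total += float(np.sum(self._site_vegf(free[:, 1])))
        return total / (27.0 * self._sens_scale)

    def _free_candidates(self, site, cell_id: int):
        """Unoccupied in-bounds Moore neighbours of a tip site."""
        lat = self._lat
        nb = MOORE_OFFSETS + np.asarray(site, dtype=np.int64)
        nb[:, 0] %= lat.nx
        ok = (nb[:, 1] >= 0) & (nb[:, 1] < lat.ny) & (nb[:, 2] >= 0) & (nb[:, 2] < lat.nz)
        nb = nb[ok]
        occ = lat.occupancy[nb[:, 0], nb[:, 1], nb[:, 2]]
        return nb[~occ]

    def _spacing_ok(self, coord, cell_id: int) -> bool:
        """Chebyshev spacing >= filspacing between active filopodia bases,
        with circumferential wrap."""
        s = self.config.filopodia.filspacing
        bases = self.base_coords[cell_id]
        if not bases:
            return True
        i0, j0 = coord
        nc = self.vessel.n_circ
        for di in range(-s + 1, s):
            for dj in range(-s + 1, s):
                if (i0 + di, (j0 + dj) % nc) in bases:
                    return False
        return True

    # -- the step ------------------------------------------------------

    def step(self, record_map: bool = False):
        """Advance one time step; optionally return the sensory-map counts."""
        cfg = self.config
        sig = cfg.signalling
        fil = cfg.filopodia
        rng = self.rng
        n_cells = self.vessel.n_cells
        map_counts = (
            np.zeros(self.geom.n_bins, dtype=np.int64) if record_map else None
        )

        vstar_body_all = [None] * n_cells
        vstar_fil_all = [None] * n_cells

        # 1+2: distribute receptors and activate
        for c, cell in enumerate(self.vessel.cells):
            if c in self.frozen:
                self.vstar_buf[c].append(0.0)
                continue
            fils = self.fils[c]
            fil_ell = (
                np.fromiter(
                    itertools.chain.from_iterable(f.ell for f in fils),
                    dtype=float,
                )
                if fils
                else np.zeros(0)
            )
            n_fil = len(fil_ell)
            n_tot = cell.n_agents + n_fil
            ell = np.concatenate([cell.ell, fil_ell]) if n_fil else cell.ell
            p = np.minimum(ell, 1.0)
            if sig.stochastic_activation:
                # integer split, remainder to uniformly random agents;
                # discrete receptors then activate binomially
                total = int(self.vegfr_cell[c])
                base, rem = divmod(total, n_tot)
                veg = np.full(n_tot, base, dtype=np.int64)
                if rem:
                    veg[rng.permutation(n_tot)[:rem]] += 1
                vstar = rng.binomial(veg, p)
            else:
                # mean-field mode: real-valued equal share, expected
                # activation (used by the delay-map reduction checks)
                veg = np.full(n_tot, self.vegfr_cell[c] / n_tot)
                vstar = veg * p
            vstar_body_all[c] = vstar[: cell.n_agents]
            vstar_fil_all[c] = vstar[cell.n_agents:]
            cell.vegfr = veg[: cell.n_agents]
            cell.vegfr_active = vstar_body_all[c]
            self._veg_fil[c] = veg[cell.n_agents:]
            total_act = float(vstar.sum())
            self.vstar_cell[c] = total_act
            self.vstar_buf[c].append(total_act)

            if record_map:
                np.add.at(map_counts, self._body_bins[c], vstar_body_all[c])
                if n_fil:
                    fbins = np.fromiter(
                        itertools.chain.from_iterable(f.bins for f in fils),
                        dtype=np.int64,
                    )
                    np.add.at(map_counts, fbins, vstar_fil_all[c])

        # 3: Notch binding across interfaces (scalar per interface)
        alloc = np.zeros((n_cells, n_cells))  # alloc[p, c]: per-agent dll4 p shows c
        for p, cell in enumerate(self.vessel.cells):
            if p in self.frozen:
                for c in range(n_cells):
                    if self.pairs[p, c] and c not in self.frozen:
                        # external Dll4 split equally over the frozen cell's
                        # active-facing interfaces (two flanks -> total/2 each)
                        n_if = sum(
                            1
                            for q in range(n_cells)
                            if self.pairs[p, q] and q not in self.frozen
                        )
                        share = self.d_ext_total / 2.0 / max(n_if, 1)
                        alloc[p, c] = share / self.pairs[p, c]
            else:
                nj = self._jcount[p]
                if nj:
                    alloc[p, :] = self.dll4_cell[p] / nj

        consumed = np.zeros(n_cells)
        for c in range(n_cells):
            nstar = 0.0
            for p in range(n_cells):
                k = self.pairs[c, p]
                if not k:
                    continue
                bound = k * min(alloc[p, c], sig.notch_max)
                if c not in self.frozen:
                    nstar += bound
                if p not in self.frozen:
                    consumed[p] += bound
            if c in self.frozen:
                self.nstar_buf[c].append(0.0)
                self.nstar_cell[c] = 0.0
            else:
                self.nstar_cell[c] = nstar
                self.nstar_buf[c].append(nstar)
        self.dll4_cell = np.maximum(self.dll4_cell - consumed, 0.0)

        # 4: filopodia dynamics
        for c, cell in enumerate(self.vessel.cells):
            if c in self.frozen:
                continue
            self._filopodia_step(c, cell, vstar_body_all[c], vstar_fil_all[c])

        # 5: spring relaxation — identity in the constrained vessel (all
        # body agents anchored, chain agents created at rest length)

        # 6: delayed gene regulation
        for c in range(n_cells):
            if c in self.frozen:
                continue
            delayed_n = self.nstar_buf[c].read()
            delayed_v = self.vstar_buf[c].read()
            self.vegfr_cell[c] = max(0.0, sig.vegfr_max - sig.sigma * delayed_n)
            if sig.dll4_mode == "replace":
                d = sig.delta * delayed_v
            else:
                d = self.dll4_cell[c] + sig.delta * delayed_v
            self.dll4_cell[c] = min(sig.d_max, max(0.0, d))

        self.t += 1
        return map_counts

    # -- filopodia sub-step -------------------------------------------

    def _filopodia_step(self, c: int, cell, vstar_body, vstar_fil) -> None:
        cfg = self.config.filopodia
        rng = self.rng
        lat = self._lat
        fils = self.fils[c]

        # (a) established protrusions first: tip extension attempts (they
        # hold first claim on free actin), then one retraction burst for
        # still-retracting chains.  A post-burst tip is a live memAgent:
        # a successful extension draw rescues the filopodium from
        # retraction (anchors make established chains far stickier than
        # nascent stubs, which lack adhesions and vanish on their first
        # burst).
        if fils:
            offsets = np.cumsum([f.n_agents for f in fils])
            draws = rng.random(len(fils))
            survivors = []
            max_agents = int(round(cfg.max_length_um / GRID_UM))
            for i, f in enumerate(fils):
                tip_vstar = float(vstar_fil[offsets[i] - 1])
                p = min(1.0, cfg.F * tip_vstar / self.p_cap)
                if f.n_agents >= max_agents:
                    # transport-limited: a successful draw maintains the
                    # tip in place instead of adding an agent
                    if draws[i] < p:
                        f.state = "extending"
                        f.steps_since_extension = 0
                        survivors.append(f)
                        continue
                    extended = False
                else:
                    extended = (
                        self.actin[c] >= self.step_cost
                        and draws[i] < p
                        and self._extend(c, cell, f)
                    )
                if extended:
                    f.state = "extending"
                elif f.state == "retracting":
                    removed = f.burst_retract()
                    for s in removed:
                        lat.release(s)
                    self.actin[c] += self.step_cost * len(removed)
                    if f.n_agents == 0:
                        self.base_coords[c].discard(f.base_coord)
                        continue
                else:
                    f.mark_idle(cfg.filtipmax)
                survivors.append(f)
            self.fils[c] = fils = survivors

        # (b) new initiations from the body surface (the nucleation
        # barrier makes de novo initiation rarer than tip elongation)
        if self.actin[c] >= self.step_cost:
            p_init = np.minimum(cfg.init_factor * cfg.F * vstar_body / self.p_cap, 1.0)
            hits = np.nonzero(rng.random(cell.n_agents) < p_init)[0]
            if len(hits):
                for k in hits[rng.permutation(len(hits))]:
                    if self.actin[c] < self.step_cost:
                        break
                    coord = (int(cell.mesh_coords[k, 0]), int(cell.mesh_coords[k, 1]))
                    if not self._spacing_ok(coord, c):
                        continue
                    f = Filopodium(cell_id=c, base_idx=int(k), base_coord=coord)
                    if self._extend(c, cell, f, base_site=tuple(cell.sites[k])):
                        self.fils[c].append(f)
                        self.base_coords[c].add(coord)

    def _interior(self, site) -> bool:
        lat = self._lat
        return (
            1 <= site[0] <= lat.nx - 2
            and 1 <= site[1] <= lat.ny - 2
            and 1 <= site[2] <= lat.nz - 2
        )

    def _extend(self, c: int, cell, f: Filopodium, base_site=None) -> bool:
        """Attempt one grid-step extension of filopodium ``f``; returns
        whether a new chain agent was placed."""
        site = f.tip_site if base_site is None else base_site
        if self._interior(site):
            nxt, ell = self._pick_site_fast(site, c)
        else:
            nxt, ell = self._pick_site_slow(site, c)
        if nxt is None:
            return False
        pos = (np.asarray(nxt, dtype=float) + 0.5) * GRID_UM
        map_bin = project_activation(pos, self.geom)
        f.add_agent(nxt, ell, map_bin, self.adhesion_every)
        self._lat.occupy(nxt, c)
        self.actin[c] -= self.step_cost
        return True

    def _pick_site_fast(self, site, c: int):
        """Guided step choice via flat-index gathers (interior sites)."""
        x, y, z = site
        base = (x * self._lat.ny + y) * self._nz + z
        nbf = base + self._deltas26
        occ = self._occ_flat[nbf]
        free = np.nonzero(~occ)[0]
        if len(free) == 0:
            return None, 0.0
        rng = self.rng
        if rng.random() < self.config.filopodia.G and not self._uniform:
            ys = self._dy26[free]
            best = np.nonzero(ys == ys.max())[0]
            k = free[best[rng.integers(len(best))]] if len(best) > 1 else free[best[0]]
        else:
            k = free[rng.integers(len(free))]
        flat = int(base + self._deltas26[k])
        y2 = (flat % self._nyz) // self._nz
        nxt = (x + int(MOORE_OFFSETS[k, 0]), int(y2), z + int(MOORE_OFFSETS[k, 2]))
        # sensing input of the new agent (occlusion-corrected mean VEGF)
        if self._interior(nxt):
            nbf2 = flat + self._deltas26
            own2 = self._own_flat[nbf2] == c
            if self._uniform:
                total = self._V * (1 + int(np.sum(~own2)))
            else:
                ys2 = y2 + self._dy26
                total = self._V * (y2 + float(np.sum(ys2[~own2])))
            ell = total / (27.0 * self._sens_scale)
        else:
            ell = self._sensing_input_fast(nxt, c)
        return nxt, ell

    def _pick_site_slow(self, site, c: int):
        """Boundary-safe step choice (lattice walls, axis wrap)."""
        from .filopodia import choose_step_direction

        cand = self._free_candidates(site, c)
        if len(cand) == 0:
            return None, 0.0
        vegf = self._site_vegf(cand[:, 1])
        nxt = choose_step_direction(site, cand, vegf, self.config.filopodia.G, self.rng)
        return nxt, self._sensing_input_fast(nxt, c)

    # -- run loop ------------------------------------------------------

    def n_filopodia(self) -> np.ndarray:
        return np.array([len(fs) for fs in self.fils])

    def fil_agent_counts(self) -> np.ndarray:
        return np.array([sum(f.n_agents for f in fs) for fs in self.fils])

    def run(
        self,
        max_steps: int,
        record_ap: bool = False,
        ap_alpha: float = 1.0,
        record_every: int = 1,
    ) -> Trace:
        """Run for ``max_steps`` steps, recording the per-cell trace.

        With ``record_ap`` the sensory map is accumulated each step and
        its intensity and entropy stored alongside the trace.
        """
        n = self.vessel.n_cells
        T = max_steps
        tr = Trace(
            t=np.arange(T),
            vegfr=np.empty((T, n)),
            vegfr_active=np.empty((T, n)),
            dll4=np.empty((T, n)),
            notch_active=np.empty((T, n)),
            n_filopodia=np.empty((T, n), dtype=np.int64),
            fil_agents=np.empty((T, n), dtype=np.int64),
            seed=self.seed,
        )
        if record_ap:
            tr.ap_intensity = np.empty(T)
            tr.ap_entropy = np.empty(T)
        for i in range(T):
            counts = self.step(record_map=record_ap)
            tr.vegfr[i] = self.vegfr_cell
            tr.vegfr_active[i] = self.vstar_cell
            tr.dll4[i] = self.dll4_cell
            tr.notch_active[i] = self.nstar_cell
            tr.n_filopodia[i] = self.n_filopodia()
            tr.fil_agents[i] = self.fil_agent_counts()
            if record_ap:
                tr.ap_intensity[i] = intensity(counts)
                tr.ap_entropy[i] = entropy(counts, alpha=ap_alpha)
        return tr

    def run_steps(self, n_steps: int):
        """Advance without recording (used between hysteresis windows)."""
        for _ in range(n_steps):
            self.step()

    def dll4_window(self, n_steps: int):
        """Advance ``n_steps`` recording the first active cell's Dll4 and
        filopodia deployment fraction (hysteresis bookkeeping)."""
        active = [c for c in range(self.vessel.n_cells) if c not in self.frozen]
        c = active[0]
        a0 = self.config.filopodia.actin_pool_um
        d = np.empty(n_steps)
        fr = np.empty(n_steps)
        for i in range(n_steps):
            self.step()
            d[i] = self.dll4_cell[c]
            fr[i] = 1.0 - self.actin[c] / a0
        return d, fr
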