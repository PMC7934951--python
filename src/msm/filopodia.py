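"""Filopodia: stochastic extension, gradient-guided stepping, burst retraction.

A filopodium is a non-branched chain of new memAgents growing one grid
site (0.5 um) at a time from a base agent on the cell surface.  Extension
is stochastic with probability ``P = min(1, F * Vegfr*_tip / p_cap)`` and
costs actin from the cell pool (``token_strength`` per um).  Every 2 um
along the chain an adhesion anchors the filopodium to the environment.
Direction choice couples movement to sensing: with probability ``G`` the
tip steps into the adjacent free site with the highest VEGF, otherwise it
steps uniformly at random — so even at G = 0 the up-gradient direction is
taken roughly a third of the time on the cubic lattice.

A tip idle for ``filtipmax`` consecutive steps flips the filopodium into
retraction: one burst per step snaps the chain back to the most distal
remaining adhesion, which then releases so the next burst can proceed.
Actin returns to the cell pool as agents are deleted, so the actin ledger
balances exactly at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .lattice import GRID_UM
from .config import FilopodiaConfig as FilopodiaParams  # spec-level parameter bundle

#: fraction of uniformly random 26-neighbourhood steps that move up the
#: gradient on the cubic lattice (9 of 26 ~ 1/3; the idealised one-third
#: is the conventional adjustment used when quoting effective guidance)
RANDOM_UP_FRACTION = 1.0 / 3.0


def effective_up_gradient_probability(G: float, p_random: float = RANDOM_UP_FRACTION) -> float:
    """Effective probability of an up-gradient step under guidance ``G``.

    The guided mixture is ``G + (1 - G) * p_random``: the guided fraction
    always climbs (in a vertical linear gradient the max-VEGF neighbour is
    up-gradient) and the random fraction still lands up-gradient with
    probability ``p_random``.
    """
    if not 0.0 <= G <= 1.0:
        raise ValueError("G must lie in [0, 1]")
    return G + (1.0 - G) * p_random


def extension_probability(vegfr_active, F: float, p_cap: float):
    """P(extend) = min(1, F * Vegfr* / p_cap), vectorised."""
    return np.minimum(np.asarray(vegfr_active, dtype=float) * F / p_cap, 1.0)


@dataclass
class Filopodium:
    """State of one filopodium: an ordered chain of agent records.

    Chain bookkeeping is kept in plain lists (chains are short and mutate
    at the tip); parallel entries hold each chain agent's grid site,
    cached sensing input, sensory-map bin and adhesion flag.
    """

    cell_id: int
    base_idx: int  # body-agent index of the base
    base_coord: tuple  # (axial, circ) mesh coordinate, for spacing checks
    sites: list = field(default_factory=list)
    ell: list = field(default_factory=list)
    bins: list = field(default_factory=list)
    adhesion: list = field(default_factory=list)
    state: str = "extending"
    steps_since_extension: int = 0

    @property
    def n_agents(self) -> int:
        return len(self.sites)

    @property
    def length_um(self) -> float:
        return self.n_agents * GRID_UM

    @property
    def tip_site(self) -> Optional[tuple]:
        return self.sites[-1] if self.sites else None

    def add_agent(self, site, ell: float, map_bin: int, adhesion_every: int) -> None:
        """Append a new chain agent at ``site``; place an adhesion every
        ``adhesion_every`` agents (2 um at the default grid)."""
        self.sites.append(tuple(site))
        self.ell.append(float(ell))
        self.bins.append(int(map_bin))
        self.adhesion.append((len(self.sites) % adhesion_every) == 0)
        self.steps_since_extension = 0

    def mark_idle(self, filtipmax: int) -> None:
        self.steps_since_extension += 1
        if self.steps_since_extension >= filtipmax:
            self.state = "retracting"

    def burst_retract(self) -> list:
        """One retraction burst: snap back to the most distal remaining
        adhesion (which then releases), deleting traversed agents.

        Returns the list of removed sites; an empty chain afterwards means
        the filopodium has fully retracted and should be discarded.
        """
        if not self.sites:
            return []
        anchors = [i for i, a in enumerate(self.adhesion) if a]
        # retract to the last adhesion, exclusive; no adhesion -> full burst
        keep = anchors[-1] + 1 if anchors else 0
        removed = self.sites[keep:]
        del self.sites[keep:], self.ell[keep:], self.bins[keep:], self.adhesion[keep:]
        if anchors:
            self.adhesion[anchors[-1]] = False  # released, next burst proceeds
        return removed


def choose_step_direction(
    tip_site,
    candidate_sites: np.ndarray,
    candidate_vegf: np.ndarray,
    G: float,
    rng: np.random.Generator,
):
    """Pick the next site for an extending tip.

    With probability ``G`` the candidate with maximal VEGF is chosen (ties
    broken uniformly); otherwise a uniformly random candidate.  Returns
    ``None`` when no free candidate exists (the tip idles).
    """
    m = len(candidate_sites)
    if m == 0:
        return None
    if rng.random() < G:
        vmax = candidate_vegf.max()
        best = np.nonzero(candidate_vegf == vmax)[0]
        pick = best[rng.integers(len(best))] if len(best) > 1 else best[0]
    else:
        pick = rng.integers(m)
    return tuple(int(v) for v in candidate_sites[pick])
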