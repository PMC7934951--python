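"""VEGF receptor activation, Notch-Dll4 binding, delayed gene regulation.

The per-step signalling cascade is:

* receptor activation: an agent holding ``Vegfr_m`` receptors exposed to
  ligand input ``l`` activates ``Vegfr*_m = Vegfr_m * l``, capped at
  ``Vegfr_m`` (a receptor is either active or not),
* Notch binding at junctions: ``Notch* = min(Dll4_available, Notch_max)``,
  with exactly the bound amount of Dll4 removed from the apposed agent
  (lateral-inhibition consumption sink),
* gene regulation after a 28-step delay::

      Vegfr_cell <- max(0, Vegfr_max - sigma * N*(t - delay))
      D_cell     <- min(d_max, D_cell + delta * Vegfr*(t - delay))

  where the Dll4 pool is additionally depleted by neighbour Notch
  consumption during the step and floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GeneRegulationParams:
    sigma: float = 12.0  # Notch -> Vegfr inhibition strength
    delta: float = 0.7  # Vegfr* -> Dll4 production gain
    delay_steps: int = 28
    vegfr_max: float = 12000.0
    notch_max: float = 50.0  # per-agent Notch ceiling
    d_max: float = 10000.0  # Dll4 ceiling (600-ligand criterion = 6%)
    dll4_mode: str = "accumulate"

    def __post_init__(self) -> None:
        for name in ("sigma", "delta", "vegfr_max", "notch_max", "d_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.delay_steps < 1:
            raise ValueError("delay_steps must be >= 1")


class DelayBuffer:
    """Zero-primed history of per-cell totals read ``delay`` steps late.

    ``append`` records the value produced at the current step; ``read``
    returns the record from ``delay_steps`` ago, or 0.0 for the start-up
    period where no record exists yet.
    """

    def __init__(self, delay_steps: int):
        self.delay_steps = int(delay_steps)
        self._values: list[float] = []

    def append(self, value: float) -> None:
        self._values.append(float(value))

    def read(self) -> float:
        """The record from ``delay_steps`` before the current step.

        With the step-``t`` record just appended (entries ``0 .. t``),
        this returns the entry from step ``t - delay_steps``; zero during
        the primed start-up period.
        """
        i = len(self._values) - 1 - self.delay_steps
        if i < 0:
            return 0.0
        return self._values[i]

    def __len__(self) -> int:
        return len(self._values)


def activate_vegfr(vegfr, ligand_input):
    """Expected activated receptor count ``Vegfr* = Vegfr * l``, capped.

    ``ligand_input`` is the aggregated VEGF available to the agent (its
    sensing-neighbourhood input).  The result never exceeds the receptor
    count: activation saturates once every receptor is bound.  Vectorised
    over agents.
    """
    vegfr = np.asarray(vegfr, dtype=float)
    lig = np.asarray(ligand_input, dtype=float)
    return np.minimum(vegfr * lig, vegfr)


def sample_activation(vegfr, ligand_input, rng: np.random.Generator):
    """Stochastic per-agent activation: each discrete receptor activates
    independently with probability ``min(1, l)``.

    The expectation equals :func:`activate_vegfr`; sampling keeps
    activation counts integral, as the sensory-map entropy estimate
    assumes, and provides the demographic noise that breaks symmetry
    between otherwise identical cells.
    """
    p = np.minimum(np.asarray(ligand_input, dtype=float), 1.0)
    return rng.binomial(np.asarray(vegfr, dtype=np.int64), p)


def bind_notch(available_dll4: float, notch_max: float, is_junction: bool = True):
    """Notch activation at one junction agent.

    Returns ``(notch_active, dll4_consumed)``; both are
    ``min(available_dll4, notch_max)`` — bound ligand is removed from the
    apposed cell.  Non-junction agents never receive ligand and return 0.
    The equality case resolves to the full available amount.
    """
    if not is_junction:
        return 0.0, 0.0
    if available_dll4 < 0:
        raise ValueError("available_dll4 must be >= 0")
    bound = min(available_dll4, notch_max)
    return bound, bound


def gene_regulation_update(
    vegfr_total: float,
    dll4_total: float,
    delayed_notch: float,
    delayed_vegfr_active: float,
    params: GeneRegulationParams,
):
    """One delayed gene-regulatory update of the cell pools.

    Notch consumption of the Dll4 pool is applied separately at binding
    time; this function handles the delayed production/inhibition terms.
    Returns ``(vegfr_total, dll4_total)``.
    """
    new_vegfr = max(0.0, params.vegfr_max - params.sigma * delayed_notch)
    if params.dll4_mode == "replace":
        new_dll4 = params.delta * delayed_vegfr_active
    else:
        new_dll4 = dll4_total + params.delta * delayed_vegfr_active
    new_dll4 = min(params.d_max, max(0.0, new_dll4))
    return new_vegfr, new_dll4
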