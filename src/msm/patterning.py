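"""Salt-and-pepper pattern detection and timing criteria.

Two pattern readouts are implemented:

* the ten-cell ring criterion — four or five pairwise non-adjacent tip
  cells (cells that have sprouted filopodia and are not inhibited) active
  simultaneously and persisting for 100 consecutive steps;
* the two-cell Dll4-advantage criterion — one cell maintaining an
  advantage of 600 ligands over the other for 100 steps, the waiting
  window being subtracted from the reported time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import PatternConfig
from .engine import Trace


@dataclass
class PatternResult:
    patterned: bool
    time_to_pattern: Optional[int]
    tip_ids: frozenset
    run_seed: int


def classify_tips(
    vegfr_cell: np.ndarray,
    n_filopodia: np.ndarray,
    vegfr_max: float,
    tip_fraction: float = 0.5,
) -> np.ndarray:
    """Tip mask: a cell is a tip iff it has sprouted at least one
    filopodium and has not been inhibited (Vegfr above ``tip_fraction`` of
    the receptor ceiling)."""
    return (np.asarray(n_filopodia) >= 1) & (
        np.asarray(vegfr_cell) > tip_fraction * vegfr_max
    )


def _nonadjacent_on_ring(tips: np.ndarray) -> bool:
    """True iff no two tip cells are ring neighbours (periodic wrap)."""
    idx = np.nonzero(tips)[0]
    n = len(tips)
    s = set(idx.tolist())
    return all((i + 1) % n not in s for i in idx)


def time_to_pattern(
    trace: Trace,
    vegfr_max: float,
    criteria: PatternConfig | None = None,
    seed: int | None = None,
) -> PatternResult:
    """Earliest step from which the ring tip-pattern criteria hold for the
    full stability window.

    The qualifying condition — between ``min_tips`` and ``max_tips``
    pairwise non-adjacent tips — must hold at every step of
    ``[t, t + stability_window]``; the tip set itself may fluctuate.
    """
    crit = criteria or PatternConfig()
    T, _ = trace.dll4.shape
    ok = np.zeros(T, dtype=bool)
    last_tips = frozenset()
    tipsets = []
    for t in range(T):
        tips = classify_tips(
            trace.vegfr[t], trace.n_filopodia[t], vegfr_max, crit.tip_vegfr_fraction
        )
        k = int(tips.sum())
        ok[t] = crit.min_tips <= k <= crit.max_tips and _nonadjacent_on_ring(tips)
        tipsets.append(frozenset(np.nonzero(tips)[0].tolist()))

    w = crit.stability_window
    run = 0
    for t in range(T):
        run = run + 1 if ok[t] else 0
        if run >= w + 1:
            start = t - w
            return PatternResult(
                patterned=True,
                time_to_pattern=start,
                tip_ids=tipsets[t],
                run_seed=seed if seed is not None else trace.seed,
            )
    return PatternResult(
        patterned=False,
        time_to_pattern=None,
        tip_ids=last_tips,
        run_seed=seed if seed is not None else trace.seed,
    )


def dll4_advantage_time(
    dll4: np.ndarray,
    advantage: float = 600.0,
    window: int = 100,
    seed: int = 0,
) -> PatternResult:
    """Two-cell patterning time under the Dll4-advantage criterion.

    ``dll4`` is a (T, 2) per-step array.  Returns the start of the first
    window of ``window`` steps throughout which ``|D1 - D2| >= advantage``
    with constant sign; the waiting window itself is excluded from the
    reported time.  A sign flip inside a window restarts it.
    """
    d = np.asarray(dll4)
    if d.ndim != 2 or d.shape[1] != 2:
        raise ValueError("dll4_advantage_time expects a (T, 2) two-cell trace")
    diff = d[:, 0] - d[:, 1]
    lead = np.where(diff >= advantage, 1, np.where(diff <= -advantage, -1, 0))
    run = 0
    sign = 0
    for t in range(len(lead)):
        if lead[t] != 0 and lead[t] == sign:
            run += 1
        elif lead[t] != 0:
            sign = lead[t]
            run = 1
        else:
            sign = 0
            run = 0
        if run >= window + 1:
            start = t - window
            winner = 0 if sign > 0 else 1
            return PatternResult(
                patterned=True,
                time_to_pattern=start,
                tip_ids=frozenset({winner}),
                run_seed=seed,
            )
    return PatternResult(False, None, frozenset(), seed)


def export_time_space(trace: Trace, frame_stride: int = 100) -> np.ndarray:
    """Time-space matrix of Dll4 per cell, one frame every ``frame_stride``
    steps (the classic green-purple kymograph layout)."""
    return trace.dll4[::frame_stride].copy()


def export_time_space_csv(trace: Trace, path, frame_stride: int = 100) -> None:
    import pandas as pd

    mat = export_time_space(trace, frame_stride)
    df = pd.DataFrame(
        mat, columns=[f"cell_{i}" for i in range(mat.shape[1])]
    )
    df.insert(0, "t", np.arange(0, trace.dll4.shape[0], frame_stride))
    df.to_csv(path, index=False)
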