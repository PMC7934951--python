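"""Reproducible experiment drivers: sweeps, replicates, aggregation.

Every replicate's seed is ``base_seed + replicate_index``, and each run
consumes a single seeded generator, so re-running any experiment with the
same configuration yields identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .active_perception import APMeasureSeries, entropy, intensity
from .config import ConfigError, SimConfig, control_config
from .engine import Simulation
from .hysteresis import HysteresisCurve, run_hysteresis
from .patterning import PatternResult, classify_tips, dll4_advantage_time

#: parameter ranges admitted by the sweep drivers
F_RANGE = (0.0, 3.0)
G_RANGE = (0.0, 1.0)
V_GRADIENT_RANGE = (0.0, 0.05)
V_UNIFORM_RANGE = (0.4, 1.5)


def _check_range(name, value, lo, hi):
    if not lo <= value <= hi:
        raise ConfigError(f"{name}={value} outside admitted range [{lo}, {hi}]")


# ----------------------------------------------------------------------
# ring patterning runs

def run_ring_patterning(config: SimConfig, seed: int) -> PatternResult:
    """One ten-cell (or n-cell) run, stopped as soon as the ring pattern
    criteria have held for the full stability window."""
    sim = Simulation(config, seed=seed)
    crit = config.pattern
    sig = config.signalling
    max_steps = config.max_steps
    from .patterning import _nonadjacent_on_ring

    run = 0
    for t in range(max_steps):
        sim.step()
        tips = classify_tips(
            sim.vegfr_cell, sim.n_filopodia(), sig.vegfr_max, crit.tip_vegfr_fraction
        )
        k = int(tips.sum())
        ok = crit.min_tips <= k <= crit.max_tips and _nonadjacent_on_ring(tips)
        run = run + 1 if ok else 0
        if run >= crit.stability_window + 1:
            return PatternResult(
                patterned=True,
                time_to_pattern=t - crit.stability_window,
                tip_ids=frozenset(np.nonzero(tips)[0].tolist()),
                run_seed=seed,
            )
    return PatternResult(False, None, frozenset(), seed)


def run_timing_sweep(
    F_values: Sequence[float],
    V: float = 0.04,
    mode: str = "gradient",
    reps: int = 100,
    base_seed: int = 0,
    n_cells: int = 10,
    G: float = 0.9,
) -> pd.DataFrame:
    """Per-seed time-to-pattern table over an F grid (violin-plot ready)."""
    rows = []
    for F in F_values:
        _check_range("F", F, *F_RANGE)
        if mode == "gradient":
            _check_range("V", V, *V_GRADIENT_RANGE)
        else:
            _check_range("V", V, *V_UNIFORM_RANGE)
        _check_range("G", G, *G_RANGE)
        cfg = control_config(
            **{
                "filopodia.F": F,
                "filopodia.G": G,
                "vegf.V": V,
                "vegf.mode": mode,
                "vessel.n_cells": n_cells,
            }
        )
        for r in range(reps):
            res = run_ring_patterning(cfg, seed=base_seed + r)
            rows.append(
                {
                    "F": F,
                    "V": V,
                    "G": G,
                    "mode": mode,
                    "seed": res.run_seed,
                    "patterned": res.patterned,
                    "time_to_pattern": res.time_to_pattern,
                }
            )
    return pd.DataFrame(rows)


def summarize_timing(df: pd.DataFrame) -> pd.DataFrame:
    """Median/quartile/unpatterned-fraction summary per parameter set."""
    out = []
    for keys, g in df.groupby(["F", "V", "G", "mode"]):
        t = g.loc[g.patterned, "time_to_pattern"]
        out.append(
            {
                "F": keys[0],
                "V": keys[1],
                "G": keys[2],
                "mode": keys[3],
                "n": len(g),
                "n_unpatterned": int((~g.patterned).sum()),
                "median": float(t.median()) if len(t) else float("nan"),
                "q25": float(t.quantile(0.25)) if len(t) else float("nan"),
                "q75": float(t.quantile(0.75)) if len(t) else float("nan"),
            }
        )
    return pd.DataFrame(out)


# ----------------------------------------------------------------------
# two-cell active-perception runs

def ap_signature_run(
    config: Optional[SimConfig] = None,
    seed: int = 0,
    max_steps: Optional[int] = None,
    post_margin: int = 400,
    ap_alpha: float = 1.0,
) -> APMeasureSeries:
    """One two-cell run recording the sensory-map intensity and entropy.

    The run stops ``post_margin`` steps after the Dll4-advantage pattern
    criterion is met (or at ``max_steps``).
    """
    cfg = config or control_config(**{"vessel.n_cells": 2})
    if cfg.vessel.n_cells != 2:
        raise ValueError("AP signature runs use the two-cell vessel")
    detect_limit = max_steps if max_steps is not None else cfg.max_steps
    crit = cfg.pattern
    sim = Simulation(cfg, seed=seed)

    I, H, d_hist = [], [], []
    run = 0
    sign = 0
    t = 0
    pattern_start = None
    while True:
        counts = sim.step(record_map=True)
        I.append(intensity(counts))
        H.append(entropy(counts, alpha=ap_alpha))
        d_hist.append(sim.dll4_cell.copy())
        if pattern_start is None:
            diff = d_hist[-1][0] - d_hist[-1][1]
            lead = 1 if diff >= crit.dll4_advantage else (-1 if diff <= -crit.dll4_advantage else 0)
            if lead != 0 and lead == sign:
                run += 1
            elif lead != 0:
                sign, run = lead, 1
            else:
                sign, run = 0, 0
            if run >= crit.dll4_window + 1:
                pattern_start = t - crit.dll4_window
            elif t >= detect_limit - 1:
                break
        elif t >= pattern_start + crit.dll4_window + post_margin:
            break
        t += 1
    series = APMeasureSeries(
        t=np.arange(len(I)),
        intensity=np.array(I),
        entropy=np.array(H),
        seed=seed,
        patterned=pattern_start is not None,
        pattern_time=float(pattern_start) if pattern_start is not None else float("nan"),
    )
    return series


def entropy_drop(series: APMeasureSeries, window: int = 200, wait: int = 100) -> float:
    """Post-patterning entropy drop of one run, in bits.

    Mean entropy over the ``window`` steps before the pattern time minus
    the mean over the ``window`` steps after the stability wait completes.
    NaN for unpatterned runs or windows truncated to nothing.
    """
    if not series.patterned:
        return float("nan")
    tp = int(series.pattern_time)
    pre = series.entropy[max(0, tp - window): tp]
    post = series.entropy[tp + wait: tp + wait + window]
    if len(pre) == 0 or len(post) == 0:
        return float("nan")
    return float(pre.mean() - post.mean())


def run_ap_experiment(
    reps: int = 100,
    base_seed: int = 0,
    config: Optional[SimConfig] = None,
    drop_window: int = 200,
) -> dict:
    """Replicated two-cell AP experiment with per-step aggregation.

    Returns per-step mean and min-max envelope of I and H (over the steps
    all replicates cover), the per-replicate pattern times (patterned runs
    only) and entropy drops.
    """
    series = [
        ap_signature_run(config=config, seed=base_seed + r) for r in range(reps)
    ]
    T = min(len(s.t) for s in series)
    I = np.stack([s.intensity[:T] for s in series])
    H = np.stack([s.entropy[:T] for s in series])
    times = np.array([s.pattern_time for s in series if s.patterned])
    drops = np.array([entropy_drop(s, window=drop_window) for s in series])
    return {
        "t": np.arange(T),
        "I_mean": I.mean(axis=0),
        "I_min": I.min(axis=0),
        "I_max": I.max(axis=0),
        "H_mean": H.mean(axis=0),
        "H_min": H.min(axis=0),
        "H_max": H.max(axis=0),
        "n_patterned": int(sum(s.patterned for s in series)),
        "n": reps,
        # undefined (not zero) when nothing patterned
        "mean_pattern_time": float(times.mean()) if len(times) else float("nan"),
        "entropy_drops": drops,
        "mean_entropy_drop": float(np.nanmean(drops)) if np.any(np.isfinite(drops)) else float("nan"),
        "series": series,
    }


# ----------------------------------------------------------------------
# hysteresis experiments

def run_hysteresis_experiment(
    F: float = 2.0,
    V: float = 0.04,
    G: float = 0.9,
    mode: str = "gradient",
    reps: int = 1,
    base_seed: int = 0,
    config: Optional[SimConfig] = None,
) -> list:
    """Replicated up/down ramps at one parameter set; list of curves."""
    _check_range("F", F, *F_RANGE)
    _check_range("G", G, *G_RANGE)
    curves = []
    for r in range(reps):
        cfg = config or control_config(
            **{
                "vessel.n_cells": 3,
                "filopodia.F": F,
                "filopodia.G": G,
                "vegf.V": V,
                "vegf.mode": mode,
            }
        )
        curves.append(run_hysteresis(cfg, seed=base_seed + r))
    return curves


def aggregate_curves(curves: list) -> pd.DataFrame:
    """Per-(level, direction) mean +/- sd of equilibrium D_cell across
    replicate ramps."""
    df = pd.concat([c.to_frame() for c in curves], ignore_index=True)
    return (
        df.groupby(["d_ext", "direction"])
        .agg(mean=("mean", "mean"), sd=("mean", "std"), n=("mean", "size"))
        .reset_index()
    )
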