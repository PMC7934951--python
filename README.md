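# msm-tipselect

Agent-based simulation of endothelial **tip-cell selection**: how a row
of cells in a pre-existing vessel, stimulated by a VEGF gradient, uses
filopodia-mediated sensing coupled to Notch–Dll4 lateral inhibition to
pick an alternating ("salt-and-pepper") pattern of migratory tip cells
and inhibited stalk cells — and how the *coupling of movement and
sensing* on filopodia gives individual cells bistable, switch-like
decision dynamics.

The package implements a constrained memAgent-spring model (MSM): cell
surfaces are meshes of ~1200 membrane agents ("memAgents") connected by
Hookean springs on a 6 µm-diameter cylinder, snapped to a 0.5 µm
lattice. Per time step, each cell's receptor pool `Vegfr_cell` is
distributed equally over its current surface (body plus filopodia),
activated by local ligand (`Vegfr*_m = Vegfr_m · I`, capped), Notch
binds junction Dll4 (`Notch* = min(Dll4, Notch_max)`, consuming
neighbour ligand), filopodia extend stochastically
(`P(extend) ≈ F · Vegfr*`, up-gradient with probability `G`, actin
limited) and retract in adhesion-bounded bursts, and gene regulation
updates the pools after a 28-step delay:

    Vegfr_cell ← max(0, Vegfr_max − σ·N*′)
    D_cell     ← min(D_max, D_cell + δ·Vegfr*′)    (′ = 28 steps ago)

Three analysis testbeds ship with the model:

* **ring patterning** — time-to-pattern of a ten-cell vessel (4–5
  non-adjacent tips stable for 100 steps), for filopodia (F), gradient
  (V) and guidance (G) loss/gain-of-function sweeps;
* **single-cell hysteresis** — a centre cell flanked by two frozen Dll4
  sources whose clamped total `D_ext` is ramped quasi-statically up and
  down (increments of 50, sliding-window stationarity test with
  ε = 0.5), plus abrupt step responses at fixed `D_ext`;
* **active-perception signatures** — a two-cell vessel whose receptor
  activations are projected radially onto a fixed cylindrical sensory
  map each step, summarised by intensity `I = Σ Vegfr*` and Shannon
  entropy `H = −Σ pᵢ log₂ pᵢ` (Laplace-smoothed), with patterning
  declared once one cell holds a 600-ligand Dll4 advantage for 100
  steps.

A separate module analyses 1-D spatial intensity profiles (e.g.
phospho-Erk staining along an embryo axis) with the Lomb–Scargle
periodogram, `P = 2π/f`, including a synthetic profile generator with
"control" and "filopodia-loss" presets.

See `docs/methods.md` for model details, parameter calibration and
limitations.

## Worked example

```python
import numpy as np
from msm.experiments import ap_signature_run, entropy_drop

series = ap_signature_run(seed=0)   # two-cell vessel, control parameters
print(f"patterned at t = {series.pattern_time:.0f}")
print(f"entropy drop  = {entropy_drop(series):.2f} bits")
```

prints

```
patterned at t = 376
entropy drop  = 1.02 bits
```

— the two cells compete, one locks in as the tip around step 376 (the
first step of the sustained 600-ligand Dll4 advantage), and the spatial
entropy of the sensory map falls by about one bit: before the decision
both cells' surfaces receive activations, afterwards essentially one
does, halving the support of the activation distribution.

From the shell, the same machinery is available as subcommands:

```
msm run --cells 10 --F 2 --V 0.04 --seed 1 --out run.csv --timespace ts.csv
msm sweep --F-grid 0.5,2,3 --reps 20 --out sweep.csv
msm hyst --F 2 --V 0.04 --reps 3 --out curve.csv
msm step --d-ext 850
msm ap --reps 20 --out ap.csv
msm synth-profile --preset latb --out prof.csv
msm periodogram --in prof.csv --out spec.csv
```

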