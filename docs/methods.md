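# Methods

This note documents the model implemented in `msm`, the choices made
where the published rule set is silent, the calibration of the constants
that are not printed anywhere, and what the test suite does and does not
establish.

## The constrained memAgent-spring model

Cell surfaces are meshes of membrane agents ("memAgents") on a cylinder
(radius 3 µm, cell width 10 µm), one cell per vessel cross-section,
joined in a ring with periodic ends. Agents live in continuous space but
are snapped to a lattice of 0.5 µm cubic sites on which all local rules
operate. At the default mesh density each cell has exactly 1200 agents
(60 around the circumference × 20 axial rings). Agents are connected by
Hookean springs (quad ring-lattice topology). In this constrained mode
cells are positionally fixed: body agents are anchored, filopodium
agents are created at spring rest length and pinned by adhesions, so the
system sits at its spring-energy minimum by construction and the
per-step relaxation pass is the identity (the damped relaxation routine
is still part of the library and is exercised by the test suite).

### VEGF field and sensing

The field is static: a linear gradient `I(y) = V·y` anchored at zero at
the lattice floor (`y` in site units; the vessel rests on the floor) or
a uniform value. An agent's ligand input is the mean `I` over its own
site and its 26-neighbourhood, excluding sites occupied by its own cell
(occlusion: receptors face extracellular space), divided by a receptor
half-saturation scale `sensing_scale` (default 3). Per-agent activation
is `Vegfr*_m = Vegfr_m · input`, capped at `Vegfr_m` — a receptor is
active or not. In the engine each discrete receptor activates
independently with probability `min(1, input)` (binomial sampling): the
expectation reproduces the multiplicative law, activation counts stay
integral for the sensory map, and the demographic noise is what breaks
symmetry between initially identical cells. Setting
`signalling.stochastic_activation: false` recovers the deterministic
expectation; in that mode the engine matches a directly iterated
two-variable delay map step for step (tested).

Why the normalisations: summing raw `I` over all 27 sites saturates the
per-agent cap at the published `V` values for essentially every agent
above the second lattice row, which erases the gradient information the
guidance and bistability mechanisms need; the neighbourhood **mean**
keeps the input on the per-site scale `V·y`. The half-saturation scale
then sets where climbing stops paying: with `sensing_scale = 3`, a tip
saturates near `y ≈ 78` sites, so a filopodium keeps gaining activation
over its whole permitted length.

### Signalling and gene regulation

Junction agents (those with a Moore neighbour owned by another cell; 60
per interface, two interfaces per cell) receive the cell's Dll4 pool in
equal shares; all agents receive equal shares of the receptor pool
(integer split, remainder to uniformly random agents). Notch binding at
a junction consumes apposed ligand: `Notch* = min(Dll4_available,
Notch_max)`, the bound amount debited from the neighbour's pool. With
the default per-agent ceiling (50) the junction capacity (6000) exceeds
typical pools, so a cell's Dll4 is turned over essentially every step
and `D_cell` tracks `δ·Vegfr*` with a 28-step lag — a faithful
consumption-bounded reading of the printed accumulation rule
(`dll4_mode: replace` is also implemented).

Gene regulation, after the 28-step delay:

    Vegfr_cell ← max(0, Vegfr_max − σ·N*(t−28))
    D_cell     ← min(d_max, D_cell − consumed + δ·Vegfr*(t−28))

`d_max = 10000` follows from the anchor that the 600-ligand patterning
criterion is 6% of the ceiling.

### Filopodia

Extension is stochastic, `P(extend) = min(1, F·Vegfr*_tip / p_cap)`,
one grid step at a time, choosing among free Moore neighbours: with
probability `G` the candidate with maximal VEGF (ties uniform),
otherwise uniformly at random — at `G = 0` roughly a third of random
steps (9 of 26) still move up-gradient. Each 0.5 µm step costs actin
(`token_strength` per µm) from the shared cell pool of 300 µm; an
adhesion pins the chain every 2 µm. A tip idle for `filtipmax = 15`
steps flips to retraction: one burst per step back to the most distal
remaining adhesion (released afterwards), actin returning as agents are
deleted. A post-burst tip is a live membrane agent and may re-extend,
rescuing the chain — this is what makes anchored, established filopodia
far stickier than nascent stubs, which have no anchors and vanish on
their first burst.

Two quantities the published rule set leaves to prior calibrations are
explicit parameters here:

* `init_factor` (default 0.01) — the nucleation-to-elongation rate
  ratio. De novo initiation from the body surface uses the same
  probability law as tip elongation scaled by this factor. Without it,
  all ~1200 body agents nucleate at the elongation rate and the cell
  grows a lawn of hundreds of one-agent stubs; with it the cell carries
  tens of filopodia, as observed in endothelial cells.
* `max_length_um` (default 30) — a transport-limited maximal filopodium
  length. A tip at the cap that wins its extension draw is maintained
  in place (no actin spent, idle clock reset); persistence therefore
  still tracks activation. Without the cap single filopodia grow past
  100 µm and their saturated tips erase the F/V/G dependence of the
  single-cell bistability.

`p_cap` defaults to 1.1 × the per-agent receptor count at rest
(`vegfr_max / 1200`), placing control-condition tip extension well
above the retraction knee and the loss-of-function condition (F = 0.5)
below it.

### Update order

Per step: distribute pools → activate receptors → bind Notch →
filopodia (tip extensions and bursts, then initiations) → (spring
relaxation — identity here) → delayed gene regulation. A single seeded
generator serves all draws in this fixed order, so runs are
bit-reproducible.

## Calibrated constants

`Vegfr_max = 12000`, `σ = 12`, `δ = 1.35`, `Notch_max = 50`,
actin 300 µm/cell, plus the sensing and filopodia constants above.
The calibration anchors (fixed before the analyses, in this order):
a ten-cell control ring must pattern well inside 2000 steps; the
two-cell testbed must reach the 600-ligand advantage; full inhibition
of a clamped cell occurs at external Dll4 `≈ Vegfr_max/σ = 1000`, which
brackets the step-response targets 500/850/950 within and beyond the
bistable window. With these values the control window of the
quasi-static ramp spans roughly D_ext 750–850.

## Analyses

**Ring patterning.** A cell is a tip iff it has at least one filopodium
and `Vegfr_cell > Vegfr_max/2` (the branch separator; the published
definition — "sprouted filopodia and not inhibited" — does not quantify
"inhibited"). The ring is patterned at the earliest `t` from which 4–5
pairwise non-adjacent tips persist for 100 consecutive steps.

**Two-cell patterning.** The filopodia-independent criterion: one cell
holds a Dll4 advantage ≥ 600 with constant sign for 100 steps; the
waiting window is excluded from the reported time.

**Hysteresis.** Three cells; the flanks are frozen Dll4 sources
presenting a clamped total `D_ext` (half each) at their interfaces with
the centre and consuming the centre's ligand through their Notch, never
updating their own state. The ramp rises in steps of 50, waiting at
each level for the sliding-window stationarity test (windows of 250,
ε = 0.5, 250-step transient, 60000-step ceiling) and stopping after two
consecutive inhibited levels; then descends. Branches are classified by
the filopodia deployment fraction (actin committed), which is bimodal;
`D_cell` itself scales with the receptor pool at every level, so a
single global `D_cell` midpoint — the obvious alternative — mislabels
the active branch at high `D_ext`.

**Step response.** After 10⁴ uninhibited steps (reduced in tests),
`D_ext` jumps to a target and the run continues. The smoothed `D_cell`
trace is classified against two bands placed relative to the expected
active-branch level at the clamp (the level-zero equilibrium scaled by
the remaining receptor pool): no excursion below the low band = active;
one one-way transition = inhibited; two or more crossings = flip-flop.

**Sensory map.** Every activation, including those on filopodia far
from the surface, is projected radially to the fixed cylindrical
surface grid (one bin per 0.5 × 0.5 µm patch, 2400 bins for two cells):
the azimuth and axial coordinates are kept, the radial distance
discarded; activations over a neighbour's territory credit the bin
beneath them. Intensity is the total count; entropy is Shannon entropy
(bits) of the Laplace-smoothed bin distribution (α = 1 count — the
published account names the smoothing but not the constant). The
entropy drop of a run is the mean over the 200 steps before the pattern
time minus the mean over the 200 steps after the 100-step stability
wait completes.

**Spatial periodicity.** Lomb–Scargle periodograms (scipy's
least-squares implementation, validated in the tests against a direct
per-frequency sinusoid fit and against the FFT periodogram on even
sampling) over a 500-point log-spaced angular-frequency grid from
`2π/span` to `π/Δx`. Frequencies are angular (rad per length unit), so
the dominant period is `P = 2π/f`; modes with periods above 80% of the
profile span are offset-like and excluded from dominance. The synthetic
profile generator emulates staining-intensity traces: Gaussian bumps at
a fixed spacing (default 90 length units — the intersegmental-vessel
spacing) with multiplicative amplitude noise, positional jitter and
dropout; the "filopodia-loss" preset (heavy jitter, 50% dropout) mimics
diffuse patterning. It reproduces the *shape* of such profiles only —
no imaging noise model, no nuclear masking, no embryo-to-embryo
variation — so tests on it validate the spectral analysis, not the
biology of the staining.

## Problem sizes in the shipped tests

Replicates and horizons are scaled to single-CPU runs: timing orderings
use 8 seeds per condition (2000-step ceiling), the entropy-drop check
30 two-cell replicates, hysteresis ramps single seeds per condition,
step responses 2000 pre-step and 15000 post-step steps. The acceptance
script uses 60 two-cell replicates for the entropy drop. These sizes
resolve the medians and means asserted; they do not resolve tail
behaviour (e.g. the exact fraction of flip-flop realisations at the
bistable window's edge).

## Known limitations

* With the extension probability linear in local VEGF, halving the
  gradient (V = 0.02) halves every filopodial rate but leaves the
  tall-tip/nascent-stub activation ratio unchanged, so the clamped-cell
  analysis retains a bistable window at V = 0.02 (shifted to lower
  D_ext) rather than losing it entirely; gain-of-function F deepens it.
  Distinguishing loss of bistability from a down-shifted window at
  V = 0.02 would require a nonlinearity (e.g. cooperative activation)
  the implemented rule set does not contain.
* At the window's upper edge (D_ext ≈ 850) transitions are abrupt and
  stochastic with dwell times of 10³–10⁴ steps, but within a 3×10⁴-step
  horizon most realisations cross one way only: return nucleation at
  the same clamp where established tips collapse is rare under the
  linear rule, so two-way flip-flop is a minority outcome across seeds.
* Uniform-VEGF rings break symmetry only through demographic activation
  noise and do not usually reach the full pattern criteria within the
  5000-step ceiling; the gradient-versus-uniform comparison is an
  ordering, with the uniform time read as its censoring bound.
* The mechanical subsystem is inert by construction (fixed cells); the
  spring machinery is correct but untested against any migratory
  regime.
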