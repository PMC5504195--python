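# Methods

## Model overview

The plant is discretised into hydraulic nodes — one root segment, five
stem junctions, and one sheath plus one leaf per junction (16 nodes in the
standard build) — connected by a xylem and a phloem resistor network that
meet at every node.  Four coupled subsystems are advanced with a common
explicit-Euler step:

1. **Water.**  Axial xylem flow follows the xylem water-potential
   gradient; axial phloem flow follows the turgor pressure
   `P_P = Ψ_P − Π`; the lateral flow `(Ψ_X − Ψ_P)/r_lat` couples the two
   circuits at each node.  The osmotic potential `Π = −R·T·C_S` is fixed
   by the instantaneous sucrose state, so node-wise conservation
   (`Σ J_W = 0`) is a linear system in the 2n potentials.  The system
   matrix depends only on the resistances and is LU-factorised once;
   each step solves for a new right-hand side (osmotic terms, boundary
   fluxes).  Boundary conditions: a prescribed transpiration flux out of
   each leaf xylem node, and a fixed soil water potential behind the
   root radial resistance.  There is no storage term: the water field is
   quasi-static, and total transpiration equals soil inflow at every
   step (verified to ~1e-15 relative).
2. **Carbon.**  Per leaf, photosynthesis feeds a starch pool
   (`dS/dt = P − k4·S`); the converted flux `k4·S` loads the leaf phloem
   sucrose pool; sucrose advects along phloem flows with first-order
   upwinding and is respired everywhere at `k1` (see *Units of k1*
   below).  Lateral sucrose flow is ignored.  This is the minimal Münch
   loop: daytime assimilate drives the phloem stream toward the root;
   starch rundown overnight collapses the leaf osmotic drive, so the
   stream is weakest a few hours after lights-on.
3. **Silicon.**  Root uptake crosses two transporter barriers
   (exodermis, endodermis) with a passive membrane leak, both transporter
   terms scaled by the expression factor α.  From the root stele Si
   advects with the xylem stream only (no transport against the flow),
   is ρ-enriched into the DVB branch at each junction under exact mass
   conservation, and unloads first-order into tissue cells, a terminal
   sink.  A per-run ledger (cumulative soil influx vs. inventory change)
   closes to machine precision by construction and is asserted to 0.1%
   in the tests.
4. **Signal.**  Leaves generate the (dimensionless) signal per the
   selected control law, the phloem stream carries it rootward, it decays
   at `dec`, and the root concentration — read with delay χ (5 h for
   water-stress control, else 0, via linear interpolation on the recorded
   history, padded with the initial value) — sets
   `α = max(0, 1 − C_R)` (accumulation, water stress) or
   `α = min(1, C_R)` (shortage).

Step order: water solve → carbon → silicon → signal generation/transport
→ expression factor.  The simulation is fully deterministic.

## Parameters

Two provenance classes exist.  *Pinned* constants: the diurnal forcing
(14-h light / 10-h dark; standard transpiration 0.4 ml cm⁻² day⁻¹ with a
2-h midday peak and a 10% night floor; standard photosynthesis 0.0015 in
model units, taken as given without unit conversion — its printed
magnitude is not plausible as a molar flux and is treated as a model
input constant), the signalling grids (`dec` ∈ {0.05, 0.1, 0.2};
`slp_c`, `slp_r` ∈ {0.005, 0.01, 0.02}; `slp_J` ∈ {0.05, 0.1, 0.2};
χ = 5 h), the carbon grids (`k4` ∈ {0.1, 0.15, 0.2}; `k1` ∈
{2…20}·10⁻⁵ with the operating point k1 = 8·10⁻⁵, k4 = 0.1), the cortex
volume (1 ml), the calibration exposure (1.0 mM, zero initial internal
Si, 5-min sampling) and the 4-day horizon.

*Package defaults*: the structural tables behind the simplified plant
(resistances, tissue volumes, leaf area, ρ, `k_m_unload`, the soil
boundary) are not printed anywhere and are this package's own choices,
marked as such in `config.py`.  They were chosen **once** to place the
model in a physiologically sensible regime — midday leaf xylem potential
≈ −0.2 MPa, phloem osmotic potentials ≈ −0.4…−0.6 MPa, phloem flow a few
percent of transpiration and weakest near dawn, leaf-cell Si on the mM
scale that the shortage law `slp·(1 − C_cyt)` presumes — and then frozen.
The free signal scale for water-stress control
(`trans_signal_scale = 12`, multiplying per-leaf transpiration in
ml h⁻¹ before `slp_J`; legitimate because the signal's units are
explicitly arbitrary) was calibrated once against the water-stress
efficiency experiment and likewise frozen.  The `shortage_ref`
normalisation defaults to 1.0 mM, i.e. the shortage law is used exactly
as written, with the generation rate floored at zero once leaf-cell Si
exceeds 1 mM.

### Units of k1

The printed k1 grid (10⁻⁵–10⁻⁴) read as h⁻¹ would give respiration time
constants above 5000 h; sucrose could then never settle into a stable
daily cycle within a 4-day run, and no grid point would classify as
cyclically stable.  The package therefore reads the k1 grid as s⁻¹ and
converts with `k1_time_factor = 3600` (time constants 1.4–14 h across
the grid).  Under this convention the designated operating point
(k1 = 8·10⁻⁵, k4 = 0.1) is cyclically stable and the slow corner of the
grid (k1 = 2·10⁻⁵) still drifts, giving the scan discriminating power.

### Junction partition

Combining the DVB enrichment `C_DVB = ρ·C_EVB` with flux conservation
forces `C_EVB = (J_DVB + J_EVB)·C / (ρ·J_DVB + J_EVB)`, i.e. ρ weights
the DVB flow in the denominator.  The variant with ρ on the EVB flow
does not conserve Si (a test demonstrates this) and is available only
behind `conserve_mass=False` for comparison.

## Numerics

- Explicit Euler, default `dt = 0.05 h`; a test verifies that halving dt
  changes day-4 means by < 1%.  The carbon-stability scan uses
  `dt = 0.02 h` because the slow-respiration corner accumulates enough
  sucrose to stiffen the osmosis–flow coupling.
- Advection is first-order upwind on the node graph, with conduit
  (`V_con`) mixing volumes for Si — except the root stele pool, which
  uses the sieve-tube volume as the root balance is written (switchable
  via `root_si_volume`) — and sieve-tube (`V_st`) volumes for sucrose
  and signal.
- Pools that would cross zero are clipped with a warning; an overshoot
  beyond 1% of the pool raises an instability error advising a smaller
  step.
- Cyclic-stability classification: a series is `cyclic_stable` when the
  last two daily cycles agree within 2% (relative L∞) and the final
  amplitude is non-degenerate; `decaying` when the amplitude falls below
  10⁻³ of the series maximum; otherwise `drifting`.
- Investment efficiency integrates the recorded top-leaf unloading flux
  and α by trapezoidal quadrature; the day/night split follows the
  forcing's light mask.  Doubling the recording stride moves IE by
  < 0.1%.

## Calibration

The forward model for the uptake experiment is the root two-compartment
system at α = 1 with constant exposure and a constant first-order
turnover of the stele pool standing in for xylem export to the shoot
(`k_turnover = 2 h⁻¹`; a sealed stele could not reproduce a saturating
sap curve).  The system is linear, so it is solved in closed form via
the eigendecomposition of the 2×2 rate matrix (stiff-integrator fallback
for degenerate spectra); a test pins it against an independent RK4 at a
100× finer step.  The likelihood is the standard Gaussian density with
the per-time σ_t stored alongside the data (the σ-dependent constant
affects no posterior over θ).  Priors are bounded uniform
(tr_exo, tr_end ∈ [0.01, 10] ml h⁻¹; p_cm ∈ [0.001, 1] ml h⁻¹).

The sampler is a random-walk Metropolis–Hastings chain with Gaussian
proposals.  The posterior is a narrow curved ridge in (tr_end, p_cm) —
the endodermal pumping and the passive leak trade off — which isotropic
proposals traverse too slowly, so during burn-in (first 50% of the
chain) the proposal covariance is adapted to the empirical covariance of
the chain so far, alongside a scalar scale tuned into the 20–40%
acceptance band; both are frozen after burn-in so the retained chain
satisfies detailed balance.  The chain starts from the best of 64 prior
draws (a cold start far out on the flat likelihood shelf can collapse
the adaptive scale).  With 12 000 iterations, 95% credible intervals
cover the generating parameters in ≥ 17/20 synthetic replicates at 5%
noise, and with a constant likelihood the chain reproduces the uniform
prior (KS < 0.05 on a 10× thinned chain).

## What the synthetic data do and do not show

The synthetic boundary forcing is an idealised trapezoid (linear rise
from lights-on to the 2-h flat peak centred on midday, linear fall to
lights-off, constant night floor; the exact published waveform is not
tabulated, and the generator's shape function is pluggable).  The
field-forcing reader converts eddy-covariance LE to transpiration via
the latent heat of vaporisation and −NEE (clipped at 0) to
photosynthesis, with linear gap filling; it reproduces the same
qualitative expression patterns, but real data carry weather-driven
variability, evaporation and soil respiration that the model ignores.
The calibration generator adds independent Gaussian noise to the forward
model itself, so parameter-recovery results certify the estimation
machinery, not the adequacy of the two-compartment root model for real
sap measurements.

## Problem sizes

The standard run is 4 simulated days at dt = 0.05 h (1920 steps, 16
nodes, a 32×32 pre-factorised solve per step; well under a second of
wall time).  The efficiency experiment is four such runs; the carbon
scan is 30 carbon-only runs at dt = 0.02 h; the coverage experiment is
20 chains of 12 000 iterations on 240-point series.

## Limitations

- The carbon model is a deliberately minimal reconstruction (starch →
  sucrose → respiration); it omits stem carbohydrate storage and
  remobilisation, so the reproductive stage is out of scope.
- One root segment; no root architecture, no soil water dynamics
  (`Ψ_soil` fixed).
- The water-stress drive is proportional to transpiration — a proxy, not
  a water-status model; the signal itself is abstract by design (no ABA
  biochemistry).
- Si unloading is linear and unsaturating; deposited Si never remobilises.
- Absolute flow magnitudes depend on the package-default resistances and
  volumes; conclusions should be read at the level of diurnal phase
  structure, orderings and relative efficiencies, not absolute fluxes.
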