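# Methods

## The model

`selfgrad` simulates the guidance of zebrafish ventrolateral mesoderm by a
self-generated chemokine gradient. Mesodermal progenitors internalize at the
blastoderm margin (`x = 0`) and migrate along the animal–vegetal axis toward
the animal pole (`x = L`). The secreted ligand (Toddler/ELABELA/Apela) is
produced broadly by the overlying tissue; the migrating cells express its
receptor (Aplnr), which both removes the ligand (scavenging) and reads its
gradient (sensing). Local removal at the margin, where cells are dense, tilts
an initially flat ligand field into an animal-ward gradient that the same
cells then follow.

The continuum model couples the mesodermal line density `c(x, t)` (cells/µm)
to the ligand concentration `T(x, t)` (arbitrary concentration units):

    ∂c/∂t = D_c ∂²c/∂x² − ∂/∂x[ β (∂T/∂x) c ] + J(x, t)
    ∂T/∂t = D_T ∂²T/∂x² + T₀(x) − T/τ_T − α c T/(T + K)

* `D_c` — random cell motility (µm²/min);
* `β (∂T/∂x)` — chemotactic drift, linear in the local ligand slope;
* `J` — constant influx of cells into the margin bin while internalization
  lasts;
* `D_T` — ligand diffusion; `τ_T` — ligand lifetime; `T₀(x)` — production
  profile (uniform, graded toward the margin, graded toward the animal pole,
  or absent);
* the sink `α c T/(T + K)` removes ligand in proportion to the local cell
  density with a per-cell capacity that saturates at `α` — each cell removes
  ligand at a near-constant rate whenever `T ≫ K`. The Michaelis form keeps
  the sink smooth and positivity-preserving near `T = 0`. The exact uptake
  law, influx law, and boundary conditions are modelling choices of this
  package (one-pool saturating uptake, constant influx, reflecting walls):
  the closed embryo cap motivates zero-flux boundaries, and constant influx
  is the simplest law consistent with continuous internalization.

Runs start from an empty domain (`c = 0`) with the ligand at its
production–degradation equilibrium `T = T₀(x)·τ_T`, reflecting that ligand
expression precedes gastrulation. A margin bolus initial condition
(`initial_cells`) replaces the influx for cohort experiments.

### Units and gauge

Concentration units are arbitrary; only the products `α·β` and `β·T₀·τ_T`
are physically meaningful. The package fixes `T₀ = 1/min` and expresses the
guidance strength through the coupling product `g = α·β`. `with_coupling`
varies `β` (sensing) at fixed `α`: the front position responds monotonically
in that direction, whereas increasing `α` alone past its optimum depletes
the ligand globally and shortens the front — uptake and sensing are not
interchangeable in this model even though only their product is quoted.

### Default calibration

| parameter | value | why |
|---|---|---|
| `L`, bins | 600 µm, 60 | embryo margin-to-pole distance; 10-µm bins |
| `D_T` | 3×10³ µm²/min | measured diffusivity of a small secreted peptide |
| `τ_T` | 120 min | measured single-exponential ligand lifetime (~2 h) |
| `D_c` | 35 µm²/min | set so the unguided (ligand-null) front at 300 min is about half the wild-type front, the anchor reported for mutants |
| `α` | 3 conc·µm/(cell·min) | with β, puts the wild-type front near 500 µm at 300 min |
| `β` | 32 µm²/(min·conc) | same calibration; `g = αβ = 96` |
| `K` | 0.01·T₀·τ_T = 1.2 | per-cell capacity effectively constant down to strongly depleted ligand |
| influx | 2 cells/min | 600 internalized cells over a 300-min run |
| duration | 300 min | gastrulation window analysed in the source experiments |

`√(D_T τ_T) = 600 µm` — ligand produced anywhere reaches the whole domain
before decaying, which is why the *sink* location (the cells), not the
source location, sets the gradient direction. The defaults give a wild-type
front (0.95 density quantile) of 523 µm, a ligand-null front of 213 µm
(ratio 0.41), and rescue fronts of 434 µm (margin-graded production) and
558 µm (animal-graded), all at 300 min.

Two consequences of `√(D_T τ_T) = L` are worth stating because they bound
what the model can show. First, a production *gradient* with no sink still
drifts cells: the steady ligand slope of a ramp source is a fixed fraction
(~40%) of the steepest self-generated slope, so switching the sink off
abolishes guidance exactly only for uniform production; a margin-directed
ramp then pushes cells weakly backwards and an animal-directed ramp still
guides them (consistent with an ectopic animal-pole source rescuing
migration). Second, the margin-graded rescue with the sink active saturates
near 0.83× the uniform-production front, because the ligand available ahead
of the front is smaller when production is concentrated behind it.

### Discretization

Finite volumes on a uniform grid; forward Euler in time; central
differences for diffusion; first-order upwinding for the advective flux;
reflecting (zero-flux) boundaries. The step obeys
`dt ≤ 0.5·min(dx²/(2 max(D_c, D_T)), dx/max|v|)`, checked every step
(violation raises a `StabilityError` naming the bound), plus an analogous
bound for the sink/decay loss rate. With no influx the scheme conserves
cell mass to round-off; both fields remain non-negative (negative values
beyond round-off raise a `ConsistencyError`; values within round-off are
clipped). Halving `dx` (with `dt` following the stability bound) moves the
300-min front by <2% on the default configuration.

## Receptor-turnover extension

A single per-cell receptor pool `r(x, t)` is replenished toward its
capacity and consumed by ligand binding:

    dr/dt = ρ_R (r_cap − r) − k_bind r T,   r_cap = r_max · f_oe

Both the uptake rate `α` and the sensitivity `β` scale with `r/r_max`,
implementing the dual scavenger/sensor role with one pool (the minimal
model exhibiting the threshold-and-rescue phenomenology; the source work
states only that receptor turnover is accounted for). Defaults
`ρ_R = 0.1/min`, `k_bind = ρ_R/150` place the guidance threshold between
ligand production multipliers 2 and 10: at baseline ligand the cells
deplete their surroundings and keep their receptors (`k_bind·T_local ≪
ρ_R`); past the threshold they cannot clear the ligand, receptors stay
occupied, and both roles collapse together — a self-reinforcing switch.
Tripling the receptor capacity (`f_oe = 3`) restores ≥80% of baseline
guidance at a five-fold ligand excess.

### Directionality index

Tissue-level directionality of a cohort released as a margin bolus is
measured on a seeded agent cohort sampled from the trajectory's drift
field: the index is the mean over agents of signed animal-ward displacement
divided by path length, in [−1, 1]. For deterministic drift (`D_c = 0`)
this reduces to centroid displacement over centroid path (1.0 for monotone
drift, 0.0 for a cohort that returns to its start); a centroid-only
definition was rejected because a deterministic density centroid moves
monotonically even under pure diffusion against a reflecting wall and would
score unguided cohorts at 1. Pure diffusion scores ≈0.14 with the default
5-min observation step (the reflecting margin gives a small positive bias,
and the value depends on the sampling step as for any straightness of a
random walk), so guidance effects are quoted as the *excess* over the
unguided (`β = 0`) baseline.

## Quantification

* **Track metrics** — speed = path length / duration; straightness = net
  displacement / path length; net displacement toward a target is the
  signed AV-axis displacement truncated at first source contact or 120 min.
* **Epiboly correction** — the margin reference displacement (linearly
  interpolated in time) is subtracted from each track's AV coordinate, so a
  margin-comoving cell becomes stationary.
* **Rose histograms** — twelve 30° bins *centered* on the cardinal
  directions (90° = animal pole), folded 12 → 7 classes by mirroring about
  the animal–vegetal axis (θ → 180° − θ); the on-axis bins (±90°) are their
  own class. Centering the bins on the axis is what makes the fold close
  (edge-aligned bins pair the two animal-most bins with each other and
  cannot produce 7 classes).
* **Velocity kymographs** — per-sample velocity is the change in
  distance-to-margin over a centered 10-min window (the 14-frame window of
  the reference tracking protocol); samples within half a window of a track
  end are dropped by default, because a shrunk window divides the same
  positional noise by a smaller span and produces unbounded-variance
  samples. Samples pool into (distance, time) bins; empty bins are missing.
* **Field kymographs** — the continuum analogue uses the *flux velocity*
  `u = β ∂T/∂x − D_c (∂c/∂x)/c`, the mean velocity a tracked cell
  population reports; a purely diffusing population spreading from the
  margin therefore shows positive early velocities that decay, matching
  unguided embryos. The advective-only variant is available by flag.
* **Intensity profiles** — minimum subtracted as background, maximum
  normalized to 1.
* **Membrane/cytoplasm ratio** — the cell mask is eroded by thresholding
  its Euclidean distance transform at the band width (1.25 µm by default;
  pixel-size independent); the removed rim is the membrane mask and the
  ratio of mean intensities is the internalization read-out.
* **Motility from MSD** — pooled squared displacements for lags ≤ 10 min,
  `MSD = 2 d D τ` fitted through the origin; a curvature diagnostic flags
  ballistic (quadratic) MSD growth.

## Fitting

* **Decay time** — weighted log-domain line fit (convex) refined by
  nonlinear least squares of `A·exp(−t/τ)`; a runs test on the
  log-residuals flags non-single-exponential decay. Noiseless bias <2% for
  τ from 10 to 10⁴ min; with the 7-point/30-min protocol at 10%
  multiplicative noise the median estimate is within 10% of truth.
* **Guidance strength** — scalar minimization over `log₁₀(αβ)` of a
  count-weighted least-squares mismatch between observed and simulated
  kymographs on shared non-missing bins. Physical velocities are compared
  directly; for normalized observations the unknown scale is profiled out
  analytically, making the fit exactly invariant to uniform rescaling. A
  coarse log-grid scan brackets the minimum before bounded refinement,
  guarding against a shallow secondary basin the profiled objective
  develops at extreme couplings; the default bracket is ±1.25 decades,
  over which the objective is unimodal (checked on 25 log-spaced points).
  Track-derived kymographs additionally use a per-bin minimum sample count
  (10) since consecutive window samples of one track are correlated.

## Synthetic data

Agents follow `x ← x + β (∂T/∂x) dt + √(2 D_c dt) ξ` (Euler–Maruyama,
0.5-min step, reflecting walls) with the gradient interpolated linearly in
space and time from a saved PDE run; receptor-extended trajectories
attenuate the drift by `r/r_max`. Agents do not interact, and the advection
term of the PDE is linear in `c`, so the agent density obeys the same
Fokker–Planck equation as the continuum — coarse-binned agent histograms
match the PDE profile within sampling error (≤3 SE per 50-µm bin at
n = 1000), which is the module's central consistency property. Ligand-null
tracks force `β = 0`; margin tracks recede vegetally at constant speed;
decay series apply mean-one log-normal noise of specified CV to an exact
exponential; cell images are disks whose membrane band is defined by the
same distance-transform rule the measurement uses (so the noiseless ratio
is exact); source-attraction tracks drift straight toward a point source
only within a finite range (100 µm default). All generators are
deterministic given their seed. Observation noise defaults to zero (the
tracking noise of the reference data is unreported).

### What the generators do not emulate

Real embryos are curved surfaces with epiboly flows, cell division,
crowding, and tracking errors; the generators produce 1D (or flat 2D)
non-interacting tracks with exact time stamps. Passing tests therefore
demonstrate the internal consistency of model, measurement, and inference —
not that the biological parameter values are correct, beyond the anchors
(`τ_T`, `D_T`, front ratios) taken from the source measurements.

## Problem sizes

The packaged study conditions are: 60-bin grid over 600 µm, 300-min runs,
600 influxed cells (150-cell boluses for cohort experiments); 200 noisy
decay series of 7 points; 200 tracks for kymograph-based fitting (40-bin
grid for fitting round trips); 100 Brownian tracks × 60 samples × 10 seeds
for motility recovery; 1000 agents for density-consistency checks.

## Known limitations

* 1D geometry: no dorsoventral convergence, tissue mechanics, contact
  inhibition, or second-ligand (Apelin) competition.
* Explicit first-order time stepping: robust but slow near stability
  limits; the 40-bin fitting grid trades ~2% front accuracy for speed.
* The receptor pool is a single effective species; no explicit
  ligand–receptor complex trafficking or GPCR signalling cascade.
* `D_T` is a configured constant; estimating it from molecular weight is
  out of scope.
* The directionality index depends on the agent observation step (as any
  path-based straightness does); comparisons are made at a fixed 5-min
  step against the matched unguided baseline.
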