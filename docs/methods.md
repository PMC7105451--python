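# Methods

This note documents the model as implemented: its assumptions, the numerical
choices, which constants are published inputs and which are free constants
fixed by calibration, and what the test suite does and does not establish.

## Model structure and assumptions

The simulation is two-dimensional and cell-based: every cell is a circle
with a fixed radius (no deformation), in one of three phenotypes —
epithelial, cancer, T-lymphocyte — and either alive or removed. The tumour
islet occupies the disk ‖r‖ < R1 = 120 μm; the desmoplastic stroma is the
annulus 120 < ‖r‖ < 200 μm with uniform density and circumferential fibre
orientation; the computational domain is the disk of radius 300 μm with a
reflecting boundary.

Sub-step order per tick (Δt = 0.01 h): concentration fields → stromal state
(λ₂, k) → epithelial/cancer positions → T-lymphocyte positions → fate events
→ therapy trigger check. All cells within a sub-step see the same
beginning-of-step state (synchronous update), and random draws follow a
fixed per-cell order, so a run is a pure function of its config and seed.

### Mechanics

Epithelial and cancer cells communicate through substrate strain energy:
cell j's signal at distance d is M⁰·exp(−λd/R) with λ = E_s/E_c = 10 for the
published moduli. A sensing threshold (config `signal_threshold`, default
1e-9 kg/(μm·h²)) reflects the finite sensitivity of mechanosensing; with
λ = 10 a neighbour's signal at mere contact distance is already ~1e-11, so
under the default parameters directed mechanotaxis is effectively inactive
and islet cells move by random walk plus Hertz contact relaxation. The
threshold also bounds the interaction range, which the compiled kernel
exploits with a linked-cell neighbour grid. The public functions in
`tislet.mechanics` implement the unthresholded definitions exactly (the
brute-force oracles in the tests rely on this).

Contact repulsion enters the drift as a separate vector α·Σ M^ij ê_ij
pointing away from each impinging neighbour, alongside the signal term
α·M·ẑ. Folding the Hertz magnitude into the scalar prefactor of ẑ instead
(a literal "deduction") reverses sign at deep overlap and drives cells into
each other, so the vector form is used. For unequal radii the impingement
depth is h = max(R_i+R_j−d, 0) and the mean radius replaces R; contacts
involving a T-lymphocyte use its much larger modulus E_t = 250, so islet
cells yield to T-cells rather than vice versa.

### Stromal confinement and carrying capacity

Epithelial and cancer cells reflect at R1: the dense stroma is treated as
mechanically impenetrable to them, while T-lymphocytes may cross it (their
motion inside is governed by the orientation tensor). This choice is forced
by the model's own stated carrying capacity: ≈250 cells is the R1 disk
packed with R = 8 cells, which is only a ceiling if islet cells cannot
leave. The capacity itself is emergent, set by two rules: a daughter cell is
placed tangent to its parent at a seeded random angle (up to 8 resamples)
and rejected if it would overlap any cell by more than `placement_slack`·R
(default 1.25R), and division is blocked when the contact-corrected signal
M̂ = M − ΣM^ij falls below `division_signal_min` (default −0.02) — a
crowding gate. With the defaults the untreated islet reaches ≈240 cancer
cells by 150 h.

### T-lymphocytes

T-cells neither emit nor sense mechanical signals; they chemotax up the
cancer-secreted chemokine gradient (closed-form steady-state point sources,
distances clamped below at one cell radius) with drift β∇c, plus the same
η random walk. Inside the annulus the drift+noise vector is premultiplied by
μ_j·Ψ. Note the chemotactic constant β multiplies ∇c in both regimes; the
annulus update adds the mobility factor μ_j exactly as the two update rules
print. Killing is an exponential waiting-time process at rate `kill_rate`
while a T-cell impinges on a cancer cell (at most one engulfment per T-cell
per step); instantaneous kill-on-contact is available
(`kill_rate = inf`-like behaviour via large rates) but annihilates the islet
within hours of infiltration, which is inconsistent with the
PEGPH20-only endpoint, so the rate-based form is the default. T-cells are
not consumed or exhausted by killing.

### Fate processes

An event with rate λ fires in a step with probability 1−exp(−λΔt). The
initiating mutation uses the published rate 100/h (per-step probability
0.63), converting one uniformly chosen epithelial cell; that rate cannot
plausibly govern every per-cell event (it would convert the whole islet in
two steps), so ongoing epithelial→cancer mutation proceeds at a separate
calibrated rate, and division/death rates are likewise calibrated (below).
The first mutation triggers the immune response: N_T = 30 T-lymphocytes
seeded uniformly outside the annulus. Gemcitabine multiplies division and
mutation rates by exp(−A·c_drug), c_drug evaluated at each cell's own
position. Dead and killed cells are removed immediately and exert no
further forces.

### Fields and injections

Only the chemokine *gradient* is ever used (the 2-D steady concentration is
log-divergent and never needed). Enzyme and drug concentrations from a
finite-duration point injection are evaluated in closed form,
c(ρ,t) = γ₀/(4πD)·[E1(ρ²/4D(t−t₀)) − E1(ρ²/4D(t−t₁))], with the second term
dropped while the source is on; the Gaussian exponent is the standard
negative heat-kernel exponent (the printed positive sign diverges). E1 is
computed by a compiled series/continued-fraction routine verified against
`scipy.special.exp1` to ~1e-10 and against adaptive quadrature of the
defining integral to 1e-6.

The enzyme diffusivity deserves a note: the published input table lists
10 μm²/h, but the published decay of λ₂ in *all ten* subdomains within about
an hour of injection requires a diffusion length of hundreds of μm in ~1 h,
i.e. D_en ≳ 3×10⁴ μm²/h — and 10 μm²/h (0.003 μm²/s) is three to four orders
slower than any protein diffuses. The default is therefore
D_en = 3.6×10⁴ μm²/h (10 μm²/s, the table value read in per-second units),
which reproduces the published behaviour; it is an ordinary config key.

The injection sits just outside the annulus (R2+20 μm) at angle 162°,
equidistant from stromal sensing points 5 and 6 — these two sense the
highest concentration and degrade fastest. The drug injection uses the same
angle at the annulus mid-radius. λ₂ and k live per subdomain, sensed at the
ten midpoints, updated by clamped forward Euler (the update never crosses
its fixed point even if L·c·Δt > 1).

## Numerical choices

* Δt = 0.01 h (published). The deterministic displacement per step is capped
  at `max_det_step` = 2 μm = R/4, so the realised step always satisfies the
  stability bound Δt ≤ R/(2·max‖v‖); Hertz repulsion through α = 5120 is
  stiff at deep overlap and would otherwise overshoot. A step larger than
  R/2 aborts the run with a diagnostic.
* Coincident cells (distance < 1e-6 μm) are separated by a deterministic
  1e-3 μm pseudo-random jitter before directions are formed.
* The resultant direction ẑ is zeroed below norm 1e-14.
* Reflecting boundaries are radial: a cell at r > r_max maps to 2r_max − r.
* The kernel is compiled with numba; identical seeds give bit-identical
  trajectories on a given build.

## Published inputs vs calibrated constants

Published inputs (used as printed): R = 8, R_t = 5, F = 30, E_s = 5,
E_c = 0.5, E_t = 250, β (velocity parameter) = 60, μ = 0.2, D_c = 5e3,
D_drug = 1e4, γ = γ₀ = 5e6, Δt = 0.01, R1 = 120, R2 = 200, N = 10
subdomains, λ₂(0) = 10, k(0) = 0.3, trigger 35%/50%, enzyme duration 1 h,
drug lag 10 h, sampling distributions of F, D_c, β, k, trigger fraction and
τ. D_en is the published value in per-second units (see above).

Calibrated free constants (the sources give no numbers; fixed once against
the published scenario outcomes — trigger crossing near 45–60 h, untreated
capacity ≈250, untreated CDF(f_c ≤ 0.5) ≈ 51% at 80 h, and final fractions
≈42% / ≈11% / ≈31% for the three treated scenarios — and not tuned per
study):

| constant | config key | default |
|---|---|---|
| random-walk scale η | `eta` | 2 μm/√h |
| chemotactic constant β (drift) | `chemotactic_coeff` | 0.4 |
| chemotactic mobility μ_j | `chemotactic_mobility` | 0.5 |
| stromal decay rate L | `ecm_decay_rate` | 0.7 |
| radial weight λ₁, speed scale v⁰ | `lambda1`, `v0` | 1.0 |
| division rate λ₀ | `division_rate` | 0.018 /h |
| ongoing mutation rate | `mutation_rate` | 0.00465 /h |
| cancer death rate | `death_rate` | 0.001 /h |
| kill rate | `kill_rate` | 0.85 /h |
| drug sensitivity A | `drug_sensitivity` | 1.5 |
| signal threshold | `signal_threshold` | 1e-9 |
| crowding gate | `division_signal_min` | −0.02 |
| placement tolerance | `placement_slack` | 1.25 R |
| initial epithelium / T-cells | `n_epithelial`, `n_tcells` | 110 / 30 |

With these defaults the untreated islet crosses the 35% trigger at
t0 ≈ 50–60 h (single published runs show 45–49 h; the crossing time is
seed-dependent either way).

## Problem sizes

The default study sizes are chosen for desk-scale reproduction: ensembles of
200 samples for the Monte Carlo studies (the original analyses used 5000)
and 12–20 seeds for scenario means. At n = 200 the binomial uncertainty of
the CDF estimate is ±7 percentage points (95%), and correlation estimates of
magnitude ~0.85 carry sampling error well under the comparison bands; the
acceptance script reports the n it used for every quantity.

## What the generator emulates, and what it does not

The scenario configs *are* the synthetic data: no external inputs exist.
They emulate the study conditions — an initially healthy packed epithelium,
one initiating mutation, a fixed-size immune contingent, intact anisotropic
stroma, point injections on a fixed timeline. They do not emulate real
tissue: vasculature, interstitial pressure, immune influx/exhaustion, 3-D
geometry, cell deformation, stromal heterogeneity and drug pharmacokinetics
beyond a single diffusing bolus are all absent. Passing tests therefore
establish internal correctness of the equations and reproduction of the
model's published behaviour, not clinical validity.

## Known limitations

* Endpoints of the treated scenarios sit near a kill/growth balance and are
  the most seed-sensitive quantities; they are compared as ensemble means
  with ±10-percentage-point bands.
* The islet carrying capacity is emergent from packing rules, not imposed;
  it is reproducibly ≈230–250 but depends on the placement tolerance and
  crowding gate.
* The compiled kernel and the Python reference steps are separate code
  paths; they are cross-checked at η = 0 by tests, and fate logic is
  mirrored (not shared) between `cell_fate.step_fates` and the kernel.
* Monte Carlo ensembles run sequentially by default; `workers > 1` uses
  joblib and preserves determinism because every sample's seed derives from
  (master seed, sample index).
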