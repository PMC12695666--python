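# Methods

## 1D loop-extrusion model

The genomic region (default 2.6 Mb) is a lattice of 1-kb sites.  Each
cohesin complex occupies two sites (its legs); legs step outward one site at
a time so that a free loop grows at the total motor speed *v* (each leg at
*v*/2, symmetric two-sided extrusion).  Cohesin unbinds with exponential
lifetime *τ* (minutes) and loads at rate *N*·/τ with *N*· = density ×
region length, at uniformly drawn unoccupied adjacent site pairs (up to 10
placement attempts per event, else the event is deferred); this birth-death
balance makes the stationary extruder count equal density × length, which
the test suite verifies to within Monte-Carlo error.

CTCF sites are point obstacles with orientation.  A site built from a peak
list receives residence time τᵢ = τ_CTCF · strengthᵢ / mean(strength), so
the landscape mean equals the genome-wide value (default 2.5 min).  Sites
bind and unbind dynamically; the on-rate is chosen so stationary occupancy
equals the configured target (default 0.5).  A leg attempting to move onto
a bound site whose motif faces it ('+' blocks leftward-moving legs, '−'
rightward; convergent sites face the TAD interior) draws a stall once per
encounter with that bound molecule: on stall the leg is pinned **adjacent
to** the site until that molecule unbinds (re-binding after release triggers
a fresh draw); on pass it traverses.  Legs never bypass other legs or the
region boundary — a blocked leg waits without consuming a stall draw.

Time advances in fixed Bernoulli steps with every per-step probability kept
≤ 0.2 (the step is also snapped to divide the sampling interval exactly), a
discretization that matches the underlying exponential rates to within a few
percent; extruder lifetimes pass a Kolmogorov–Smirnov test against the
exponential law at α = 0.01 on 10⁴ lifetimes.  Simulations discard a
burn-in of 3τ before sampling.

A consequence of the stall-adjacent convention is that a loop stalled at
both anchors leaves a 2-lattice-unit unextruded path, so *closed* states
(path ≤ 1 lattice unit, below) are rare at every parameter combination we
simulate — consistent with closed states being an upper-bounded, minor
fraction.

## Loop topology

The shortest unextruded 1D path between two loci treats each extruded loop
as a zero-weight shortcut between its legs and each genomic gap between
neighboring leg positions as a weighted edge; Dijkstra runs over the whole
region because loops outside the interval can shorten the path.  States:
*closed* if the path is at most one lattice unit, *open* if it equals the
genomic separation with no leg strictly inside, *extruding* otherwise.  The
implementation is checked against exhaustive path enumeration on 1,000
random configurations.  Processivity is the mean extruded length over
completed lifetimes, excluding boundary-touching extruders whose extrusion
is truncated.

## Polymer model and time mapping

The chain is a free-draining Rouse polymer: one bead per `monomer_bp`
(default 1 kb), harmonic bonds of natural scale *b* (default 40 nm), no
excluded volume by default (connectivity and extruder bonds dominate the
anchor-scale observables; a soft-repulsion option exists for short chains).
Each extruder adds a harmonic bond between the beads holding its legs,
refreshed at every 1D sample.  Dynamics are overdamped Langevin
(Euler–Maruyama); the time mapping is set by the monomer diffusion
coefficient *D* (default 2×10⁴ nm²/s), chosen so that the relaxation time
of a TAD-sized segment (~350 kb) is ≈ 5 min, the scale on which live-cell
two-point MSDs plateau.  The default step is 0.08/κ with κ = 3D/b²; the
scheme inflates the stationary variance of the fastest modes by ~κ·Δt/2,
which is negligible at anchor separations (tests verify ideal-chain
statistics at a finer step).

Because the equilibrium ensemble of any fixed bond topology is an exact
Gaussian network, initial conformations are drawn directly from the
Boltzmann distribution of the first frame's bonds (Cholesky factor of the
reduced graph Laplacian) instead of burning in; the cohesin-free chain's
stationary ensemble is likewise exactly samplable, and is used as the
zero-density control in the distance-reduction computation.

Coarse-graining rule: for λ-fold coarser beads, *b*′ = *b*√λ and
*D*′ = *D*/λ, which preserves the relaxation time of any genomic scale.
Production-size runs (2.6-Mb chains) use 2-kb beads under this rule.

Contact maps count bead pairs within a contact radius (default 100 nm) per
frame via a k-d tree; *p(s)* is the diagonal average.  On ideal-chain
ensembles the *p(s)* log-log slope reproduces the closed-form −3/2.

## Measurement emulator

Each reporter position is perturbed by isotropic Gaussian noise with
per-axis σ(t) = σ₀(1 + β·t/3600): σ₀ = 50 nm and β = 0.3 h⁻¹ by default,
a minimal one-parameter linearization of photobleaching chosen so
series-mean distance uncertainties fall in the experimentally reported
70–105 nm band over a 2-h acquisition.  The distance is the norm of the
noisy difference vector, so the upward bias at small true separations is
emergent; σ_d = √(σ₁² + σ₂²) is propagated per frame.  Frames drop
i.i.d. at a configurable missing rate (default 0.15, the scale of routine
quality filtering; stringent filtering corresponds to higher rates).
Reporters sit 10 kb outside each anchor by default (configurable per
region).  Defaults follow the study conditions: 30-s frames for 2 h (240
frames; a 9-s/36-min fast mode is a parameter change) and ensembles of
tens to hundreds of series per condition.

Two observable models generate the reporter-reporter vector:

- **polymer** — the coupled simulation's bead coordinates;
- **gaussian-ou** (default for grid-scale inference) — a quasi-static
  shortcut: the vector follows an Ornstein–Uhlenbeck process whose per-axis
  stationary variance is ℓ(t)/monomer_bp · b²/3 for the current shortest
  unextruded path ℓ(t), with relaxation time equal to the slowest Rouse
  mode of the effective segment.  This preserves the distance scale, its
  coupling to extrusion, and minute-scale temporal correlation at a small
  fraction of the cost; it omits the polymer's full mode spectrum and any
  lag of chain conformation behind topology changes, so inference runs
  compare simulation to reference under the same observable model.

What the generator does **not** emulate: spot-detection failures correlated
with distance, chromatin-state heterogeneity between cells, cell-cycle
drift, compartment-scale interactions, and other SMC complexes.  Passing
tests therefore demonstrate correctness of the estimators under the stated
model, not robustness to every real-data pathology.

## Proximal-state segmentation

A proximal state is a maximal run of frames with distance below the spatial
threshold, bridging up to one non-qualifying (above-threshold or invalid)
frame, kept if its duration reaches the temporal threshold (default 4 min).
Intervals touching the series boundary are censored; frequency counts only
non-left-censored onsets per observed hour; lifetimes average fully
uncensored intervals.  The default spatial threshold is calibrated as the
90th percentile of distances during ground-truth closed frames of matched
simulations (when closed frames are too rare, the pipeline falls back to
the 10th percentile of the depleted-condition distances).  The temporal
threshold is swept so that depleted-condition fractions span 1–10%, the
robustness-check convention.  Bootstrap CIs resample whole series (default
10,000 draws, 2.5–97.5 percentiles).

## Three-state mixture and open-fraction bound

Distances (radial, by isotropy) are modeled as a convex mixture of a
proximal density (reflected-boundary KDE of segmented proximal frames; KDE
datasets are subsampled to 4,000 points for O(n·m) evaluation cost), an
open density (KDE of cohesin-depleted frames), and an extruding family of
Maxwell laws whose per-axis variance interpolates linearly in effective
separation s_eff between the measurement-noise floor and the open-state
scale (moment-matched, σ_open² = E[d²]/3).  The s_eff grid is log-spaced on
[s_total/8, s_total] (default 20 points): states with less than s_total/8
unextruded are observationally proximal-like, and admitting them would make
the family collinear with the proximal component.  The s_eff = s_total
member is the empirical open density itself.

Weights are fit by EM (closed-form responsibility averages; tolerance 1e-8
relative log-likelihood, ≤ 10⁴ iterations).  Because members near
s_total nearly duplicate the open density, the MLE split between them is
ill-determined; ties are resolved **toward the open state**: after
convergence, an extruding member's weight moves to f_open whenever the
likelihood cost is below 0.02 nats per reassigned observation (the scale of
KDE-vs-parametric mismatch, far below the divergence between genuinely
distinct scales).  Generate-and-recover tests hold to ±0.05 (two-way) and
±0.07 (three-way at n = 10⁴).

The model-free bound uses observed_mass ≥ f_open × open_mass per distance
bin: the bound is the minimum mass ratio over upper-tail bins (edges at
open-sample quantiles above the median, 6 bins) whose open mass has
binomial relative error < 20%, clipped to [0, 1].  As a minimum of noisy
ratios it is slightly downward-biased at finite n.

## Closing rate

Series are aligned on eligible proximal onsets — not left-censored and not
preceded by another proximal interval ending within a 10-min exclusion
window (the unspecified-in-source window is exposed in config).  Only
frames strictly before the onset are pooled: the onset frame is
sub-threshold by construction, and including it would plant an artificial
terminal drop in every aligned curve, shuffled controls included.  Squared
distances pool with inverse-variance weights (1/σ_d²); the fit uses the
total pooled weight per lag and ignores lags backed by fewer than three
series.

The model is a constant plateau R²_plateau followed by a linear decrease to
R²_int at t = 0 with breakpoint t_extr, fit by weighted least squares with
exhaustive breakpoint search on the lag grid (no local minima).  The
piecewise model is selected only if its decrease is supported by ≥ 3 lag
points, its slope is negative, and it reduces the constant model's weighted
SSE by ≥ 10%; otherwise the result is "constant" and no CR is reported.
CR = |slope| × s_reporters / (R²_plateau − R²_int) = s_reporters/|t_extr|,
using the ideal-chain proportionality of squared distance to unextruded
contour length anchored at (plateau ↔ full separation) and (intercept ↔ 0).
Bootstrap draws resample series; a draw is kept if ≥ 15 distinct series
contribute and the piecewise model is selected; the median and 10–90
percentiles over kept draws are reported, and zero kept draws is an
"undetectable" result rather than an error.  On noiseless constructed
curves the fit is exact; on synthetic pure-extrusion ensembles the CR is
recovered within ±20%.

## Deviation score and grid inference

A metric bundle holds the distance deciles (9 quantiles — decile
comparison avoids binning sensitivity), the two-point MSD at fixed frame
lags, the proximal fraction/frequency/lifetime, and optionally p(s).
Deviation between two bundles: mean squared log-ratio over shared support
for curves, squared relative error for scalars (averaged over the deciles
for the distance term; a zero reference with non-zero simulation caps at 1
so surfaces stay finite), equally weighted by default with all sub-scores
reported.  Bundles are only comparable at identical cadence, segmentation
settings and lag grids.

The grid search simulates each (density, residence) cell at fixed motor
speed with identical analysis settings (gaussian-ou observable by default)
and scores it against the reference bundle; the q-best sets are the
⌈q·n_assessed⌉ lowest cells with lexicographic tie-breaking (lower density,
then lower residence), so the 10% set nests in the 25% set.
`recovery_check` generates a synthetic reference at known truth and passes
when the truth density's column intersects the 10% set.  Desk-scale
validation uses a 6×4 grid (densities 2–36 Mb⁻¹, residences 10–33 min),
20 series of 1 h per cell on a 1.2-Mb region — sizes chosen so the
procedure's discrimination, not the compute, is what is being tested.

## Problem sizes in the shipped analyses

The acceptance script simulates 10 h of 1D dynamics (after a 3τ burn-in)
for the closed-fraction computations, and 64 coupled replicates × 20 min
(2-kb beads, first 5 min discarded as conformational transient) against a
3,000-draw exact equilibrium control for the distance-reduction
computation; the test suite uses smaller analogues of the same procedures.

## Known limitations

- The Euler–Maruyama step trades short-scale variance accuracy (~5–10% at
  the default step) for speed; anchor-scale statistics are unaffected.
- The quasi-static observable model underestimates conformational lag; the
  coupled polymer model is the reference when lag matters.
- The mixture decomposition's proximal/extruding boundary is intrinsically
  soft; fractions near that boundary carry model uncertainty beyond the
  bootstrap CIs.
- CR detectability degrades above ~0.5 kb/s at 30-s cadence (the sampling
  theorem of the aligned-curve method), so only upper bounds on motor speed
  are attainable from such data.
- Closed-state fractions depend on the stall-adjacent pinning convention;
  calling them against a 2-lattice-unit tolerance would roughly merge them
  with the proximal-state definition.
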