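# loopx

Simulation and analysis of cohesin-mediated DNA loop extrusion from
live-cell imaging of TAD anchors.

Topologically associating domains (TADs) arise from cohesin complexes that
reel chromatin into growing loops until they are halted by convergently
oriented CTCF sites at the TAD boundaries ("anchors").  Live-cell imaging of
two fluorescently labeled anchors yields noisy time series of their 3D
distance *d(t)*; this package provides everything needed to simulate that
observable from first principles and to estimate the underlying extrusion
dynamics from it:

- a stochastic **1D lattice model** of cohesin loading, two-sided extrusion
  at motor speed *v*, exponential unbinding with residence time *τ*, and
  orientation-dependent stalling (probability 0.5) at dynamically bound CTCF
  sites whose local residence times scale with ChIP-seq peak strength around
  a genome-wide mean of 2.5 min;
- a **Rouse bead-spring polymer** coupled to the 1D trajectory through
  harmonic extruder bonds, producing conformations, contact maps, *p(s)*
  curves and two-point MSDs;
- a **measurement emulator** (30-s frames over 2 h by default, per-spot
  localization errors growing with photobleaching, reporter-anchor offsets,
  missing frames) so simulated data carry the statistical structure of the
  experiment;
- estimators for the observable quantities: **proximal-state** segmentation
  (spatial + temporal threshold) with fraction/frequency/lifetime and
  bootstrap CIs; a **three-state mixture** decomposing the distance
  distribution into proximal, open and extruding fractions plus a model-free
  upper bound on the open fraction; and the **closing rate** (CR, kb/s) from
  piecewise-linear fits to onset-aligned mean squared distances with shuffle
  controls and bootstrap gating;
- **grid-based inference** of cohesin density and residence time at fixed
  motor speed by minimizing a deviation score between simulated and
  reference metric bundles, with 10%/25% best-parameter sets and
  parameter-recovery validation.

The loop topology module computes the shortest *unextruded* 1D path between
two loci (loops act as zero-length shortcuts, Dijkstra over the whole
region), which defines the open/extruding/closed states and the closing
rate's genomic calibration.

## Worked example

Run the full pipeline on a 600-kb synthetic region with convergent CTCF
anchors 200 kb apart, at cohesin density 12 Mb⁻¹, residence time 22 min and
motor speed 0.25 kb/s, with and without cohesin (the "auxin" condition
emulates RAD21 depletion by setting density to zero):

```python
from loopx.pipeline import run_pipeline

config = {
    "region": {
        "label": "L1-like", "region_length": 600_000,
        "anchor_a": 200_000, "anchor_b": 400_000,
        "peaks": [(200_000, "+", 3.0), (400_000, "-", 3.0),
                  (80_000, "-", 1.0), (520_000, "+", 1.0)],
    },
    "extrusion": {"density": 12.0, "residence_time": 22.0, "motor_speed": 0.25},
    "model": {"duration": 7200.0, "missing_rate": 0.15},
    "n_series": 60, "seed": 1,
    "bootstrap": {"proximal": 1000, "cr": 200},
}
print(run_pipeline(config).round(3).to_string(index=False))
```

```
 region condition  proximal_fraction  proximal_frequency_per_h  proximal_lifetime_min  n_series  f_proximal  f_open  f_extruding  open_bound  cr_median_kb_s cr_detectable  cr_kept_draws
L1-like untreated              0.126                     0.819                  6.085        60       0.003     0.1        0.898       0.109           0.171          True            5.0
L1-like     auxin              0.005                     0.059                  4.400        60       0.000     1.0        0.000       1.000             NaN           NaN            NaN
```

Reading the table: with cohesin the anchors are proximal 12.6% of the time,
coming together ~0.8 times per hour for ~6 min, and the mixture attributes
~90% of frames to actively extruding states with an open-state upper bound
of 11% — whereas without cohesin the region is essentially always open
(f_open = 1, bound = 1) and proximity events almost vanish.  The closing
rate estimate (0.17 kb/s) comes from the few bootstrap draws that pass the
≥15-series/non-constant gates at this small ensemble size; at full scale
(hundreds of series) most draws qualify.

A `loopx` command-line tool exposes the same stages
(`simulate1d | synth | segment | statefrac | closingrate | report`); see
`loopx --help`.

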