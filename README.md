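# urbancanopy

Estimating urban above-ground biomass (AGB) from multi-scale LiDAR.

Urban forests store substantial carbon, but conventional biomass allometry —
built from destructively harvested forest trees and keyed on stem diameter —
transfers poorly to open-grown, pollarded, street-canyon trees, and stem
diameter cannot be seen from the air at all. `urbancanopy` implements a
pipeline for city-scale AGB mapping from two LiDAR scales:

* **terrestrial laser scanning (TLS)** provides per-tree woody volume via
  quantitative structure models (QSMs), from which new allometry is
  calibrated on metrics an airborne sensor can also measure; and
* **airborne laser scanning (ALS)** at the low pulse densities of open
  government archives (~2 pulses m⁻²) provides wall-to-wall coverage, from
  which individual trees are detected and attributed.

It is written for researchers in ecological remote sensing and urban
forestry who want individual-tree AGB maps, with honest uncertainties, from
freely available LiDAR.

## The method

**Individual tree detection (ITD).** Points whose emitting pulse produced a
single return (buildings, roads) and points with height z ≤ 1 m are
discarded. DBSCAN (eps = 3.5 m, min_samples = 20) clusters the remaining
returns in 3-D into crowns and merged canopies. Each cluster *c* with
maximum height *H*, projected crown area *Ar* (2-D convex hull) and
equivalent radius *r* = √(Ar/π) is tested against an allometric width
bound: if

&nbsp;&nbsp;&nbsp;&nbsp;β + α·H < r

(the line through the upper 95 % prediction bound of a TLS-calibrated
radius-on-height regression), the cluster is a merged canopy and is divided
by BIRCH hierarchical clustering in the xy-plane with radius threshold
B_t = β′ + α′·H from the mean regression line, re-testing subclusters until
all satisfy the bound. Cleaning removes crowns with area < 10 m²,
implausibly tall crowns, and vertically offset duplicates.

**Allometry.** From QC-filtered QSM trees (reconstruction 95 % CI ≤ 10 % of
volume; slice-wise mean 4-nearest-neighbour distance ≤ 5 cm) the package
fits, through the origin,

&nbsp;&nbsp;&nbsp;&nbsp;V = k_Ar·Ar + k_exp·(a·bᴴ)

where a·bᴴ is an exponential height term. Volume converts to biomass via
wood density (AGB = V·ρ/1000, Mg) and to carbon with the 0.471 woody-tissue
carbon fraction.

**Uncertainty.** A Monte Carlo engine propagates three error sources —
per-tree QSM volume (Gaussian), crown-measurement H/Ar (per-crown sds from
repeated 75 % point subsampling) and wood density (empirical distribution
over a street-tree database) — through 100 simulations, and isolates each
component's variance share by freezing the others.

All stages are testable without external data through a synthetic-scene
generator with known per-tree ground truth (`urbancanopy.synthetic`).

## Worked example

```python
import numpy as np
import urbancanopy as uc
from urbancanopy import synthetic as syn
from urbancanopy.uncertainty import DensityPDF, MCConfig, VolumePDF

# a synthetic 50-tree scene with known ground truth
cloud, truth = syn.well_separated_scene(n_trees=50, seed=7)

# calibrate splitting thresholds from a QSM-style tree table
params = syn.AllometricParams(height_range=(12.0, 18.0), radius_sd=0.25)
split, bt = syn.calibration_thresholds(seed=123, params=params)

# individual tree detection
seg = uc.SegmentationParams(split_model=split, bt_model=bt)
crowns = uc.segment_trees(cloud, seg)
m = syn.match_crowns(truth, crowns, max_dist=2.0)

# volume allometry from a 99-tree synthetic QSM table (10 % volume noise)
trees = syn.generate_tree_population(99, syn.AllometricParams(noise_cv=0.10),
                                     seed=11)
qsm = uc.qsm_trees_from_dataframe(syn.make_qsm_table(trees, seed=12))
res = uc.fit_volume_allometry(qsm)
print(res.summary())

# biomass, carbon, Monte Carlo uncertainty budget
uc.attribute_biomass(crowns, res, density=537.0)
cfg = MCConfig(n_sims=100, seed=42)
rng = np.random.default_rng(1)
pdfs = {"density": DensityPDF(np.abs(rng.normal(537.0, 80.0, 500))),
        "als": uc.crown_metric_pdfs(crowns, cfg),
        "qsm": {c.id: VolumePDF(0.0, 0.03 * c.V) for c in crowns}}
mc = uc.run_monte_carlo(crowns, res, pdfs, cfg)
shares = uc.variance_decomposition(crowns, res, pdfs, cfg)
```

This prints:

```
Volume allometry  V = k_Ar*Ar + k_exp*(a*b^H)   [through origin]
n = 99
k_Ar  =    0.05024  (se 0.00124)  [m^3 per m^2]
k_exp =    1.00000  (se 0.01904)
a     =    0.10160  [m^3]
b     =    1.16010  [per m of height]
R^2 (uncentred) = 0.9935
RMSE = 0.762 m^3   residual sd = 0.770 m^3
```

with `m` reporting precision 0.96 / recall 1.00 for the 52 detected crowns
(the generating coefficients were k_Ar = 0.05, a = 0.08, b = 1.17 — the
area coefficient is recovered to 0.5 %, the exponential term's product
a·bᴴ to similar accuracy with a and b individually trading off), a Monte
Carlo total of 68.1 ± 1.3 Mg AGB over the scene, and variance shares
`{'als': 0.01, 'density': 0.95, 'qsm': 0.04}` — wood density dominating the
budget, as expected when species cannot be identified from the air.

A command-line interface mirrors the library:
`urbancanopy simulate | filter | segment | fit-allometry | estimate-agb | mc`
(see `urbancanopy --help`).

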