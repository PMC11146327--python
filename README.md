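# unbendfish

Postmortem *rigor mortis* arches the bodies of fishes: axial musculature
contracts as soft tissue decays, bending the vertebral column upward or
downward. In fossil fishes this taphonomic curvature is frozen into the
specimen, and in landmark-based (geometric morphometric) studies it
contaminates every downstream analysis — it shortens standard length, spreads
spurious variation across many principal components, and covaries with
biological signals such as allometry. `unbendfish` quantifies that arching
and removes it mathematically, for paleontologists and ichthyologists working
with 2D landmark data.

## What it computes

**Index of curvature (IC).** For an ordered chain of landmarks tracing the
body axis (snout → vertebral column → hypurals; by default landmarks
12, 15, 16, 17, 18, 19, 4 of a 19-point scheme with four vertebral
semilandmarks), with arc length *A* (summed interlandmark distances) and
chord *C* (straight snout–hypural distance):

    IC = 1 − C / A

IC is dimensionless, similarity-invariant, 0 for a straight body, and reads
directly as a relative length reduction (IC = 0.0137 ⇔ 1.37 % shortening).

**Generalized Procrustes analysis (GPA).** Configurations are translated to
a common centroid, scaled to unit centroid size
CS = √Σᵢ‖xᵢ − x̄‖², and rotated (proper rotations only) to the iteratively
re-estimated consensus, leaving pure shape variation.

**Two corrections.**

- *Regression unbending* — multivariate regression of the Procrustes
  coordinates on IC; the residuals (plus the consensus shape) are devoid of
  any linear IC effect by construction.
- *Curve-fit (Tps-style) unbending* — per specimen, a quadratic or cubic
  polynomial is fitted through the axis landmarks in the chord-aligned
  frame, and every landmark is remapped to (s, d): arc length along the
  curve and signed perpendicular offset from it. The axis becomes a straight
  horizontal line; the semilandmarks that only traced the curvature are then
  dropped and the data re-superimposed.

**Evaluation battery.** Shape PCA; Goodall-style permutation regression of
shape on IC; per-PC and scalar OLS regressions (classical F tests); Welch's
t for between-species IC differences; and a permutation contrast of total
Procrustes variance (disparity) between original and corrected data.

**Synthetic bent fish.** A generator bends schematic two-species templates
isometrically along polynomial curves with a size-linked curvature
distribution and digitizing noise, providing exact ground truth for every
stage: `bend` is the mathematical inverse of the curve-fit straightening.

## Worked example

```sh
unbendfish simulate --seed 42 --n-per-species 20,10 \
    --out-tps demo.tps --out-truth demo_truth.csv
unbendfish run demo.tps --seed 7 --perm 999 --out-dir demo_out
```

The run prints (abridged):

```json
{
  "n": 30,
  "original": {
    "mean_ic": 0.01613815416557761,
    "max_ic": 0.05389248472048791,
    "total_procrustes_variance": 0.006604824768113549,
    "ic_vs_size": {"F": 37.313900875860874, "p": 1.367387962988806e-06,
                   "slope": -0.0003626351133378539}
  },
  "regression": {
    "variance_corrected": 0.006471635826516504,
    "corrected_shape_vs_ic_r2": 0.0007102782207937912
  },
  "tps": {
    "variance_corrected": 0.0014277275478108344,
    "disparity_p_perm": 0.001,
    "residual_ic_mean": 1.7948195168511945e-05
  }
}
```

Reading it: the simulated sample arches mildly (mean IC ≈ 0.016, i.e. 1.6 %
length reduction), smaller fish are more curved (negative IC–size slope,
p ≈ 1e−6). Regression unbending removes the linear IC–shape association
(R² drops to 0.0007) but, because specimens arch both dorsally and
ventrally, trims little total variance. Curve-fit unbending straightens each
fish geometrically: residual IC collapses to ~2e−5 and total Procrustes
variance falls by ~78 % (permutation p = 0.001) — the removed share was
taphonomic arching, not biology.

Per-specimen diagnostics, PCA tables, corrected TPS files, and the resolved
run configuration are written to `demo_out/`.

## Library use

```python
import numpy as np
from unbendfish import (AxisSpec, SimConfig, simulate_sample, gpa,
                        curvature_table, tps_unbend_dataset,
                        procrustes_variance)

axis = AxisSpec()                       # chain 12,15,16,17,18,19,4
ds, truth = simulate_sample(SimConfig(seed=1))
sds = gpa(ds)
ic = np.array([r.ic for r in curvature_table(sds, axis)])
result = tps_unbend_dataset(ds, axis, degree=3)   # drops semilandmarks 16-19
print(procrustes_variance(sds), procrustes_variance(result.corrected))
```

Real data enter through `read_tps` (TpsDig dialect: `LM=`, `ID=`, `IMAGE=`,
`SCALE=` records) or `read_table` (wide CSV), with `average_replicates` to
merge repeated digitizations.

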