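# acinomorph

Quantitative 3D morphometry of **terminal branching units** — a "mother"
terminal bronchiole and its two "daughter" alveolar sacs — as imaged by
propagation-based phase-contrast synchrotron CT of a mouse lung, built
as a fully synthetic, testable pipeline.

The respiratory zone sits below the resolution of conventional lung
imaging, so basic geometric facts about its terminal units — how much
narrower a sac mouth is than its parent duct, how unequal two sibling
sacs are — have been hard to measure directly.  This package implements
the complete measurement chain needed to quantify them from
phase-contrast µCT at 1.74 µm isotropic voxels, and exercises every
stage against known ground truth:

* **phantoms** (`acinomorph.phantoms`): terminal-unit geometries
  (cylindrical bronchiole, two ellipsoidal sacs with alveolated/bumpy
  walls joined through circular mouths) with analytic diameters and a
  brute-force 4×-resolution oracle for surfaces and volumes;
* **beam simulation** (`acinomorph.projection`): parallel-beam line
  integrals (default 500 projections over 180°), the bright/dark
  boundary fringe characteristic of propagation-based phase contrast
  (`p − strength·∇²p`), and Poisson photon noise;
* **reconstruction** (`acinomorph.recon`): filtered back projection
  (ramp or Shepp–Logan filter, frequency-domain, power-of-two padding);
* **segmentation** (`acinomorph.segmentation`): per-slice Canny edge
  detection binarizing each voxel into air–tissue boundary (1) versus
  non-boundary (0) — air lumen and tissue alike;
* **extraction** (`acinomorph.extraction`): annotation-driven
  6-connected flood fill recovering mother and daughter interiors,
  truncated by cap and mouth planes;
* **morphometry** (`acinomorph.morphometry`): the seven parameters per
  unit — d₀ (mother diameter), d₁ ≥ d₂ (major/minor sac mouth
  diameters, each the geometric mean √(long·short) of a ring's maximal
  chord and perpendicular extent), S₁, S₂ (6-neighbour face-counting
  surface areas, µm²) and V₁, V₂ (voxel-counting volumes, nL);
* **asymmetry statistics** (`acinomorph.asymmetry`): per-unit ratios
  d₁/d₀, d₁/(d₁+d₂), S₁/(S₁+S₂), V₁/(V₁+V₂) and box-plot summaries,
  plus a bundled 16-unit reference morphometry table of mouse terminal
  branching units.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

Simulate one terminal unit at default study conditions (128³ grid,
1.74 µm voxels, 500 projections, fringes, photon noise), push it through
reconstruction → segmentation → extraction → measurement, and compare
with the oracle:

```python
from acinomorph import PhantomSpec, PipelineConfig, run_pipeline
from acinomorph.asymmetry import compute_ratios

result = run_pipeline(PhantomSpec(rng_seed=42), PipelineConfig(seed=7))
measured, truth = result.record, result.ground_truth.record
for k in ("d0_um", "d1_um", "d2_um", "S1_um2", "S2_um2", "V1_nL", "V2_nL"):
    print(f"{k:12s} {getattr(measured, k):10.4g} {getattr(truth, k):13.4g}")
print(f"d1/(d1+d2) = {compute_ratios(measured).d1_frac:.3f}")
```

prints (about two minutes on one CPU):

```
d0_um             72.04            72
d1_um             50.56            50
d2_um              42.1            42
S1_um2        2.908e+04     2.923e+04
S2_um2        2.326e+04     2.338e+04
V1_nL            0.2482         0.251
V2_nL            0.1785        0.1794
d1/(d1+d2) = 0.546
```

i.e. the full imaging chain recovers the mother diameter (72 µm), both
mouth diameters, and the sac surfaces/volumes to within ~1%, and the
sibling mouth-diameter ratio 0.546 quantifies this unit's (mild)
branching asymmetry — 0.5 would be a perfectly symmetric bifurcation.

The same chain is available stage by stage from the shell, exchanging
multi-page TIFFs with JSON sidecars:

```bash
acinomorph simulate --out-labels unit.tif --out-annotation unit_ann.json --out-truth truth.csv
acinomorph project unit.tif --out sino.tif --seed 1
acinomorph reconstruct sino.tif --out recon.tif
acinomorph segment recon.tif --out mask.tif
acinomorph extract mask.tif unit_ann.json --volume recon.tif --out labels.tif
acinomorph measure labels.tif --out morph.csv
acinomorph summarize morph.csv --out-json summary.json
```

Statistics of the bundled reference table:

```bash
$ acinomorph reproduce-paper
16 terminal branching units
medians:
  d1/d0: 0.82
  d1/(d1+d2): 0.55
  S1/(S1+S2): 0.57
  V1/(V1+V2): 0.60
extremes:
  d0: 52.5 / 123 um
  sac mouth diameter: 29 / 92 um
  sac surface area: 8510 / 97700 um^2
  sac volume: 0.0305 / 0.92 nL
```

The medians say that even at the most distal end of the airway tree the
bifurcations are measurably asymmetric: the major sac carries 55% of the
sibling mouth diameter, 57% of the surface, and 60% of the volume.

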