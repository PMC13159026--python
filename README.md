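# ccmorph

Mid-sagittal corpus callosum (CC) morphometry in Python: sub-voxel
mesh-based thickness profiling via the Laplace equation, mid-sagittal plane
estimation from segmentation label centroids, parametric CC
sub-segmentation schemes, summary shape metrics, and the evaluation/group
statistics that go with them. Every stage is testable end to end on
synthetic ribbon shapes with analytic ground truth — no imaging data
required.

## What it does

- **midplane** — estimate the subject mid-sagittal plane by rigidly
  registering (Kabsch/SVD) label centroids to a template segmentation and
  pulling the template mid-plane back through the inverse transform;
  extract slice stacks around the plane; standardize head pose from AC/PC
  landmarks; quantify plane disagreement as the volume enclosed between two
  planes inside an origin-centered cylinder.
- **meshing** — convert a binary mid-sagittal CC mask into a conforming
  triangle mesh with a sub-voxel boundary (marching squares + Chaikin
  smoothing + conforming Delaunay triangulation), locate the
  anterior/posterior endpoints from the AC/PC landmarks, and partition the
  boundary into inferior and superior chains.
- **laplace** — solve the Laplace equation with opposite charges on the two
  chains (P1 cotangent finite elements), build the harmonic-conjugate
  potential, extract the **intercallosal line** (zero level set) and
  measure thickness as the length of conjugate-potential level paths
  between the chains; curvature and length come from the line. A
  gradient-streamline tracer provides an independent oracle for the
  level-path shortcut.
- **subseg** — five parametric sub-segmentation schemes: anchor-line
  (Witelson / Hofer-Frahm fractions, or AC/PC anchored), eigendirection,
  radial rays, and the perpendicular scheme that cuts along
  conjugate-potential level paths at arc-length fractions of the
  intercallosal line. Crossing triangles are split exactly, so region
  areas always sum to the mesh area.
- **morphometrics** — area, perimeter, circularity, CC index, line length,
  curvature, mean thickness, and the resolution-corrected 5 mm volume.
- **evalstats** — Dice, 95th-percentile Hausdorff distance, per-position
  OLS group models with covariates + Benjamini-Hochberg correction, and the
  absolute-agreement ICC for test-retest reliability.
- **synthdata** — ribbon generators (straight / circular arc, configurable
  half-width profile), rasterized or analytic, paired label volumes with a
  known rigid transform, and test-retest cohorts with pose jitter and
  boundary noise.

## Test

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, one test per acceptance
criterion (analytic thickness on rectangle/annulus fixtures, FEM
correctness against closed forms, level-set vs. streamline equivalence,
registration recovery, plane-disagreement Monte-Carlo oracle,
sub-segmentation area conservation, volume-correction invariance,
statistics calibration, end-to-end parameter recovery + determinism).

## CLI

```bash
# synthetic fixture: mask + landmarks + ground truth
ccmorph synth ribbon --kind arc --resolution 0.5 --seed 1 --out-dir fixture/

# full pipeline: mask -> mesh -> thickness -> metrics -> sub-segmentation
ccmorph run --mask fixture/mask.nii --landmarks fixture/ac_pc.json \
            --out-dir out/ --report out/report.json

# individual stages
ccmorph midplane --subject-seg subj.nii --template-seg tpl.nii --out plane.json
ccmorph mesh --mask fixture/mask.nii --landmarks fixture/ac_pc.json --out mesh.off
ccmorph thickness --mesh mesh.off --landmarks fixture/ac_pc.json --n 100 --out profile.tsv
ccmorph subseg --mask fixture/mask.nii --landmarks fixture/ac_pc.json \
               --scheme hofer-frahm --out subseg.tsv
ccmorph stats group --profiles profiles.tsv --covariates cov.tsv --out stats.tsv
ccmorph stats icc --pairs pairs.tsv
```

Landmark files are JSON with keys `"AC"` and `"PC"` (2D mid-sagittal or 3D
world mm); planes serialize as a 4x4 frame matrix; meshes export as OFF and
ASCII VTK.

## Conventions

World coordinates are RAS mm; the 2D mid-sagittal frame is (a, s) =
(anterior+, superior+). Masks are indexed `mask[i, j]` with voxel centers
at `origin + (i, j) * resolution`. The intercallosal line is oriented
anterior to posterior; thickness profiles sample at `s_i = (i + 0.5) / n`
equally spaced in arc length (n = 100 by default). Boundary chains carry
charges -1 (inferior) and +1 (superior); ribbon end caps detected by
boundary turning receive natural boundary conditions so analytic fixtures
(rectangles, annulus sectors) are reproduced exactly.
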