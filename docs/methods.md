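# Methods

## Problem and model

Compression of mandarin fruit damages the pulp before the peel shows any
visible injury. On a CT section the damage reads as growth of the dark
central cavity around which the pulp segments sit, sometimes with displaced
pulp ("blockage") lodged inside it. `pulpscan` quantifies that damage:

* **Damage rate** of one fruit: `A = (S2 − S1)/S1 × 100 %`, where `S1`/`S2`
  are the cavity pixel areas before/after compression. The statistic is a
  ratio of areas from the same scanner geometry, so no physical pixel
  calibration is needed, and negative values (cavity shrinkage) are
  reported, not clamped.
* **Storage metrics**: respiration rate `(C1 − C2)·V/(m·t)` in
  mL CO₂ kg⁻¹ h⁻¹ (C₁/C₂ the CO₂ volume fractions of the sealed box with and
  without fruit, V container volume in mL, m fruit mass in kg, t sealing
  time in h); decay rate `100·decayed/group_size` with the protocol group
  size of 20; percent change vs control `100·(control − treated)/control`
  (positive = depressed below control).
* **Deformation regressions**: OLS of damage rate (Y1, %) and storage decay
  rate (Y2, %) on platen deformation X (mm), with `R² = 1 − SSE/SST` and a
  two-sided t-test on the slope (n − 2 df).

## Cavity segmentation

Stages (intermediates A–G are retained on every run):

1. **Binarize** — global threshold, Otsu by default, fixed value optional.
   Foreground is strictly `> threshold`; a constant image yields a warning
   and all-background.
2. **Mask** — largest foreground component (the fruit disk), hole-filled so
   the cavity stays inside, then eroded by a disk "erosion core". Default
   radii 15 px (cross) / 25 px (longitudinal) at 512×512, calibrated on the
   phantom suite; the right core size depends on section kind because
   longitudinal sections expose more peel curvature.
3. **Multiply** — intensities kept inside the mask, zero outside.
4. **Isolate** — dark pixels inside the mask become candidates (threshold
   recomputed over the mask interior); the zeroed exterior is excluded so it
   cannot merge with the cavity. Among candidate components the cavity is
   the one whose centroid is nearest the fruit centroid (damage concentrates
   near the fruit axis); exact distance ties go to the larger component.
5. **Refine** — dilation then erosion (default disk radius 3 each),
   disconnecting enclosed bright material from the exterior.
6. **Region growing** — from a seed (candidate centroid by default,
   image-center or explicit optional), growth covers every pixel not
   connected to the frame border through background: dark cavity pixels and
   bright blockage alike, giving the filled cavity.
7. **Blockage call and area** — the cavity is *blocked* when the candidate's
   enclosed holes exceed 1 % of the full cavity area (strict inequality).
   Unblocked cavities are measured from the refined dark component,
   blocked ones from the filled mask.

Conventions chosen for bit-stable re-runs: 8-connected components/growth
(4-connected optional; holes use the complementary connectivity), pixels
beyond the frame are background, areas are raw pixel counts.

## Phantom generator

The generator emulates the two section categories the damage study
distinguishes — cavity without and with blockage — with exact ground truth:
a bright peel annulus, pulp wedges separated by thin septa, a dark central
cavity (ellipse with a seeded lobed perturbation, since real cavities are
irregular), 1–5 convex bright fragments wholly inside the cavity (≥3 px dark
margin so they read as enclosed holes), point-like dark pulp ruptures, and
clipped additive Gaussian noise. Default gray levels (0–255 scale):
background 0, cavity 10, rupture 12, septum 140, pulp 160, blockage 175,
peel 230. The septum level was placed near the pulp level so a global
threshold groups septa with tissue, which is how septa behave against the
much darker cavity in real sections. Cavity-dark polarity is the CT-rendering
convention; an inversion flag covers bright-cavity modalities. Default frame
is 512×512 (a desk-scale stand-in for the scanner's native frame; any size is
supported and geometry scales with it).

**Pairs and the damage model.** A pre/post pair shares one seed: the post
section scales both cavity semi-axes by √(area factor) so the lobed cavity
grows self-similarly, and the recorded true damage rate is computed from the
two rasterized truths, never from the model. The default damage model
interpolates the study's group mean damage rates (3.82, 5.74, 10.81,
16.58 % at 4, 8, 12, 16 mm) and is deterministic at the mean; fruit-to-fruit
variability enters through `random_spec`'s seeded geometry (fruit radius
200–232 px, peel 14–22 px, cavity semi-axis 34–46 px, aspect 0.75–0.95,
lobe amplitude 0.04–0.10), not through an extra rate noise term — the group
tables constrain means, and adding rate noise would only dilute the
recovery check. Blockage starts at 12 mm (fraction 0.12, growing to 0.20 at
16 mm, capped at 0.30), where displaced pulp was first observed.

**What the phantom does not emulate:** beam hardening, ring artifacts,
partial-volume blur at boundaries, anatomical texture inside pulp wedges,
and 3-D structure. Passing recovery tests therefore shows the pipeline's
logic is correct on cleanly contrasted sections; it does not bound errors on
low-contrast or artifact-laden scanner data, where the erosion core and
threshold method may need per-batch tuning.

## Numerical choices and degenerate inputs

* Otsu on a constant region raises "no cavity found"; blank images fail the
  same way before masking.
* An erosion core larger than the fruit raises an explicit "core too large"
  error rather than returning an empty mask.
* A refine step that empties the candidate raises; radii (0, 0) are the
  identity.
* A region-growing seed on border-connected background is rejected; when the
  candidate centroid falls in a hole, the seed snaps to the nearest growable
  pixel.
* `R²` is defined as 1 when SST = 0 (all responses equal, perfect fit);
  slope p-values are NaN below n = 3.
* The reference decay fit is exact in double precision (slope 210/80,
  intercept 2.5, both binary-representable); tests assert equality, not
  approximation.

## Regressions on the reference tables

The decay regression on the four group decay rates reproduces the published
model exactly (Y2 = 2.625X + 2.5, R² displaying 0.97, slope p ≈ 0.016 < 0.05).
The damage regression on the four group *means* gives slope 1.084 and
intercept −1.60 — not the published per-fruit model Y1 = 0.964X − 0.468,
which was fitted on unreleased per-fruit rates. `fit_report` flags this
discrepancy instead of matching it; forcing agreement would misrepresent
what the group means support. The control group (X = 0) is excluded from
fits by default because the reference tables list only 4–16 mm.

## Problem sizes

Recovery and group-mean tests run 30 phantoms (or pairs) per class/level at
512×512, the per-group sample size of the compression study. The
`scripts/acceptance.py` summary uses 12 pairs per deformation level and 10
recovery phantoms per class, enough for the group means' standard error to
sit well inside the reported tolerances while keeping a full rerun under
half a minute.

## Known limitations

* The cavity-selection rule (centroid nearest fruit centroid) assumes the
  cavity is the most axial dark structure; a grossly off-axis cavity plus a
  large central rupture could be mis-selected.
* The blockage call depends on the 1 % enclosed-hole threshold; fragments
  touching the cavity wall (no dark margin) merge with the wall and are not
  counted as blockage.
* Per-metric group sizes differ in the storage protocol (20 fruits for
  decay, fewer for destructive assays); `group_size` is per-observation and
  defaults to 20 only for decay counting.
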