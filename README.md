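# pulpscan

Quantifying internal compression damage in mandarin fruit from CT section
images.

Compressed mandarins often look intact — the peel is elastic — while the
pulp inside is already ruptured, and such fruit decays much faster in
storage. On a CT section the damage is visible as growth of the dark
central cavity, sometimes with displaced pulp ("blockage") lodged inside
it. `pulpscan` is for postharvest researchers who want to turn section
images and storage observations into damage and decay statistics:

* **Cavity segmentation** — a mask-based morphological pipeline
  (binarize → erode a fruit mask → multiply → isolate the dark central
  component → dilate/erode refinement → region-growing fill) extracts the
  central cavity and measures its pixel area, absorbing bright blockage
  into the measurement when present.
* **Damage rate** — for a fruit scanned before (`S1`) and after (`S2`)
  compression, `A = (S2 − S1)/S1 × 100 %`, summarized per deformation
  group as mean ± sample SD.
* **Storage quality metrics** — respiration rate
  `(C1 − C2)·V/(m·t)` (mL CO₂ kg⁻¹ h⁻¹), decay rate
  `100·decayed/group size`, and percent change vs an uncompressed control.
* **Deformation regressions** — OLS models `Y1 = aX + b` (damage rate, %)
  and `Y2 = aX + b` (storage decay rate, %) on compression deformation X
  (mm), with R² and a t-test on the slope.
* **Phantom generator** — synthetic sections (peel annulus, pulp wedges,
  septa, dark lobed cavity, blockage fragments, ruptures, noise) with
  exact ground truth, so the whole pipeline is testable without scanner
  data.

## Worked example

```python
from pulpscan import (PhantomSpec, generate_pair, extract_cavity_area,
                      damage_rate, fit_ols)
from pulpscan.deformation_regression import table_points, predict

# a synthetic fruit compressed by 12 mm, scanned before and after
pair = generate_pair(PhantomSpec(seed=42), deformation_mm=12.0)
s1 = extract_cavity_area(pair.pre_image).area_px
post = extract_cavity_area(pair.post_image)
print(f"S1 = {s1} px, S2 = {post.area_px} px (blocked={post.blocked})")
print(f"damage rate A = {damage_rate(s1, post.area_px):.2f} % "
      f"(phantom truth: {pair.true_damage_rate:.2f} %)")

# decay-rate regression on the reference group table (4-16 mm)
decay = fit_ols(table_points("decay"), response="Y2")
print(decay.equation(), f"R² = {decay.r_squared:.2f}")
print(f"predicted decay at 10 mm: {predict(decay, 10.0).value:.1f} %")
```

prints

```
S1 = 4040 px, S2 = 4464 px (blocked=True)
damage rate A = 10.50 % (phantom truth: 10.52 %)
Y2 = 2.625X + 2.5 R² = 0.97
predicted decay at 10 mm: 28.8 %
```

The post-compression cavity was classified as blocked (displaced pulp
fragments inside it), so its area comes from the region-growing fill; the
measured damage rate tracks the phantom's exact truth to 0.02 percentage
points. The decay model says each extra millimetre of deformation adds
about 2.6 percentage points of storage decay.

A command-line interface mirrors the library:
`pulpscan phantom|segment|damage|storage|regress|run` (see `--help`).

Note on the damage regression: fitted on the four reference *group means*,
the damage model is `Y1 = 1.084X - 1.6`, which intentionally differs from
the originally published per-fruit model (`Y1 = 0.964X - 0.468`, fitted on
per-fruit rates that were never released); `fit_report` flags this rather
than forcing agreement. The decay model is reproduced exactly.

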