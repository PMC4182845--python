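# mulchres

Estimate **mulch residue** on agricultural plots from color
photographs, by measuring the percentage of bare soil exposed where
the mulch film (black polyethylene, biodegradable plastic, or paper)
has degraded.

Soil and black mulch are nearly indistinguishable in every RGB plane,
but clearly separated in **HSV saturation**: soil is chromatic, intact
black film is nearly achromatic, so the saturation histogram of a
mulched-plot photograph is bimodal. `mulchres` thresholds that
histogram, cleans the binary mask, and reports percent bare soil —
the plot-level measure of mulch deterioration — then compares
thresholding methods and mulch materials statistically.

## What it computes

For an m×n photograph with saturation plane f(x, y), quantized to 256
gray levels with histogram probabilities p_k:

- **Otsu (OT)** — the split t maximizing the between-class variance
  σ_b²(t) = ω₀ω₁(m₁ − m₂)², equivalently minimizing the within-class
  variance (σ_b² + σ_w² = σ_total² at every split).
- **Ridler–Calvard / isodata (RC)** — the fixed point of
  t ← (m₁(t) + m₂(t))/2, iterated from the histogram mean to sub-bin
  precision.
- **Local entropy (LE)** — the split maximizing the summed Shannon
  entropies (H = −Σ p log₂ p) of the background-background and
  foreground-foreground quadrants of the gray-level co-occurrence
  matrix.
- **Manual (MT)** — a user-chosen threshold.

A pixel is soil iff S > t (strict). Noise components with area
< ⌊m·n/100⌋ are removed from the mask and its complement
(8-connectivity), and the bare-soil area is
A = 100 · #white / (m·n) percent.

The statistics layer runs paired two-tailed t-tests of each method
against expert-traced reference areas (with a Shapiro–Wilk gate that
routes non-normal difference series to the paired Wilcoxon signed-rank
test), and one-way ANOVA with **Duncan's multiple range test**
(α = 0.05) to compare deterioration across mulch materials.

The package embeds the per-image table of a field campaign — 24 plot
photographs, 4 mulch materials × 6 blocks, with every method's
threshold and area plus the expert reference area — and reproduces the
campaign's summary statistics from it. Because the original
photographs are not distributable, the image pipeline itself is
validated on synthetic two-class scenes with known ground-truth soil
fraction (`mulchres.make_scene` / `mulchres.scene_batch`).

## Worked example

Segment a synthetic scene whose true bare-soil fraction is 35%:

```python
from mulchres import make_scene, process_image

scene = make_scene(soil_fraction=0.35, seed=7)
for method in ("otsu", "rc", "le"):
    rec = process_image(scene.image, method, image_id="demo")
    print(f"{rec.method}: t={rec.t:.4f}  area={rec.area_pct:.2f}%  "
          f"(pre-cleanup {rec.area_pct_precleanup:.2f}%)")
print(f"ground truth: {scene.truth_area_pct:.2f}%")
```

```
OT: t=0.3216  area=32.16%  (pre-cleanup 35.01%)
RC: t=0.3249  area=32.16%  (pre-cleanup 35.00%)
LE: t=0.3216  area=32.16%  (pre-cleanup 35.01%)
ground truth: 35.00%
```

All three automatic thresholds land in the histogram valley near 0.32
and recover the true area before cleanup; the small-object rule then
deletes tears below ⌊m·n/100⌋ pixels, trimming the estimate by a few
points on this blob-heavy scene.

Reproduce the study-level comparison tables from the embedded dataset:

```bash
mulchres reproduce-tables
```

```
Paired comparisons vs reference area:
 g1   g2     dif  mean_g1  mean_g2  sd_dif     test  statistic  p_bilateral  normality_p
A_R A_OT -1.7349  40.6900  42.4249  7.4188        t    -1.1456       0.2637       0.0987
A_R A_RC -1.1650  40.6900  41.8550  7.6146        t    -0.7495       0.4611       0.0810
A_R A_MT -3.2176  40.6900  43.9076  6.5259        t    -2.4155       0.0241       0.0421
A_R A_LE -5.0493  40.6900  45.7393 19.2282 wilcoxon    97.0000       0.1355       0.0071

Per-mulch deterioration (mean ± SE, Duncan letters):
                    a_r            a_ot            a_rc            a_le
mulch
1        50.90 ± 8.06 a  50.60 ± 4.12 a  50.33 ± 4.18 a  40.78 ± 8.74 a
2        52.76 ± 5.17 a  54.66 ± 5.05 a  54.10 ± 5.14 a  51.70 ± 3.88 a
3        17.65 ± 4.54 b  19.62 ± 4.52 b  18.85 ± 4.85 b  37.77 ± 7.56 a
4        41.45 ± 3.30 a  44.82 ± 1.16 a  44.14 ± 1.82 a  52.71 ± 9.24 a
P-value          0.0008          0.0000          0.0000          0.2446
```

Reading the output: only the manual threshold differs significantly
from the expert reference (p = 0.0241 < 0.05), and only the
entropy-method differences fail the normality gate and use Wilcoxon.
In the per-mulch table, polyethylene (mulch 3) carries its own Duncan
letter under the reliable methods — under 20% bare soil versus ≈ 50%
for the biodegradable films 100 days after laying — while the
entropy method blurs the materials (its column, analyzed after the
squaring transform, is non-significant).

Other commands: `mulchres process --input <dir> --method otsu --out
areas.csv` segments a directory of photographs; `mulchres simulate
--out <dir> --seed 1` writes a synthetic 24-scene campaign with ground
truth; `mulchres fixtures table1 --out table1.csv` exports the
embedded dataset.

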