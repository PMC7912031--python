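# irhisto — infrared spectral histology of hair follicles

`irhisto` is a reusable, tested implementation of a label-free mid-IR
hyperspectral analysis pipeline for hair-follicle cryosections. The hair
follicle is a layered mini-organ — connective tissue sheath (CTS),
germinative matrix and differentiation zone in the bulb, inner and outer
root sheaths (IRS/ORS), and the hair shaft — embedded for sectioning in OCT
compound. Its glycosaminoglycan (GAG) content, and in particular the
sulfation of heparan-sulfate chains, varies both between structures and
across the hair growth cycle (anagen → catagen → telogen). In FTIR images
that sulfation appears as the anti-symmetric S=O stretching band near
1248 cm⁻¹, so the 1350–1190 cm⁻¹ window acts as a sulfation marker on top
of the protein/carbohydrate fingerprint region (1800–900 cm⁻¹).

The pipeline covers the four chemometric stages such studies chain
together, each exposed both as scikit-learn-style estimators and as plain
functions on the package's `Spectrum` / `SpectralImage` data model:

- **Preprocessing** of extracted pixel spectra: Savitzky–Golay smoothing
  (7 points), elastic (rubber-band / lower-convex-hull) baseline removal,
  vector normalization, offset correction, plus a template-subtraction
  atmospheric correction for residual water-vapor/CO₂ lines.
- **EMSC** (extended multiplicative scatter correction) of whole images:
  per pixel least squares `s ≈ a + Σ c_j t^j + b·m(ν)` with a common
  reference `m`, removing polynomial baselines and dividing out the
  thickness/scatter factor `b`, with robust rejection of outlier pixels
  (`rms > median + 5·MAD`, `b` outside `[0.05, 20]`).
- **Windowed PCA** of region-mean spectra with 95 % confidence ellipses
  (`√χ²₂(0.95) ≈ 2.448` times the covariance eigen-axes) and an
  ellipse-intersection separation report, over the fingerprint or
  sulfation window.
- **Common k-means** (k = 10, Euclidean, k-means++ with restarts) over the
  pooled pixels of several images, with false-color maps, centroid
  dendrogram (Newick export), and ground-truth cluster annotation.
- **Correlation maps**: per-pixel Pearson r against reference spectra of
  standard compounds (heparan sulfate HS, glypican-1 GPC1, hyaluronic acid
  HA), displayed on a 0–1 scale.

Because no instrument data ships with the study this package
operationalizes, a first-class **phantom generator** produces
hair-follicle-like hyperspectral images with ground-truth structure labels,
known pure signatures, and instrument-like degradations (log-normal
scatter, polynomial baselines, noise, a water-vapor comb, artifact pixels).
Every analysis claim in the test suite is checked against that ground
truth.

## Worked example

```python
from irhisto import (PhantomConfig, generate, atmospheric_correct,
                     correct_image, correlate_image, structure_profile,
                     reference_spectra)

truth = generate(PhantomConfig(phase="anagen", seed=7))      # 128x64 cube
img = atmospheric_correct(truth.image, truth.vapor)          # remove vapor comb
res = correct_image(img, poly_order=2)                       # EMSC + outliers
print(f"rejected outlier pixels: {int(res.outlier_mask.sum())}")

cmap = correlate_image(img, reference_spectra()["HS"])       # HS Pearson map
for name in ("ORS", "IRS", "germinative_matrix", "differentiation_zone"):
    mean, sd = structure_profile(cmap, truth.labels)[name]
    print(f"HS correlation in {name}: {mean:.3f} +/- {sd:.3f}")
```

prints

```
rejected outlier pixels: 162
HS correlation in ORS: 0.808 +/- 0.048
HS correlation in IRS: 0.794 +/- 0.053
HS correlation in germinative_matrix: 0.744 +/- 0.062
HS correlation in differentiation_zone: 0.739 +/- 0.034
```

The phantom plants 1 % artifact pixels and EMSC rejects them (162 of
8192 ≈ 2 %, artifacts plus a small false-positive tail); the HS map ranks
the ORS highest, the IRS close behind, and the bulb structures lower — the
expected heparan-sulfate distribution of an anagen follicle.

A command-line interface mirrors the stages
(`irhisto phantom | preprocess | emsc | pca | kmeans | corrmap | run |
accept`); `irhisto run --config run.toml` executes the whole pipeline and
writes a manifest with content hashes for reproducibility.

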