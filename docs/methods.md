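# Methods

This note documents the models, defaults, and design choices behind
`irhisto`, and what the phantom-based tests do and do not establish about
real instrument data.

## Data model and conventions

Spectra and cubes carry a strictly monotonic wavenumber axis stored
*descending* (FTIR convention); readers accept either orientation and flip
bands on ingest. Spectral windows are closed intervals `[lo, hi]` in cm⁻¹
with inclusive band membership. Spatial coordinates are `(row, col)`,
0-based, row 0 at the top. Three cube dialects are supported (HDF5,
ENVI BSQ/BIL/BIP, and a long-table CSV); reference spectra read from
two-column text or AFFN `(X++(Y..Y))` JCAMP-DX — compressed JCAMP
(SQZ/DIF/PAC) is rejected explicitly rather than mis-parsed.

## Phantom generator

The generator is the package's study-condition definition, not a test
fixture. A deterministic longitudinal-section template lays out OCT
background (~45 % of pixels), concentric hair-shaft/IRS/ORS/CTS columns,
and a bulb ellipse split into germinative matrix (below the papilla base)
and differentiation zone (above). Default image: 128×64 pixels, 6.25 µm
pixels, axis 1800→900 cm⁻¹ at 4 cm⁻¹ (226 bands).

Pure signatures are sums of Gaussian bands (Gaussian, not Voigt: adequate
for chemometrics and closed-form for oracles). All tissue structures share
amide I/II/III bands (1655/1545/1310 cm⁻¹) scaled by a per-structure
protein density; carbohydrate bands at 1080/1030 cm⁻¹ and the sulfation
band at 1248 cm⁻¹ (σ = 10 cm⁻¹) vary by structure. Two design constraints
shaped the defaults, both consequences of EMSC's b-normalization collapsing
overall scale:

- structures must differ in *shape*, so the collagen-rich CTS carries
  extra 1204/1338 cm⁻¹ bands and the keratin-dense hair shaft has low
  carbohydrate plus a 1175 cm⁻¹ cysteic-acid-like band;
- the germinative matrix and differentiation zone are identical except for
  a small sulfation offset (heights 0.15 vs 0.12 AU), so they are
  distinguishable in the 1350–1190 cm⁻¹ window but nearly degenerate over
  the full fingerprint — a common clustering merges them into one "bulb"
  class, as observed histologically.

Phase dependence is confined to the HS-like sulfation heights of the ORS
and IRS (ORS 0.22 → 0.26, IRS 0.04 → 0.09 from anagen to
catagen/telogen): HS concentrates in the ORS during anagen and extends
into the IRS afterwards. The shifts are deliberately smaller than
between-structure contrasts so that one common k-means still groups
structures across phases.

Degradation model per pixel: `cube = b·pure + baseline(ν) + vapor(ν) + ε`
with `b` log-normal (median 1, σ_log = 0.15), a random polynomial baseline
of order ≤ 2 (coefficient SDs 0.02/0.01/0.005 AU on the rescaled axis),
i.i.d. Gaussian noise (0.01 AU), and a per-image comb of narrow
(σ ≤ 2 cm⁻¹, i.e. sub-band at 4 cm⁻¹ spacing) water-vapor lines confined
to 1800–1400 cm⁻¹ so the sulfation window stays clean. A configurable
fraction (default 1 %) of pixels is replaced by artifacts: half are
saturation-like spikes (×5 amplitude with strong added shape noise —
saturation distorts band shapes, and a pure amplitude spike would lie
exactly in the EMSC model span and be undetectable by any residual rule),
half are detector-glitch pixels of broadband noise at band-height scale
(SD 0.5 AU). Everything is reproducible from one integer seed.

Reference spectra (HS, GPC1, HA, OCT) are synthetic analogues: HS carries
the dominant 1248 cm⁻¹ band plus carbohydrate and the moderate
N-acetyl/N-sulfo amide bands real GAG standards show; HA is the
non-sulfated control (zero absorbance at 1248 cm⁻¹); GPC1 is
amide-dominant with weak sulfation; OCT is the embedding signature.

What the phantom does **not** emulate: resonant-Mie dispersion artifacts,
spatial texture within structures, biological within-structure
compositional variability, instrument line-shape effects, and the true
(unpublished) tissue signatures — band positions beyond the 1248 cm⁻¹
anchor are design values. Passing tests therefore demonstrate that the
operators behave correctly under a faithful degradation model, not that
the pipeline's quantitative outputs match any particular instrument.

## Preprocessing

The spectrum-level chain follows the classical OPUS-style order:
Savitzky–Golay (7 points, polynomial order 3 — the order is not part of
the stated protocol and is exposed as a parameter), rubber-band baseline
(lower convex hull, the standard reading of "elastic" correction), vector
normalization, offset correction. The printed order is kept even though
offsetting after normalization breaks unit norm; a
`renormalize_after_offset` flag restores it. The chain is *not* exactly
idempotent: SG smoothing is a convolution, not a projection, so a second
application still moves a processed spectrum at the ~10⁻³ level; the
tests assert the achievable contraction property and exact idempotence of
the baseline/normalize/offset sub-chain.

Atmospheric correction subtracts `α·template` (α ≥ 0) per pixel with α
fitted by least squares restricted to the template's support bands. Both
pixel and template are first detrended with a short SG smooth: the vapor
lines are much narrower than tissue bands, so detrending removes the
broad-band leakage that otherwise biases α by an order of magnitude. The
fit is exact for polynomial backgrounds (SG reproduces polynomials up to
its order) and reduces vapor MSE by ~100 % on vapor-only phantoms.

## EMSC

Model `s(ν) = a + Σ_{j≤d} c_j t^j + b·m(ν) + r(ν)` with `t` the axis
affinely mapped to [−1, 1] (conditioning independent of the wavenumber
scale), `d = 2` by default (offset, slope, curvature — the baseline and
thickness terms), and `m` the mean of masked-in pixels pooled over *all*
images of a run, so corrected images share one spectral space before
common clustering. Corrected spectrum: `(s − baseline)/b`. Outlier rule:
`rms > median(rms) + 5·MAD(rms)` or `b < 0.05` or `b > 20`, computed over
the pooled pixel population; all three constants are parameters. With a
single common reference on multi-tissue images the residual contains a
deterministic per-structure mismatch, so the recovered `b` equals
`c_s · b_true` with a structure-dependent projection factor; within one
structure the recovery is exact on noise-free phantoms (r = 1.000 in the
ORS), while a pooled correlation across structures is bounded away from 1
by construction.

## Windowed PCA

Region-mean spectra (whole-region or operator-style small zones of
(2·2+1)² pixels; the number of zones per image is configurable and
reported) are preprocessed with the standard chain after cropping, column
mean-centered, and decomposed by SVD. Loadings follow a deterministic sign
convention (largest-magnitude element positive). Confidence ellipses are
population-covariance χ² ellipses (`√5.991` at 95 %), not small-sample
Hotelling T²; overlap is decided by sampling 360 boundary points plus
center-containment tests both ways.

Which PC pair carries the structural contrast is window-dependent and is
an explicit argument: in the fingerprint window the sulfation contrast
concentrates almost entirely in PC2 while protein/carbohydrate contrasts
span PC1/PC3, so structure discrimination there is examined in the
(PC1, PC3) plane; the sulfation window uses (PC1, PC2). Structure
discrimination experiments run on anagen phantoms only: mixing phases
would make the IRS group bimodal in the sulfation window (a phase effect
by design, not a discrimination failure). Under the defaults, the
germinative-matrix and differentiation-zone ellipses overlap over
1800–900 cm⁻¹ and the germinative matrix separates from all four other
structures over 1350–1190 cm⁻¹.

## Segmentation

Common k-means pools the masked-in pixels of all images (k = 10 by
default, Euclidean distance, k-means++ with 10 restarts, best inertia
kept). On tiny problems (< 50·k samples) the greedy k-means++ seeding is
nearly deterministic and restarts collapse, so additional random-init
restarts are added there; this is what lets restarted k-means match the
exhaustive-enumeration optimum in ≥ 95 % of 100 small seeded trials. The
conventional clustering range 1800–800 cm⁻¹ exceeds the acquired axis
(which stops at 900 cm⁻¹); windows are clamped to the axis intersection
with a logged warning. Cluster labels are canonicalized by centroid
brightness and colored from a fixed 10-entry palette. OCT pixels are
clustered, not masked: their EMSC correction divides by a small fitted
`b`, inflating their within-class spread, and k-means consequently spends
five clusters on OCT and five on tissue (CTS, bulb, IRS, ORS, shaft) at
the defaults — the 5 + 5 split, with the OCT clusters forming a separate
clade of the ward dendrogram over centroid spectra (exported as Newick
with merge-height branch lengths). Cluster annotation assigns each
cluster its plurality ground-truth structure (ties break toward the lower
vocabulary id); the reported adjusted Rand index compares truth labels
with annotation-mapped cluster labels, since the raw 10-vs-7 ARI is
dominated by the deliberate OCT split.

## Correlation maps

Per masked-in pixel, Pearson r against a reference spectrum over a window
(default: the full processed axis), clipped to the displayed [0, 1] scale
(a flag preserves signed r). Pearson was chosen over cosine because it is
offset- as well as gain-invariant; both are available. Maps are computed
on atmospheric-corrected, non-normalized pixels: Pearson's affine
invariance makes EMSC unnecessary here, and b-normalization would
re-weight band shapes. Zero-variance pixels score 0 and are counted in
the log. Renderings are linear grayscale PNGs (0 → black, 1 → white).
Known phantom limitation: the keratin-dense hair-shaft signature carries
little carbohydrate, so HA correlation in the shaft is near zero rather
than moderate.

## Pipeline and reproducibility

`run_pipeline` executes phantom → atmospheric → EMSC → PCA / k-means /
correlation maps from one flat TOML/YAML config; every artifact is hashed
into a YAML manifest, and identical config + seed gives identical text
hashes. All randomness flows from a single master seed through
`numpy.random.SeedSequence` substreams. The acceptance experiments run
the same code paths at the default problem sizes (three 128×64 phantoms
for clustering, six for PCA), which keeps the whole acceptance run under
a minute on one CPU.
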