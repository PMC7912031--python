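"""End-to-end reproduction experiments on ground-truthed phantoms.

Each function recomputes one headline result of the pipeline from scratch
under the default study conditions: the k-means cluster-count split between
tissue and embedding medium, the windowed-PCA discrimination of the
germinative matrix, the operator oracles (Savitzky-Golay, rubber-band,
EMSC, confidence ellipses), the correlation-map structure profiles, and the
small-instance k-means optimality rate.  All randomness derives from one
master seed through named substreams.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np

from .corrmap import correlate_image, structure_profile
from .emsc import EMSCModel, correct_images, fit_emsc_pixel
from .pca import confidence_ellipse, region_mean_spectra, run_pca, separation_report
from .phantom import PHASES, PhantomConfig, generate, reference_spectra
from .preprocess import atmospheric_correct, savitzky_golay, rubber_band_baseline
from scipy.cluster import hierarchy

from .segmentation import (
    CommonKMeans,
    annotate_clusters,
    centroid_dendrogram,
    common_kmeans,
    mapped_structure_ari,
)
from .spectral_data import SpectralWindow, Spectrum, WavenumberAxis

logger = logging.getLogger(__name__)

CLUSTER_WINDOW = SpectralWindow(800.0, 1800.0)
FINGERPRINT = SpectralWindow(900.0, 1800.0)
SULFATION = SpectralWindow(1190.0, 1350.0)
PCA_STRUCTURES = ["germinative_matrix", "differentiation_zone", "IRS", "ORS",
                  "hair_shaft"]


def _streams(seed: int, n: int = 24) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _phase_trio(streams):
    """Default anagen/catagen/telogen phantoms, atmospheric-corrected."""
    truths, images = [], []
    for phase, s in zip(PHASES, streams):
        truth = generate(PhantomConfig(phase=phase, seed=int(s)))
        truths.append(truth)
        images.append(atmospheric_correct(truth.image, truth.vapor))
    return truths, images


def cluster_count_experiment(seed: int) -> dict:
    """Common k-means (k=10) over the three default phase phantoms.

    Returns the number of clusters majority-assigned to tissue structures
    and to OCT, plus the annotation-level adjusted Rand index.
    """
    st = _streams(seed)
    truths, images = _phase_trio(st[:3])
    results = correct_images(images, poly_order=2)
    corrected = [r.corrected for r in results]
    model, maps = common_kmeans(corrected, k=10, window=CLUSTER_WINDOW,
                                seed=int(st[3]), n_init=10)
    annotation = annotate_clusters(maps, [t.labels for t in truths])
    n_oct = sum(1 for s, _ in annotation.values() if s == "OCT")
    n_pixels = int(sum(img.mask.sum() for img in images))
    oct_ids = {cid for cid, (s, _) in annotation.items() if s == "OCT"}
    dend = centroid_dendrogram(model, linkage="ward")
    return {
        "tissue_clusters": len(annotation) - n_oct,
        "oct_clusters": n_oct,
        "oct_forms_clade": _leaves_form_clade(dend.linkage_matrix,
                                              {c - 1 for c in oct_ids}, model.k),
        "segmentation_ari": mapped_structure_ari(maps, [t.labels for t in truths]),
        "outlier_recall": _outlier_recall(truths, results),
        "outlier_fpr": _outlier_fpr(truths, results),
        "n_pixels": n_pixels,
    }


def _leaves_form_clade(Z: np.ndarray, leaf_ids: set[int], n_leaves: int) -> bool:
    """True when the smallest subtree containing ``leaf_ids`` holds no others."""
    tree = hierarchy.to_tree(Z)

    def visit(node):
        # returns (leaf set, best clade found)
        if node.is_leaf():
            return {node.id}, None
        left, found_l = visit(node.left)
        right, found_r = visit(node.right)
        leaves = left | right
        found = found_l or found_r
        if found is None and leaf_ids <= leaves:
            found = leaves == leaf_ids
        return leaves, found

    _, found = visit(tree)
    return bool(found)


def _outlier_recall(truths, results) -> float:
    tp = sum((r.outlier_mask & t.outlier_mask).sum() for t, r in zip(truths, results))
    pos = sum(t.outlier_mask.sum() for t in truths)
    return float(tp / pos)


def _outlier_fpr(truths, results) -> float:
    fp = sum((r.outlier_mask & ~t.outlier_mask).sum() for t, r in zip(truths, results))
    neg = sum((~t.outlier_mask).sum() for t in truths)
    return float(fp / neg)


def pca_discrimination_experiment(seed: int, n_images: int = 6) -> dict:
    """Windowed PCA of small-zone mean spectra from anagen phantoms.

    The fingerprint window is examined in the (PC1, PC3) score plane and the
    sulfation window in (PC1, PC2) — the planes that carry the structural
    contrasts in each window.  Reports whether the germinative matrix and
    differentiation zone ellipses overlap over 1800-900 cm^-1, and from how
    many of the four other structures the germinative matrix is separated
    over 1350-1190 cm^-1.
    """
    st = _streams(seed)
    rng = np.random.default_rng(int(st[4]))
    sset = None
    for i in range(n_images):
        truth = generate(PhantomConfig(phase="anagen", seed=int(st[5 + i])))
        img = atmospheric_correct(truth.image, truth.vapor)
        s = region_mean_spectra(img, truth.labels, PCA_STRUCTURES,
                                zone_size=2, n_zones=3, rng=rng)
        sset = s if sset is None else sset.extend(s)
    res_fp = run_pca(sset, FINGERPRINT, n_components=3)
    rep_fp = separation_report(res_fp, (1, 3))
    res_su = run_pca(sset, SULFATION, n_components=2)
    rep_su = separation_report(res_su, (1, 2))
    overlap = rep_fp[("germinative_matrix", "differentiation_zone")] == "overlapping"
    n_sep = sum(1 for pair, verdict in rep_su.items()
                if "germinative_matrix" in pair and verdict == "separated")
    return {
        "fingerprint_gm_dz_overlapping": bool(overlap),
        "sulfation_gm_separated_count": n_sep,
        "n_samples": len(sset.group),
    }


def operator_oracle_experiment(seed: int) -> dict:
    """Closed-form and generator-ground-truth checks of the core operators."""
    st = _streams(seed)
    axis = WavenumberAxis.from_range(1800, 900, 4)
    nu = axis.values
    t = np.linspace(-1, 1, nu.size)

    # Savitzky-Golay preserves cubics exactly (interior points).
    cubic = Spectrum(axis, 0.3 + 0.5 * t - 0.2 * t**2 + 0.7 * t**3)
    smoothed = savitzky_golay(cubic, 7, 3)
    sg_err = float(np.max(np.abs(smoothed.absorbance[3:-3] - cubic.absorbance[3:-3])))

    # Rubber band maps affine spectra to zero.
    affine = Spectrum(axis, 0.2 + 0.001 * nu)
    corrected, _ = rubber_band_baseline(affine)
    rb_err = float(np.max(np.abs(corrected.absorbance)))

    # EMSC exact recovery in the model span: s = 2 m + 0.5.
    ref = reference_spectra(axis)["GPC1"]
    model = EMSCModel(reference=ref, poly_order=2)
    coeffs, corr, _ = fit_emsc_pixel(Spectrum(axis, 2.0 * ref.absorbance + 0.5), model)
    emsc_err = float(max(abs(coeffs[-1] - 2.0), abs(coeffs[0] - 0.5),
                         np.max(np.abs(corr.absorbance - ref.absorbance))))

    # b-map recovery on a scatter+baseline phantom (no noise): within the
    # ORS the fitted b is proportional to the applied b.
    truth = generate(PhantomConfig(noise_sd=0.0, vapor_amp=0.0,
                                   outlier_fraction=0.0, seed=int(st[11])))
    res = correct_images([truth.image], poly_order=2)[0]
    ors = truth.labels.mask_of("ORS")
    b_r = float(np.corrcoef(res.b_map[ors], truth.applied_b[ors])[0, 1])

    # Correlation-map invariance to per-pixel gain/offset: EMSC with a
    # constant-offset model on a scatter-only phantom is an affine map per
    # pixel, so Pearson maps before and after must agree.
    scatter = generate(PhantomConfig(noise_sd=0.0, vapor_amp=0.0,
                                     baseline_coeffs_sd=(0.02, 0.0, 0.0),
                                     outlier_fraction=0.0, seed=int(st[12])))
    res0 = correct_images([scatter.image], poly_order=0)[0]
    hs = reference_spectra(axis)["HS"]
    before = correlate_image(scatter.image, hs)
    after = correlate_image(res0.corrected, hs)
    keep = res0.corrected.mask
    inv_err = float(np.max(np.abs(before.values[keep] - after.values[keep])))

    # Chi-square ellipse: coverage of the 95% ellipse at n = 10^4 and
    # isotropy of the radii (sqrt(5.991) ~ 2.448) at n = 2000.
    rng = np.random.default_rng(int(st[13]))
    pts = rng.standard_normal((10_000, 2))
    ell = confidence_ellipse(pts)
    coverage = float(ell.contains(pts).mean())
    pts2 = rng.standard_normal((2000, 2))
    ell2 = confidence_ellipse(pts2)
    radius_dev = float(max(abs(ell2.r1 / np.sqrt(5.991) - 1),
                           abs(ell2.r2 / np.sqrt(5.991) - 1)))

    # Atmospheric correction on a vapor-only phantom.
    base = dict(noise_sd=0.0, scatter_sigma=0.0, baseline_coeffs_sd=(0, 0, 0),
                outlier_fraction=0.0, seed=int(st[14]))
    vap = generate(PhantomConfig(vapor_amp=0.05, **base))
    clean = generate(PhantomConfig(vapor_amp=0.0, **base))
    mse0 = float(np.mean((vap.image.cube - clean.image.cube) ** 2))
    corr_img = atmospheric_correct(vap.image, vap.vapor)
    mse1 = float(np.mean((corr_img.cube - clean.image.cube) ** 2))

    return {
        "sg_cubic_max_err": sg_err,
        "rubber_band_affine_max_err": rb_err,
        "emsc_span_max_err": emsc_err,
        "emsc_b_recovery_r": b_r,
        "corrmap_affine_invariance_max_dev": inv_err,
        "ellipse_coverage": coverage,
        "ellipse_radius_rel_dev": radius_dev,
        "vapor_mse_reduction": 1.0 - mse1 / mse0,
    }


def corrmap_profile_experiment(seed: int) -> dict:
    """Correlation-map structure profiles across phases.

    HS-reference maps must rank the ORS above the differentiation zone in
    anagen; the IRS correlation with HS must rise from anagen to catagen;
    HA-reference maps must rank the IRS above the ORS.
    """
    st = _streams(seed)
    refs = reference_spectra()
    profiles = {}
    for phase, s in [("anagen", int(st[15])), ("catagen", int(st[16]))]:
        truth = generate(PhantomConfig(phase=phase, seed=s, outlier_fraction=0.0))
        img = atmospheric_correct(truth.image, truth.vapor)
        for ref_name in ("HS", "HA"):
            cmap = correlate_image(img, refs[ref_name])
            profiles[(phase, ref_name)] = structure_profile(cmap, truth.labels)
    return {
        "hs_ors_minus_dz": profiles[("anagen", "HS")]["ORS"][0]
        - profiles[("anagen", "HS")]["differentiation_zone"][0],
        "hs_irs_catagen_minus_anagen": profiles[("catagen", "HS")]["IRS"][0]
        - profiles[("anagen", "HS")]["IRS"][0],
        "ha_irs_minus_ors": min(profiles[(p, "HA")]["IRS"][0]
                                - profiles[(p, "HA")]["ORS"][0]
                                for p in ("anagen", "catagen")),
    }


def _exhaustive_kmeans_inertia(X: np.ndarray, k: int) -> float:
    """Global k-means optimum by enumeration of all label assignments."""
    n = X.shape[0]
    labels = np.array(list(itertools.product(range(k), repeat=n)))
    sq = float((X**2).sum())
    best = np.full(labels.shape[0], sq)
    reduction = np.zeros(labels.shape[0])
    for c in range(k):
        member = labels == c
        counts = member.sum(axis=1)
        sums = member.astype(float) @ X
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (sums**2).sum(axis=1) / counts
        term[counts == 0] = 0.0
        reduction += term
    return float((sq - reduction).min())


def kmeans_oracle_experiment(seed: int, n_trials: int = 100, n_points: int = 10,
                             k: int = 3) -> dict:
    """Fraction of trials where restarted k-means attains the global optimum.

    Small 2-D Gaussian-mixture instances are solved both by the package's
    k-means (k-means++ with 10 restarts) and by exhaustive enumeration of
    all partitions; a trial succeeds when the inertias agree to 1e-9
    relative.
    """
    st = _streams(seed)
    rng = np.random.default_rng(int(st[17]))
    hits = 0
    for trial in range(n_trials):
        centers = rng.uniform(-2, 2, size=(k, 2))
        X = centers[rng.integers(k, size=n_points)] + rng.standard_normal((n_points, 2))
        est = CommonKMeans(k=k, n_init=10, seed=int(rng.integers(2**31))).fit(X)
        opt = _exhaustive_kmeans_inertia(X, k)
        if est.inertia_ <= opt * (1 + 1e-9) + 1e-12:
            hits += 1
    return {"global_optimum_rate": hits / n_trials, "n_trials": n_trials}


def run_all(seed: int) -> dict:
    """All acceptance experiments; returns {name: {value, n}} JSON structure."""
    out = {}
    c = cluster_count_experiment(seed)
    out["tissue_clusters"] = {"value": c["tissue_clusters"], "n": c["n_pixels"]}
    out["oct_clusters"] = {"value": c["oct_clusters"], "n": c["n_pixels"]}
    out["segmentation_mapped_ari"] = {"value": round(c["segmentation_ari"], 4),
                                      "n": c["n_pixels"]}
    out["oct_clusters_form_clade"] = {"value": int(c["oct_forms_clade"]),
                                      "n": c["n_pixels"]}
    out["emsc_outlier_recall_pct"] = {"value": round(100 * c["outlier_recall"], 2),
                                      "n": c["n_pixels"]}
    out["emsc_outlier_false_positive_pct"] = {
        "value": round(100 * c["outlier_fpr"], 2), "n": c["n_pixels"]}

    p = pca_discrimination_experiment(seed)
    out["fingerprint_gm_dz_overlapping"] = {
        "value": int(p["fingerprint_gm_dz_overlapping"]), "n": p["n_samples"]}
    out["sulfation_gm_separated_count"] = {
        "value": p["sulfation_gm_separated_count"], "n": p["n_samples"]}

    o = operator_oracle_experiment(seed)
    out["sg_cubic_max_err"] = {"value": o["sg_cubic_max_err"], "n": 226}
    out["rubber_band_affine_max_err"] = {"value": o["rubber_band_affine_max_err"],
                                         "n": 226}
    out["emsc_span_max_err"] = {"value": o["emsc_span_max_err"], "n": 226}
    out["emsc_b_recovery_r"] = {"value": round(o["emsc_b_recovery_r"], 5),
                                "n": 128 * 64}
    out["corrmap_affine_invariance_max_dev"] = {
        "value": o["corrmap_affine_invariance_max_dev"], "n": 128 * 64}
    out["ellipse_coverage_pct"] = {"value": round(100 * o["ellipse_coverage"], 2),
                                   "n": 10_000}
    out["vapor_mse_reduction_pct"] = {
        "value": round(100 * o["vapor_mse_reduction"], 2), "n": 128 * 64}

    m = corrmap_profile_experiment(seed)
    out["hs_ors_minus_dz_correlation"] = {"value": round(m["hs_ors_minus_dz"], 4),
                                          "n": 128 * 64}
    out["hs_irs_catagen_minus_anagen"] = {
        "value": round(m["hs_irs_catagen_minus_anagen"], 4), "n": 128 * 64}
    out["ha_irs_minus_ors_correlation"] = {"value": round(m["ha_irs_minus_ors"], 4),
                                           "n": 128 * 64}

    k = kmeans_oracle_experiment(seed)
    out["kmeans_global_optimum_rate_pct"] = {
        "value": round(100 * k["global_optimum_rate"], 1), "n": k["n_trials"]}
    return out
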