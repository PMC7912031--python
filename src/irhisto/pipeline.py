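"""End-to-end pipeline orchestration with a reproducibility manifest.

A run executes, as enabled by the configuration: phantom generation (one
image per phase) -> atmospheric correction -> common EMSC -> region
extraction + preprocessing + windowed PCA / common k-means / correlation
maps.  Every produced file is recorded in the manifest with a content hash,
so identical configs and seeds produce identical manifests for text
artifacts.  All randomness flows from the single master seed through named
per-stage substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corrmap import correlate_image, render_map, structure_profile
from .emsc import correct_images
from .io import write_cube, write_jcamp, write_label_map
from .pca import region_mean_spectra, run_pca
from .phantom import PHASES, PhantomConfig, generate, reference_spectra
from .preprocess import atmospheric_correct
from .segmentation import annotate_clusters, centroid_dendrogram, common_kmeans
from .spectral_data import SpectralWindow, ValidationError

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

PCA_STRUCTURES = ["germinative_matrix", "differentiation_zone", "IRS", "ORS",
                  "hair_shaft"]


@dataclass
class RunConfig:
    """Flat configuration: one mapping per stage, plus seed and output dir."""

    seed: int = 0
    out_dir: str = "irhisto_run"
    log_level: str = "INFO"
    phantom: dict = field(default_factory=lambda: {"enabled": True,
                                                   "phases": list(PHASES)})
    emsc: dict = field(default_factory=lambda: {"enabled": True, "poly_order": 2})
    pca: dict = field(default_factory=lambda: {"enabled": True,
                                               "windows": [[900, 1800], [1190, 1350]],
                                               "n_components": 3})
    kmeans: dict = field(default_factory=lambda: {"enabled": True, "k": 10,
                                                  "window": [800, 1800],
                                                  "n_init": 10})
    corrmap: dict = field(default_factory=lambda: {"enabled": True,
                                                   "references": ["HS", "GPC1", "HA"]})


@dataclass
class RunManifest:
    """Record of one pipeline run: config, versions, hashes, warnings."""

    config: dict
    version: str
    seed: int
    files: dict[str, str] = field(default_factory=dict)      # path -> sha256
    warnings: list[str] = field(default_factory=list)
    timings_s: dict[str, float] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    """Load a TOML or YAML run configuration."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute the enabled stages and write all artifacts plus a manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(cfg), version=__version__, seed=cfg.seed)
    streams = np.random.SeedSequence(cfg.seed).generate_state(16) % (2**31)

    def record(path: Path):
        manifest.files[str(path.relative_to(out))] = _sha256(path)

    def stage(name):
        t0 = time.perf_counter()
        return lambda: manifest.timings_s.__setitem__(
            name, round(time.perf_counter() - t0, 3))

    if not cfg.phantom.get("enabled", True):
        raise ValidationError("pipeline currently requires the phantom stage")

    done = stage("phantom")
    truths = []
    for i, phase in enumerate(cfg.phantom.get("phases", list(PHASES))):
        pcfg = PhantomConfig(phase=phase, seed=int(streams[i]),
                             **cfg.phantom.get("config", {}))
        truth = generate(pcfg)
        truths.append(truth)
        write_cube(truth.image, out / f"phantom_{phase}.h5", "hdf5-cube")
        record(out / f"phantom_{phase}.h5")
        write_label_map(truth.labels, out / f"labels_{phase}.csv")
        record(out / f"labels_{phase}.csv")
    refs = reference_spectra(truths[0].image.axis)
    for name, spec in refs.items():
        write_jcamp(spec, out / f"ref_{name}.jdx")
        record(out / f"ref_{name}.jdx")
    done()

    done = stage("atmospheric")
    images = []
    for truth in truths:
        img = truth.image
        if truth.vapor is not None:
            img = atmospheric_correct(img, truth.vapor)
        images.append(img)
    # correlation maps run on atmospheric-corrected (non-normalized) pixels;
    # Pearson r is gain/offset invariant, so EMSC is unnecessary there and
    # its b-normalization would re-weight band shapes
    atm_images = list(images)
    done()

    results = None
    if cfg.emsc.get("enabled", True):
        done = stage("emsc")
        results = correct_images(images, poly_order=int(cfg.emsc.get("poly_order", 2)))
        for truth, res in zip(truths, results):
            phase = truth.image.name.split("_")[1]
            pd.DataFrame(res.b_map).to_csv(out / f"emsc_b_{phase}.csv",
                                           index=False, header=False)
            record(out / f"emsc_b_{phase}.csv")
        images = [res.corrected for res in results]
        done()

    if cfg.pca.get("enabled", True):
        done = stage("pca")
        rng = np.random.default_rng(int(streams[8]))
        sset = None
        for truth, img in zip(truths, images):
            s = region_mean_spectra(img, truth.labels, PCA_STRUCTURES,
                                    zone_size=2, n_zones=3, rng=rng)
            sset = s if sset is None else sset.extend(s)
        for lo, hi in cfg.pca.get("windows", [[900, 1800], [1190, 1350]]):
            res = run_pca(sset, SpectralWindow(lo, hi),
                          n_components=int(cfg.pca.get("n_components", 3)))
            tag = f"{int(hi)}_{int(lo)}"
            pd.DataFrame(res.scores,
                         index=pd.Index(res.group, name="group")).to_csv(
                out / f"pca_scores_{tag}.csv")
            record(out / f"pca_scores_{tag}.csv")
            pd.DataFrame(res.loadings, columns=res.axis.values).to_csv(
                out / f"pca_loadings_{tag}.csv", index=False)
            record(out / f"pca_loadings_{tag}.csv")
        done()

    if cfg.kmeans.get("enabled", True):
        done = stage("kmeans")
        lo, hi = cfg.kmeans.get("window", [800, 1800])
        window = SpectralWindow(lo, hi)
        clamped = window.clamp_to(images[0].axis)
        if (clamped.lo, clamped.hi) != (window.lo, window.hi):
            manifest.warnings.append(
                f"kmeans window [{window.lo}, {window.hi}] clamped to "
                f"[{clamped.lo}, {clamped.hi}]")
        model, maps = common_kmeans(images, k=int(cfg.kmeans.get("k", 10)),
                                    window=window, seed=int(streams[9]),
                                    n_init=int(cfg.kmeans.get("n_init", 10)))
        pd.DataFrame(model.centroids).to_csv(out / "kmeans_centroids.csv",
                                             index=False, header=False)
        record(out / "kmeans_centroids.csv")
        for truth, lab in zip(truths, maps.labels):
            phase = truth.image.name.split("_")[1]
            pd.DataFrame(lab).to_csv(out / f"kmeans_labels_{phase}.csv",
                                     index=False, header=False)
            record(out / f"kmeans_labels_{phase}.csv")
        dend = centroid_dendrogram(model)
        (out / "kmeans_dendrogram.nwk").write_text(dend.newick + "\n")
        record(out / "kmeans_dendrogram.nwk")
        annotation = annotate_clusters(maps, [t.labels for t in truths])
        with open(out / "kmeans_annotation.json", "w") as fh:
            json.dump({str(c): {"structure": s, "purity": p}
                       for c, (s, p) in annotation.items()}, fh, indent=1)
        record(out / "kmeans_annotation.json")
        done()

    if cfg.corrmap.get("enabled", True):
        done = stage("corrmap")
        for truth, img in zip(truths, atm_images):
            phase = truth.image.name.split("_")[1]
            for ref_name in cfg.corrmap.get("references", ["HS", "GPC1", "HA"]):
                cmap = correlate_image(img, refs[ref_name])
                stem = f"corrmap_{ref_name}_{phase}"
                pd.DataFrame(cmap.values).to_csv(out / f"{stem}.csv",
                                                 index=False, header=False)
                record(out / f"{stem}.csv")
                render_map(cmap, out / f"{stem}.png")
                record(out / f"{stem}.png")
                profile = structure_profile(cmap, truth.labels)
                pd.DataFrame(profile, index=["mean", "sd"]).T.to_csv(
                    out / f"{stem}_profile.csv")
                record(out / f"{stem}_profile.csv")
        done()

    manifest.save(out / "manifest.yaml")
    return manifest
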