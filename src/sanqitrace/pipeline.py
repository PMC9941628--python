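"""End-to-end orchestration of the two analyses.

`run_traceability` drives the imaging/classification chain: obtain
spectra (from files or the simulator), average replicate scans, window to
the 7000–4000 cm^-1 fingerprint region, build one synchronous 2D-COS map
per sample, render 128x128 RGB images, split 60/30/10 stratified by
origin, train the 32-layer residual network, and write images, curves,
confusion matrices, and a hashed manifest.

`run_climate` drives the chemometric chain: Pearson collinearity screen
of the climate factors, per-origin saponin summary, PCA of the contents,
one PLS regression per saponin with VIP selection, and CSV reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from . import twodcos
from .chemometrics import (
    pca_fit,
    pearson_screen,
    plsr_fit,
    saponin_summary,
    vip_select,
)
from .spectra import average_replicates, read_spectra, select_band
from .synthetic import (
    SAPONINS,
    ClimateSimConfig,
    SpectraSimConfig,
    simulate_climate_table,
    simulate_spectra,
)

__all__ = ["PipelineConfig", "run_traceability", "run_climate"]

log = logging.getLogger("sanqitrace")


@dataclass
class PipelineConfig:
    """One config object for both pipelines; exactly one source per input."""

    outdir: str | Path = "sanqitrace_out"
    # spectra source: either a file (+format) or a simulation config
    spectra_path: str | Path | None = None
    spectra_format: str = "long"
    labels_path: str | Path | None = None
    spectra_sim: SpectraSimConfig | None = None
    # climate source
    climate_path: str | Path | None = None
    climate_sim: ClimateSimConfig | None = None
    # stage parameters (defaults = the study protocol)
    band_high: float = 7000.0
    band_low: float = 4000.0
    map_mode: str = "self-outer"
    image_size: int = 128
    pearson_threshold: float = 0.8
    split_fractions: tuple[float, float, float] = (0.6, 0.3, 0.1)
    split_seed: int = 0
    net_spec: clf.NetSpec = field(default_factory=clf.NetSpec)
    train: clf.TrainConfig = field(default_factory=clf.TrainConfig)
    write_images: bool = True

    def __post_init__(self) -> None:
        if self.spectra_path is not None and self.spectra_sim is not None:
            raise ValueError("give spectra as a file OR a simulation, not both")
        if self.climate_path is not None and self.climate_sim is not None:
            raise ValueError("give the climate table as a file OR a simulation")


def _stage(name: str):
    log.info("== %s ==", name)
    return time.time()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, entries: dict) -> Path:
    files = sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": entries,
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    out = outdir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return out


def _load_spectra(config: PipelineConfig):
    if config.spectra_sim is not None or config.spectra_path is None:
        sim = config.spectra_sim or SpectraSimConfig()
        collection, labels = simulate_spectra(sim)
        return collection, labels, {"source": "simulated", "seed": sim.seed}
    collection = read_spectra(config.spectra_path, format=config.spectra_format)
    if config.labels_path is not None:
        labels = pd.read_csv(config.labels_path)
    else:
        labels = pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in collection],
                "label": [str(s.meta.get("label", "")) for s in collection],
            }
        )
    if (labels["label"] == "").any():
        raise ValueError("traceability stage: missing class labels for some samples")
    return collection, labels, {"source": str(config.spectra_path)}


def build_images(config: PipelineConfig):
    """Spectra -> averaged -> windowed -> per-sample map -> rendered image."""
    collection, labels, provenance = _load_spectra(config)
    label_of = dict(zip(labels["sample_id"].astype(str), labels["label"].astype(str)))
    images, ids, y_names = [], [], []
    for sample in collection:
        avg = average_replicates(sample)
        windowed = select_band(avg, config.band_high, config.band_low)
        if config.map_mode == "replicates":
            windowed_raw = select_band(sample, config.band_high, config.band_low)
            smap = twodcos.per_sample_map(windowed_raw, mode="replicates")
        else:
            smap = twodcos.per_sample_map(windowed, mode=config.map_mode)
        img = twodcos.render_image(smap, size=config.image_size)
        images.append(img)
        ids.append(sample.sample_id)
        y_names.append(label_of.get(sample.sample_id, str(sample.meta.get("label", ""))))
    classes = sorted(set(y_names))
    y = np.array([classes.index(n) for n in y_names])
    pixels = (
        np.stack([im.pixels for im in images]).astype(np.float32) / 255.0
    ).transpose(0, 3, 1, 2)
    return images, pixels, ids, y, classes, provenance


def run_traceability(config: PipelineConfig) -> dict:
    """Run the full origin-traceability pipeline; returns a report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = _stage("spectra -> 2D-COS images")
    images, pixels, ids, y, classes, provenance = build_images(config)
    log.info("rendered %d images in %.1fs", len(images), time.time() - t0)

    _stage("stratified split")
    split = clf.stratified_split(y, config.split_fractions, seed=config.split_seed)
    part_of = np.empty(len(ids), dtype=object)
    for name in ("train", "test", "external"):
        part_of[split.partition(name)] = name
    index = pd.DataFrame(
        {"sample_id": ids, "class": [classes[c] for c in y], "split": part_of}
    )
    index.to_csv(outdir / "image_index.csv", index=False)
    if config.write_images:
        img_dir = outdir / "images"
        img_dir.mkdir(exist_ok=True)
        for im, sid in zip(images, ids):
            twodcos.save_image(im, img_dir / f"{sid}.png")

    t0 = _stage("train residual network")
    model = clf.build_network(config.net_spec, n_classes=len(classes),
                              seed=config.train.seed)
    report = clf.train(model, pixels, y, split, config.train)
    log.info(
        "trained %d epochs in %.1fs; accuracy train/test/external = %s",
        report.epochs_run,
        time.time() - t0,
        {k: round(v, 4) for k, v in report.accuracy.items()},
    )

    curves = pd.DataFrame(
        {
            "epoch": np.arange(1, report.epochs_run + 1),
            "train_acc": report.train_acc,
            "test_acc": report.test_acc,
            "train_loss": report.train_loss,
            "test_loss": report.test_loss,
            "train_acc_smooth": report.smoothed("train_acc", config.train.smoothing),
            "test_acc_smooth": report.smoothed("test_acc", config.train.smoothing),
            "train_loss_smooth": report.smoothed("train_loss", config.train.smoothing),
            "test_loss_smooth": report.smoothed("test_loss", config.train.smoothing),
        }
    )
    curves.to_csv(outdir / "curves.csv", index=False)
    for name, cm in report.confusion.items():
        pd.DataFrame(cm, index=classes, columns=classes).to_csv(
            outdir / f"confusion_{name}.csv"
        )
    manifest = _write_manifest(
        outdir,
        {
            "pipeline": "traceability",
            "provenance": provenance,
            "classes": classes,
            "band": [config.band_high, config.band_low],
            "map_mode": config.map_mode,
            "image_size": config.image_size,
            "split_fractions": list(config.split_fractions),
            "split_seed": config.split_seed,
            "train": vars(config.train),
            "epochs_run": report.epochs_run,
        },
    )
    return {
        "report": report,
        "split": split,
        "classes": classes,
        "index": index,
        "manifest_path": manifest,
        "outdir": outdir,
    }


def run_climate(config: PipelineConfig) -> dict:
    """Run the chemometric pipeline; returns a report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _stage("load climate/saponin table")
    if config.climate_sim is not None or config.climate_path is None:
        sim = config.climate_sim or ClimateSimConfig()
        table = simulate_climate_table(sim)
    else:
        table = pd.read_csv(config.climate_path)

    _stage("pearson screen")
    retained, corr = pearson_screen(table, threshold=config.pearson_threshold)
    corr.to_csv(outdir / "correlation_matrix.csv")
    dropped = [c for c in corr.columns if c not in retained]
    pd.DataFrame({"retained": pd.Series(retained), "dropped": pd.Series(dropped)}).to_csv(
        outdir / "screening.csv", index=False
    )

    _stage("saponin summary")
    summary = saponin_summary(table)
    summary.to_csv(outdir / "content_summary.csv")

    _stage("pca")
    pca = pca_fit(table[list(SAPONINS)])
    pd.DataFrame(
        {
            "component": np.arange(1, len(pca.explained_variance_pct) + 1),
            "explained_variance_pct": pca.explained_variance_pct,
            "cumulative_pct": np.cumsum(pca.explained_variance_pct),
        }
    ).to_csv(outdir / "pca_variance.csv", index=False)

    _stage("plsr + vip")
    fits, equations, vip_rows = {}, [], []
    for s in SAPONINS:
        fit = plsr_fit(table, s, predictors=retained, n_components=len(retained))
        fits[s] = fit
        equations.append({"saponin": s, "equation": fit.equation()})
        for name, v in zip(fit.predictors, fit.vip):
            vip_rows.append(
                {"saponin": s, "variable": name, "vip": v,
                 "selected": name in vip_select(fit)}
            )
    pd.DataFrame(equations).to_csv(outdir / "equations.csv", index=False)
    pd.DataFrame(vip_rows).to_csv(outdir / "vip.csv", index=False)
    manifest = _write_manifest(
        outdir,
        {
            "pipeline": "climate",
            "pearson_threshold": config.pearson_threshold,
            "retained": retained,
        },
    )
    return {
        "retained": retained,
        "summary": summary,
        "pca": pca,
        "fits": fits,
        "manifest_path": manifest,
        "outdir": outdir,
    }
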