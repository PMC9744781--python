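"""End-to-end pipeline driver, configuration, logging, and plotting.

``run_pipeline`` composes the stages — simulate, band-pass filter, epoch,
reject, baseline, average, extract features, run the contrast battery,
decode — one subject at a time (a full subject's continuous record is
large; evoked responses are small), writing a manifest of every artifact
it produces.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import io as eio
from .average import average_epochs
from .classify import evaluate_loso
from .features import extract_feature_table, marker_registry
from .montage import build_default_montage, project_2d
from .preprocess import (
    DEFAULT_BAND,
    DEFAULT_REJECT_UV,
    bandpass,
    baseline_correct,
    extract_epochs,
    reject_artifacts,
)
from .simulate import SimulationConfig, default_templates, simulate_subject
from .stats import run_paper_contrasts

__all__ = ["PipelineConfig", "run_pipeline", "process_subject",
           "plot_topomap", "plot_waveforms"]

log = logging.getLogger("erpmark")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration (YAML-addressable, seed-propagating)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    band_low_hz: float = DEFAULT_BAND[0]
    band_high_hz: float = DEFAULT_BAND[1]
    reject_uv: float = DEFAULT_REJECT_UV
    alpha: float = 0.01
    write_edf: bool = False   # continuous EDFs are bulky; opt in
    seed: int = 0

    def __post_init__(self):
        if self.seed != self.simulation.seed:
            self.simulation = dataclasses.replace(self.simulation,
                                                  seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            flat = yaml.safe_load(f) or {}
        sim_fields = {f.name for f in
                      dataclasses.fields(SimulationConfig)}
        sim_kw = {k: v for k, v in flat.items() if k in sim_fields}
        top_kw = {k: v for k, v in flat.items()
                  if k not in sim_fields and k != "categories"}
        if "seed" in flat:  # the seed is shared by both layers
            top_kw["seed"] = flat["seed"]
        if "categories" in flat:
            sim_kw["categories"] = tuple(flat["categories"])
        return cls(simulation=SimulationConfig(**sim_kw), **top_kw)

    def to_yaml(self, path) -> None:
        flat = dataclasses.asdict(self.simulation)
        flat["categories"] = list(flat["categories"])
        for f in dataclasses.fields(self):
            if f.name != "simulation":
                flat[f.name] = getattr(self, f.name)
        with open(path, "w") as fh:
            yaml.safe_dump(flat, fh, sort_keys=False)


def process_subject(config: PipelineConfig, subject: int,
                    montage=None, templates=None):
    """simulate -> filter -> epoch -> reject -> baseline -> per-category
    evokeds for one subject. Returns (evokeds dict, rejection stats)."""
    rec, sched = simulate_subject(config.simulation, subject,
                                  montage=montage, templates=templates)
    rec = bandpass(rec, config.band_low_hz, config.band_high_hz)
    epochs = extract_epochs(rec, sched)
    epochs = reject_artifacts(epochs, config.reject_uv)
    epochs = baseline_correct(epochs)
    # average every scheduled category; zero kept epochs for a category is
    # an explicit failure, never a silently absent evoked
    evokeds = {c: average_epochs(epochs, c)
               for c in config.simulation.categories}
    stats = {
        "subject": subject,
        "n_epochs": epochs.n_epochs,
        "n_kept": epochs.n_kept,
        "rejected_fraction": 1.0 - epochs.n_kept / epochs.n_epochs,
    }
    log.info("subject %d: kept %d/%d epochs", subject, epochs.n_kept,
             epochs.n_epochs)
    return evokeds, stats, (rec, sched, epochs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage for the whole cohort and write the artifact bundle:
    features.csv, anova.json, classification report, rejection summary and
    a manifest (path, stage, seed, sha256) per artifact."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = build_default_montage()
    templates = default_templates()
    manifest = []

    def register(path: Path, stage: str):
        manifest.append({
            "path": str(path.relative_to(out)), "stage": stage,
            "seed": config.seed, "sha256": _sha256(path),
        })

    evokeds_by_subject = {}
    rejection = []
    for subject in range(config.simulation.n_subjects):
        evokeds, stats, (rec, sched, _) = process_subject(
            config, subject, montage, templates
        )
        evokeds_by_subject[subject] = evokeds
        rejection.append(stats)
        ev_path = out / f"events_sub{subject:02d}.tsv"
        eio.write_events_tsv(sched, config.simulation.fs, ev_path)
        register(ev_path, "simulate")
        if config.write_edf:
            edf_path = out / f"eeg_sub{subject:02d}.edf"
            eio.write_edf(rec, edf_path)
            register(edf_path, "simulate")
        del rec

    table = extract_feature_table(evokeds_by_subject, marker_registry())
    feat_path = out / "features.csv"
    eio.write_feature_csv(table, feat_path)
    register(feat_path, "features")

    contrasts = run_paper_contrasts(table, alpha=config.alpha)
    anova_path = out / "anova.json"
    eio.write_anova_json(contrasts, anova_path)
    register(anova_path, "stats")

    report = evaluate_loso(table)
    cls_path = out / "classification.json"
    with open(cls_path, "w") as f:
        json.dump(report.as_dict(), f, indent=1)
    register(cls_path, "classify")
    conf_path = out / "confusion.csv"
    report.confusion.to_csv(conf_path)
    register(conf_path, "classify")

    rej_path = out / "rejection.json"
    with open(rej_path, "w") as f:
        json.dump(rejection, f, indent=1)
    register(rej_path, "preprocess")

    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)

    return {
        "features": table,
        "contrasts": contrasts,
        "classification": report,
        "rejection": rejection,
        "manifest": manifest,
    }


# --------------------------------------------------------------------------
# plotting
# --------------------------------------------------------------------------

def plot_topomap(evoked, window_ms: tuple[float, float], ax=None):
    """Interpolated scalp map of window-mean voltage on the head disc,
    symmetric color scale about zero. Returns the matplotlib figure."""
    from .preprocess import ms_to_sample
    from scipy.interpolate import griddata

    montage = evoked.montage
    onset = evoked.onset_index
    lo = onset + ms_to_sample(window_ms[0], evoked.fs)
    hi = onset + ms_to_sample(window_ms[1], evoked.fs)
    values = evoked.data[:montage.n_channels, lo:hi].mean(axis=1)
    pos = project_2d(montage)

    if ax is None:
        fig, ax = plt.subplots(figsize=(4, 4))
    else:
        fig = ax.figure
    grid = np.linspace(-1, 1, 101)
    gx, gy = np.meshgrid(grid, grid)
    gz = griddata(pos, values, (gx, gy), method="cubic")
    gz[gx ** 2 + gy ** 2 > 1] = np.nan
    vmax = max(np.nanmax(np.abs(gz)), 1e-12)
    im = ax.imshow(gz, extent=(-1, 1, -1, 1), origin="lower",
                   cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, lw=1.5))
    ax.scatter(pos[:, 0], pos[:, 1], s=4, c="k")
    ax.set_xlim(-1.1, 1.1); ax.set_ylim(-1.1, 1.1)
    ax.set_aspect("equal"); ax.axis("off")
    ax.set_title(f"{evoked.category} {window_ms[0]:g}-{window_ms[1]:g} ms")
    fig.colorbar(im, ax=ax, shrink=0.7, label="uV")
    return fig


def plot_waveforms(evokeds: dict, channels: list[str], ax=None):
    """Overlaid category traces at given channels, negative up, onset at
    0 ms (classic ERP plotting conventions)."""
    if not evokeds:
        raise ValueError("no evoked responses to plot")
    first = next(iter(evokeds.values()))
    montage = first.montage
    idx = [montage.index(c) for c in channels]  # raises on unknown channel

    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    for cat, ev in sorted(evokeds.items()):
        trace = ev.data[idx].mean(axis=0) if idx else np.zeros_like(ev.time_ms)
        ax.plot(ev.time_ms, trace, label=cat, lw=1)
    ax.invert_yaxis()  # negative up
    ax.axvline(0, color="k", lw=0.8)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (uV, negative up)")
    ax.set_title(", ".join(channels))
    ax.legend(fontsize=7)
    return fig
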