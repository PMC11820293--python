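"""End-to-end pipeline: simulate -> extract -> normalize -> classify -> fit
-> associate, with a manifest for reproducibility.

Each stage reads the previous stage's files from the output directory, so
stages can also be run individually (see :mod:`thermotype.cli`).  A fixed
seed makes the whole run byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__, assoc, cttyping, filling, normct, synthgen, thermal

log = logging.getLogger("thermotype")

STAGES = ("simulate", "extract", "normalize", "classify", "fit", "associate")


@dataclasses.dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Defaults describe the demo trial: 18 lines (4 cold, 4 warm, 10
    mediate) x 3 replicate plots, five measurement days per season, two
    seasons with a +1.5 degC ambient offset, pixel noise 0.2 degC.
    """

    out_dir: str = "run"
    seed: int = 0
    n_cold: int = 4
    n_warm: int = 4
    n_mediate: int = 10
    plots_per_line: int = 3
    grid_shape: tuple[int, int] = (8, 7)
    dates: Sequence[int] = (0, 6, 12, 18, 23)
    noise_sd: float = 0.2
    replicate_sd: float = 0.1
    soil_margin: float = 8.0
    mask_threshold: float | None = None  # None -> ambient + soil_margin/2
    epsilon: float = cttyping.DEFAULT_EPSILON
    normalization_order: str = "normalize_first"
    y_definition: str = "at_T"
    bh_correct: bool = False
    filling_noise_sd: float = 0.5
    trait_targets: dict = dataclasses.field(default_factory=lambda: {
        "Pn": (20.0, 3.0, -0.9),      # net photosynthetic rate, umol CO2/m2/s
        "Cond": (0.45, 0.08, -0.7),   # stomatal conductance, mol H2O/m2/s
        "Trmmol": (6.0, 1.2, -0.6),   # transpiration, mmol H2O/m2/s
        "GPC": (14.0, 1.5, 0.5),      # grain protein content, %
        "SV": (35.0, 5.0, 0.3),       # sedimentation value, mL
    })

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid_shape" in doc:
            doc["grid_shape"] = tuple(doc["grid_shape"])
        if "dates" in doc:
            doc["dates"] = tuple(doc["dates"])
        return cls(**doc)

    @property
    def n_lines(self) -> int:
        return self.n_cold + self.n_warm + self.n_mediate


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False)
    return len(df)


def _field_spec(cfg: RunConfig) -> tuple[synthgen.FieldSpec, dict]:
    offsets, slopes, true_types = synthgen.plant_line_effects(
        cfg.n_cold, cfg.n_warm, cfg.n_mediate, seed=cfg.seed)
    spec = synthgen.FieldSpec(
        n_lines=cfg.n_lines, plots_per_line=cfg.plots_per_line,
        grid_shape=cfg.grid_shape, line_offset=offsets, trend_slope=slopes,
        replicate_sd=cfg.replicate_sd, noise_sd=cfg.noise_sd,
        soil_margin=cfg.soil_margin, seed=cfg.seed)
    return spec, true_types


def stage_simulate(cfg: RunConfig, out: Path) -> dict:
    spec, true_types = _field_spec(cfg)
    layout = synthgen.build_layout(spec)
    layout.to_yaml(out / "layout.yaml")
    frames_dir = out / "frames"
    frames_dir.mkdir(exist_ok=True)
    truth_parts = []
    n_frames = 0
    for season in spec.seasons:
        frames, truth, _ = synthgen.make_thermal_frames(
            spec, cfg.dates, season, layout=layout)
        truth_parts.append(truth)
        for fr in frames:
            thermal.write_frame(fr, frames_dir / f"{season}_d{fr.date:02d}.tif")
            n_frames += 1
    truth = pd.concat(truth_parts, ignore_index=True)
    truth["true_type"] = truth["line"].map(true_types)
    _write_csv(truth, out / "truth_ct.csv")

    fill_spec = synthgen.FillingSpec.random(
        cfg.n_lines, seed=cfg.seed, noise_sd=cfg.filling_noise_sd)
    _write_csv(synthgen.make_filling_series(fill_spec), out / "filling.csv")
    truth_fill = pd.DataFrame(
        [{"line": l, "k": k, "a": a, "b": b}
         for l, (k, a, b) in fill_spec.params.items()])
    _write_csv(truth_fill, out / "truth_filling.csv")
    _write_csv(synthgen.demo_weather(), out / "weather.csv")
    return {"frames": n_frames, "truth_rows": len(truth)}


def stage_extract(cfg: RunConfig, out: Path) -> dict:
    layout = thermal.PlotLayout.from_yaml(out / "layout.yaml")
    spec, _ = _field_spec(cfg)
    rows = []
    for path in sorted((out / "frames").glob("*.tif")):
        frame = thermal.read_frame(path)
        thr = cfg.mask_threshold
        if thr is None:
            thr = float(frame.meta.get("ambient_c", 25.0)) + cfg.soil_margin / 2.0
        mask = thermal.apply_soil_mask(frame, thr)
        rows.append(thermal.extract_ct(frame, layout, mask=mask))
    ct = pd.concat(rows, ignore_index=True)
    n = _write_csv(ct, out / "ct_raw.csv")
    return {"ct_rows": n}


def stage_normalize(cfg: RunConfig, out: Path) -> dict:
    layout = thermal.PlotLayout.from_yaml(out / "layout.yaml")
    ct = pd.read_csv(out / "ct_raw.csv")
    rel = normct.normalize(ct, layout.adjacency, order=cfg.normalization_order)
    n = _write_csv(rel, out / "ct_relative.csv")
    offs = normct.season_offset_check(ct)
    _write_csv(offs, out / "season_offsets.csv")
    return {"rel_rows": n,
            "mean_season_offset_c": float(offs["diff"].mean())}


def stage_classify(cfg: RunConfig, out: Path) -> dict:
    rel = pd.read_csv(out / "ct_relative.csv")
    calls = cttyping.classify_table(rel, epsilon=cfg.epsilon)
    n = _write_csv(calls, out / "type_calls.csv")
    counts = calls["call"].value_counts().to_dict()
    return {"lines": n, "calls": counts}


def stage_fit(cfg: RunConfig, out: Path) -> dict:
    series = pd.read_csv(out / "filling.csv")
    fits = filling.fit_table(series, y_definition=cfg.y_definition)
    n = _write_csv(fits, out / "filling_fits.csv")
    (out / "filling_fits.json").write_text(
        json.dumps(fits.set_index("line").to_dict(orient="index"), indent=2,
                   sort_keys=True))
    return {"fits": n, "n_adequate": int(fits["adequate"].sum())}


def stage_associate(cfg: RunConfig, out: Path) -> dict:
    rel = pd.read_csv(out / "ct_relative.csv")
    calls = pd.read_csv(out / "type_calls.csv")
    trait_spec = synthgen.TraitSpec(traits=cfg.trait_targets, seed=cfg.seed)
    traits = synthgen.make_trait_table(trait_spec, rel, ct_col="rel_ct")
    _write_csv(traits, out / "traits.csv")
    panel = assoc.correlation_panel(
        traits, ["rel_ct", *cfg.trait_targets], bh_correct=cfg.bh_correct)
    _write_csv(panel, out / "corr_panel.csv")

    labelled = traits.merge(calls[["line", "call"]], on="line")
    cw = labelled[labelled["call"].isin(["cold", "warm"])]
    contrasts = {}
    for trait in cfg.trait_targets:
        c = assoc.group_contrast(cw, trait)
        c["comparison"] = " vs ".join(c["comparison"])
        c["pairwise_p"] = {f"{g1} vs {g2}": p for (g1, g2), p in c["pairwise_p"].items()}
        contrasts[trait] = c
    (out / "contrasts.json").write_text(json.dumps(contrasts, indent=2))

    weather = pd.read_csv(out / "weather.csv")
    summary = assoc.weather_summary(weather, window=(30, 42))
    (out / "weather_summary.json").write_text(json.dumps(summary, indent=2))
    return {"panel_cells": len(panel), "traits": len(cfg.trait_targets),
            "rain_fraction_pct": summary["fraction_pct_rounded"]}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "normalize": stage_normalize,
    "classify": stage_classify,
    "fit": stage_fit,
    "associate": stage_associate,
}


def run_stage(name: str, cfg: RunConfig) -> dict:
    """Run a single named stage against the config's output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("[%s] starting", name)
    info = _STAGE_FUNCS[name](cfg, out)
    log.info("[%s] done: %s", name, info)
    return info


def run_all(cfg: RunConfig) -> dict:
    """Execute all six stages and write a run manifest.

    The manifest records the package version, seed, per-stage summaries
    and a SHA-256 digest of every output file; identical config and seed
    yield an identical manifest.  Any stage error halts the run with the
    stage name attached.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}
    for name in STAGES:
        try:
            report["stages"][name] = run_stage(name, cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    report["files"] = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir()) if p.is_file() and p.suffix != ".json"
    }
    (out / "manifest.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
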