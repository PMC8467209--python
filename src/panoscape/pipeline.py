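"""End-to-end orchestration: scenes -> audits -> models -> tables.

A run is driven by one :class:`RunConfig` (YAML-serializable) and one root
seed; all stage randomness is split from that seed, so two runs with the
same config produce byte-identical CSV output.  Stages:

1. obtain scenes (load panorama/label pairs from a directory, or render
   synthetic ones);
2. audit every scene on both layers (constituent elements, colors) on the
   Hammer equal-area raster;
3. obtain responses (load a CSV, or simulate a cohort from the audits);
4. fit the linear models for the nine physiological indicators and the
   multinomial models for the three subjective ratings, per layer;
5. compute the 12x12 mixed correlation matrix;
6. write CSV tables, human-readable text renderings with significance
   stars, and a deterministic run manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .color import ColorRules, default_rules
from .metrics import (
    COLOR_COVARIATES,
    ELEMENT_COVARIATES,
    ClassScheme,
    audit_scene,
    audits_to_frame,
    covariate_table,
)
from .rasters import read_labels, read_rgb
from .simulate import (
    DEFAULT_SCHEME,
    EffectConfig,
    default_effects,
    generate_cohort,
    generate_scene,
    sample_scene_specs,
)
from .stats import (
    PHYSIOLOGICAL,
    SUBJECTIVE,
    correlate,
    fit_linear,
    fit_multinomial,
    render_correlation,
    render_linear,
    render_multinomial,
    tidy_linear,
    tidy_multinomial,
)

log = logging.getLogger("panoscape")

LAYERS = {"elements": ELEMENT_COVARIATES, "colors": COLOR_COVARIATES}


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    out_dir: str = "panoscape_run"
    seed: int = 0
    n_scenes: int = 39
    scene_width: int = 512
    projection_width: int | None = None  # default: preserve scene width
    connectivity: int = 8
    n_participants: int = 26
    scenes_per_participant: int = 12
    layers: tuple = ("elements", "colors")
    scenes_dir: str | None = None  # load instead of synthesize
    responses_path: str | None = None  # load instead of simulate
    scheme_path: str | None = None
    rules_path: str | None = None
    effects_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.layers = tuple(cfg.layers)
        return cfg

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["layers"] = list(self.layers)
        return d


@dataclass
class RunManifest:
    """Deterministic bookkeeping of a run: config snapshot, per-stage row
    counts (including the per-family valid N), and software version."""

    config: dict
    counts: dict
    version: str = __version__

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {"config": self.config, "counts": self.counts, "version": self.version},
                sort_keys=True,
            )
        )


def _load_scheme(cfg: RunConfig) -> ClassScheme:
    return ClassScheme.from_yaml(cfg.scheme_path) if cfg.scheme_path else DEFAULT_SCHEME


def _load_rules(cfg: RunConfig) -> ColorRules:
    return ColorRules.from_yaml(cfg.rules_path) if cfg.rules_path else default_rules()


def _load_effects(cfg: RunConfig) -> EffectConfig:
    eff = (
        EffectConfig.from_yaml(cfg.effects_path)
        if cfg.effects_path
        else default_effects()
    )
    eff.n_participants = cfg.n_participants
    eff.scenes_per_participant = cfg.scenes_per_participant
    return eff


def _gather_scenes(cfg: RunConfig, seed: int):
    """Yield (scene_id, rgb, labels, street_scale) tuples."""
    if cfg.scenes_dir:
        scenes = []
        root = Path(cfg.scenes_dir)
        meta_path = root / "scenes.yaml"
        meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
        for rgb_path in sorted(root.glob("*_rgb.png")):
            sid = rgb_path.name[: -len("_rgb.png")]
            rgb = read_rgb(rgb_path)
            labels = read_labels(root / f"{sid}_labels.png")
            scale = (meta.get(sid) or {}).get("street_scale", "medium")
            scenes.append((sid, rgb, labels, scale))
        if not scenes:
            raise FileNotFoundError(f"no '*_rgb.png' scenes under {root}")
        return scenes
    specs = sample_scene_specs(cfg.n_scenes, seed=seed, width=cfg.scene_width)
    scenes = []
    for spec in specs:
        rgb, labels, _ = generate_scene(spec)
        scenes.append((spec.scene_id, rgb, labels, spec.street_scale))
    return scenes


def validate_inputs(scenes, responses: pd.DataFrame | None, scheme: ClassScheme) -> list[str]:
    """Report-only input validation: 2:1 aspect, scheme label coverage,
    response schema and value ranges."""
    violations: list[str] = []
    for sid, rgb, labels, scale in scenes:
        if rgb.width != 2 * rgb.height:
            violations.append(f"{sid}: panorama aspect is not 2:1 ({rgb.width}x{rgb.height})")
        if labels.values.shape[:2] != rgb.values.shape[:2]:
            violations.append(f"{sid}: label raster not aligned to panorama")
        present = np.unique(labels.values[labels.valid_mask()])
        unmapped = [int(i) for i in present if int(i) not in scheme.mapping]
        if unmapped:
            violations.append(f"{sid}: label ids not covered by scheme: {unmapped}")
        if scale not in ("small", "medium", "large"):
            violations.append(f"{sid}: unknown street scale {scale!r}")
    if responses is not None:
        required = ["participant_id", "scene_id", "gender", "street_scale"]
        for col in required:
            if col not in responses.columns:
                violations.append(f"responses: missing column {col!r}")
        for col in ["EVA.In", "EVA.Co", "EVA.Vi"]:
            if col in responses:
                vals = pd.to_numeric(responses[col], errors="coerce").dropna()
                bad = vals[~vals.isin([1, 2, 3])]
                if len(bad):
                    violations.append(
                        f"responses: {col} outside {{1,2,3}} in {len(bad)} rows"
                    )
        for col in ["EEG.En", "EEG.Ex", "EEG.St", "EEG.Re", "EEG.In", "EEG.Fo"]:
            if col in responses:
                vals = pd.to_numeric(responses[col], errors="coerce").dropna()
                if ((vals < 0) | (vals > 1)).any():
                    violations.append(f"responses: {col} outside [0, 1]")
        for col in ["SCR.n", "SCR.Amp", "HR.Avg"]:
            if col in responses:
                vals = pd.to_numeric(responses[col], errors="coerce").dropna()
                if (vals < 0).any():
                    violations.append(f"responses: {col} negative")
    return violations


def run_all(cfg: RunConfig) -> RunManifest:
    """Execute the full pipeline; returns the manifest after writing all
    outputs under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = out / "tables"
    tables.mkdir(exist_ok=True)

    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    seeds = np.random.SeedSequence(cfg.seed).spawn(2)
    scene_seed = int(seeds[0].generate_state(1)[0] % (2**31 - 1))
    cohort_seed = int(seeds[1].generate_state(1)[0] % (2**31 - 1))

    scheme = _load_scheme(cfg)
    rules = _load_rules(cfg)

    stage = "scenes"
    try:
        scenes = _gather_scenes(cfg, scene_seed)
        log.info("gathered %d scenes", len(scenes))

        stage = "auditing"
        audits = []
        for sid, rgb, labels, scale in scenes:
            a, c = audit_scene(
                labels,
                rgb,
                scheme,
                rules,
                street_scale=scale,
                scene_id=sid,
                out_width=cfg.projection_width,
                connectivity=cfg.connectivity,
            )
            audits.extend([a, c])
        audit_frame = audits_to_frame(audits)
        audit_frame.to_csv(out / "audits.csv", index=False)
        wide = covariate_table(audit_frame)

        stage = "responses"
        if cfg.responses_path:
            responses = pd.read_csv(cfg.responses_path)
        else:
            responses = generate_cohort(wide, _load_effects(cfg), seed=cohort_seed)
        responses.to_csv(out / "responses.csv", index=False)

        violations = validate_inputs(scenes, responses, scheme)
        for v in violations:
            log.warning("validation: %s", v)

        stage = "model fitting"
        data = responses.merge(
            wide.drop(columns=["street_scale"]), on="scene_id", how="left"
        )
        for layer in cfg.layers:
            covs = LAYERS[layer]
            lin = [
                fit_linear(data, covs, y, drop_collinear=True) for y in PHYSIOLOGICAL
            ]
            tidy_linear(lin).to_csv(tables / f"linear_{layer}.csv", index=False)
            (tables / f"linear_{layer}.txt").write_text(render_linear(lin))
            mn = [
                fit_multinomial(data, covs, y, drop_collinear=True) for y in SUBJECTIVE
            ]
            tidy_multinomial(mn).to_csv(tables / f"multinomial_{layer}.csv", index=False)
            (tables / f"multinomial_{layer}.txt").write_text(render_multinomial(mn))

        stage = "correlation"
        corr = correlate(responses)
        corr.r.to_csv(tables / "correlations.csv")
        corr.p.to_csv(tables / "correlations_p.csv")
        (tables / "correlations.txt").write_text(render_correlation(corr))
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    counts = {
        "scenes_audited": len(scenes),
        "records": len(responses),
        "valid_eeg": int(responses["EEG.En"].notna().sum()),
        "valid_scr": int(responses["SCR.n"].notna().sum()),
        "valid_hr": int(responses["HR.Avg"].notna().sum()),
        "valid_eva": int(responses["EVA.In"].notna().sum()),
        "validation_violations": len(violations),
    }
    manifest = RunManifest(config=cfg.to_dict(), counts=counts)
    manifest.to_yaml(out / "manifest.yaml")
    return manifest
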