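"""End-to-end pipeline: catalog -> pool -> design -> simulate -> analyze -> models.

Every stage derives its own seed deterministically from the master seed,
writes its outputs into a stage subdirectory of the run directory, and
records a checksum in ``manifest.json``.  Re-running resumes: a stage
whose outputs exist with matching config fingerprint is loaded from disk
instead of recomputed, so deleting one stage directory recomputes only
that stage and its dependents.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .image import GrayImage
from . import design as design_mod
from . import gaze as gaze_mod
from . import models as models_mod
from . import stimgen
from . import synth

__all__ = ["PipelineConfig", "run_end_to_end", "analyze_simulation", "stage_seed"]

STAGES = ("catalog", "pool", "design", "simulate", "analyze", "models")


@dataclass
class PipelineConfig:
    """All tunables of the pipeline; round-trips through YAML unchanged."""

    # geometry (stimulus pixels; 40 px per visual degree)
    width: int = 1280
    height: int = 1024
    target_diameter: int = 235
    ring_radius: float = 355.0
    n_locations: int = 10
    px_per_degree: float = 40.0
    # rendering
    hues: tuple[int, ...] = (90, 210, 330)
    saturation: float = 1.0
    blur_sigma: float = 8.0
    annulus_width: float = 24.0
    # salience screening
    screening: bool = True
    theta_target: float = 0.25
    theta_rival: float = 0.10
    # catalog / pool
    n_per_category: int = 9
    n_candidates: int = 320
    # design
    n_versions: int = 8
    trials_per_version: int = 36
    congruency_tolerance: int = 1
    # simulation
    n_participants: int = 39
    group: str = "infant"
    runs_per_participant: int = 1
    effects: dict = field(default_factory=dict)
    # trial rules
    dwell_ms: float = 100.0
    timeout_ms: float = 4500.0
    hit_min_prop: float = 0.8
    # seeds
    master_seed: int = 7
    write_gaze_csv: bool = True

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["hues"] = list(d["hues"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["hues"] = tuple(d.get("hues", (90, 210, 330)))
        return cls(**d)

    def fingerprint(self, keys: tuple[str, ...] | None = None) -> str:
        d = asdict(self)
        d["hues"] = list(d["hues"])
        if keys is not None:
            d = {k: d[k] for k in keys}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(p for p in path.rglob("*") if p.is_file()):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()


def _ring(cfg: PipelineConfig):
    return stimgen.ring_locations(
        cfg.width, cfg.height, cfg.ring_radius, cfg.n_locations, target_diameter=cfg.target_diameter
    )


def analyze_simulation(
    sim: synth.SimOutput,
    design: design_mod.ExperimentDesign,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Re-derive trial outcomes from simulated gaze and build the model table.

    Applies hit detection against the target-disk mask of each trial's
    location, the inclusion rules, and merges the design predictors; the
    result is the standardized trial-level analysis table.
    """
    cfg = cfg or PipelineConfig()
    ring = _ring(cfg)
    masks = {
        i: stimgen._disk_mask((cfg.height, cfg.width), pos, cfg.target_diameter / 2.0)
        for i, pos in enumerate(ring.positions)
    }
    truth = sim.truth.set_index("trial_id")
    positions = [tuple(map(float, p)) for p in ring.positions]
    outcomes = []
    trial_fixations = []
    for trial in sim.trials:
        info = truth.loc[trial.trial_id] if trial.trial_id in truth.index else None
        loc = int(info["location_idx"])
        out = gaze_mod.analyze_trial(
            trial,
            masks[loc],
            positions=positions,
            aoi_radius=cfg.target_diameter / 2.0,
            dwell_ms=cfg.dwell_ms,
            timeout_ms=cfg.timeout_ms,
        )
        outcomes.append((out, info))
        trial_fixations.append((trial.participant_id, gaze_mod.detect_fixations(trial), loc))
    included, miss_threshold = gaze_mod.apply_inclusion(
        [o for o, _ in outcomes], hit_min_prop=cfg.hit_min_prop
    )
    rows = []
    for out, info in outcomes:
        if not out.included:
            continue
        drow = design.trials.loc[info["design_index"]]
        rec = dict(vars(out))
        rec["target_location_idx"] = int(info["location_idx"])
        rec["run"] = int(info["run"])
        for col in (
            "background_id", "target_source_id", "location_idx", "hue", "color",
            "bg_category", "tg_category", "category_congruency", "depth_congruency",
            "curvature", "regularity", "symmetry", "depth",
            "child_dissimilarity", "adult_dissimilarity",
            "diff_luminance", "diff_alpha", "diff_deviation", "diff_entropy", "diff_skew",
        ):
            rec[col] = drow[col]
        rows.append(rec)
    table = pd.DataFrame(rows)
    table.attrs["miss_threshold_ms"] = miss_threshold
    kept_fix = [tf for tf, (out, _) in zip(trial_fixations, outcomes) if out.included]
    table.attrs["aoi"] = gaze_mod.aoi_analysis(
        kept_fix, positions, aoi_radius=cfg.target_diameter / 2.0
    )
    return models_mod.build_model_table(table)


# ---------------------------------------------------------------- stage IO


def _save_catalog(cat: stimgen.Catalog, path: Path) -> None:
    (path / "images").mkdir(parents=True, exist_ok=True)
    for img_id, img in cat.images.items():
        img.save(path / "images" / f"{img_id}.png")
    meta = pd.DataFrame(
        {
            "image_id": list(cat.images),
            "category": [cat.categories[i] for i in cat.images],
            "depth_class": [cat.depth_classes[i] for i in cat.images],
            "curvature": [cat.rated[i].curvature for i in cat.images],
            "regularity": [cat.rated[i].regularity for i in cat.images],
            "symmetry": [cat.rated[i].symmetry for i in cat.images],
            "depth": [cat.rated[i].depth for i in cat.images],
        }
    )
    meta.to_csv(path / "labels.csv", index=False)
    cat.child_dissimilarity.to_csv(path / "child_dissim.csv")
    cat.adult_dissimilarity.to_csv(path / "adult_dissim.csv")
    rows = []
    for img_id, plist in cat.patches.items():
        for p in plist:
            rows.append(
                {"image_id": img_id, "patch_index": p.patch_index,
                 "cx": p.center_in_source[0], "cy": p.center_in_source[1],
                 "diameter": p.diameter}
            )
    pd.DataFrame(rows).to_csv(path / "patches.csv", index=False)


def _load_catalog(path: Path) -> stimgen.Catalog:
    meta = pd.read_csv(path / "labels.csv")
    images = {r.image_id: GrayImage.open(path / "images" / f"{r.image_id}.png")
              for r in meta.itertuples()}
    rated = {
        r.image_id: stimgen.RatedProperties(r.curvature, r.regularity, r.symmetry, r.depth)
        for r in meta.itertuples()
    }
    pt = pd.read_csv(path / "patches.csv")
    patches: dict[str, list] = {}
    for r in pt.itertuples():
        img = images[r.image_id]
        d = int(r.diameter)
        x0 = min(max(0, int(r.cx) - d // 2), img.width - d)
        y0 = min(max(0, int(r.cy) - d // 2), img.height - d)
        crop = GrayImage(img.levels[y0 : y0 + d, x0 : x0 + d])
        patches.setdefault(r.image_id, []).append(
            stimgen.TargetPatch(r.image_id, int(r.patch_index), (int(r.cx), int(r.cy)), d, crop)
        )
    return stimgen.Catalog(
        images=images,
        categories=dict(zip(meta.image_id, meta.category)),
        depth_classes=dict(zip(meta.image_id, meta.depth_class)),
        rated=rated,
        child_dissimilarity=pd.read_csv(path / "child_dissim.csv", index_col=0),
        adult_dissimilarity=pd.read_csv(path / "adult_dissim.csv", index_col=0),
        patches=patches,
    )


def run_end_to_end(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages, resuming completed ones; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {"stages": {}}
    manifest["config_fingerprint"] = cfg.fingerprint()
    manifest["master_seed"] = cfg.master_seed
    cfg.to_yaml(out / "config.yaml")

    def fresh(stage: str) -> bool:
        entry = manifest["stages"].get(stage)
        sdir = out / stage
        return (
            entry is not None
            and sdir.exists()
            and entry.get("fingerprint") == cfg.fingerprint()
            and entry.get("checksum") == _checksum(sdir)
        )

    def record(stage: str) -> None:
        manifest["stages"][stage] = {
            "fingerprint": cfg.fingerprint(),
            "seed": stage_seed(cfg.master_seed, stage),
            "checksum": _checksum(out / stage),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    current_stage = "catalog"
    try:
        # --- catalog
        cdir = out / "catalog"
        if fresh("catalog"):
            catalog = _load_catalog(cdir)
        else:
            catalog = synth.synth_catalog(
                seed=stage_seed(cfg.master_seed, "catalog"),
                n_per_category=cfg.n_per_category,
                size=(cfg.height, cfg.width),
                patch_diameter=cfg.target_diameter,
            )
            cdir.mkdir(exist_ok=True)
            _save_catalog(catalog, cdir)
            record("catalog")

        ring = _ring(cfg)

        current_stage = "pool"
        pdir = out / "pool"
        if fresh("pool"):
            pool = pd.read_csv(pdir / "manifest.csv")
        else:
            pool = stimgen.build_pool(
                catalog,
                ring,
                theta_target=cfg.theta_target,
                theta_rival=cfg.theta_rival,
                seed=stage_seed(cfg.master_seed, "pool"),
                n_candidates=cfg.n_candidates,
                screen=cfg.screening,
                blur_sigma=cfg.blur_sigma,
            )
            pdir.mkdir(exist_ok=True)
            pool.to_csv(pdir / "manifest.csv", index=False)
            record("pool")

        current_stage = "design"
        ddir = out / "design"
        if fresh("design"):
            trials = pd.read_csv(ddir / "design.csv")
            des = design_mod.ExperimentDesign(
                trials, cfg.n_versions, cfg.trials_per_version, cfg.congruency_tolerance
            )
        else:
            des = design_mod.build_design(
                pool,
                n_versions=cfg.n_versions,
                trials_per_version=cfg.trials_per_version,
                seed=stage_seed(cfg.master_seed, "design"),
                congruency_tolerance=cfg.congruency_tolerance,
            )
            ddir.mkdir(exist_ok=True)
            des.trials.to_csv(ddir / "design.csv", index=False)
            report = design_mod.audit_design(des)
            (ddir / "audit.json").write_text(
                json.dumps({"valid": report.valid, "violations": report.violations}, indent=2)
            )
            record("design")

        current_stage = "simulate"
        sdir = out / "simulate"
        effects = (
            synth.EffectSpec.adult(**cfg.effects)
            if cfg.group == "adult"
            else synth.EffectSpec.infant(**cfg.effects)
        )
        sim = synth.simulate_dataset(
            des,
            effects,
            n_participants=cfg.n_participants,
            group=cfg.group,
            seed=stage_seed(cfg.master_seed, "simulate"),
            ring=ring,
            width=cfg.width,
            height=cfg.height,
            runs_per_participant=cfg.runs_per_participant,
        )
        if not fresh("simulate"):
            sdir.mkdir(exist_ok=True)
            sim.truth.to_csv(sdir / "truth.csv", index=False)
            if cfg.write_gaze_csv:
                gaze_mod.write_gaze_csv(sim.trials, sdir / "gaze.csv")
            record("simulate")

        current_stage = "analyze"
        adir = out / "analyze"
        if fresh("analyze"):
            table = pd.read_csv(adir / "trials.csv")
        else:
            table = analyze_simulation(sim, des, cfg)
            adir.mkdir(exist_ok=True)
            table.to_csv(adir / "trials.csv", index=False)
            gaze_mod.performance_summary(table).to_csv(adir / "performance_summary.csv")
            record("analyze")

        current_stage = "models"
        mdir = out / "models"
        if not fresh("models"):
            suite = models_mod.run_model_suite(table, group=cfg.group)
            bias = models_mod.stimulus_bias_check(des.trials)
            mdir.mkdir(exist_ok=True)
            suite["results"].to_csv(mdir / "results.csv", index=False)
            (mdir / "decisions.json").write_text(json.dumps(suite["decisions"], indent=2, default=float))
            bias.to_csv(mdir / "bias_check.csv", index=False)
            aoi = table.attrs.get("aoi")
            if aoi is not None:
                count_fit = models_mod.aoi_count_model(aoi["counts"], n_aoi=cfg.n_locations)
                (mdir / "aoi_model.json").write_text(
                    json.dumps(
                        {
                            "lrt": vars(count_fit["lrt"]),
                            "contrast_p": count_fit["contrast_p"],
                            "overdispersion": count_fit["overdispersion"],
                            "chance_level": aoi["chance_level"],
                            "first_fixation_rates": aoi["first_fixation_rates"],
                        },
                        indent=2,
                        default=float,
                    )
                )
            record("models")
    except Exception as exc:  # noqa: BLE001 - halt with stage context, keep prior outputs
        raise RuntimeError(f"pipeline halted at stage {current_stage!r}: {exc}") from exc
    return out
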