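"""End-to-end orchestration: simulate fixtures, run every analysis stage,
write a machine-readable report.

All randomness flows from one root seed; each stage derives its own
substream so stages stay reproducible independently of each other. Reports
carry no timestamps, so identical configs produce byte-identical JSON.
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

from . import benchmarks, envsites, soil
from .brt import BRTConfig, cv_auc, fit_brt, relative_influence
from .detection import DetectionParams, detect_circles, evaluate_detection, write_detections_csv
from .envelope import fit_quantile_piecewise, fraction_above
from .fieldstats import SummaryStat, fold_ratio, interior_correlation, t_test_summary
from .geometry import CirclePattern
from .spatial import clark_evans, summarize_patterns

__all__ = ["RunConfig", "run_simulate", "run_full"]

logger = logging.getLogger("fairycircles")


@dataclass
class RunConfig:
    """Declarative run configuration (YAML-loadable)."""

    seed: int = 0
    out_dir: str = "fc_run"
    # simulate stage
    n_circles: int = 100
    pixel_scale: float = 0.5
    n_env_sites: int = 500
    label_noise: float = 0.05
    n_soil_sites: int = 5
    soil_noise_sd: float = 0.1
    # detection stage
    detection: dict = field(default_factory=dict)
    # niche stage (scaled so learning_rate * n_trees stays near 3.6)
    brt_learning_rate: float = 0.01
    brt_n_trees: int = 360
    brt_cv_folds: int = 5
    # envelope stage
    envelope_n: int = 800
    tau: float = 0.9

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage substream derived from the root seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_simulate(config: RunConfig) -> dict:
    """Generate every synthetic input (pattern CSV, raster PNG, env CSV,
    soil CSVs) and write a manifest with parameters, seed and checksums."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    pattern, image = benchmarks.detection_scene(
        seed=config.stage_seed("scene"),
        n_circles=config.n_circles,
        pixel_scale=config.pixel_scale,
    )
    pattern.to_csv(out / "circles_true.csv")
    image.write_png(out / "landscape.png")

    env = envsites.gen_env_presence(
        config.n_env_sites,
        label_noise=config.label_noise,
        seed=config.stage_seed("env"),
    )
    env.to_csv(out / "env_sites.csv", index=False)

    transect = soil.gen_soil_transect(
        n_sites=config.n_soil_sites,
        noise_sd=config.soil_noise_sd,
        seed=config.stage_seed("transect"),
    )
    soil.samples_to_dataframe(transect).to_csv(out / "soil_transect.csv", index=False)
    paired = soil.gen_paired_soil(seed=config.stage_seed("paired"))
    paired.to_csv(out / "soil_paired.csv", index=False)

    files = [
        "circles_true.csv",
        "landscape.png",
        "landscape.png.json",
        "env_sites.csv",
        "soil_transect.csv",
        "soil_paired.csv",
    ]
    manifest = {
        "seed": config.seed,
        "parameters": asdict(config),
        "outputs": {f: _sha256(out / f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("simulate stage done in %.2f s", time.perf_counter() - t0)
    return manifest


def run_full(config: RunConfig) -> dict:
    """Simulate, then run detection, dispersion statistics, the occupancy
    envelope, the niche model and the soil statistics; return (and write)
    one JSON report. Stage failures are recorded, not swallowed."""
    out = Path(config.out_dir)
    report: dict = {"seed": config.seed, "stages": {}}
    failed = False

    def _stage(name, fn):
        nonlocal failed
        t0 = time.perf_counter()
        try:
            result = fn()
            report["stages"][name] = {"status": "ok", "result": result}
        except Exception as exc:  # noqa: BLE001 - report and mark failed
            logger.exception("stage %s failed", name)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            failed = True
        logger.info("stage %s: %.2f s", name, time.perf_counter() - t0)

    manifest = run_simulate(config)
    report["manifest"] = manifest["outputs"]

    pattern = CirclePattern.from_csv(out / "circles_true.csv")
    scene_pattern, image = benchmarks.detection_scene(
        seed=config.stage_seed("scene"),
        n_circles=config.n_circles,
        pixel_scale=config.pixel_scale,
    )

    def detect_stage():
        params = DetectionParams(**config.detection)
        detected = detect_circles(image, params)
        write_detections_csv(detected, out / "detections.csv")
        score = evaluate_detection(detected, scene_pattern)
        return {"n_detected": len(detected), **score}

    def stats_stage():
        ce = clark_evans(scene_pattern.centers, scene_pattern.window)
        summary = summarize_patterns(scene_pattern)
        return {"clark_evans": ce.as_dict(), "summary": summary.as_dict()}

    def envelope_stage():
        x, y, truth = benchmarks.tent_envelope_data(
            n=config.envelope_n, seed=config.stage_seed("envelope"), tau=config.tau
        )
        fit = fit_quantile_piecewise(x, y, tau=config.tau)
        return {
            "fit": fit.as_dict(),
            "true_breakpoint": truth["breakpoint"],
            "fraction_above": fraction_above(fit, x, y),
        }

    def niche_stage():
        env = pd.read_csv(out / "env_sites.csv")
        covs = ["bio4", "evi1", "map_mm"]
        cfg = BRTConfig(
            learning_rate=config.brt_learning_rate,
            n_trees=config.brt_n_trees,
            cv_folds=config.brt_cv_folds,
            seed=config.stage_seed("brt"),
        )
        model = fit_brt(env[covs], env["presence"].to_numpy(), cfg)
        cv = cv_auc(env[covs], env["presence"].to_numpy(), cfg)
        return {
            "cv_auc": cv["auc_mean"],
            "cv_auc_se": cv["auc_se"],
            "relative_influence": relative_influence(model).round(3).to_dict(),
        }

    def soil_stage():
        transect = pd.read_csv(out / "soil_transect.csv")
        corr = interior_correlation(transect)
        moisture = t_test_summary(
            SummaryStat(2.2, 0.2, 11), SummaryStat(0.95, 0.18, 11)
        )
        return {
            "interior_sm_soc": corr,
            "moisture_welch_p": moisture.p_two_sided,
            "moisture_fold": fold_ratio(2.2, 0.95),
        }

    _stage("detection", detect_stage)
    _stage("spatial_stats", stats_stage)
    _stage("envelope", envelope_stage)
    _stage("niche", niche_stage)
    _stage("field_stats", soil_stage)

    report["status"] = "failed" if failed else "ok"
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    _write_text_report(report, out / "report.txt")
    return report


def _write_text_report(report: dict, path: Path) -> None:
    lines = [f"fairy-circle pipeline report (seed {report['seed']})", ""]
    for name, stage in report["stages"].items():
        lines.append(f"[{name}] {stage['status']}")
        if stage["status"] == "ok":
            for key, val in stage["result"].items():
                if isinstance(val, dict):
                    continue
                lines.append(f"  {key}: {val}")
        else:
            lines.append(f"  error: {stage['error']}")
    path.write_text("\n".join(lines) + "\n")
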