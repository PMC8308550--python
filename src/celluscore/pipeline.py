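"""Pipeline configuration and orchestration.

A single YAML document drives the full chain
simulate-images → score → simulate-trial → analyze → report.  Every stage is
deterministic for fixed seeds, artifacts land under one output directory,
and a failed image in a batch is recorded rather than aborting the batch.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as imio
from . import synthetic_skin as skin
from . import trial_sim, trial_stats
from .grading import normalize_to_baseline
from .undulation_score import ScoreParams, score_image

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_STAGES"]

log = logging.getLogger(__name__)

DEFAULT_STAGES = ("simulate-images", "score", "simulate-trial", "analyze", "report")

_DEFAULT_IMAGES = (
    {
        "name": "flat",
        "surface": "flat",
        "extent_mm": [60.0, 70.0],
        "noise_sd": 0.0,
    },
    {
        "name": "ridges",
        "surface": "sinusoid",
        "amplitude_mm": 0.12,
        "wavelength_mm": 10.0,
        "orientation_deg": 0.0,
        "extent_mm": [60.0, 70.0],
        "noise_sd": 1.0,
    },
    {
        "name": "dimples",
        "surface": "dimples",
        "n_dimples": 40,
        "extent_mm": [60.0, 70.0],
        "noise_sd": 1.0,
    },
)


@dataclass(frozen=True)
class PipelineConfig:
    """Whole-pipeline settings; round-trips losslessly through YAML."""

    seed: int = 0
    stages: tuple = DEFAULT_STAGES
    images: tuple = _DEFAULT_IMAGES
    px_per_mm: float = 10.0
    base_level: float = 180.0
    score: dict = field(
        default_factory=lambda: {"origin_mm": [4.0, 4.0]}
    )
    trial: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["images"] = [dict(i) for i in d["images"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "images" in d:
            d["images"] = tuple(dict(i) for i in d["images"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _build_field(spec: dict, seed: int) -> skin.SurfaceField:
    kind = spec.get("surface", "flat")
    extent = tuple(spec.get("extent_mm", (60.0, 70.0)))
    if kind == "flat":
        return skin.make_flat_field(extent)
    if kind == "sinusoid":
        return skin.make_undulation_field(
            amplitude_mm=spec.get("amplitude_mm", 0.1),
            wavelength_mm=spec.get("wavelength_mm", 10.0),
            orientation_deg=spec.get("orientation_deg", 0.0),
            phase_rad=spec.get("phase_rad", 0.0),
            extent_mm=extent,
        )
    if kind == "dimples":
        return skin.make_dimple_field(
            n_dimples=spec.get("n_dimples", 40),
            extent_mm=extent,
            seed=seed,
        )
    raise ValueError(f"unknown surface kind {kind!r}")


def _stage_simulate_images(config: PipelineConfig, out: Path) -> list:
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, spec in enumerate(config.images):
        seed = config.seed + 100 + i
        fld = _build_field(spec, seed)
        img = skin.render_image(
            fld,
            px_per_mm=spec.get("px_per_mm", config.px_per_mm),
            base_level=spec.get("base_level", config.base_level),
            noise_sd=spec.get("noise_sd", 0.0),
            seed=seed,
        )
        name = spec.get("name", f"image{i:02d}")
        paths.append(imio.write_image(img, img_dir / f"{name}.png", fld.descriptor, seed))
    return paths


def _stage_score(config: PipelineConfig, out: Path) -> pd.DataFrame:
    img_dir = out / "images"
    params_kw = {
        k: v for k, v in config.score.items() if k not in ("origin_mm",)
    }
    params = ScoreParams(**params_kw)
    origin = tuple(config.score.get("origin_mm", (0.0, 0.0)))
    rows, failures = [], []
    score_dir = out / "scores"
    score_dir.mkdir(parents=True, exist_ok=True)
    for path in sorted(img_dir.glob("*.png")) + sorted(img_dir.glob("*.tif*")):
        try:
            img = imio.read_image(path)
            result = score_image(img, origin, params)
        except Exception as exc:  # batch continues; failure reported
            log.error("scoring %s failed: %s", path.name, exc)
            failures.append({"image": path.name, "error": str(exc)})
            continue
        (score_dir / f"{path.stem}.json").write_text(
            json.dumps(
                {
                    "image": path.name,
                    "roi_scores": list(result.roi_scores),
                    "total": result.total,
                    "region_origin_mm": list(result.region_origin_mm),
                    "params": dataclasses.asdict(params),
                },
                indent=1,
            )
        )
        rows.append({"image_id": path.stem, "total": result.total})
    df = pd.DataFrame(rows, columns=["image_id", "total"])
    df.to_csv(score_dir / "scores.csv", index=False)
    if failures:
        (score_dir / "failures.json").write_text(json.dumps(failures, indent=1))
    return df


def _stage_simulate_trial(config: PipelineConfig, out: Path):
    cfg = trial_sim.default_trial_config(seed=config.seed)
    if config.trial:
        cfg = dataclasses.replace(cfg, **config.trial)
    ds = trial_sim.simulate_trial(cfg)
    trial_dir = out / "trial"
    trial_dir.mkdir(parents=True, exist_ok=True)
    ds.data.to_csv(trial_dir / "trial.csv", index=False)
    ds.ledger.to_csv(trial_dir / "ledger.csv", index=False)
    trial_sim.simulate_grades(cfg, ds).to_csv(trial_dir / "grades.csv", index=False)
    trial_sim.simulate_likert(cfg).to_csv(trial_dir / "likert.csv", index=False)
    return ds


def _stage_analyze(config: PipelineConfig, out: Path) -> dict:
    trial_dir = out / "trial"
    data = pd.read_csv(trial_dir / "trial.csv")
    ledger = pd.read_csv(trial_dir / "ledger.csv")
    ds = trial_sim.TrialDataset(data, ledger)
    complete = trial_sim.TrialDataset(ds.complete_cases(), ledger)

    results: dict = {"outcomes": {}, "likert": {}}
    for outcome in sorted(complete.data["outcome"].unique()):
        anova = trial_stats.rm_anova(complete, outcome)
        contrasts = {
            arm: [
                dataclasses.asdict(r)
                for r in trial_stats.baseline_contrasts(complete, outcome, arm)
            ]
            for arm in ("placebo", "herbal")
        }
        results["outcomes"][outcome] = {
            "anova": anova.table.to_dict("records"),
            "baseline_contrasts": contrasts,
        }
    likert_path = trial_dir / "likert.csv"
    if likert_path.exists():
        likert = pd.read_csv(likert_path)
        for question, grp in likert.groupby("question"):
            res = trial_stats.wilcoxon_signed_rank(
                grp["herbal_score"].to_numpy(), grp["placebo_score"].to_numpy()
            )
            results["likert"][question] = dataclasses.asdict(res)
    comments_path = trial_dir / "comments.csv"
    if comments_path.exists():
        comments = pd.read_csv(comments_path)
        tab = trial_stats.tabulate_comments(comments, len(ds.completers))
        results["comments"] = tab.to_dict("records")
    results["summary"] = trial_stats.summarize(complete).to_dict("records")

    res_dir = out / "results"
    res_dir.mkdir(parents=True, exist_ok=True)
    (res_dir / "results.json").write_text(json.dumps(results, indent=1, default=float))
    return results


def _md_table(df: pd.DataFrame) -> str:
    header = [str(df.index.name or "")] + [str(c) for c in df.columns]
    lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
    for idx, row in df.iterrows():
        cells = [str(idx)] + [str(v) for v in row.tolist()]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def _stage_report(config: PipelineConfig, out: Path) -> Path:
    results = json.loads((out / "results" / "results.json").read_text())
    trial = pd.read_csv(out / "trial" / "trial.csv")
    ledger = pd.read_csv(out / "trial" / "ledger.csv")
    ds = trial_sim.TrialDataset(trial, ledger)
    lines = ["# Trial report", ""]
    lines.append(
        f"Participants: {len(ledger)} enrolled, "
        f"{int((~ledger['completed']).sum())} withdrawn, "
        f"{len(ds.completers)} completers."
    )
    for outcome in sorted(trial["outcome"].unique()):
        sub = ds.complete_cases()
        sub = sub[sub["outcome"] == outcome]
        norm = normalize_to_baseline(sub)
        tab = (
            norm.groupby(["thigh", "week"])["value"]
            .mean()
            .unstack("week")
            .round(1)
        )
        lines += ["", f"## {outcome} (percent of baseline, completer means)", ""]
        lines.append(_md_table(tab))
    report = out / "results" / "report.md"
    report.parent.mkdir(parents=True, exist_ok=True)
    report.write_text("\n".join(lines) + "\n")
    return report


_STAGE_FUNCS = {
    "simulate-images": _stage_simulate_images,
    "score": _stage_score,
    "simulate-trial": _stage_simulate_trial,
    "analyze": _stage_analyze,
    "report": _stage_report,
}


def run_pipeline(config: PipelineConfig, out_dir) -> int:
    """Run the configured stages in order; returns 0 on success.

    Any stage failure aborts with a stage-tagged RuntimeError.  Only stages
    listed in ``config.stages`` run, in pipeline order.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for stage in DEFAULT_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        log.info("stage %s starting (seed=%d)", stage, config.seed)
        try:
            _STAGE_FUNCS[stage](config, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)
    return 0
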