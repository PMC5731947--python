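"""Config-driven end-to-end orchestration.

Stage order mirrors the analysis: co-metastasis testing, MEI screening,
collinearity filtering, normalization, cascade fitting, 10-fold CV, index
regression, evaluation — then scoring and evaluation of an optional
held-out validation cohort.  Every artifact is written under the configured
output directory and listed in a manifest; all randomness flows from one
global seed through a documented per-stage derivation, so identical
configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cascade import (
    build_cascade,
    cascade_predict_cohort,
    kfold_cv,
    model_to_dict,
)
from .cohort import CohortDataset, load_cohort
from .comet import analyze_comet, comet_network, SIGNIFICANCE_NEG_LOG10, DISPLAY_NEG_LOG10
from .evaluation import evaluate_scores, report_to_dict
from .index_model import fit_ocmi, ocmi_score, ocmi_to_dict
from .screening import collinearity_filter, normality_report, screen_meis
from .synthetic import SyntheticConfig, config_from_dict, config_to_dict, default_config, generate_cohort


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


#: Stage-seed derivation: seed_stage = (global_seed + OFFSET[stage]) mod 2^31.
STAGE_SEED_OFFSETS = {
    "simulate_training": 0,
    "simulate_validation": 1_000_003,
    "cascade": 2_000_003,
    "kfold": 3_000_017,
}


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) + STAGE_SEED_OFFSETS[stage]) % (2**31)


@dataclass
class PipelineConfig:
    output_dir: str = "ocmi_output"
    training_path: str | None = None
    validation_path: str | None = None
    synthetic: bool = False
    synthetic_config: SyntheticConfig | None = None
    synthetic_validation_n: int | None = None
    alpha: float = 0.001
    min_abs_rho: float = 0.1
    collinearity_threshold: float = 0.3
    mom_threshold: int = 3
    edge_threshold_significant: float = SIGNIFICANCE_NEG_LOG10
    edge_threshold_display: float = DISPLAY_NEG_LOG10
    epsilon: float = 0.005
    k_folds: int = 10
    ladder_order: list | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.synthetic and self.training_path is None:
            raise ConfigError("either a training cohort path or synthetic mode is required")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha outside (0,1): {self.alpha}")
        for name in ("min_abs_rho", "collinearity_threshold"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigError(f"{name} outside [0,1): {v}")
        if not 0 <= self.mom_threshold <= 15:
            raise ConfigError(f"mom_threshold outside 0..15: {self.mom_threshold}")
        if self.k_folds < 2:
            raise ConfigError(f"k_folds must be >= 2: {self.k_folds}")


def config_from_yaml_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    if "synthetic_config" in d and d["synthetic_config"] is not None:
        d["synthetic_config"] = config_from_dict(d["synthetic_config"])
    try:
        cfg = PipelineConfig(**d)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None
    cfg.validate()
    return cfg


def _config_digest(config: PipelineConfig) -> str:
    d = dict(config.__dict__)
    d.pop("output_dir")  # paths do not affect results
    if config.synthetic_config is not None:
        d["synthetic_config"] = config_to_dict(config.synthetic_config)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    Any stage failure raises :class:`StageError` after writing a partial
    manifest naming the failed stage.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_sha256": _config_digest(config),
        "seed": config.seed,
        "version": __version__,
        "stages": [],
        "files": [],
    }

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest["files"].append(name)

    stage = "load"
    try:
        if config.synthetic:
            stage = "simulate_training"
            syn = config.synthetic_config or default_config()
            syn_train = SyntheticConfig(**{**syn.__dict__, "seed": stage_seed(config.seed, stage)})
            training, _ = generate_cohort(syn_train, label="training")
            validation = None
            if config.synthetic_validation_n:
                stage = "simulate_validation"
                syn_val = SyntheticConfig(**{
                    **syn.__dict__,
                    "n_patients": config.synthetic_validation_n,
                    "seed": stage_seed(config.seed, stage),
                })
                validation, _ = generate_cohort(syn_val, label="validation")
        else:
            training = load_cohort(config.training_path, label="training")
            validation = (
                load_cohort(config.validation_path, label="validation")
                if config.validation_path
                else None
            )
        manifest["stages"].append({"stage": stage, "n_records": len(training)})

        stage = "comet"
        comet = analyze_comet(training)
        emit("incidence.tsv", lambda p: comet.incidence.rename("incidence").to_csv(p, sep="\t"))
        emit("comet_raw_p.tsv", lambda p: comet.raw_p.to_csv(p, sep="\t"))
        emit("comet_adjusted_p.tsv", lambda p: comet.adjusted_p.to_csv(p, sep="\t"))
        emit("comet_neg_log10_p.tsv", lambda p: comet.neg_log10_p.to_csv(p, sep="\t"))

        def _write_edges(path):
            edges = comet_network(comet, config.edge_threshold_display)
            with open(path, "w") as fh:
                fh.write("site_i\tsite_j\tneg_log10_p\n")
                for a, b, v in edges:
                    fh.write(f"{a}\t{b}\t{v!r}\n")

        emit("comet_edges.tsv", _write_edges)
        manifest["stages"].append({
            "stage": stage,
            "n_tests": len(comet.pair_counts),
            "n_significant_pairs": len(comet.significant_pairs),
        })

        stage = "screen_meis"
        screen = screen_meis(training, alpha=config.alpha, min_abs_rho=config.min_abs_rho)
        emit("normality.tsv", lambda p: normality_report(training).to_csv(p, sep="\t", index=False))
        manifest["stages"].append({
            "stage": stage,
            "n_meis": len(screen.rows),
            "n_metastasis_related": len(screen.metastasis_related),
            "n_mom_related": len(screen.mom_related),
        })

        stage = "collinearity_filter"
        retained, eliminations = collinearity_filter(
            screen.mom_related, training, screen, config.collinearity_threshold
        )
        emit("screening.tsv", lambda p: screen.to_frame().to_csv(p, sep="\t", index=False))
        manifest["stages"].append({
            "stage": stage,
            "n_retained": len(retained),
            "eliminated": [e[0] for e in eliminations],
        })
        if not retained:
            raise ValueError("no MEI survived screening and collinearity filtering")

        stage = "cascade"
        model = build_cascade(
            training,
            ordered_meis=config.ladder_order or retained,
            seed=stage_seed(config.seed, stage),
            epsilon=config.epsilon,
        )
        manifest["stages"].append({
            "stage": stage,
            "used_meis": model.used_meis,
            "rejected": [n for n, _ in model.rejected],
            "rho_train": model.rho_train,
        })

        stage = "kfold"
        cv = kfold_cv(
            training,
            k=config.k_folds,
            seed=stage_seed(config.seed, stage),
            ordered_meis=config.ladder_order or retained,
            epsilon=config.epsilon,
        )
        emit("cv_report.json", lambda p: _write_json(p, {
            "pooled_rho": cv.pooled_rho,
            "fold_rho": cv.fold_rho,
            "fold_sizes": cv.fold_sizes,
        }))
        manifest["stages"].append({"stage": stage, "pooled_rho": cv.pooled_rho})

        stage = "fit_ocmi"
        nnc_train = cascade_predict_cohort(model, training)
        index = fit_ocmi(
            nnc_train,
            training.column("laterality"),
            training.column("ascites"),
            training.site_counts(),
        )
        emit("model.json", lambda p: _write_json(p, {
            "format_version": 1,
            "package_version": __version__,
            "nnc": model_to_dict(model),
            "ocmi": ocmi_to_dict(index),
        }))
        manifest["stages"].append({"stage": stage, "coefficients": ocmi_to_dict(index)})

        stage = "evaluate_training"
        manifest_section = _score_and_evaluate(
            training, model, index, config, outdir, manifest, prefix="training"
        )
        manifest["stages"].append({"stage": stage, **manifest_section})

        if validation is not None:
            stage = "evaluate_validation"
            manifest_section = _score_and_evaluate(
                validation, model, index, config, outdir, manifest, prefix="validation"
            )
            manifest["stages"].append({"stage": stage, **manifest_section})
    except Exception as exc:
        manifest["failed_stage"] = stage
        _write_json(outdir / "manifest.json", manifest)
        raise StageError(stage, exc) from exc

    _write_json(outdir / "manifest.json", manifest)
    manifest["files"].append("manifest.json")
    return manifest


def _score_and_evaluate(cohort, model, index, config, outdir: Path, manifest: dict, prefix: str) -> dict:
    nnc = cascade_predict_cohort(model, cohort)
    raw, normalized = ocmi_score(index, nnc, cohort.column("laterality"), cohort.column("ascites"))

    scores = {"NNC": nnc, "OCMI": raw}
    norm_map = {"NNC": nnc, "OCMI": normalized}
    first_mei = model.used_meis[0]
    scores[first_mei] = cohort.mei_frame()[first_mei].to_numpy()

    report = evaluate_scores(cohort, scores, mom_threshold=config.mom_threshold, normalized=norm_map)

    name = f"evaluation_{prefix}.json"
    _write_json(outdir / name, report_to_dict(report))
    manifest["files"].append(name)

    per_patient = cohort.to_frame()[["patient_id"]].copy()
    per_patient["nnc_output"] = nnc
    per_patient["raw_ocmi"] = raw
    per_patient["normalized_ocmi"] = normalized
    name = f"scores_{prefix}.tsv"
    per_patient.to_csv(outdir / name, sep="\t", index=False)
    manifest["files"].append(name)

    for score_name, ev in report.scores.items():
        if ev.mp is not None:
            safe = score_name.replace("/", "_")
            curve_name = f"mp_curve_{prefix}_{safe}.tsv"
            ev.mp.to_frame().to_csv(outdir / curve_name, sep="\t", index=False)
            manifest["files"].append(curve_name)

    summary = report_to_dict(report)["scores"]
    return {"n_records": len(cohort), "scores": summary}
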