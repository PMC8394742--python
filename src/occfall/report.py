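"""Experiment orchestration, result tables and run provenance.

:func:`run_all` executes the requested protocol stages in order
fair -> ensemble -> ablation (later stages consume the winners of the
fair stage), and persists a machine-readable ``report.json`` plus one CSV
table per stage and a ``run.log``.  Re-running with the same config and
seed reproduces the JSON byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datamodel import Manifest, ValidationError, load_traces, read_manifest
from .evaluation import (AblationReport, EnsembleReport, EvalReport,
                         run_ablation, run_ensemble, run_fair_experiment,
                         top_combos)
from .features import features_frame
from .models import MODEL_KINDS
from .synth import GeneratorConfig, generate_dataset

log = logging.getLogger("occfall")

STAGES = ("fair", "ensemble", "ablation")


class ConfigError(ValueError):
    """The run configuration is inconsistent or incomplete."""


@dataclass
class RunConfig:
    """Everything one experiment run needs, loadable from YAML."""

    manifest: str | None = None
    generator: dict | None = None
    models: tuple = MODEL_KINDS
    feature_sets: tuple = ("BCDFGIK", "ABCDEFGHIJKL")
    k: int = 5
    seed: int = 0
    out_dir: str = "occfall_run"
    stages: tuple = STAGES
    honest_threshold: bool = False

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s): {unknown}")
        for dependent in ("ensemble", "ablation"):
            if dependent in self.stages and "fair" not in self.stages:
                raise ConfigError(
                    f"stage {dependent!r} requires the 'fair' stage")
        unknown = [m for m in self.models if m not in MODEL_KINDS]
        if unknown:
            raise ConfigError(f"unknown model kind(s): {unknown}")
        if self.manifest is None and self.generator is None:
            raise ConfigError("config needs either a manifest path or a "
                              "generator section")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("models", "feature_sets", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("models", "feature_sets", "stages"):
            d[key] = list(d[key])
        return d


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _combo_dict(combo) -> dict:
    return {
        "model_kind": combo.model_kind,
        "params": combo.params,
        "feature_set": combo.feature_set,
        "failed": combo.failed,
        "error": combo.error,
        "folds": None if combo.failed else [asdict(f) for f in combo.folds],
        "auc_mean": None if combo.failed else combo.auc_mean,
        "se_mean": None if combo.failed else combo.se_mean,
        "sp_mean": None if combo.failed else combo.sp_mean,
        "g_mean": None if combo.failed else combo.g_mean,
        "g_sd": None if combo.failed else combo.g_sd,
        "fair_threshold": None if combo.failed else combo.fair_threshold,
    }


def _fair_dict(report: EvalReport) -> dict:
    return {
        "model_kind": report.model_kind,
        "n_adl": report.n_adl, "n_fall": report.n_fall,
        "k": report.k, "seed": report.seed,
        "best": _combo_dict(report.best),
        "combos": [_combo_dict(c) for c in report.combos],
    }


def _ensemble_dict(report: EnsembleReport) -> dict:
    return {
        "members": [_combo_dict(c) for c in report.members],
        "folds": [asdict(f) for f in report.folds],
        "se_mean": report.se_mean, "sp_mean": report.sp_mean,
        "g_mean": report.g_mean, "g_sd": report.g_sd,
        "seed": report.seed, "k": report.k,
    }


def _ablation_dict(report: AblationReport) -> dict:
    return {
        "model_kind": report.model_kind, "params": report.params,
        "feature_set": report.feature_set, "threshold": report.threshold,
        "fair_g": report.fair_g, "fair_sp": report.fair_sp,
        "rows": {c: asdict(r) for c, r in report.rows.items()},
    }


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the bundle dict (also written as ``report.json``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        bundle = _run_all(config, out_dir)
    finally:
        log.removeHandler(handler)
        handler.close()
    return bundle


def _run_all(config: RunConfig, out_dir: Path) -> dict:
    if config.manifest is not None:
        manifest = read_manifest(config.manifest)
        log.info("loaded manifest %s (%d traces)", config.manifest,
                 len(manifest))
    else:
        gen_cfg = GeneratorConfig(**{**config.generator,
                                     "seed": config.generator.get(
                                         "seed", config.seed)})
        manifest = generate_dataset(gen_cfg, out_dir / "dataset")
        log.info("generated synthetic dataset (%d traces)", len(manifest))

    frame = features_frame(load_traces(manifest), "ABCDEFGHIJKL")
    bundle: dict = {
        "provenance": {
            "seed": config.seed,
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "version": __version__,
        },
    }

    fair_reports: list[EvalReport] = []
    if "fair" in config.stages:
        bundle["fair"] = {}
        for kind in config.models:
            log.info("fair stage: %s", kind)
            report = run_fair_experiment(
                manifest, kind, feature_sets=config.feature_sets,
                k=config.k, seed=config.seed,
                honest=config.honest_threshold, frame=frame)
            fair_reports.append(report)
            bundle["fair"][kind] = _fair_dict(report)
            log.info("fair %s best: G=%.4f AUC=%.4f", kind,
                     report.best.g_mean, report.best.auc_mean)

    if "ensemble" in config.stages:
        members = top_combos(fair_reports, 3)
        if len(members) < 3:
            raise ConfigError("fewer than 3 valid configurations available "
                              "for the ensemble stage")
        log.info("ensemble stage: %s",
                 [(m.model_kind, m.feature_set) for m in members])
        ens = run_ensemble(manifest, members, seed=config.seed,
                           k=config.k, frame=frame)
        bundle["ensemble"] = _ensemble_dict(ens)
        log.info("ensemble: G=%.4f", ens.g_mean)

    if "ablation" in config.stages:
        bundle["ablation"] = {}
        for report in fair_reports:
            log.info("ablation stage: %s", report.model_kind)
            abl = run_ablation(manifest, report.best, seed=config.seed,
                               frame=frame)
            bundle["ablation"][report.model_kind] = _ablation_dict(abl)

    (out_dir / "report.json").write_text(
        json.dumps(bundle, sort_keys=True, indent=1))
    for name, table in render_tables(bundle).items():
        table.to_csv(out_dir / f"table_{name}.csv", index=False)
    return bundle


# ---------------------------------------------------------------------------
# tables

def _fmt(x) -> str:
    return f"{x:.4f}"


def render_tables(bundle: dict) -> dict[str, pd.DataFrame]:
    """Render per-stage result tables with 4-decimal formatting.

    Columns follow the published layout: Features, OCC, Kernel/Distance,
    hyperparameter, AUC, Se, Sp, G (with "± sd" appended) and, for the
    ablation table, a signed Loss column.
    """
    if not bundle or not any(s in bundle for s in STAGES):
        raise ValidationError("empty report bundle")
    tables: dict[str, pd.DataFrame] = {}
    if "fair" in bundle:
        rows = []
        for kind, rep in bundle["fair"].items():
            best = rep["best"]
            rows.append({
                "Features": best["feature_set"],
                "OCC": kind,
                "Kernel/Distance": best["params"].get(
                    "kernel", best["params"].get("metric", "-")),
                "Neighbors/HiddenNeurons/Components": best["params"].get(
                    "k", best["params"].get(
                        "hidden_neurons",
                        best["params"].get("n_components", "-"))),
                "AUC": _fmt(best["auc_mean"]),
                "Se": _fmt(best["se_mean"]),
                "Sp": _fmt(best["sp_mean"]),
                "G": f"{best['g_mean']:.4f} ± {best['g_sd']:.4f}",
            })
        tables["fair"] = pd.DataFrame(rows)
    if "ensemble" in bundle:
        ens = bundle["ensemble"]
        rows = [{
            "Algorithm": "Majority Voting Ensemble",
            "Members": "; ".join(
                f"{m['model_kind']}[{m['feature_set']}]"
                for m in ens["members"]),
            "Se": _fmt(ens["se_mean"]),
            "Sp": _fmt(ens["sp_mean"]),
            "G": f"{ens['g_mean']:.4f} ± {ens['g_sd']:.4f}",
        }]
        tables["ensemble"] = pd.DataFrame(rows)
    if "ablation" in bundle:
        rows = []
        for kind, rep in bundle["ablation"].items():
            for category, row in sorted(rep["rows"].items()):
                rows.append({
                    "OCC": kind,
                    "HeldOutCategory": category,
                    "Se": _fmt(row["se"]),
                    "Sp": _fmt(row["sp"]),
                    "G": _fmt(row["g"]),
                    "Loss": f"{row['loss']:+.4f}",
                })
        tables["ablation"] = pd.DataFrame(rows)
    return tables
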