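"""End-to-end orchestration: simulate-or-ingest -> preprocess -> features ->
surrogacy -> classification, with a manifest for exact re-runs.

A run is described by a :class:`RunConfig` (loadable from YAML).  Outputs are
CSV/JSON tables: the cleaned series, epoch manifest, feature table, contrast
and trend tables, per-cell agreement table, Bland-Altman plot data,
surrogate decisions, and classifier evaluation reports.  The manifest records
the config hash, seed, per-stage timings and row counts; identical config and
seed reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
import pandas as pd
import yaml

from . import rr_io
from .preprocess import SCALES, CleanConfig, clean_rr, epoch_manifest, segment_epochs
from .hrv_features import extract_all
from .surrogacy_stats import (
    ALPHA,
    RHO_THRESHOLD,
    ULTRA_SHORT_SCALES,
    AgreementResult,
    ContrastResult,
    agreement_table,
    all_scale_surrogates,
    bland_altman,
    contrast_table,
    decisions_frame,
    select_surrogates,
    stress_contrast,
)
from .stress_classifier import (
    DEFAULT_INPUT_FEATURES,
    compare_scales,
    default_specs,
    report_summary_frame,
)
from .synthetic_rr import default_sim_config, generate
from .hrv_features import FEATURE_NAMES

__all__ = ["RunConfig", "run", "load_run_config"]

log = logging.getLogger("hrvstress")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str = "hrvstress_run"
    seed: int = 0
    # Input: either paths to an RR file + segment file, or the built-in
    # synthetic study (used when rr_path is None).
    rr_path: str | None = None
    segments_path: str | None = None
    rr_unit: str = "ms"
    clean: CleanConfig = field(default_factory=CleanConfig)
    scales: tuple[str, ...] = SCALES
    alpha: float = ALPHA
    rho_threshold: float = RHO_THRESHOLD
    families: tuple[str, ...] = ("svm_rbf", "knn", "random_forest", "adaboost")
    # 'all_scale_surrogates' or an explicit feature list.
    feature_policy: str | tuple[str, ...] = "all_scale_surrogates"
    classify_scales: tuple[str, ...] | None = None  # default: all requested scales

    def __post_init__(self) -> None:
        unknown = set(self.scales) - set(SCALES)
        if unknown:
            raise ValueError(f"unknown scales {sorted(unknown)}")
        if "5min" not in self.scales:
            raise ValueError("scales must include the 5min reference scale")

    def canonical(self) -> dict:
        d = asdict(self)
        d["clean"] = asdict(self.clean)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML (keys mirror the dataclass fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "clean" in raw:
        raw["clean"] = CleanConfig(**raw["clean"])
    for key in ("scales", "families", "classify_scales"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    if isinstance(raw.get("feature_policy"), list):
        raw["feature_policy"] = tuple(raw["feature_policy"])
    return RunConfig(**raw)


def _stage(manifest: dict, name: str, t0: float, **counts) -> float:
    dt = time.perf_counter() - t0
    manifest["stages"].append({"stage": name, "seconds": round(dt, 3), **counts})
    log.info("stage %-12s %6.2fs %s", name, dt, counts or "")
    return time.perf_counter()


def run(config: RunConfig) -> dict:
    """Execute the full study flow; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.canonical(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
        "outputs": [],
    }

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        rr_io.write_table(df, path)
        manifest["outputs"].append(name)

    t0 = time.perf_counter()

    # --- ingest or simulate -------------------------------------------------
    if config.rr_path is not None:
        if config.segments_path is None:
            raise ValueError("segments_path is required with rr_path")
        series = rr_io.read_rr_text(config.rr_path, unit=config.rr_unit)
        segments = rr_io.read_segments(config.segments_path)
    else:
        series, segments, _truth = generate(default_sim_config(seed=config.seed))
    t0 = _stage(manifest, "ingest", t0, n_beats=len(series))

    # --- preprocess ---------------------------------------------------------
    cleaned = clean_rr(series, config.clean)
    n_flagged = int((cleaned.flags != 0).sum())
    epochs = segment_epochs(cleaned, segments, config.clean, config.scales)
    rr_io.write_rr_text(cleaned, out / "cleaned_rr.txt")
    manifest["outputs"].append("cleaned_rr.txt")
    man = epoch_manifest(epochs)
    if len(man):
        emit(man, "epochs.csv")
    t0 = _stage(manifest, "preprocess", t0, n_flagged=n_flagged,
                n_epochs=len(epochs), n_valid=len(epochs.valid()))

    # --- features -----------------------------------------------------------
    features = extract_all(epochs)
    emit(features, "features.csv")
    t0 = _stage(manifest, "features", t0, n_rows=len(features))

    # --- surrogacy ----------------------------------------------------------
    ultra = tuple(s for s in config.scales if s != "5min")
    contrasts_df = contrast_table(features, FEATURE_NAMES, config.scales, alpha=config.alpha)
    emit(contrasts_df, "contrasts.csv")
    if ultra:
        agreements_df = agreement_table(features, FEATURE_NAMES, ultra)
        emit(agreements_df, "agreement.csv")
        contrasts = [
            stress_contrast(features, f, s, alpha=config.alpha)
            for f in FEATURE_NAMES for s in config.scales
        ]
        agreements = [
            bland_altman(features, f, s, stress)
            for f in FEATURE_NAMES for s in ultra for stress in ("low", "high")
        ]
        ba_rows = []
        for a in agreements:
            for m, d in zip(a.pair_means, a.pair_diffs):
                ba_rows.append({"feature": a.feature, "scale": a.scale,
                                "stress": a.stress, "pair_mean": m, "pair_diff": d})
        emit(pd.DataFrame(ba_rows), "bland_altman_points.csv")
        decisions = select_surrogates(
            contrasts, agreements, ultra,
            rho_threshold=config.rho_threshold, rho_alpha=config.alpha,
        )
        emit(decisions_frame(decisions), "decisions.csv")
        surrogates = all_scale_surrogates(decisions, ultra)
        manifest["all_scale_surrogates"] = surrogates
        t0 = _stage(manifest, "surrogacy", t0, n_decisions=len(decisions),
                    n_surrogates=len(surrogates))
    else:
        log.info("only the 5min scale requested; surrogacy stage skipped")
        manifest["all_scale_surrogates"] = None
        surrogates = []
        t0 = _stage(manifest, "surrogacy", t0, skipped=True)

    # --- classification -----------------------------------------------------
    if config.feature_policy == "all_scale_surrogates":
        input_features = tuple(surrogates) if surrogates else DEFAULT_INPUT_FEATURES
        if not surrogates:
            log.info("no all-scale surrogates available; falling back to %s",
                     DEFAULT_INPUT_FEATURES)
    else:
        input_features = tuple(config.feature_policy)
    specs = [s for name, s in default_specs().items() if name in config.families]
    classify_scales = config.classify_scales or config.scales
    reports = compare_scales(features, input_features, specs, classify_scales,
                             seed=config.seed)
    emit(report_summary_frame(reports), "classification_summary.csv")
    eval_json = {
        f"{scale}/{family}": {
            "summary": rep.summary(),
            "splits": [
                {"tp": s.tp, "tn": s.tn, "fp": s.fp, "fn": s.fn,
                 "best_params": s.best_params}
                for s in rep.splits
            ],
        }
        for (scale, family), rep in reports.items()
    }
    with open(out / "evaluation.json", "w") as fh:
        json.dump(eval_json, fh, indent=2)
    manifest["outputs"].append("evaluation.json")
    manifest["input_features"] = list(input_features)
    _stage(manifest, "classify", t0,
           n_cells=len(reports), n_features=len(input_features))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
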