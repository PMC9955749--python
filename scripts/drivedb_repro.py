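#!/usr/bin/env python
"""Reproduce the driver-stress analysis on the PhysioNet driver database.

This script is OPTIONAL and needs data you must download yourself
(https://physionet.org/content/drivedb/1.0.0/).  The database ships raw ECG;
beat detection is out of scope here, so first extract RR intervals with the
PhysioNet HRV toolkit (or any beat detector) and prepare, per driver:

    <dir>/<record>.rr.txt        RR intervals in ms, one per line
    <dir>/<record>.segments.csv  start_s,end_s,label with label in
                                 {low, high, excluded} encoding the
                                 rest / city / highway protocol phases

Then:

    python scripts/drivedb_repro.py --data <dir> --out results/drivedb

The script pools epochs across drivers, emits contrast / trend / agreement /
decision tables and classifier reports, and REPORTS (never asserts) how the
recovered all-scale surrogate set compares with the published selection
{MeanNN, SDNN, NN20, MeanHR}.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

from hrvstress import (
    build_design,
    clean_rr,
    default_specs,
    extract_all,
    read_rr_text,
    read_segments,
    segment_epochs,
    stress_contrast,
    write_table,
)
from hrvstress.hrv_features import FEATURE_NAMES
from hrvstress.preprocess import SCALES, EpochSet
from hrvstress.surrogacy_stats import (
    ULTRA_SHORT_SCALES,
    agreement_table,
    all_scale_surrogates,
    bland_altman,
    contrast_table,
    decisions_frame,
    select_surrogates,
)
from hrvstress.stress_classifier import report_summary_frame, evaluate

PUBLISHED_SURROGATES = ["MeanNN", "SDNN", "NN20", "MeanHR"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, required=True)
    parser.add_argument("--out", type=Path, required=True)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    records = sorted(p.name[: -len(".rr.txt")] for p in args.data.glob("*.rr.txt"))
    if not records:
        raise SystemExit(f"no *.rr.txt files in {args.data}")

    pooled = EpochSet(epochs=[])
    for rec in records:
        series = read_rr_text(args.data / f"{rec}.rr.txt", record_id=rec)
        segments = read_segments(args.data / f"{rec}.segments.csv")
        pooled.extend(segment_epochs(clean_rr(series), segments))
    table = extract_all(pooled)
    write_table(table, args.out / "features.csv")

    write_table(contrast_table(table), args.out / "contrasts.csv")
    write_table(agreement_table(table), args.out / "agreement.csv")
    contrasts = [stress_contrast(table, f, s) for f in FEATURE_NAMES for s in SCALES]
    agreements = [bland_altman(table, f, s, stress)
                  for f in FEATURE_NAMES for s in ULTRA_SHORT_SCALES
                  for stress in ("low", "high")]
    decisions = select_surrogates(contrasts, agreements)
    write_table(decisions_frame(decisions), args.out / "decisions.csv")
    surrogates = all_scale_surrogates(decisions)

    reports = {}
    features = tuple(surrogates) if len(surrogates) >= 2 else tuple(PUBLISHED_SURROGATES)
    for scale in SCALES:
        X, y, _ = build_design(table, scale, features)
        for family, spec in default_specs().items():
            reports[(scale, family)] = evaluate(spec, X, y, seed=args.seed, scale=scale)
    write_table(report_summary_frame(reports), args.out / "classification_summary.csv")

    comparison = {
        "recovered_all_scale_surrogates": surrogates,
        "published_all_scale_surrogates": PUBLISHED_SURROGATES,
        "agreement": sorted(set(surrogates) & set(PUBLISHED_SURROGATES)),
        "only_recovered": sorted(set(surrogates) - set(PUBLISHED_SURROGATES)),
        "only_published": sorted(set(PUBLISHED_SURROGATES) - set(surrogates)),
        "n_records": len(records),
    }
    (args.out / "surrogate_comparison.json").write_text(json.dumps(comparison, indent=2))
    print(json.dumps(comparison, indent=2))


if __name__ == "__main__":
    main()
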