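"""End-to-end orchestration: image -> biomarkers, cohort -> tables/models.

``analyze_image`` runs the per-image chain (ROI histogram -> multilevel
Otsu -> echogenicity partition, plus the morphometry appropriate to the
view) and returns a JSON-serialisable dict with provenance.

``run_study`` reproduces the study's table shapes on a cohort (simulated
or loaded from CSV): a by-sex comparison table, by-sarcopenia and
by-dynapenia comparison tables, a correlation table of functional
variables against ultrasound variables, and the two logistic model
designs for both outcomes.  Everything is deterministic under the
configured seed and every output carries provenance (config hash, seed,
package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .echo import multi_otsu, partition_roi, roi_histogram
from .errors import ValidationError
from .morpho import (fat_thickness, muscle_area, muscle_thickness,
                     pennation_angle, roi_truncated)
from .score import MALE, compute_cutoffs, published_cutoffs, score_cohort
from .simcohort import CohortSpec, generate_cohort, read_cohort
from .simimg import VIEW_LONGITUDINAL, read_frame, read_mask
from .stats import compare_groups, correlate, run_model

log = logging.getLogger("sonomyo")

_US_VARIABLES = ["sft_cm", "rfmt_cm", "rfma_cm2", "rfmai_cm2_m2", "mit_pct",
                 "fatit_pct", "nmnfit_pct", "pennation_deg"]
_SEX_TABLE_VARIABLES = ["age", "bmi", "arm_circ_cm", "calf_circ_cm",
                        "resistance_ohm", "reactance_ohm", "phase_angle_deg",
                        "asmi", *_US_VARIABLES, "handgrip_kg"]
_FUNCTIONAL_VARIABLES = ["phase_angle_deg", "resistance_ohm",
                         "reactance_ohm", "handgrip_kg"]

_CONFIG_SCHEMA = {
    "cohort": dict,        # {"source": "simulate"|"csv", "path": ..., "n_total": ..., "seed": ...}
    "cutoffs": str,        # "published" | "computed" | path to YAML
    "models": list,        # e.g. [{"model": 1, "outcome": "sarcopenia"}, ...]
    "seed": int,
}


def analyze_image(frame_path, mask_path, row_calib: float, col_calib: float,
                  view: str, height_m: float | None = None) -> dict:
    """Per-image analysis: echogenicity biomarkers plus view-appropriate
    morphometry, with provenance. Deterministic for fixed inputs."""
    frame = read_frame(frame_path, row_calib, col_calib, view)
    roi = read_mask(mask_path)
    if frame.shape != roi.shape:
        raise ValidationError(
            f"shape mismatch: frame {frame.shape} vs mask {roi.shape}")

    hist = roi_histogram(frame, roi)
    thresholds = multi_otsu(hist, n_classes=3)
    part = partition_roi(frame, roi, thresholds)

    result = {
        "thresholds": list(thresholds.thresholds),
        "MiT": part.mit_pct,
        "FATiT": part.fatit_pct,
        "NMNFiT": part.nmnfit_pct,
        "roi_pixels": roi.n_pixels,
        "truncated": roi_truncated(roi),
        "view": view,
    }
    result["rfma_cm2"] = muscle_area(roi, row_calib, col_calib)
    result["rfmt_cm"] = muscle_thickness(roi, row_calib)
    if height_m is not None:
        result["rfmai_cm2_m2"] = result["rfma_cm2"] / height_m ** 2
    if view == VIEW_LONGITUDINAL:
        result["sft_cm"] = fat_thickness(frame)
        result["pennation_deg"] = pennation_angle(frame, roi)
    result["provenance"] = {
        "frame": str(frame_path),
        "mask": str(mask_path),
        "row_calib_cm": row_calib,
        "col_calib_cm": col_calib,
        "version": __version__,
    }
    return result


# ---------------------------------------------------------------------------
# Study runner
# ---------------------------------------------------------------------------

def _validate_config(config: dict) -> dict:
    unknown = sorted(set(config) - set(_CONFIG_SCHEMA))
    if unknown:
        raise ValidationError(f"unknown config keys: {', '.join(unknown)}")
    cfg = {
        "cohort": {"source": "simulate"},
        "cutoffs": "computed",
        "models": [{"model": m, "outcome": o}
                   for m in (1, 2) for o in ("sarcopenia", "dynapenia")],
        "seed": 0,
    }
    cfg.update(config)
    src = cfg["cohort"].get("source", "simulate")
    if src not in ("simulate", "csv"):
        raise ValidationError(f"cohort.source must be simulate/csv, got {src!r}")
    if src == "csv" and "path" not in cfg["cohort"]:
        raise ValidationError("cohort.source=csv requires cohort.path")
    for entry in cfg["models"]:
        if entry.get("model") not in (1, 2) or entry.get("outcome") not in (
                "sarcopenia", "dynapenia"):
            raise ValidationError(f"invalid model request: {entry}")
    return cfg


def _comparison_table(df: pd.DataFrame, split: pd.Series, variables,
                      labels) -> pd.DataFrame:
    rows = []
    for var in variables:
        if var not in df.columns:
            continue
        a = df.loc[split, var].dropna().to_numpy(float)
        b = df.loc[~split, var].dropna().to_numpy(float)
        cmp = compare_groups(a, b)
        rows.append({
            "variable": var,
            f"mean_{labels[0]}": a.mean(),
            f"sd_{labels[0]}": a.std(ddof=1),
            f"mean_{labels[1]}": b.mean(),
            f"sd_{labels[1]}": b.std(ddof=1),
            "test": cmp.test_used,
            "p_value": cmp.p_value,
        })
    return pd.DataFrame(rows)


def _correlation_table(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for fvar in _FUNCTIONAL_VARIABLES:
        row = {"variable": fvar}
        for uvar in _US_VARIABLES:
            sub = df[[fvar, uvar]].dropna()
            res = correlate(sub[fvar], sub[uvar], method="pearson")
            row[f"r_{uvar}"] = res.r
            row[f"p_{uvar}"] = res.p_value
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(config: dict | str | Path, out_dir, seed: int | None = None) -> dict:
    """Execute a full synthetic study and write the report bundle.

    Returns a dict with the in-memory tables and the provenance record.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(open(config)) or {}
    cfg = _validate_config(config)
    if seed is not None:
        cfg["seed"] = seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
    log.info("run_study seed=%s config=%s", cfg["seed"], cfg_hash)

    if cfg["cohort"]["source"] == "simulate":
        spec = CohortSpec(n_total=int(cfg["cohort"].get("n_total", 647)),
                          seed=int(cfg["seed"]))
        cohort = generate_cohort(spec)
    else:
        cohort = read_cohort(cfg["cohort"]["path"])

    if cfg["cutoffs"] == "published":
        cutoffs = published_cutoffs()
    elif cfg["cutoffs"] == "computed":
        cutoffs = compute_cutoffs(cohort)
    else:
        from .score import load_cutoffs
        cutoffs = load_cutoffs(cfg["cutoffs"])
    scored = score_cohort(cohort, cutoffs)

    by_sex = _comparison_table(scored, scored["sex"] == MALE,
                               _SEX_TABLE_VARIABLES, ("male", "female"))
    by_sarc = _comparison_table(scored, scored["sarcopenia"].astype(bool),
                                _US_VARIABLES, ("sarcopenia", "no_sarcopenia"))
    by_dyna = _comparison_table(scored, scored["dynapenia"].astype(bool),
                                _US_VARIABLES, ("dynapenia", "no_dynapenia"))
    correlations = _correlation_table(scored)

    model_tables = {}
    for entry in cfg["models"]:
        key = f"model{entry['model']}_{entry['outcome']}"
        fit = run_model(scored, entry["model"], entry["outcome"])
        model_tables[key] = fit.table.reset_index(names="predictor")

    scored.to_csv(out / "cohort_scored.csv", index=False)
    by_sex.to_csv(out / "table_by_sex.csv", index=False)
    by_sarc.to_csv(out / "table_by_sarcopenia.csv", index=False)
    by_dyna.to_csv(out / "table_by_dynapenia.csv", index=False)
    correlations.to_csv(out / "table_correlations.csv", index=False)
    for key, tbl in model_tables.items():
        tbl.to_csv(out / f"table_{key}.csv", index=False)

    provenance = {
        "seed": cfg["seed"],
        "config_hash": cfg_hash,
        "version": __version__,
        "n_subjects": int(len(scored)),
        "cutoffs_provenance": cutoffs.provenance,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")

    return {"cohort": scored, "by_sex": by_sex, "by_sarcopenia": by_sarc,
            "by_dynapenia": by_dyna, "correlations": correlations,
            "models": model_tables, "provenance": provenance}
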