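"""Batch pipeline: manifest of recordings -> metrics tables -> statistics.

The analyze stage walks a cohort manifest (one row per specimen per test),
reads each recording, dispatches on the test kind and collects one wide row
of metrics per specimen.  Failures are isolated per specimen: a corrupt file
flags that specimen and the rest complete.  The stats stage runs the per-sex
two-way ANOVA + Tukey layer over every outcome column of a tidy table.
Every output row carries the hash of the configuration that produced it, and
outputs are byte-identical across reruns with the same inputs and config.
"""

from __future__ import annotations

import json
import logging
import pathlib

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .creep import fit_creep
from .cyclic import axial_metrics, extract_cycle, torsional_metrics
from .errors import PipelineError, SpineMechError
from .failure import detect_failure
from .recording import read_recording
from .stats import summarize_groups, tukey_hsd, two_way_anova

logger = logging.getLogger("spinemech")

_FLOAT_FORMAT = "%.12g"
_LABELS = ["specimen_id", "sex", "genotype", "diet"]


def analyze_recording(recording, cfg: PipelineConfig) -> dict:
    """Metrics for one recording, keyed by outcome name."""
    kind = recording.test_kind
    if kind == "axial_cyclic":
        loop = extract_cycle(recording, cfg.cycle_index, cfg.frequency)
        m = axial_metrics(loop, cfg)
        return {
            "compressive_stiffness": m.stiffness_negative,
            "tensile_stiffness": m.stiffness_positive,
            "rom": m.range_of_motion,
            "neutral_zone": m.neutral_zone_length,
            "load_range": m.load_range,
        }
    if kind == "torsional_cyclic":
        loop = extract_cycle(recording, cfg.cycle_index, cfg.frequency)
        m = torsional_metrics(loop, cfg)
        return {
            "torsional_stiffness": m.stiffness_mean,
            "torque_range": m.load_range,
            "torsional_neutral_zone": m.neutral_zone_length,
        }
    if kind == "creep":
        fit = fit_creep(recording, cfg=cfg)
        return {
            "k0": fit.model.k0,
            "k1": fit.model.k1,
            "k2": fit.model.k2,
            "tau1": fit.model.tau1,
            "tau2": fit.model.tau2,
            "elastic_displacement": fit.elastic_displacement,
            "creep_displacement": fit.creep_displacement,
            "total_displacement": fit.total_displacement,
            "creep_residual_rms": fit.residual_rms,
        }
    if kind == "torsion_to_failure":
        m = detect_failure(recording, cfg)
        return {
            "failure_strength": m.failure_strength,
            "angle_to_failure": m.angle_to_failure,
            "failed": m.failed,
        }
    raise SpineMechError(f"cannot analyze test kind {kind!r}")


def run_analysis(
    manifest,
    cfg: PipelineConfig | None = None,
    base_dir=None,
    out_dir=None,
) -> dict:
    """Analyze every recording referenced by a manifest.

    ``manifest`` is a DataFrame or CSV path with columns
    specimen_id, sex, genotype, diet, kind, path.  Returns a dict with the
    wide per-specimen ``metrics`` table, the per-file ``status`` table and
    the run ``report``; writes ``metrics.csv``, ``status.csv`` and
    ``run_report.json`` when ``out_dir`` is given.
    """
    cfg = cfg or PipelineConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest_path = pathlib.Path(manifest)
        if base_dir is None:
            base_dir = manifest_path.parent
        manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        raise PipelineError("manifest is empty")
    base_dir = pathlib.Path(base_dir) if base_dir is not None else pathlib.Path(".")

    rows: dict = {}
    status = []
    for record in manifest.to_dict(orient="records"):
        sid = record["specimen_id"]
        rows.setdefault(
            sid, {k: record.get(k) for k in _LABELS}
        )
        try:
            rec = read_recording(base_dir / record["path"],
                                 test_kind=record.get("kind"))
            metrics = analyze_recording(rec, cfg)
            rows[sid].update(metrics)
            status.append({"specimen_id": sid, "kind": record["kind"],
                           "path": record["path"], "status": "ok", "error": ""})
        except (SpineMechError, OSError) as exc:
            logger.warning("specimen %s %s failed: %s", sid, record.get("kind"), exc)
            status.append({"specimen_id": sid, "kind": record.get("kind"),
                           "path": record.get("path"), "status": "error",
                           "error": f"{type(exc).__name__}: {exc}"})

    status_df = pd.DataFrame(status)
    n_ok = int((status_df["status"] == "ok").sum())
    if n_ok == 0:
        raise PipelineError("every recording failed to analyze")
    metrics_df = pd.DataFrame(list(rows.values()))
    metrics_df["config_hash"] = cfg.hash

    report = {
        "config": cfg.to_dict(),
        "config_hash": cfg.hash,
        "spinemech_version": __version__,
        "n_files": int(len(manifest)),
        "n_ok": n_ok,
        "n_failed": int(len(manifest)) - n_ok,
    }
    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics_df.to_csv(out / "metrics.csv", index=False,
                          float_format=_FLOAT_FORMAT)
        status_df.to_csv(out / "status.csv", index=False)
        with open(out / "run_report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return {"metrics": metrics_df, "status": status_df, "report": report}


def run_stats(
    outcomes,
    cfg: PipelineConfig | None = None,
    by: str = "sex",
    factors=("genotype", "diet"),
    out_dir=None,
) -> dict:
    """Two-way ANOVA + Tukey + summaries per stratum per outcome column.

    ``outcomes`` is a tidy DataFrame or CSV path (labels + numeric outcome
    columns).  Strata with degenerate designs are skipped with a note in the
    returned ``skipped`` list rather than aborting the batch.
    """
    cfg = cfg or PipelineConfig()
    if not isinstance(outcomes, pd.DataFrame):
        outcomes = pd.read_csv(outcomes)
    factors = list(factors)
    label_cols = set(_LABELS + [by] + factors + ["config_hash", "failed"])
    outcome_cols = [
        c for c in outcomes.columns
        if c not in label_cols and pd.api.types.is_numeric_dtype(outcomes[c])
    ]
    if not outcome_cols:
        raise PipelineError("no numeric outcome columns found")

    anova_rows, tukey_rows, summary_rows, skipped = [], [], [], []
    strata = sorted(outcomes[by].dropna().unique()) if by in outcomes else [None]
    for stratum in strata:
        sub = outcomes if stratum is None else outcomes[outcomes[by] == stratum]
        for col in outcome_cols:
            values = sub[col]
            mask = values.notna()
            try:
                res = two_way_anova(values[mask], sub.loc[mask, factors[0]],
                                    sub.loc[mask, factors[1]], ss_type=cfg.ss_type)
                groups = (sub.loc[mask, factors[0]].astype(str) + "/"
                          + sub.loc[mask, factors[1]].astype(str))
                tk = tukey_hsd(values[mask], groups)
            except SpineMechError as exc:
                skipped.append({"stratum": stratum, "outcome": col,
                                "reason": f"{type(exc).__name__}: {exc}"})
                continue
            for effect in ("genotype", "diet", "genotype:diet"):
                anova_rows.append({
                    by: stratum, "outcome": col, "effect": effect,
                    "sum_sq": res.table.loc[effect, "sum_sq"],
                    "df": res.table.loc[effect, "df"],
                    "F": res.f(effect), "p": res.p(effect),
                    "significant": res.p(effect) < cfg.alpha,
                })
            tk.insert(0, "outcome", col)
            tk.insert(0, by, stratum)
            tukey_rows.append(tk)
            summary = summarize_groups(values[mask], sub.loc[mask, factors[0]],
                                       sub.loc[mask, factors[1]])
            summary.insert(0, "outcome", col)
            summary.insert(0, by, stratum)
            summary_rows.append(summary)

    anova_df = pd.DataFrame(anova_rows)
    tukey_df = (pd.concat(tukey_rows, ignore_index=True)
                if tukey_rows else pd.DataFrame())
    summary_df = (pd.concat(summary_rows, ignore_index=True)
                  if summary_rows else pd.DataFrame())
    for df in (anova_df, tukey_df, summary_df):
        if not df.empty:
            df["config_hash"] = cfg.hash

    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        anova_df.to_csv(out / "anova.csv", index=False, float_format=_FLOAT_FORMAT)
        tukey_df.to_csv(out / "tukey.csv", index=False, float_format=_FLOAT_FORMAT)
        summary_df.to_csv(out / "group_summary.csv", index=False,
                          float_format=_FLOAT_FORMAT)
    return {"anova": anova_df, "tukey": tukey_df, "summary": summary_df,
            "skipped": skipped}


def run_pipeline(manifest, cfg=None, base_dir=None, out_dir=None,
                 extra_outcomes=None) -> dict:
    """analyze + stats in one call; merges extra outcome tables (e.g.
    morphometry) on the label columns before the statistics stage."""
    cfg = cfg or PipelineConfig()
    analysis = run_analysis(manifest, cfg, base_dir=base_dir, out_dir=out_dir)
    outcomes = analysis["metrics"]
    if extra_outcomes is not None:
        if not isinstance(extra_outcomes, pd.DataFrame):
            extra_outcomes = pd.read_csv(extra_outcomes)
        outcomes = outcomes.merge(extra_outcomes, on=_LABELS, how="outer")
    stats = run_stats(outcomes.drop(columns=["config_hash"]), cfg,
                      out_dir=out_dir)
    return {**analysis, **stats, "outcomes": outcomes}
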