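"""End-to-end workflow: fit, diagnose, remove outliers, refit, compare.

The pipeline fits the bivariate Poisson regression to the full data,
computes averaged deviance residuals against that single full fit, and
then — independently for each cutoff — drops the flagged records and
refits from scratch.  Each cutoff entry reports the reduced fit, the
fitted-mean and raw Spearman correlations, AIC values, and per-term
coefficient deltas.  Removal is single-pass: no re-flagging after the
refit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .correlation import correlation_fitted, correlation_raw
from .design import ModelSpec
from .diagnostics import DiagnosticsConfig, compute_residuals, flag_outliers
from .model import FitResult, fit

__all__ = [
    "PipelineReport",
    "run_pipeline",
    "compare_fits",
    "read_records",
    "write_report",
]

ALPHA = 0.05  # significance threshold for change flags


def _fit_summary(fr: FitResult) -> dict:
    return {
        "n_used": fr.n_used,
        "n_dropped": fr.n_dropped,
        "loglik": fr.loglik,
        "n_params": fr.n_params,
        "aic": fr.aic,
        "theta3": fr.params.theta3,
        "converged": fr.converged,
        "coefficients": fr.coefficient_table().to_dict(orient="records"),
    }


@dataclass
class PipelineReport:
    full_fit: FitResult
    full_residuals: pd.DataFrame
    correlation_raw_full: dict
    correlation_fitted_full: dict
    cutoffs: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "full_fit": _fit_summary(self.full_fit),
            "correlation_raw": self.correlation_raw_full,
            "correlation_fitted": self.correlation_fitted_full,
            "cutoffs": [
                {k: v for k, v in entry.items() if k != "reduced_fit_result"}
                for entry in self.cutoffs
            ],
        }


def run_pipeline(
    records: pd.DataFrame,
    spec: ModelSpec,
    diag: DiagnosticsConfig | None = None,
    estimate_theta3: bool = False,
    seed: int | None = None,
) -> PipelineReport:
    """Run the full fit / diagnose / remove / refit / compare workflow."""
    diag = diag or DiagnosticsConfig()
    try:
        full = fit(records, spec, estimate_theta3=estimate_theta3)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'fit_full' failed: {e}") from e

    X, y1, y2, kept, _ = full.encoder.transform(records)
    ids = (
        kept["record_id"].to_numpy()
        if "record_id" in kept.columns
        else kept.index.to_numpy()
    )
    try:
        residuals = compute_residuals(full, y1, y2, record_ids=ids, config=diag)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'residuals' failed: {e}") from e

    corr_raw = correlation_raw(y1, y2).to_dict()
    corr_fit_full = correlation_fitted(full).to_dict()

    report = PipelineReport(
        full_fit=full,
        full_residuals=residuals,
        correlation_raw_full=corr_raw,
        correlation_fitted_full=corr_fit_full,
        provenance={
            "seed": seed,
            "config_hash": _spec_hash(spec, diag),
            "version": __version__,
        },
    )

    id_col = "record_id" if "record_id" in kept.columns else None
    for cutoff in diag.cutoffs:
        out_report = flag_outliers(residuals, cutoff)
        entry: dict = {"cutoff": cutoff, "outlier_report": out_report.to_dict()}
        if out_report.n_flagged > 0.5 * full.n_used:
            entry["error"] = (
                f"cutoff {cutoff:g} flags {out_report.n_flagged} of "
                f"{full.n_used} records (> 50%) — aborting this cutoff"
            )
            report.cutoffs.append(entry)
            continue
        flagged = set(out_report.flagged_ids)
        if id_col:
            reduced_records = kept.loc[~kept[id_col].isin(flagged)]
        else:
            reduced_records = kept.loc[~kept.index.isin(flagged)]
        try:
            reduced = fit(reduced_records, spec, estimate_theta3=estimate_theta3)
        except Exception as e:
            raise RuntimeError(
                f"pipeline stage 'refit@{cutoff:g}' failed: {e}"
            ) from e
        _, ry1, ry2, _, _ = reduced.encoder.transform(reduced_records)
        entry.update(
            reduced_fit=_fit_summary(reduced),
            reduced_fit_result=reduced,
            correlation_fitted_full=corr_fit_full,
            correlation_fitted_reduced=correlation_fitted(reduced).to_dict(),
            correlation_raw=corr_raw,
            correlation_raw_reduced=correlation_raw(ry1, ry2).to_dict(),
            aic_full=full.aic,
            aic_reduced=reduced.aic,
            coefficient_deltas=compare_fits(full, reduced).to_dict(orient="records"),
        )
        report.cutoffs.append(entry)
    return report


def compare_fits(full: FitResult, reduced: FitResult) -> pd.DataFrame:
    """Per-term coefficient deltas (reduced - full) with change flags."""
    if full.term_names != reduced.term_names or full.spec.to_dict() != reduced.spec.to_dict():
        raise ValueError("fits use different model specifications")
    t_full = full.coefficient_table()
    t_red = reduced.coefficient_table()
    out = t_full[["margin", "term"]].copy()
    out["estimate_full"] = t_full["estimate"]
    out["estimate_reduced"] = t_red["estimate"]
    out["delta"] = t_red["estimate"] - t_full["estimate"]
    out["se_ratio"] = t_red["std_error"] / t_full["std_error"]
    out["sign_change"] = np.sign(t_red["estimate"]) != np.sign(t_full["estimate"])
    out["significance_change"] = (t_full["p_value"] < ALPHA) != (t_red["p_value"] < ALPHA)
    return out


def read_records(path, spec: ModelSpec) -> pd.DataFrame:
    """Read woman-level records from CSV, validating outcome columns.

    Unknown columns are preserved but unused.  A missing required column
    or a non-integer outcome raises with the offending name / data row
    number (1-based, excluding the header).
    """
    records = pd.read_csv(path)
    missing = [c for c in spec.required_columns if c not in records.columns]
    if missing:
        raise KeyError(f"missing required column(s): {missing}")
    for col in (spec.outcome1, spec.outcome2):
        vals = pd.to_numeric(records[col], errors="coerce")
        raw_nan = records[col].isna()
        unparsable = vals.isna() & ~raw_nan
        bad = unparsable | (~vals.isna() & ((vals < 0) | (vals != np.floor(vals))))
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 1
            raise ValueError(
                f"outcome {col!r} has a non-integer or negative value "
                f"{records[col].iloc[row - 1]!r} at row {row}"
            )
    return records


def write_report(report: PipelineReport, path) -> None:
    """Emit the pipeline report as deterministic JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _spec_hash(spec: ModelSpec, diag: DiagnosticsConfig) -> str:
    payload = json.dumps(
        {"spec": spec.to_dict(), "delta": diag.delta, "cutoffs": list(diag.cutoffs)},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
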