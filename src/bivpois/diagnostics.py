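"""Deviance-residual outlier diagnostics for the bivariate Poisson fit.

Each margin gets a signed deviance residual

    d_ij = sgn(y_ij - theta_ij) * sqrt(2 * [ y_ij * log((y_ij + delta) / theta_ij)
                                             - (y_ij - theta_ij) ]),

where ``delta`` (default 1e-6) is a smoothing constant that keeps the
logarithm finite at zero counts (for ``y = 0`` the ``y*log`` term is
exactly zero, so ``d = -sqrt(2*theta)``).  The overall per-record
statistic is the average ``d* = (d1 + d2) / 2``; under a well-specified
model it is treated as approximately standard normal — in fact the
average of two roughly unit-variance residuals has variance at most one,
so the usual +-1.96 / +-2.58 cutoffs are conservative.  Flagging is
applied to ``d*``; the marginal residuals are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import FitResult

__all__ = [
    "DiagnosticsConfig",
    "OutlierReport",
    "marginal_deviance_residual",
    "overall_residual",
    "compute_residuals",
    "flag_outliers",
    "profile_outliers",
]


@dataclass
class DiagnosticsConfig:
    delta: float = 1e-6
    cutoffs: tuple[float, ...] = (1.96, 2.58)

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        cuts = tuple(float(c) for c in self.cutoffs)
        if any(c <= 0 for c in cuts) or list(cuts) != sorted(cuts):
            raise ValueError("cutoffs must be strictly positive and ascending")
        self.cutoffs = cuts


@dataclass
class OutlierReport:
    """Records beyond ``|d*| > cutoff``, split by residual sign."""

    cutoff: float
    flagged_ids: list
    n_flagged: int
    n_over_predicted: int  # d* < -cutoff: observed below prediction
    n_under_predicted: int  # d* > +cutoff
    residual_mean: float

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "n_flagged": self.n_flagged,
            "n_over_predicted": self.n_over_predicted,
            "n_under_predicted": self.n_under_predicted,
            "residual_mean": self.residual_mean,
            "flagged_ids": list(self.flagged_ids),
        }


def marginal_deviance_residual(y, theta_hat, delta: float = 1e-6):
    """Signed marginal deviance residual; 0 when ``y == theta_hat``."""
    y = np.asarray(y, dtype=float)
    theta = np.asarray(theta_hat, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("theta_hat must be strictly positive")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must contain non-negative integers")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    ylog = np.where(y > 0, y * np.log((y + delta) / theta), 0.0)
    radicand = 2.0 * (ylog - (y - theta))
    if np.any(radicand < 0):
        i = int(np.argmin(radicand))
        raise ValueError(
            f"negative radicand {radicand.flat[i]!r} at y={y.flat[i]!r}, "
            f"theta_hat={theta.flat[i]!r}, delta={delta!r}"
        )
    out = np.sign(y - theta) * np.sqrt(radicand)
    return float(out) if out.ndim == 0 else out


def overall_residual(d1, d2):
    """Average of the two marginal deviance residuals."""
    return (np.asarray(d1, dtype=float) + np.asarray(d2, dtype=float)) / 2.0


def compute_residuals(
    fit_result: FitResult,
    y1,
    y2,
    record_ids=None,
    config: DiagnosticsConfig | None = None,
) -> pd.DataFrame:
    """Per-record residual table: raw residuals, d1, d2 and d*.

    ``y1``/``y2`` must align with the fit's ``fitted_mean1``/``fitted_mean2``
    rows (i.e. the complete-case records the model was fitted on).
    """
    config = config or DiagnosticsConfig()
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if record_ids is None:
        record_ids = np.arange(len(y1))
    d1 = marginal_deviance_residual(y1, fit_result.fitted_mean1, config.delta)
    d2 = marginal_deviance_residual(y2, fit_result.fitted_mean2, config.delta)
    tab = pd.DataFrame(
        {
            "record_id": np.asarray(record_ids),
            "raw1": y1 - fit_result.fitted_mean1,
            "raw2": y2 - fit_result.fitted_mean2,
            "d1": d1,
            "d2": d2,
            "d_star": overall_residual(d1, d2),
        }
    )
    for cut in config.cutoffs:
        tab[f"flagged_at_{cut:g}"] = np.abs(tab["d_star"]) > cut
    return tab


def flag_outliers(residuals: pd.DataFrame, cutoff: float) -> OutlierReport:
    """Threshold the overall residual ``d*`` at ``+-cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if len(residuals) == 0:
        raise ValueError("empty residual table")
    d = residuals["d_star"].to_numpy()
    over = d < -cutoff
    under = d > cutoff
    flagged = residuals.loc[over | under, "record_id"].tolist()
    return OutlierReport(
        cutoff=float(cutoff),
        flagged_ids=flagged,
        n_flagged=len(flagged),
        n_over_predicted=int(over.sum()),
        n_under_predicted=int(under.sum()),
        residual_mean=float(d.mean()),
    )


def plot_residuals(residuals: pd.DataFrame, path, cutoffs=(1.96, 2.58)) -> None:
    """Optional index plot of d* with cutoff lines, written as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.scatter(residuals["record_id"], residuals["d_star"], s=4, alpha=0.5)
    for c in cutoffs:
        ax.axhline(c, color="tab:red", lw=0.8, ls="--")
        ax.axhline(-c, color="tab:red", lw=0.8, ls="--")
    ax.set_xlabel("record id")
    ax.set_ylabel("overall deviance residual d*")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


_SCHOOL_BINS = ((0, 0, "0"), (1, 8, "1-8"), (9, None, "9+"))
_PARITY_BINS = ((0, 0, "0"), (1, 4, "1-4"), (5, None, "5+"))


def _bin_label(v: float, bins) -> str:
    for lo, hi, label in bins:
        if v >= lo and (hi is None or v <= hi):
            return label
    raise ValueError(f"value {v!r} fell outside the bin scheme")


def profile_outliers(
    report: OutlierReport,
    records: pd.DataFrame,
    covariates: list[str] | None = None,
    outcome1: str = "schooling_years",
    outcome2: str = "children_ever_born",
    id_column: str = "record_id",
) -> dict[str, pd.DataFrame]:
    """Describe flagged records against the rest of the sample.

    Returns per-covariate category shares of the flagged and non-flagged
    sets, plus the outcome-extremity cross-tab (schooling 0 / 1-8 / 9+ by
    parity 0 / 1-4 / 5+) of the flagged set.  An empty flag set yields
    empty tables, not an error.
    """
    flagged_mask = records[id_column].isin(set(report.flagged_ids))
    missing = set(report.flagged_ids) - set(records[id_column])
    if missing:
        raise KeyError(f"flagged ids not present in records: {sorted(missing)[:5]}")
    if covariates is None:
        covariates = [
            c
            for c in records.columns
            if c not in (id_column, outcome1, outcome2, "is_contaminated")
        ]
    out: dict[str, pd.DataFrame] = {}
    for cov in covariates:
        rows = []
        for group, mask in (("flagged", flagged_mask), ("non_flagged", ~flagged_mask)):
            sub = records.loc[mask, cov]
            counts = sub.value_counts()
            total = len(sub)
            for cat, k in counts.items():
                rows.append(
                    {
                        "covariate": cov,
                        "group": group,
                        "category": cat,
                        "count": int(k),
                        "share": k / total if total else np.nan,
                    }
                )
        out[cov] = pd.DataFrame(rows)

    rows = []
    for group, mask in (("flagged", flagged_mask), ("non_flagged", ~flagged_mask)):
        sub = records.loc[mask]
        for _, r in sub.iterrows():
            rows.append(
                {
                    "group": group,
                    "schooling_bin": _bin_label(r[outcome1], _SCHOOL_BINS),
                    "parity_bin": _bin_label(r[outcome2], _PARITY_BINS),
                }
            )
    if rows:
        grid = (
            pd.DataFrame(rows)
            .value_counts(["group", "schooling_bin", "parity_bin"])
            .rename("count")
            .reset_index()
        )
    else:
        grid = pd.DataFrame(columns=["group", "schooling_bin", "parity_bin", "count"])
    out["outcome_extremity"] = grid
    return out
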