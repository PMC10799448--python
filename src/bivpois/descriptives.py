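"""Descriptive tables: binned outcome distributions by covariate category.

Schooling years are classed as {0, 1-8, 9+} and children ever born
(parity) as {0, 1-4, 5+}; each covariate is cross-tabulated against the
bins with a Pearson chi-square test (no continuity correction) and row
percentages, the layout survey reports use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = ["BinningRule", "bin_outcomes", "crosstab_chi2", "describe"]


@dataclass(frozen=True)
class BinningRule:
    """Bin edges for the two outcomes; ``(lo, hi, label)`` with ``hi=None`` open."""

    schooling_bins: tuple = ((0, 0, "0"), (1, 8, "1-8"), (9, None, "9+"))
    parity_bins: tuple = ((0, 0, "0"), (1, 4, "1-4"), (5, None, "5+"))


def _assign(values: np.ndarray, bins) -> np.ndarray:
    out = np.empty(len(values), dtype=object)
    assigned = np.zeros(len(values), dtype=bool)
    for lo, hi, label in bins:
        mask = (values >= lo) & (values <= (np.inf if hi is None else hi)) & ~assigned
        out[mask] = label
        assigned |= mask
    if not assigned.all():
        bad = values[~assigned][0]
        raise ValueError(f"outcome value {bad!r} not covered by the bin scheme")
    return out


def bin_outcomes(
    records: pd.DataFrame,
    rule: BinningRule | None = None,
    outcome1: str = "schooling_years",
    outcome2: str = "children_ever_born",
) -> pd.DataFrame:
    """Add ``schooling_bin`` and ``parity_bin`` categorical columns."""
    rule = rule or BinningRule()
    out = records.copy()
    y1 = records[outcome1].to_numpy(dtype=float)
    y2 = records[outcome2].to_numpy(dtype=float)
    if np.any(y1 < 0) or np.any(y2 < 0):
        raise ValueError("outcomes must be non-negative")
    out["schooling_bin"] = _assign(y1, rule.schooling_bins)
    out["parity_bin"] = _assign(y2, rule.parity_bins)
    return out


def crosstab_chi2(
    records: pd.DataFrame, covariate: str, bin_column: str
) -> tuple[pd.DataFrame, float, float]:
    """Contingency table of ``covariate`` x ``bin_column`` with Pearson chi-square.

    Returns ``(table_with_row_percentages, statistic, p_value)``; the test
    uses no continuity correction and ``(r-1)(c-1)`` degrees of freedom.
    """
    table = pd.crosstab(records[covariate], records[bin_column])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 categories on each dimension")
    obs = table.to_numpy(dtype=float)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if np.any(expected == 0):
        raise ValueError(
            "zero expected cell count — merge sparse categories before testing"
        )
    stat, p, _, _ = chi2_contingency(obs, correction=False)
    pct = table.div(table.sum(axis=1), axis=0) * 100.0
    out = table.copy()
    for col in table.columns:
        out[f"{col} (%)"] = pct[col].round(1)
    return out, float(stat), float(p)


def describe(
    records: pd.DataFrame,
    covariates: list[str],
    rule: BinningRule | None = None,
    outcome1: str = "schooling_years",
    outcome2: str = "children_ever_born",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format descriptive table plus per-covariate chi-square summary."""
    binned = bin_outcomes(records, rule, outcome1, outcome2)
    long_rows, chi_rows = [], []
    for bin_col, outcome in (("schooling_bin", outcome1), ("parity_bin", outcome2)):
        for cov in covariates:
            table, stat, p = crosstab_chi2(binned, cov, bin_col)
            counts = pd.crosstab(binned[cov], binned[bin_col])
            for cat in counts.index:
                row_total = counts.loc[cat].sum()
                for b in counts.columns:
                    long_rows.append(
                        {
                            "outcome": outcome,
                            "covariate": cov,
                            "category": cat,
                            "bin": b,
                            "count": int(counts.loc[cat, b]),
                            "row_pct": 100.0 * counts.loc[cat, b] / row_total,
                        }
                    )
            chi_rows.append(
                {
                    "outcome": outcome,
                    "covariate": cov,
                    "chi2": stat,
                    "df": (counts.shape[0] - 1) * (counts.shape[1] - 1),
                    "p_value": p,
                }
            )
    return pd.DataFrame(long_rows), pd.DataFrame(chi_rows)
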