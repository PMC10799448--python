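"""Model specification and design-matrix encoding.

A :class:`ModelSpec` names the two count outcomes and lists the covariates
with their type (categorical or continuous) and, for categoricals, the
reference category.  Encoding is reference (treatment) coding with a
deterministic column order: covariates in declaration order, dummy columns
in sorted category order with the reference dropped.  The same design
matrix is used for both margins (parallel, non-exchangeable model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CovariateSpec", "ModelSpec", "DesignEncoder", "encode_design"]


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate: its column name, kind, and reference category."""

    name: str
    kind: str  # "categorical" | "continuous"
    reference: str | None = None

    def __post_init__(self):
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown covariate kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and self.reference is None:
            raise ValueError(f"categorical covariate {self.name!r} needs a reference category")


@dataclass
class ModelSpec:
    """Outcome columns plus the covariate encoding plan."""

    outcome1: str = "schooling_years"
    outcome2: str = "children_ever_born"
    covariates: list[CovariateSpec] = field(default_factory=list)
    intercept: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        covs = []
        for c in d.get("covariates", []):
            covs.append(
                CovariateSpec(
                    name=c["name"],
                    kind=c["kind"],
                    reference=c.get("reference"),
                )
            )
        return cls(
            outcome1=d.get("outcome1", "schooling_years"),
            outcome2=d.get("outcome2", "children_ever_born"),
            covariates=covs,
            intercept=bool(d.get("intercept", True)),
        )

    def to_dict(self) -> dict:
        return {
            "outcome1": self.outcome1,
            "outcome2": self.outcome2,
            "intercept": self.intercept,
            "covariates": [
                {"name": c.name, "kind": c.kind, "reference": c.reference}
                for c in self.covariates
            ],
        }

    @property
    def required_columns(self) -> list[str]:
        return [self.outcome1, self.outcome2] + [c.name for c in self.covariates]


class DesignEncoder:
    """Reference-coded design matrix builder with a frozen category map.

    ``fit`` learns the category levels present in the training data (the
    declared reference must be among them); ``transform`` then rejects
    unseen categories so prediction never silently extrapolates.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec

    def fit(self, records: pd.DataFrame) -> "DesignEncoder":
        missing = [c for c in self.spec.required_columns if c not in records.columns]
        if missing:
            raise KeyError(f"missing required column(s): {missing}")
        self.categories_: dict[str, list[str]] = {}
        kept = records.dropna(subset=self.spec.required_columns)
        for cov in self.spec.covariates:
            if cov.kind != "categorical":
                continue
            levels = sorted(str(v) for v in kept[cov.name].unique())
            if cov.reference not in levels:
                raise ValueError(
                    f"reference category {cov.reference!r} of {cov.name!r} "
                    f"not present in the data (seen: {levels})"
                )
            self.categories_[cov.name] = [cov.reference] + [
                lv for lv in levels if lv != cov.reference
            ]
        self.columns_ = self._column_names()
        return self

    def _column_names(self) -> list[str]:
        cols = ["intercept"] if self.spec.intercept else []
        for cov in self.spec.covariates:
            if cov.kind == "categorical":
                cols.extend(f"{cov.name}[{lv}]" for lv in self.categories_[cov.name][1:])
            else:
                cols.append(cov.name)
        return cols

    def transform(
        self,
        records: pd.DataFrame,
        require_outcomes: bool = True,
        check_degenerate: bool | None = None,
    ) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None, pd.DataFrame, int]:
        """Encode records.

        Returns ``(X, y1, y2, kept_records, n_dropped)``; ``y1``/``y2`` are
        ``None`` when ``require_outcomes`` is false.  Rows with a missing
        value in any required column are dropped (complete-case) and counted.
        Constant encoded columns are rejected when fitting (the default for
        ``require_outcomes=True``) but allowed when merely predicting on a
        subset of records.
        """
        if check_degenerate is None:
            check_degenerate = require_outcomes
        spec = self.spec
        cols = [c.name for c in spec.covariates]
        if require_outcomes:
            cols = [spec.outcome1, spec.outcome2] + cols
        missing = [c for c in cols if c not in records.columns]
        if missing:
            raise KeyError(f"missing required column(s): {missing}")
        kept = records.dropna(subset=cols)
        n_dropped = len(records) - len(kept)

        blocks = []
        if spec.intercept:
            blocks.append(np.ones((len(kept), 1)))
        for cov in spec.covariates:
            if cov.kind == "categorical":
                levels = self.categories_[cov.name]
                vals = kept[cov.name].astype(str)
                unseen = sorted(set(vals) - set(levels))
                if unseen:
                    raise ValueError(
                        f"unseen categor{'y' if len(unseen) == 1 else 'ies'} "
                        f"{unseen} in covariate {cov.name!r}"
                    )
                for lv in levels[1:]:
                    blocks.append((vals == lv).to_numpy(dtype=float)[:, None])
            else:
                blocks.append(kept[cov.name].to_numpy(dtype=float)[:, None])
        X = np.hstack(blocks) if blocks else np.empty((len(kept), 0))

        # degenerate columns make the information matrix singular
        if check_degenerate:
            for j, name in enumerate(self.columns_):
                if name == "intercept":
                    continue
                if len(kept) > 1 and np.ptp(X[:, j]) == 0:
                    raise ValueError(f"encoded column {name!r} is constant")

        y1 = y2 = None
        if require_outcomes:
            y1 = _as_counts(kept[spec.outcome1], spec.outcome1)
            y2 = _as_counts(kept[spec.outcome2], spec.outcome2)
        return X, y1, y2, kept, n_dropped


def _as_counts(series: pd.Series, name: str) -> np.ndarray:
    vals = series.to_numpy(dtype=float)
    bad = np.where((vals < 0) | (vals != np.floor(vals)))[0]
    if bad.size:
        raise ValueError(
            f"outcome {name!r} must be a non-negative integer; "
            f"offending row index {series.index[bad[0]]} (value {vals[bad[0]]!r})"
        )
    return vals.astype(np.int64).astype(float)


def encode_design(records: pd.DataFrame, spec: ModelSpec):
    """Fit an encoder on ``records`` and encode them in one step.

    Returns ``(X, y1, y2, encoder, n_dropped)``.
    """
    enc = DesignEncoder(spec).fit(records)
    X, y1, y2, _, n_dropped = enc.transform(records)
    return X, y1, y2, enc, n_dropped
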