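"""Synthetic DHS-like woman records with known ground truth.

The generator draws categorical covariates from configurable frequency
tables, two continuous covariates (current age, age at first sexual
intercourse, with age-at-first-sex <= age enforced by resampling), and
paired count outcomes from the trivariate-reduction construction

    y1 = A + C,  y2 = B + C,
    A ~ Poisson(exp(x'beta_schooling)),
    B ~ Poisson(exp(x'beta_fertility)),
    C ~ Poisson(theta3_shared),

so that the joint law of (y1, y2) given covariates is exactly the
bivariate Poisson pmf.  The common shock can only induce non-negative
dependence; the negative schooling-fertility association characteristic
of survey data is produced by shared covariates entering the two margins
with opposite signs, which is also how the fitted-mean correlation of the
regression model becomes strongly negative.

An optional contamination step overwrites a seeded fraction of records
with outcome pairs that contradict their covariate prediction (zero
schooling with high parity, or 9+ schooling years with zero parity),
mimicking the outlier profile such models flag in real surveys.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CovariateSpec, ModelSpec

__all__ = [
    "SimConfig",
    "sample_covariates",
    "sample_outcomes",
    "inject_outliers",
    "simulate",
    "default_scenario",
    "recovery_scenario",
    "calibration_scenario",
    "contamination_scenario",
]

AGE_COLUMN = "age"
AGE1STSEX_COLUMN = "age_first_sex"

_ETA_MAX = 30.0


@dataclass
class SimConfig:
    """Ground-truth configuration for one synthetic scenario.

    ``beta_schooling`` / ``beta_fertility`` are on the log-link scale, one
    entry per encoded design column in deterministic order: intercept,
    then for each categorical covariate (declaration order) one dummy per
    non-reference category (the first listed category is the reference),
    then the two continuous covariates (age, age at first sex) if enabled.
    """

    n_records: int
    seed: int
    category_probs: dict[str, dict[str, float]]
    beta_schooling: np.ndarray
    beta_fertility: np.ndarray
    theta3_shared: float = 0.0
    age_range: tuple[int, int] = (15, 49)
    age1stsex_range: tuple[int, int] = (12, 22)
    include_age: bool = True
    include_age1stsex: bool = True
    contamination_fraction: float = 0.0
    contamination_mode: str = "none"  # "none" | "swap_extremes"
    # outcome values written by swap_extremes: rates of the Poisson spread
    # above the hard floors (0/5+ children, 9+ schooling years)
    contaminated_parity_extra: float = 0.5
    contaminated_schooling_extra: float = 6.0

    def __post_init__(self):
        self.beta_schooling = np.asarray(self.beta_schooling, dtype=float)
        self.beta_fertility = np.asarray(self.beta_fertility, dtype=float)
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if self.theta3_shared < 0:
            raise ValueError("theta3_shared must be >= 0")
        if not 0.0 <= self.contamination_fraction < 0.5:
            raise ValueError("contamination_fraction must lie in [0, 0.5)")
        if self.contamination_mode not in ("none", "swap_extremes"):
            raise ValueError(f"unknown contamination_mode {self.contamination_mode!r}")
        for cov, probs in self.category_probs.items():
            total = float(sum(probs.values()))
            if abs(total - 1.0) > 1e-12:
                raise ValueError(
                    f"category probabilities for covariate {cov!r} sum to "
                    f"{total!r}, not 1"
                )
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"negative probability in covariate {cov!r}")
        p = self.n_columns
        for name, beta in (
            ("beta_schooling", self.beta_schooling),
            ("beta_fertility", self.beta_fertility),
        ):
            if beta.shape != (p,):
                raise ValueError(
                    f"{name} must have length {p} (one per encoded column), "
                    f"got {beta.shape}"
                )

    @property
    def column_order(self) -> list[str]:
        cols = ["intercept"]
        for cov, probs in self.category_probs.items():
            cats = list(probs)
            cols.extend(f"{cov}[{c}]" for c in cats[1:])
        if self.include_age:
            cols.append(AGE_COLUMN)
        if self.include_age1stsex:
            cols.append(AGE1STSEX_COLUMN)
        return cols

    @property
    def n_columns(self) -> int:
        return len(self.column_order)

    def model_spec(self) -> ModelSpec:
        """The ModelSpec matching this generator (reference = first category)."""
        covs = [
            CovariateSpec(name=cov, kind="categorical", reference=list(probs)[0])
            for cov, probs in self.category_probs.items()
        ]
        if self.include_age:
            covs.append(CovariateSpec(name=AGE_COLUMN, kind="continuous"))
        if self.include_age1stsex:
            covs.append(CovariateSpec(name=AGE1STSEX_COLUMN, kind="continuous"))
        return ModelSpec(covariates=covs)

    def true_coefficients(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.column_order,
                "beta_schooling": self.beta_schooling,
                "beta_fertility": self.beta_fertility,
            }
        )

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("age_range", "age1stsex_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _design_matrix(cov_table: pd.DataFrame, config: SimConfig) -> np.ndarray:
    blocks = [np.ones((len(cov_table), 1))]
    for cov, probs in config.category_probs.items():
        cats = list(probs)
        vals = cov_table[cov].astype(str)
        for c in cats[1:]:
            blocks.append((vals == c).to_numpy(dtype=float)[:, None])
    if config.include_age:
        blocks.append(cov_table[AGE_COLUMN].to_numpy(dtype=float)[:, None])
    if config.include_age1stsex:
        blocks.append(cov_table[AGE1STSEX_COLUMN].to_numpy(dtype=float)[:, None])
    return np.hstack(blocks)


def _linear_predictors(cov_table: pd.DataFrame, config: SimConfig):
    X = _design_matrix(cov_table, config)
    eta1 = X @ config.beta_schooling
    eta2 = X @ config.beta_fertility
    if np.any(np.abs(eta1) > _ETA_MAX) or np.any(np.abs(eta2) > _ETA_MAX):
        raise FloatingPointError(
            "linear predictor exceeds |30|; rescale coefficients or covariates"
        )
    return eta1, eta2


def sample_covariates(config: SimConfig) -> pd.DataFrame:
    """Draw the covariate table (deterministic given ``config.seed``)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_records
    out = {"record_id": np.arange(n)}
    for cov, probs in config.category_probs.items():
        cats = np.array(list(probs), dtype=object)
        p = np.array(list(probs.values()), dtype=float)
        p = p / p.sum()
        out[cov] = rng.choice(cats, size=n, p=p)
    if config.include_age:
        lo, hi = config.age_range
        age = rng.integers(lo, hi + 1, size=n)
        out[AGE_COLUMN] = age
    if config.include_age1stsex:
        lo, hi = config.age1stsex_range
        a1s = rng.integers(lo, hi + 1, size=n)
        if config.include_age:
            # resample until age at first sex does not exceed current age
            for _ in range(1000):
                bad = a1s > out[AGE_COLUMN]
                if not bad.any():
                    break
                a1s[bad] = rng.integers(lo, hi + 1, size=int(bad.sum()))
            else:
                a1s = np.minimum(a1s, out[AGE_COLUMN])
        out[AGE1STSEX_COLUMN] = a1s
    return pd.DataFrame(out)


def sample_outcomes(cov_table: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Attach paired count outcomes drawn by trivariate reduction."""
    rng = np.random.default_rng(config.seed + 1_000_003)
    eta1, eta2 = _linear_predictors(cov_table, config)
    n = len(cov_table)
    a = rng.poisson(np.exp(eta1))
    b = rng.poisson(np.exp(eta2))
    c = rng.poisson(config.theta3_shared, size=n) if config.theta3_shared > 0 else 0
    records = cov_table.copy()
    records["schooling_years"] = a + c
    records["children_ever_born"] = b + c
    records["is_contaminated"] = False
    return records


def inject_outliers(records: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Overwrite a seeded subset of outcomes against their covariate prediction.

    Records whose predicted schooling mean is above the sample median get
    (0 schooling, 5-or-more children); those below get (9-or-more schooling,
    0 children).  The flipped records carry ``is_contaminated = True``.
    """
    out = records.copy()
    frac = config.contamination_fraction
    if config.contamination_mode == "none" or frac == 0.0:
        return out
    if frac >= 0.5:
        raise ValueError("contamination_fraction must be < 0.5")
    rng = np.random.default_rng(config.seed + 2_000_003)
    n = len(out)
    n_bad = int(round(frac * n))
    if n_bad == 0:
        return out
    idx = rng.choice(n, size=n_bad, replace=False)
    eta1, _ = _linear_predictors(out, config)
    pred_schooling = np.exp(eta1)
    high = pred_schooling[idx] >= np.median(pred_schooling)

    schooling = out["schooling_years"].to_numpy().copy()
    parity = out["children_ever_born"].to_numpy().copy()
    hi_idx = idx[high]
    lo_idx = idx[~high]
    schooling[hi_idx] = 0
    parity[hi_idx] = 5 + rng.poisson(config.contaminated_parity_extra, size=len(hi_idx))
    schooling[lo_idx] = 9 + rng.poisson(
        config.contaminated_schooling_extra, size=len(lo_idx)
    )
    parity[lo_idx] = 0
    out["schooling_years"] = schooling
    out["children_ever_born"] = parity
    flags = out["is_contaminated"].to_numpy().copy()
    flags[idx] = True
    out["is_contaminated"] = flags
    return out


def simulate(config: SimConfig) -> pd.DataFrame:
    """Full generator: covariates, outcomes, optional contamination."""
    cov = sample_covariates(config)
    rec = sample_outcomes(cov, config)
    return inject_outliers(rec, config)


# ---------------------------------------------------------------------------
# shipped scenarios
# ---------------------------------------------------------------------------

# Overall-sample category counts of the 2004 Malawi DHS (n = 11,698), so the
# synthetic marginals resemble that survey's covariate mix.
_MDHS2004_COUNTS: dict[str, dict[str, int]] = {
    "ethnicity": {
        "tumbuka_tonga_other": 3618,
        "lomwe_yao_sena": 4413,
        "chewa_nyanja": 3667,
    },
    "religion": {"none_other": 127, "muslim": 1816, "christian": 9755},
    "wealth": {"poor": 4409, "middle": 2517, "rich": 4772},
    "marital_status": {"unmarried": 1902, "married_cohabiting": 8385, "separated_other": 1411},
    "occupation": {
        "not_working": 4733,
        "domestic_nonformal": 5430,
        "professional_formal": 1504,
    },
    "contraceptive_use": {"non_user_other": 9164, "user": 2534},
    "residence": {"rural": 10058, "urban": 1640},
    "region": {"northern": 1597, "central": 4199, "southern": 5902},
}


def _normalised(counts: dict[str, dict[str, int]]) -> dict[str, dict[str, float]]:
    out = {}
    for cov, cats in counts.items():
        total = sum(cats.values())
        probs = {c: k / total for c, k in cats.items()}
        # pin the float sum to exactly 1 on the last category
        last = list(probs)[-1]
        probs[last] += 1.0 - sum(probs.values())
        out[cov] = probs
    return out


def default_scenario(
    n_records: int = 5000, seed: int = 0, theta3_shared: float = 0.0, **overrides
) -> SimConfig:
    """DHS-like scenario: realistic covariate mix, marginal means of roughly
    5 schooling years and 3 children, and strongly negatively correlated
    fitted means (rank correlation about -0.6)."""
    # column order: intercept; ethnicity[2]; religion[2]; wealth[2];
    # marital[2]; occupation[2]; contraceptive[1]; residence[1]; region[2];
    # age; age_first_sex
    beta_schooling = np.array(
        [
            1.15,  # intercept
            -0.20, -0.10,  # ethnicity: lomwe_yao_sena, chewa_nyanja
            0.15, 0.35,  # religion: muslim, christian
            0.15, 0.45,  # wealth: middle, rich
            -0.35, -0.10,  # marital: married, separated
            -0.15, 0.30,  # occupation: domestic, professional
            0.08,  # contraceptive user
            0.35,  # residence: urban (ref rural)
            -0.10, -0.15,  # region: central, southern
            -0.014,  # age (per year)
            0.048,  # age at first sex (per year)
        ]
    )
    beta_fertility = np.array(
        [
            -1.40,  # intercept
            0.05, 0.03,
            0.05, 0.00,
            -0.05, -0.25,
            1.30, 1.10,
            0.12, -0.05,
            0.20,
            -0.22,  # urban
            0.05, 0.02,
            0.055,  # age
            -0.045,  # age at first sex
        ]
    )
    base = dict(
        n_records=n_records,
        seed=seed,
        category_probs=_normalised(_MDHS2004_COUNTS),
        beta_schooling=beta_schooling,
        beta_fertility=beta_fertility,
        theta3_shared=theta3_shared,
    )
    base.update(overrides)
    return SimConfig(**base)


def recovery_scenario(n_records: int = 5000, seed: int = 0, **overrides) -> SimConfig:
    """Compact scenario for parameter-recovery studies.

    Five covariates, each contributing one design column (three binary
    indicators plus the two continuous ages), so each margin estimates six
    coefficients.
    """
    probs = {
        "wealth": {"poor_middle": 0.59, "rich": 0.41},
        "marital_status": {"unmarried": 0.28, "married_cohabiting": 0.72},
        "residence": {"rural": 0.86, "urban": 0.14},
    }
    beta_schooling = np.array([1.30, 0.45, -0.25, 0.35, -0.010, 0.040])
    beta_fertility = np.array([-1.30, -0.25, 1.25, -0.20, 0.055, -0.045])
    base = dict(
        n_records=n_records,
        seed=seed,
        category_probs=probs,
        beta_schooling=beta_schooling,
        beta_fertility=beta_fertility,
    )
    base.update(overrides)
    return SimConfig(**base)


def calibration_scenario(n_records: int = 5000, seed: int = 0, **overrides) -> SimConfig:
    """Well-specified scenario for residual-calibration checks.

    Coefficients keep every fitted mean inside roughly 3-14 on both
    margins.  Poisson deviance residuals carry a negative bias that grows
    as the mean shrinks (about -0.27 at mean 0.2, -0.11 at mean 3, -0.05
    at mean 12), so mid-range means are where the averaged residual d* is
    honestly near zero mean under a correct model.
    """
    probs = {
        "wealth": {"poor": 0.38, "middle": 0.21, "rich": 0.41},
        "residence": {"rural": 0.86, "urban": 0.14},
    }
    beta_schooling = np.array([1.95, 0.15, 0.35, 0.10, 0.010])
    beta_fertility = np.array([1.60, -0.10, -0.22, -0.10, -0.005])
    base = dict(
        n_records=n_records,
        seed=seed,
        category_probs=probs,
        beta_schooling=beta_schooling,
        beta_fertility=beta_fertility,
        include_age=False,
        include_age1stsex=True,
    )
    base.update(overrides)
    return SimConfig(**base)


def contamination_scenario(
    n_records: int = 10_000,
    seed: int = 0,
    contamination_fraction: float = 0.01,
    **overrides,
) -> SimConfig:
    """Contamination-recovery stress scenario.

    A dominant wealth effect makes the predicted schooling means bimodal
    (roughly 2 versus 12), and the fertility signal is aligned with it so
    each cluster's predicted parity matches the contamination floor of the
    opposite swap.  Extreme-swapped records then contradict both margins
    at once and stand out in the averaged deviance residual, instead of
    producing opposite-signed marginal residuals that cancel in d*.
    """
    probs = {
        "wealth": {"poor": 0.38, "middle": 0.21, "rich": 0.41},
        "residence": {"rural": 0.86, "urban": 0.14},
        "occupation": {
            "not_working": 0.40,
            "domestic_nonformal": 0.47,
            "professional_formal": 0.13,
        },
    }
    beta_schooling = np.array([0.45, 0.15, 1.80, 0.20, -0.05, 0.25, 0.020])
    beta_fertility = np.array([0.00, 0.10, 1.45, 0.10, 0.05, 0.10, 0.010])
    base = dict(
        n_records=n_records,
        seed=seed,
        category_probs=probs,
        beta_schooling=beta_schooling,
        beta_fertility=beta_fertility,
        include_age=False,
        include_age1stsex=True,
        contamination_fraction=contamination_fraction,
        contamination_mode="swap_extremes",
        contaminated_parity_extra=0.3,
        contaminated_schooling_extra=10.0,
    )
    base.update(overrides)
    return SimConfig(**base)
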