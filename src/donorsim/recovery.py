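"""Post-donation hemoglobin recovery model.

A donor's hemoglobin ``t`` weeks after a donation at which the hematology
analyzer measured ``h`` g/L is modeled as

    Hb(t) = intercept + coef_index_hb * h + coef_age * age
            + ethnicity effect + blood-group effect + slope * t
            + b_i + e,        b_i ~ N(0, latent_sd^2),  e ~ N(0, residual_sd^2)

with a common linear recovery rate (slope) across donors within a sex
stratum.  The donor-level intercept ``b_i`` persists across all of that
donor's visits; the residual is fresh at every visit.

The recall policy never observes ``b_i`` — it only knows the last analyzer
measurement — so the policy-facing predictive distribution at time ``t`` is
``N(mu(t), latent_sd^2 + residual_sd^2)``.  The probability of being over
the donation threshold and the personalized-interval solver below both use
that marginal distribution.

Model fitting is statsmodels-style: :class:`HbRecoveryModel` is built from a
longitudinal table and its :meth:`~HbRecoveryModel.fit` returns an
:class:`HbRecoveryResults` carrying estimates, standard errors and a
``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import ConfigurationError, _packaged_defaults

__all__ = [
    "RecoveryModel",
    "IntervalResult",
    "default_recovery_model",
    "linear_predictor",
    "linear_predictor_frame",
    "prob_over_threshold",
    "personalized_interval",
    "simulate_true_hb",
    "HbRecoveryModel",
    "HbRecoveryResults",
    "fit_recovery_model",
]


@dataclass(frozen=True)
class RecoveryModel:
    """Coefficients and variance components of one sex stratum's recovery model."""

    sex: str
    intercept: float
    coef_index_hb: float
    slope: float
    coef_age: float = 0.0
    ethnicity_effects: Mapping[str, float] = field(default_factory=dict)
    blood_group_effects: Mapping[str, float] = field(default_factory=dict)
    latent_sd: float = 0.0
    residual_sd: float = 0.0
    ses: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.latent_sd < 0 or self.residual_sd < 0:
            raise ConfigurationError("variance components must be non-negative")
        object.__setattr__(self, "ethnicity_effects", dict(self.ethnicity_effects))
        object.__setattr__(self, "blood_group_effects", dict(self.blood_group_effects))
        object.__setattr__(self, "ses", dict(self.ses))

    @property
    def predictive_sd(self) -> float:
        """Marginal sd of a future measurement: sqrt(latent^2 + residual^2)."""
        return math.hypot(self.latent_sd, self.residual_sd)

    def replace(self, **changes) -> "RecoveryModel":
        return replace(self, **changes)


class IntervalResult(NamedTuple):
    """Personalized inter-donation interval in whole weeks, with a cap flag."""

    weeks: int
    capped: bool


def default_recovery_model(sex: str, params: Mapping | None = None) -> RecoveryModel:
    """The packaged default recovery model for one sex stratum."""
    params = params or _packaged_defaults()
    block = dict(params["recovery"][sex])
    return RecoveryModel(sex=sex, **block)


def _covariate_effect(model: RecoveryModel, donor) -> float:
    try:
        eth = model.ethnicity_effects[donor.ethnicity] if model.ethnicity_effects else 0.0
    except KeyError:
        raise ConfigurationError(
            f"unknown ethnicity category {donor.ethnicity!r} for this model"
        ) from None
    try:
        bg = model.blood_group_effects[donor.blood_group] if model.blood_group_effects else 0.0
    except KeyError:
        raise ConfigurationError(
            f"unknown blood group category {donor.blood_group!r} for this model"
        ) from None
    return model.coef_age * donor.age + eth + bg


def linear_predictor(model: RecoveryModel, donor, t: float, last_hb: float | None = None) -> float:
    """Mean hemoglobin (g/L) ``t`` weeks after the anchoring donation.

    ``last_hb`` is the analyzer measurement anchoring the trajectory; it
    defaults to the donor's index-donation hemoglobin.
    """
    if t < 0:
        raise ValueError("time since donation must be non-negative")
    h = donor.index_hb if last_hb is None else last_hb
    return model.intercept + model.coef_index_hb * h + _covariate_effect(model, donor) + model.slope * t


def linear_predictor_frame(
    model: RecoveryModel, donors: pd.DataFrame, t, last_hb=None
) -> np.ndarray:
    """Vectorized :func:`linear_predictor` over a donor table."""
    h = donors["index_hb"].to_numpy(float) if last_hb is None else np.asarray(last_hb, float)
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("time since donation must be non-negative")
    eff = np.full(len(donors), model.coef_age, dtype=float) * donors["age"].to_numpy(float)
    if model.ethnicity_effects:
        mapped = donors["ethnicity"].map(model.ethnicity_effects)
        if mapped.isna().any():
            bad = donors.loc[mapped.isna(), "ethnicity"].unique()
            raise ConfigurationError(f"unknown ethnicity categories {list(bad)}")
        eff += mapped.to_numpy(float)
    if model.blood_group_effects:
        mapped = donors["blood_group"].map(model.blood_group_effects)
        if mapped.isna().any():
            bad = donors.loc[mapped.isna(), "blood_group"].unique()
            raise ConfigurationError(f"unknown blood group categories {list(bad)}")
        eff += mapped.to_numpy(float)
    return model.intercept + model.coef_index_hb * h + eff + model.slope * t


def prob_over_threshold(
    model: RecoveryModel, donor, t: float, threshold: float, last_hb: float | None = None
) -> float:
    """P(hemoglobin >= threshold) at ``t`` weeks, under the marginal predictive law.

    With zero predictive sd the contract degenerates to a step function:
    1 when the mean is at or above threshold, else 0.
    """
    mu = linear_predictor(model, donor, t, last_hb)
    sigma = model.predictive_sd
    if sigma == 0.0:
        return 1.0 if mu >= threshold else 0.0
    return float(norm.cdf((mu - threshold) / sigma))


def personalized_interval(
    model: RecoveryModel,
    donor,
    threshold: float,
    p_min: float,
    t_min: int,
    t_max: int,
    last_hb: float | None = None,
) -> IntervalResult:
    """Smallest whole week ``t`` in [t_min, t_max] with P(over threshold) >= p_min.

    Closed form: invert ``mu(t) = threshold + z(p_min) * sigma`` and round up
    to a whole week, then nudge to guarantee exact agreement with a
    week-by-week scan of :func:`prob_over_threshold` under floating point.
    If the certainty level is never reached by ``t_max`` the interval is
    capped there and flagged.
    """
    if not 0.0 < p_min < 1.0:
        raise ValueError("p_min must be strictly between 0 and 1")
    if t_min > t_max:
        raise ValueError("t_min must not exceed t_max")

    def ok(t: int) -> bool:
        return prob_over_threshold(model, donor, t, threshold, last_hb) >= p_min

    if ok(t_min):
        return IntervalResult(int(t_min), False)
    if model.slope <= 0.0:
        # Probability non-increasing in t: never crosses.
        return IntervalResult(int(t_max), True)

    sigma = model.predictive_sd
    target = threshold + norm.ppf(p_min) * sigma
    base = linear_predictor(model, donor, 0.0, last_hb)
    t_star = math.ceil((target - base) / model.slope - 1e-12)
    t_star = max(t_star, t_min)
    # Floating-point guard: step to the exact first week the scan would accept.
    while t_star <= t_max and not ok(t_star):
        t_star += 1
    while t_star - 1 >= t_min and ok(t_star - 1):
        t_star -= 1
    if t_star > t_max:
        return IntervalResult(int(t_max), True)
    return IntervalResult(int(t_star), False)


def simulate_true_hb(
    model: RecoveryModel,
    donor,
    t: float,
    rng: np.random.Generator,
    last_hb: float | None = None,
) -> float:
    """One realization of the donor's true hemoglobin at ``t`` weeks.

    Adds the donor's persistent latent offset (carried on the donor record,
    hidden from policies) and a fresh residual draw to the linear predictor.
    """
    mu = linear_predictor(model, donor, t, last_hb)
    resid = rng.normal(0.0, model.residual_sd) if model.residual_sd > 0 else 0.0
    return mu + donor.latent_offset + resid


# ---------------------------------------------------------------------------
# Fitting


def _design_matrix(data: pd.DataFrame):
    """Design matrix for the recovery regression; returns (X, column names)."""
    cols = {"const": np.ones(len(data))}
    cols["index_hb"] = data["index_hb"].to_numpy(float)
    cols["age"] = data["age"].to_numpy(float)
    cols["t_weeks"] = data["t_weeks"].to_numpy(float)
    cat_levels = {}
    for cat in ("ethnicity", "blood_group"):
        levels = sorted(data[cat].astype(str).unique())
        cat_levels[cat] = levels
        for lv in levels[1:]:  # first level is the reference
            cols[f"{cat}[{lv}]"] = (data[cat].astype(str) == lv).to_numpy(float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    return X, names, cat_levels


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # Identify offending columns: those linearly dependent on their predecessors.
    bad = []
    for j in range(1, X.shape[1]):
        sub = X[:, : j + 1]
        if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X[:, :j]):
            bad.append(names[j])
    raise np.linalg.LinAlgError(
        f"design matrix is rank deficient; collinear terms: {bad or names}"
    )


class HbRecoveryResults:
    """Estimates from a fitted recovery regression.

    Attributes
    ----------
    params, bse : pandas.Series
        Coefficient estimates and standard errors, indexed by term name.
    latent_sd, residual_sd : float
        Estimated variance components.  With a single return measurement per
        donor the two are not separately identifiable; the total predictive
        sd is then reported as ``residual_sd`` and ``latent_sd`` is 0.
    """

    def __init__(self, model: "HbRecoveryModel", sm_results, params, bse,
                 latent_sd: float, residual_sd: float, cat_levels):
        self.model = model
        self._sm = sm_results
        self.params = params
        self.bse = bse
        self.latent_sd = float(latent_sd)
        self.residual_sd = float(residual_sd)
        self._cat_levels = cat_levels

    @property
    def predictive_sd(self) -> float:
        return math.hypot(self.latent_sd, self.residual_sd)

    def recovery_model(self) -> RecoveryModel:
        """Package the estimates as a :class:`RecoveryModel`."""
        eth = {self._cat_levels["ethnicity"][0]: 0.0}
        for lv in self._cat_levels["ethnicity"][1:]:
            eth[lv] = float(self.params[f"ethnicity[{lv}]"])
        bg = {self._cat_levels["blood_group"][0]: 0.0}
        for lv in self._cat_levels["blood_group"][1:]:
            bg[lv] = float(self.params[f"blood_group[{lv}]"])
        ses = {
            "intercept": float(self.bse["const"]),
            "coef_index_hb": float(self.bse["index_hb"]),
            "coef_age": float(self.bse["age"]),
            "slope": float(self.bse["t_weeks"]),
        }
        return RecoveryModel(
            sex=self.model.sex,
            intercept=float(self.params["const"]),
            coef_index_hb=float(self.params["index_hb"]),
            coef_age=float(self.params["age"]),
            slope=float(self.params["t_weeks"]),
            ethnicity_effects=eth,
            blood_group_effects=bg,
            latent_sd=self.latent_sd,
            residual_sd=self.residual_sd,
            ses=ses,
        )

    def summary(self):
        """The underlying statsmodels summary table."""
        return self._sm.summary()


class HbRecoveryModel:
    """Recovery regression on a longitudinal table (statsmodels-style).

    The table needs columns ``id, sex, age, ethnicity, blood_group,
    index_hb, t_weeks, return_hb``.  With one return measurement per donor
    the model is an ordinary least-squares regression of return hemoglobin
    on index hemoglobin, age, categorical covariates and time since
    donation.  When donors contribute repeated returns a donor-level random
    intercept is added (linear mixed model, fitted by REML), which separates
    the between-donor and residual variance components.
    """

    REQUIRED = ("id", "age", "ethnicity", "blood_group", "index_hb", "t_weeks", "return_hb")

    def __init__(self, data: pd.DataFrame, sex: str | None = None):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"longitudinal table is missing columns {missing}")
        if len(data) == 0:
            raise ValueError("longitudinal table is empty")
        self.data = data.reset_index(drop=True)
        if sex is None:
            sexes = data["sex"].unique() if "sex" in data.columns else []
            if len(sexes) != 1:
                raise ValueError("pass sex= explicitly for multi- or no-sex tables")
            sex = str(sexes[0])
        self.sex = sex
        self.repeated = bool(self.data["id"].duplicated().any())

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, sex: str | None = None) -> "HbRecoveryModel":
        return cls(data, sex=sex)

    def fit(self) -> HbRecoveryResults:
        import statsmodels.api as sm

        X, names, cat_levels = _design_matrix(self.data)
        _check_full_rank(X, names)
        y = self.data["return_hb"].to_numpy(float)
        if self.repeated:
            groups = self.data["id"].to_numpy()
            mixed = sm.MixedLM(y, X, groups=groups)
            res = mixed.fit(reml=True)
            params = pd.Series(res.fe_params, index=names)
            bse = pd.Series(np.asarray(res.bse_fe), index=names)
            latent_sd = float(np.sqrt(max(float(np.squeeze(res.cov_re)), 0.0)))
            residual_sd = float(np.sqrt(res.scale))
        else:
            res = sm.OLS(y, X).fit()
            params = pd.Series(res.params, index=names)
            bse = pd.Series(res.bse, index=names)
            latent_sd = 0.0
            residual_sd = float(np.sqrt(res.scale)) if res.df_resid > 0 else 0.0
        return HbRecoveryResults(self, res, params, bse, latent_sd, residual_sd, cat_levels)


def fit_recovery_model(data: pd.DataFrame, sex: str | None = None) -> RecoveryModel:
    """Convenience wrapper: fit the recovery regression, return a :class:`RecoveryModel`."""
    return HbRecoveryModel.from_dataframe(data, sex=sex).fit().recovery_model()
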