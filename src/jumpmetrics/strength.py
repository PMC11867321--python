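"""1RM back-squat estimation from jump metrics.

Two routes:

* :func:`estimate_1rm_published` applies the published single-predictor
  lines — 1RM = 0.352 x CMJ peak kinetic energy (J) + 12.775 and
  1RM = 0.078 x SJ mean power (W) + 12.254, both in kg — as fixed constants.
* :class:`OneRMRegressor` refits an estimation model from a cohort table:
  a collinearity screen over candidate predictors followed by forward
  stepwise selection with partial-F entry/removal tests, reporting adjusted
  R^2 and the standard error of estimate SEE = sqrt(sum (e - m)^2 / (N - 2)).

Refitting never overwrites the published constants.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

# Published estimation lines (kg per metric unit, kg).
PUBLISHED_EQUATIONS = {
    "CMJ": {"predictor": "peak_kinetic_energy_j", "slope": 0.352, "intercept": 12.775},
    "SJ": {"predictor": "mean_power_w", "slope": 0.078, "intercept": 12.254},
}


def estimate_1rm_published(metric_value: float, jump_type: str) -> float:
    """Estimated 1RM back squat (kg) from the published line.

    ``metric_value`` is CMJ peak kinetic energy in J or SJ mean power in W.
    """
    if jump_type not in PUBLISHED_EQUATIONS:
        raise ValueError(f"jump_type must be one of {tuple(PUBLISHED_EQUATIONS)}")
    value = np.asarray(metric_value, dtype=float)
    if np.any(value < 0):
        raise ValueError("metric value must be non-negative")
    eq = PUBLISHED_EQUATIONS[jump_type]
    out = eq["slope"] * value + eq["intercept"]
    return float(out) if out.ndim == 0 else out


def compute_see(estimated, measured) -> float:
    """Standard error of estimate: sqrt(sum (e_i - m_i)^2 / (N - 2)), in kg."""
    e = np.asarray(estimated, dtype=float)
    m = np.asarray(measured, dtype=float)
    if e.shape != m.shape or e.ndim != 1:
        raise ValueError("estimated and measured must be 1-d and of equal length")
    n = e.size
    if n < 3:
        raise ValueError("SEE needs at least 3 pairs")
    return float(np.sqrt(np.sum((e - m) ** 2) / (n - 2)))


def mean_error_percent(estimated, measured, *, method: str = "mae") -> float:
    """Mean estimation error as a percentage of the mean measured 1RM.

    ``method='mae'`` (default): 100 * mean|e - m| / mean(m).
    ``method='see'``: 100 * SEE / mean(m).
    """
    e = np.asarray(estimated, dtype=float)
    m = np.asarray(measured, dtype=float)
    if e.shape != m.shape:
        raise ValueError("estimated and measured must have equal length")
    mbar = float(m.mean())
    if mbar <= 0:
        raise ValueError("mean measured value must be positive")
    if method == "mae":
        return 100.0 * float(np.mean(np.abs(e - m))) / mbar
    if method == "see":
        return 100.0 * compute_see(e, m) / mbar
    raise ValueError("method must be 'mae' or 'see'")


@dataclass(frozen=True)
class EstimationModel:
    """Serializable summary of a fitted 1RM estimation model."""

    predictors: tuple[str, ...]
    slopes: tuple[float, ...]
    intercept: float
    adjusted_r2: float
    see: float
    n: int
    p_value: float

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["predictors"] = list(self.predictors)
        payload["slopes"] = list(self.slopes)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "EstimationModel":
        with open(path) as fh:
            payload = json.load(fh)
        payload["predictors"] = tuple(payload["predictors"])
        payload["slopes"] = tuple(payload["slopes"])
        return cls(**payload)


class OneRMRegressor(RegressorMixin, BaseEstimator):
    """Stepwise linear 1RM estimation model over jump-metric predictors.

    Fitting first screens candidate predictors for collinearity (for any
    pair with |r| above ``collinearity_r_max`` the one less correlated with
    the response is dropped), then runs forward stepwise selection: at each
    step the candidate with the smallest partial-F p-value enters if below
    ``entry_alpha``, and after every entry any included predictor whose
    partial-F p-value rises above ``removal_alpha`` is removed.  Ordinary
    least squares throughout.

    Attributes (after ``fit``)
    --------------------------
    predictors_ : list of selected predictor names (may be empty: "no model")
    coef_, intercept_ : fitted coefficients (kg per unit, kg)
    adjusted_r2_, see_, p_value_, n_ : fit summary
    dropped_collinear_ : predictors removed at the collinearity screen
    """

    def __init__(
        self,
        entry_alpha: float = 0.05,
        removal_alpha: float = 0.10,
        collinearity_r_max: float = 0.9,
        min_n: int = 8,
    ):
        self.entry_alpha = entry_alpha
        self.removal_alpha = removal_alpha
        self.collinearity_r_max = collinearity_r_max
        self.min_n = min_n

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _as_frame(X, feature_names=None) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.astype(float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(X.shape[1])]
        return pd.DataFrame(X, columns=list(feature_names))

    def _collinearity_screen(self, X: pd.DataFrame, y: np.ndarray) -> list[str]:
        keep = list(X.columns)
        dropped = []
        changed = True
        while changed:
            changed = False
            for i, a in enumerate(keep):
                for b in keep[i + 1:]:
                    r = abs(np.corrcoef(X[a], X[b])[0, 1])
                    if r > self.collinearity_r_max:
                        ra = abs(np.corrcoef(X[a], y)[0, 1])
                        rb = abs(np.corrcoef(X[b], y)[0, 1])
                        loser = a if ra < rb else b
                        keep.remove(loser)
                        dropped.append(loser)
                        changed = True
                        break
                if changed:
                    break
        self.dropped_collinear_ = dropped
        return keep

    @staticmethod
    def _ols(X: pd.DataFrame, y: np.ndarray, cols: list[str]):
        design = sm.add_constant(X[cols], has_constant="add")
        return sm.OLS(y, design).fit()

    def _stepwise(self, X: pd.DataFrame, y: np.ndarray, candidates: list[str]) -> list[str]:
        included: list[str] = []
        while True:
            remaining = [c for c in candidates if c not in included]
            entered = None
            if remaining:
                pvals = {}
                for c in remaining:
                    res = self._ols(X, y, included + [c])
                    pvals[c] = float(res.pvalues[c])
                best = min(pvals, key=pvals.get)
                if pvals[best] < self.entry_alpha:
                    included.append(best)
                    entered = best
            # backward pass: drop anything whose partial F fell out
            while included:
                res = self._ols(X, y, included)
                worst = max(included, key=lambda c: float(res.pvalues[c]))
                if float(res.pvalues[worst]) > self.removal_alpha:
                    included.remove(worst)
                    if worst == entered:
                        entered = None
                else:
                    break
            if entered is None:
                return included

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X, y, feature_names=None):
        """Fit the stepwise model; ``X`` may be a DataFrame or 2-d array."""
        Xf = self._as_frame(X, feature_names)
        y = np.asarray(y, dtype=float).ravel()
        if len(Xf) != y.size:
            raise ValueError("X and y lengths differ")
        if y.size < self.min_n:
            raise ValueError(
                f"n = {y.size} below the minimum of {self.min_n} for regression estimation"
            )
        if Xf.shape[1] < 1:
            raise ValueError("need at least one candidate predictor")
        for col in Xf.columns:
            if np.std(Xf[col].to_numpy()) == 0:
                raise ValueError(f"constant predictor column: {col!r}")

        candidates = self._collinearity_screen(Xf, y)
        selected = self._stepwise(Xf, y, candidates)
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        self.n_features_in_ = Xf.shape[1]
        self.predictors_ = selected
        self.n_ = int(y.size)
        if selected:
            res = self._ols(Xf, y, selected)
            self.coef_ = res.params[selected].to_numpy()
            self.intercept_ = float(res.params["const"])
            self.adjusted_r2_ = float(res.rsquared_adj)
            self.p_value_ = float(res.f_pvalue)
            self.results_ = res
            self.see_ = compute_see(res.fittedvalues, y)
        else:  # "no model": nothing met the entry criterion
            self.coef_ = np.empty(0)
            self.intercept_ = float(y.mean())
            self.adjusted_r2_ = 0.0
            self.p_value_ = float("nan")
            self.results_ = None
            self.see_ = compute_see(np.full_like(y, y.mean()), y)
        return self

    def predict(self, X):
        check_is_fitted(self, "predictors_")
        Xf = self._as_frame(X, getattr(self, "feature_names_in_", None))
        out = np.full(len(Xf), self.intercept_, dtype=float)
        for name, coef in zip(self.predictors_, self.coef_):
            out += coef * Xf[name].to_numpy(dtype=float)
        return out

    def to_model(self) -> EstimationModel:
        check_is_fitted(self, "predictors_")
        return EstimationModel(
            predictors=tuple(self.predictors_),
            slopes=tuple(float(c) for c in self.coef_),
            intercept=self.intercept_,
            adjusted_r2=self.adjusted_r2_,
            see=self.see_,
            n=self.n_,
            p_value=self.p_value_,
        )


def fit_model(
    cohort: pd.DataFrame,
    predictors: list[str],
    *,
    response: str = "measured_1rm_kg",
    entry_alpha: float = 0.05,
    removal_alpha: float = 0.10,
    collinearity_r_max: float = 0.9,
) -> EstimationModel:
    """Thin wrapper: stepwise-fit a cohort table and return the summary."""
    missing = [c for c in list(predictors) + [response] if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    reg = OneRMRegressor(
        entry_alpha=entry_alpha,
        removal_alpha=removal_alpha,
        collinearity_r_max=collinearity_r_max,
    )
    reg.fit(cohort[list(predictors)], cohort[response].to_numpy())
    return reg.to_model()


def loo_predictions(cohort: pd.DataFrame, predictor: str,
                    response: str = "measured_1rm_kg") -> np.ndarray:
    """Leave-one-out simple-regression predictions (small-cohort honesty check)."""
    x = cohort[predictor].to_numpy(dtype=float)
    y = cohort[response].to_numpy(dtype=float)
    out = np.empty_like(y)
    for i in range(y.size):
        mask = np.ones(y.size, dtype=bool)
        mask[i] = False
        slope, intercept, *_ = stats.linregress(x[mask], y[mask])
        out[i] = slope * x[i] + intercept
    return out
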