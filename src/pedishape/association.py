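"""Quartile logistic associations between body-shape indices and high CMRI.

Subjects are grouped into within-sex quartiles of an index (Q1 < P25,
P25 ≤ Q2 < P50, P50 ≤ Q3 < P75, Q4 ≥ P75; cutpoints are empirical type-7
percentiles, boundaries lower-inclusive). A binary logistic regression of
the high-risk flag on Q1/Q3/Q4 indicators (Q2 is the reference — Q1 can
contain underweight children and is not an ideal low-risk baseline),
adjusted for age (linear, years) and pubertal group, yields odds ratios
with Wald 95% confidence intervals.

Complete or quasi-complete separation (e.g. a quartile with no high-risk
subjects) is flagged — the affected odds ratio is reported as ``inf``/0
with a ``separation`` marker rather than silently returning an unstable
estimate. An optional ridge-stabilized refit is available for such cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .exceptions import DegenerateQuartileWarning, SeparationWarning

__all__ = [
    "QuartileAssignment",
    "AssociationResult",
    "assign_quartiles",
    "fit_logistic_association",
    "association_report",
    "QuartileRiskModel",
]

QUARTILE_LABELS = ["Q1", "Q2", "Q3", "Q4"]
_Z95 = norm.ppf(0.975)


@dataclass
class QuartileAssignment:
    """Within-sex quartile membership for one index."""

    index_name: str
    cutpoints: dict  # sex -> (q25, q50, q75)
    quartile: pd.Series  # per-subject label Q1..Q4

    def counts(self) -> pd.Series:
        return self.quartile.value_counts().reindex(QUARTILE_LABELS, fill_value=0)


def assign_quartiles(values, sex, index_name: str = "") -> QuartileAssignment:
    """Assign within-sex quartiles with lower-inclusive boundaries.

    A value exactly at the 25th percentile falls in Q2 and exactly at the
    75th percentile in Q4. Tied cutpoints (massive ties) trigger a
    :class:`~pedishape.exceptions.DegenerateQuartileWarning` naming the
    collapsed groups.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    sex = np.asarray(sex, dtype=object)
    labels = np.empty(len(values), dtype=object)
    cutpoints = {}
    for s in np.unique(sex):
        mask = sex == s
        if mask.sum() < 8:
            raise ValueError(f"need at least 8 subjects per sex (sex={s!r})")
        cuts = np.quantile(values[mask], [0.25, 0.50, 0.75])
        cutpoints[s] = tuple(cuts)
        if len(np.unique(cuts)) < 3:
            warnings.warn(
                f"tied quartile cutpoints for sex={s!r}: {cuts}; adjacent groups collapse",
                DegenerateQuartileWarning,
                stacklevel=2,
            )
        # side="right": value == cutpoint goes to the upper group
        idx = np.searchsorted(cuts, values[mask], side="right")
        labels[mask] = np.array(QUARTILE_LABELS, dtype=object)[idx]
    return QuartileAssignment(
        index_name=index_name,
        cutpoints=cutpoints,
        quartile=pd.Series(labels, index=values.index, name="quartile"),
    )


@dataclass
class AssociationResult:
    """Odds ratios of high risk per quartile, Q2 ≡ 1."""

    index_name: str
    sex: str
    table: pd.DataFrame  # quartile, odds_ratio, ci_lo, ci_hi, p_value, separation
    n_used: int
    adjusted_for: tuple = ("age_years", "pubertal_group")
    converged: bool = True


def _detect_separation(X: np.ndarray, y: np.ndarray, params: np.ndarray) -> bool:
    if not np.all(np.isfinite(params)):
        return True
    eta = X @ params
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    # fitted probabilities numerically at 0/1 for observed classes
    return bool(np.any((p > 1 - 1e-8) & (y == 1)) or np.any((p < 1e-8) & (y == 0))) or bool(
        np.max(np.abs(params)) > 15
    )


def fit_logistic_association(
    quartile,
    high_risk,
    covariates: pd.DataFrame | None = None,
    index_name: str = "",
    sex: str = "",
    ridge: float = 0.0,
) -> AssociationResult:
    """Maximum-likelihood logit of high risk on quartile indicators.

    Q2 is the reference; odds ratios are exp(coefficients) with Wald 95%
    CIs and p-values. ``covariates`` (age in years and a pubertal
    indicator, typically) enter additively. ``ridge`` > 0 requests an
    L2-regularized refit, used to stabilize separated fits on demand.
    """
    quartile = np.asarray(quartile, dtype=object)
    y = np.asarray(high_risk, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    present = [q for q in ("Q1", "Q3", "Q4") if np.any(quartile == q)]
    X = pd.DataFrame(index=range(len(y)))
    X["intercept"] = 1.0
    for q in present:
        X[q] = (quartile == q).astype(float)
    if covariates is not None:
        for col in covariates.columns:
            vals = covariates[col]
            if vals.dtype == object:
                vals = (vals == "pubertal").astype(float)
            X[col] = np.asarray(vals, dtype=float)

    model = sm.Logit(y, X.to_numpy(dtype=float))
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if ridge > 0:
                res = model.fit_regularized(
                    alpha=ridge, L1_wt=0.0, disp=0, maxiter=500
                )
                params = np.asarray(res.params, dtype=float)
                cov = np.linalg.inv(
                    model.hessian(params) * -1 + ridge * np.eye(X.shape[1])
                )
                se = np.sqrt(np.diag(cov))
            else:
                res = model.fit(disp=0, maxiter=200)
                converged = bool(res.mle_retvals.get("converged", True))
                params = np.asarray(res.params, dtype=float)
                se = np.asarray(res.bse, dtype=float)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            params = np.full(X.shape[1], np.nan)
            se = np.full(X.shape[1], np.nan)
            converged = False

    separated = _detect_separation(X.to_numpy(dtype=float), y, params) if ridge == 0 else False
    if separated:
        warnings.warn(
            f"separation detected in logistic fit ({index_name}, {sex}); "
            "odds ratios for affected quartiles are unreliable "
            "(consider ridge > 0)",
            SeparationWarning,
            stacklevel=2,
        )

    names = list(X.columns)
    rows = [
        {
            "quartile": "Q2",
            "odds_ratio": 1.0,
            "ci_lo": np.nan,
            "ci_hi": np.nan,
            "p_value": np.nan,
            "separation": False,
        }
    ]
    for q in ("Q1", "Q3", "Q4"):
        if q not in names:  # level absent from this stratum
            rows.append(
                {
                    "quartile": q,
                    "odds_ratio": np.nan,
                    "ci_lo": np.nan,
                    "ci_hi": np.nan,
                    "p_value": np.nan,
                    "separation": False,
                }
            )
            continue
        j = names.index(q)
        beta, s = params[j], se[j]
        flag = separated and (not np.isfinite(beta) or abs(beta) > 15)
        if flag or not np.isfinite(beta):
            orr, lo_v, hi_v, p = (
                (np.inf if (np.isnan(beta) or beta > 0) else 0.0),
                np.nan,
                np.nan,
                np.nan,
            )
        else:
            orr = float(np.exp(beta))
            lo_v = float(np.exp(beta - _Z95 * s))
            hi_v = float(np.exp(beta + _Z95 * s))
            p = float(2 * norm.sf(abs(beta / s))) if s > 0 else np.nan
        rows.append(
            {
                "quartile": q,
                "odds_ratio": orr,
                "ci_lo": lo_v,
                "ci_hi": hi_v,
                "p_value": p,
                "separation": flag or separated,
            }
        )
    table = pd.DataFrame(rows).set_index("quartile").loc[QUARTILE_LABELS].reset_index()
    return AssociationResult(
        index_name=index_name,
        sex=sex,
        table=table,
        n_used=len(y),
        adjusted_for=tuple(covariates.columns) if covariates is not None else (),
        converged=converged,
    )


def association_report(results: list[AssociationResult]) -> pd.DataFrame:
    """Long-format odds-ratio table across indices and sexes.

    One row per (index, sex, quartile): odds ratio, Wald CI bounds and
    p-value — the layout used for forest-style plots. An empty input
    yields an empty table with the same columns.
    """
    columns = ["index", "sex", "quartile", "odds_ratio", "ci_lo", "ci_hi", "p_value"]
    frames = []
    for r in results:
        t = r.table.copy()
        t.insert(0, "index", r.index_name)
        t.insert(1, "sex", r.sex)
        frames.append(t[columns])
    if not frames:
        return pd.DataFrame(columns=columns)
    return pd.concat(frames, ignore_index=True)


class QuartileRiskModel(BaseEstimator):
    """Sklearn-style wrapper: within-sex quartile logistic association.

    Parameters
    ----------
    index_col : str
        Column of the design frame holding the body-shape index.
    adjust : tuple of str
        Covariate columns (default age and pubertal group).
    ridge : float
        Optional L2 stabilization for separated fits.

    ``fit(X, y)`` expects a cohort-like frame (with ``sex`` and the
    adjustment columns) and a boolean high-risk outcome; fitted attributes
    are ``assignments_`` (per sex) and ``results_`` (per sex
    :class:`AssociationResult`).
    """

    def __init__(
        self,
        index_col: str = "bri",
        adjust: tuple = ("age_years", "pubertal_group"),
        ridge: float = 0.0,
    ):
        self.index_col = index_col
        self.adjust = adjust
        self.ridge = ridge

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=bool)
        self.assignments_ = {}
        self.results_ = {}
        assignment = assign_quartiles(
            X[self.index_col].values, X["sex"].values, index_name=self.index_col
        )
        for s in np.unique(X["sex"].values):
            mask = (X["sex"] == s).to_numpy()
            cov = X.loc[mask, list(self.adjust)].reset_index(drop=True)
            self.assignments_[s] = assignment.quartile[mask]
            self.results_[s] = fit_logistic_association(
                assignment.quartile[mask].values,
                y[mask],
                covariates=cov,
                index_name=self.index_col,
                sex=s,
                ridge=self.ridge,
            )
        return self

    def report(self) -> pd.DataFrame:
        return association_report(list(self.results_.values()))
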