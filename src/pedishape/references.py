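"""Quantile-regression determinants and percentile reference tables.

Two related tasks:

* **Determinant models** — sex-specific quantile regressions of BRI or
  ABSI on pubertal group (reference: prepubertal) and weight status
  (reference: wasting) at the 5th, 25th, 50th, 75th and 95th percentiles.
  Coefficients minimize the check (pinball) loss
  ρ_τ(u) = u·(τ − 1{u<0}); 95% confidence intervals come from a seeded
  nonparametric bootstrap (percentile method), and significance is read
  strictly from whether the CI excludes zero.
* **Reference tables** — stratified empirical percentiles (linear
  interpolation between order statistics, numpy's default "type 7" rule)
  of BRI and ABSI on the normal-weight cohort. BRI strata are
  sex × pubertal group; ABSI strata are sex only. P85 is computed with
  the same machinery and stored alongside the five canonical levels so
  the screening module can use it as a cutoff.

The underlying pinball-loss minimizer is statsmodels' iteratively
reweighted least squares QuantReg solver; small-instance behaviour is
validated in the test suite against an exhaustive grid-search oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import (
    RankDeficientDesignError,
    ReferenceLookupError,
    SmallStratumWarning,
)

__all__ = [
    "TAUS",
    "QuantileFit",
    "check_loss",
    "fit_quantile_regression",
    "fit_determinant_models",
    "build_percentile_reference",
    "lookup_cutoff",
]

TAUS = (0.05, 0.25, 0.50, 0.75, 0.95)
PERCENTILE_LEVELS = {"p5": 0.05, "p25": 0.25, "p50": 0.50, "p75": 0.75, "p85": 0.85, "p95": 0.95}
TABLE_LEVELS = ["p5", "p25", "p50", "p75", "p85", "p95"]


def check_loss(y, yhat, tau: float) -> float:
    """Mean pinball loss Σ ρ_τ(y − ŷ) / n."""
    u = np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)
    return float(np.mean(u * (tau - (u < 0))))


@dataclass
class QuantileFit:
    """One fitted quantile regression.

    ``params`` includes the intercept (named "intercept"); ``ci95`` has
    columns lo/hi; ``significant`` flags coefficients whose CI excludes
    zero. ``scale`` is a display multiplier (10³ for ABSI so printed
    coefficients are O(1)); raw-scale values are stored.
    """

    tau: float
    params: pd.Series
    ci95: pd.DataFrame
    significant: pd.Series
    check_loss: float
    n: int
    response: str = ""
    scale: float = 1.0

    @property
    def params_display(self) -> pd.Series:
        return self.params * self.scale

    @property
    def ci95_display(self) -> pd.DataFrame:
        return self.ci95 * self.scale


def _design_matrix(design: pd.DataFrame, n: int) -> pd.DataFrame:
    X = pd.DataFrame({"intercept": np.ones(n)})
    for col in design.columns:
        X[col] = np.asarray(design[col], dtype=float)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        degenerate = [c for c in X.columns if c != "intercept" and X[c].nunique() <= 1]
        detail = (
            f"constant/absent level column(s): {degenerate}"
            if degenerate
            else "collinear columns"
        )
        raise RankDeficientDesignError(f"design matrix is rank deficient ({detail})")


def _solve(X: pd.DataFrame, y: np.ndarray, tau: float) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.QuantReg(y, X.to_numpy(dtype=float))
        res = model.fit(q=tau, max_iter=10_000, p_tol=1e-8)
    return np.asarray(res.params, dtype=float)


def fit_quantile_regression(
    design: pd.DataFrame,
    y,
    tau: float,
    n_bootstrap: int = 1000,
    seed: int | None = None,
    response: str = "",
    scale: float = 1.0,
) -> QuantileFit:
    """Fit y ~ intercept + design at quantile ``tau`` by pinball-loss
    minimization, with seeded bootstrap percentile CIs.

    ``design`` holds the covariates (no intercept column; an intercept is
    always added). Pass an empty DataFrame for an intercept-only fit, whose
    solution is an empirical ``tau``-quantile of y.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = _design_matrix(design, n)
    if n <= X.shape[1]:
        raise ValueError("need more observations than coefficients")
    _check_rank(X)
    beta = _solve(X, y, tau)
    loss = check_loss(y, X.to_numpy() @ beta, tau)

    if n_bootstrap == 0:
        nan = np.full(X.shape[1], np.nan)
        return QuantileFit(
            tau=tau,
            params=pd.Series(beta, index=X.columns),
            ci95=pd.DataFrame({"lo": nan, "hi": nan}, index=X.columns),
            significant=pd.Series(False, index=X.columns),
            check_loss=loss,
            n=n,
            response=response,
            scale=scale,
        )

    rng = np.random.default_rng(seed)
    boots = np.empty((n_bootstrap, X.shape[1]))
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        Xb = X.iloc[idx]
        try:
            _check_rank(Xb)
            boots[b] = _solve(Xb, y[idx], tau)
        except RankDeficientDesignError:
            boots[b] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lo = np.nanpercentile(boots, 2.5, axis=0)
        hi = np.nanpercentile(boots, 97.5, axis=0)

    params = pd.Series(beta, index=X.columns)
    ci = pd.DataFrame({"lo": lo, "hi": hi}, index=X.columns)
    significant = pd.Series((ci["lo"] > 0) | (ci["hi"] < 0), index=X.columns)
    return QuantileFit(
        tau=tau,
        params=params,
        ci95=ci,
        significant=significant,
        check_loss=loss,
        n=n,
        response=response,
        scale=scale,
    )


WEIGHT_LEVELS = ["normal", "overweight", "obesity"]  # reference: wasting


def determinant_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Pubertal + weight-status indicator design (references: prepubertal, wasting)."""
    design = pd.DataFrame(index=cohort.index)
    design["pubertal"] = (cohort["pubertal_group"] == "pubertal").astype(float)
    for level in WEIGHT_LEVELS:
        design[level] = (cohort["weight_status"] == level).astype(float)
    return design


def fit_determinant_models(
    cohort: pd.DataFrame,
    response: str,
    sex: str,
    taus=TAUS,
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> dict[float, QuantileFit]:
    """Sex-specific quantile regressions of an index on pubertal group and
    weight status, one fit per requested quantile.

    ``cohort`` must carry the response column (``bri`` or ``absi``),
    ``pubertal_group`` and ``weight_status``. ABSI fits carry a ×10³
    display scale so coefficients print on the conventional magnitude.
    """
    sub = cohort[cohort["sex"] == sex]
    design = determinant_design(sub)
    y = sub[response].to_numpy(dtype=float)
    scale = 1000.0 if response == "absi" else 1.0
    seeds = np.random.SeedSequence(seed).spawn(len(taus))
    fits = {}
    for tau, ss in zip(taus, seeds):
        fits[tau] = fit_quantile_regression(
            design,
            y,
            tau,
            n_bootstrap=n_bootstrap,
            seed=np.random.default_rng(ss),
            response=response,
            scale=scale,
        )
    return fits


def build_percentile_reference(
    cohort: pd.DataFrame,
    response: str,
    scheme: str | None = None,
    min_stratum_n: int = 50,
) -> pd.DataFrame:
    """Stratified empirical percentile reference for BRI or ABSI.

    Restricted to normal-weight subjects. ``scheme`` defaults to the
    response's convention: BRI stratifies by sex × pubertal group, ABSI by
    sex only. Returns one row per stratum with columns p5…p95 (including
    the auxiliary p85), the stratum size, and a ``low_n`` flag for strata
    below ``min_stratum_n``. Percentile values are non-decreasing across
    levels by construction; this is asserted.
    """
    if scheme is None:
        scheme = "bri" if response == "bri" else "absi"
    if "weight_status" in cohort.columns:
        cohort = cohort[cohort["weight_status"] == "normal"]
    if cohort.empty:
        raise ValueError("no normal-weight subjects to build the reference from")
    strata_cols = ["sex", "pubertal_group"] if scheme == "bri" else ["sex"]
    rows = []
    for keys, grp in cohort.groupby(strata_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        vals = grp[response].to_numpy(dtype=float)
        qs = np.quantile(vals, list(PERCENTILE_LEVELS.values()))  # type 7
        assert np.all(np.diff(qs) >= -1e-12), "percentile levels must not cross"
        row = {"response": response, **dict(zip(strata_cols, keys))}
        if "pubertal_group" not in row:
            row["pubertal_group"] = "all"
        row["n_stratum"] = len(vals)
        row.update(dict(zip(TABLE_LEVELS, qs)))
        row["low_n"] = len(vals) < min_stratum_n
        rows.append(row)
    out = pd.DataFrame(rows)
    if out["low_n"].any():
        small = out.loc[out["low_n"], ["sex", "pubertal_group"]].to_dict("records")
        warnings.warn(
            f"reference strata below n={min_stratum_n}: {small}",
            SmallStratumWarning,
            stacklevel=2,
        )
    return out


def lookup_cutoff(
    reference: pd.DataFrame,
    response: str,
    sex: str,
    pubertal_group: str | None = None,
    level: str = "p75",
) -> float:
    """Scalar percentile cutoff from a reference table built by
    :func:`build_percentile_reference`.

    ``pubertal_group`` is required for pubertal-stratified references
    (BRI); pass ``None`` for sex-only references (ABSI), which match the
    "all" stratum.
    """
    if level not in reference.columns:
        raise ReferenceLookupError(f"level {level!r} not present in the reference table")
    group = pubertal_group if pubertal_group is not None else "all"
    row = reference[
        (reference["response"] == response)
        & (reference["sex"] == sex)
        & (reference["pubertal_group"] == group)
    ]
    if row.empty:
        raise ReferenceLookupError(
            f"no reference stratum for ({response}, {sex}, {group})"
        )
    return float(row[level].iloc[0])
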