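"""Independent small-scale oracles used to validate the fitted routines.

These deliberately avoid the package's own code paths: exhaustive grid
search over the pinball loss, the closed-form 2×2 cross-ratio, and direct
numeric evaluation of integrals/formulas.
"""

import numpy as np


def pinball_loss(y, yhat, tau):
    u = np.asarray(y, dtype=float) - yhat
    return float(np.mean(u * (tau - (u < 0))))


def grid_search_intercept(y, tau, step=1e-3):
    """Exhaustive 1-D grid search for the intercept-only quantile fit."""
    y = np.asarray(y, dtype=float)
    grid = np.arange(y.min(), y.max() + step, step)
    losses = [pinball_loss(y, g, tau) for g in grid]
    j = int(np.argmin(losses))
    return grid[j], losses[j]


def grid_search_binary(y, x, tau, step=1e-3):
    """Grid search for intercept + binary-covariate quantile fit.

    The loss separates over the two groups, so the joint minimum is the
    pair of per-group grid minima.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    b0, loss0 = grid_search_intercept(y[x == 0], tau, step)
    b1, loss1 = grid_search_intercept(y[x == 1], tau, step)
    n0, n1 = (x == 0).sum(), (x == 1).sum()
    total = (loss0 * n0 + loss1 * n1) / (n0 + n1)
    return (b0, b1 - b0), total


def cross_ratio(a, b, c, d):
    """Odds ratio of a 2x2 table [[a, b], [c, d]] (exposed pos/neg, ref pos/neg)."""
    return (a * d) / (b * c)


def hanley_mcneil_interval(auc, n_pos, n_neg):
    """Literal transcription of the closed-form AUC interval."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    se = np.sqrt(
        (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2))
        / (n_pos * n_neg)
    )
    from scipy.stats import norm

    z = norm.ppf(0.975)
    return max(auc - z * se, 0.0), min(auc + z * se, 1.0)


def logistic_pubertal_fraction(midpoint, slope, age_lo, age_hi, n_grid=200001):
    """Numeric integral of the puberty logistic over a uniform age range."""
    ages = np.linspace(age_lo, age_hi, n_grid)
    p = 1.0 / (1.0 + np.exp(-slope * (ages - midpoint)))
    return float(np.trapezoid(p, ages) / (age_hi - age_lo))
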