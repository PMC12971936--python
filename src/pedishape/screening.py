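"""Cutoff-based screening of high cardiometabolic risk.

Each candidate screen is a single-threshold classifier: flag a subject
positive when an index is at or above a percentile cutoff (P75/P85/P95).
For such a binary test the ROC polygon has one interior vertex, so

* Youden index J = sensitivity + specificity − 1, and
* AUC = (sensitivity + specificity) / 2 (trapezoid through (0,0),
  (1 − specificity, sensitivity), (1,1)).

AUC confidence intervals use the Hanley–McNeil standard error

    SE(A)² = [A(1−A) + (n⁺−1)(Q1−A²) + (n⁻−1)(Q2−A²)] / (n⁺·n⁻),
    Q1 = A/(2−A),  Q2 = 2A²/(1+A),

with a normal 95% interval truncated to [0, 1]; the p-value is the
two-sided normal test of AUC = 0.5 with the same SE.

BRI cutoffs are stratum-specific (sex × pubertal group, from the
normal-weight reference tables); WHtR, WHR and BMI cutoffs are within-sex
empirical percentiles of the analysis cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import UndefinedMetricError
from .references import lookup_cutoff

__all__ = [
    "confusion_metrics",
    "youden_index",
    "binary_test_auc",
    "auc_confidence_interval",
    "auc_p_value",
    "evaluate_cutoffs",
    "format_p",
]

SCREEN_LEVELS = ("p75", "p85", "p95")
DEFAULT_INDICES = ("bri", "whtr", "whr", "bmi")


def confusion_metrics(predicted, truth):
    """Sensitivity, specificity and the four confusion counts.

    ``truth`` must contain both classes; otherwise the metrics are
    undefined and an error is raised.
    """
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("truth contains a single class; metrics undefined")
    tp = int((predicted & truth).sum())
    tn = int((~predicted & ~truth).sum())
    sensitivity = tp / n_pos
    specificity = tn / n_neg
    return sensitivity, specificity, {"tp": tp, "fn": n_pos - tp, "tn": tn, "fp": n_neg - tn}


def _check_unit(name, *vals):
    for v in vals:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}: proportions must lie in [0, 1], got {v}")


def youden_index(sensitivity: float, specificity: float) -> float:
    """J = sensitivity + specificity − 1."""
    _check_unit("youden_index", sensitivity, specificity)
    return sensitivity + specificity - 1.0


def binary_test_auc(sensitivity: float, specificity: float) -> float:
    """AUC of a single-cutoff test: (sensitivity + specificity) / 2."""
    _check_unit("binary_test_auc", sensitivity, specificity)
    return (sensitivity + specificity) / 2.0


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley–McNeil standard error of an AUC estimate."""
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    if not 0.0 < auc <= 1.0:
        raise ValueError("auc must lie in (0, 1]")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def auc_confidence_interval(auc: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    """Normal 95% CI for the AUC (Hanley–McNeil SE), truncated to [0, 1]."""
    se = hanley_mcneil_se(auc, n_pos, n_neg)
    z = norm.ppf(0.975)
    return (max(auc - z * se, 0.0), min(auc + z * se, 1.0))


def auc_p_value(auc: float, n_pos: int, n_neg: int) -> float:
    """Two-sided normal test of AUC = 0.5 using the Hanley–McNeil SE."""
    se = hanley_mcneil_se(auc, n_pos, n_neg)
    if se == 0.0:
        return 0.0 if auc != 0.5 else 1.0
    return float(2.0 * norm.sf(abs(auc - 0.5) / se))


def format_p(p: float, floor: float = 0.01) -> str:
    """Report p-values below the floor as an inequality (table style)."""
    return f"<{floor:g}" if p < floor else f"{p:.3g}"


def evaluate_cutoffs(
    cohort: pd.DataFrame,
    bri_reference: pd.DataFrame | None = None,
    indices=DEFAULT_INDICES,
    levels=SCREEN_LEVELS,
) -> pd.DataFrame:
    """Screen every (index, sex, cutoff level) against the high-CMRI truth.

    ``cohort`` must carry the index columns, ``sex``, ``pubertal_group``
    and the boolean ``high_risk`` truth. Classification is inclusive
    (index ≥ cutoff). BRI uses the stratified normal-weight reference
    (``bri_reference``, as built by
    :func:`pedishape.references.build_percentile_reference`); other
    indices use within-sex empirical percentiles of the analysis cohort.
    Rows are ranked by Youden index within sex.
    """
    if "bri" in indices and bri_reference is None:
        raise ValueError("bri screening requires a bri_reference table")
    rows = []
    for s in sorted(cohort["sex"].unique()):
        sub = cohort[cohort["sex"] == s]
        truth = sub["high_risk"].to_numpy(dtype=bool)
        for index in indices:
            values = sub[index].to_numpy(dtype=float)
            for level in levels:
                if index == "bri":
                    cut = np.empty(len(sub))
                    for grp in ("prepubertal", "pubertal"):
                        mask = (sub["pubertal_group"] == grp).to_numpy()
                        cut[mask] = lookup_cutoff(
                            bri_reference, "bri", s, grp, level=level
                        )
                    cutoff_value = np.nan  # stratified; see per-stratum reference
                    stratified = True
                else:
                    q = float(level[1:]) / 100.0
                    cutoff_value = float(np.quantile(values, q))
                    cut = np.full(len(sub), cutoff_value)
                    stratified = False
                predicted = values >= cut
                sens, spec, counts = confusion_metrics(predicted, truth)
                auc = binary_test_auc(sens, spec)
                n_pos = counts["tp"] + counts["fn"]
                n_neg = counts["tn"] + counts["fp"]
                lo, hi = auc_confidence_interval(auc, n_pos, n_neg)
                rows.append(
                    {
                        "index": index,
                        "sex": s,
                        "cutoff_level": level,
                        "cutoff_value": cutoff_value,
                        "stratified_cutoff": stratified,
                        "sensitivity": sens,
                        "specificity": spec,
                        "youden": youden_index(sens, spec),
                        "auc": auc,
                        "auc_ci_lo": lo,
                        "auc_ci_hi": hi,
                        "p_value": auc_p_value(auc, n_pos, n_neg),
                        "n_pos": n_pos,
                        "n_neg": n_neg,
                    }
                )
    out = pd.DataFrame(rows)
    return (
        out.sort_values(["sex", "youden"], ascending=[True, False])
        .reset_index(drop=True)
    )
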