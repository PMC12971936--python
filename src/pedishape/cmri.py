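"""Composite cardiometabolic risk index (CMRI).

The CMRI is a continuous composite of standardized risk components:

    CMRI z = z(WC) + z(SBP) + z(DBP) + z(GLU) + z(TG) − z(HDL-C)

where each component is z-scored against sex- and age-specific means and
standard deviations estimated on a *reference population* — subjects whose
BMI lies between the sex/age-specific 5th and 95th percentiles (weight
status normal or overweight). High cardiometabolic risk is CMRI z ≥ 1,
one reference SD above the mean. A waist-omitted variant (dropping z(WC))
is available for sensitivity analyses where waist also enters the exposure
index under study.

Age cells default to 1-year bins; sparse cells (fewer than ``min_cell_n``
subjects) are pooled with the adjacent bin, with a warning, to avoid
unstable SD estimates. SDs use the n−1 denominator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .anthropometry import BmiReferenceTable, classify_weight_status, compute_bmi
from .exceptions import (
    DegenerateCellError,
    PoolingWarning,
    ReferenceLookupError,
    StratificationError,
)

__all__ = [
    "COMPONENTS",
    "ComponentStats",
    "select_reference_population",
    "estimate_component_stats",
    "compute_cmri",
    "prevalence_table",
    "CmriScorer",
]

#: component -> cohort column. GLU maps to the measured fasting blood glucose.
COMPONENTS = {
    "wc": "waist_cm",
    "sbp": "sbp_mmHg",
    "dbp": "dbp_mmHg",
    "glu": "fbg_mmol_L",
    "tg": "tg_mmol_L",
    "hdl": "hdl_mmol_L",
}

#: signs in the composite; HDL-C is protective.
COMPONENT_SIGNS = {"wc": 1, "sbp": 1, "dbp": 1, "glu": 1, "tg": 1, "hdl": -1}


@dataclass
class ComponentStats:
    """Per-(sex, age-cell, component) reference mean/SD with cell sizes.

    ``table`` is tidy with columns sex, age_lo, age_hi, component, mean,
    sd, n_ref. Age cells are half-open ``[age_lo, age_hi)`` and may span
    several pooled 1-year bins.
    """

    table: pd.DataFrame

    def cells(self, sex: str) -> pd.DataFrame:
        sub = self.table[self.table["sex"] == sex]
        if sub.empty:
            raise ReferenceLookupError(f"no reference cells for sex {sex!r}")
        return sub

    def locate(self, sex, age_years) -> np.ndarray:
        """Index of the age cell for each subject; raises on uncovered ages."""
        sex = np.asarray(sex, dtype=object)
        age = np.asarray(age_years, dtype=float)
        cell_idx = np.full(len(age), -1, dtype=int)
        bounds = self.table[["sex", "age_lo", "age_hi"]].drop_duplicates()
        for s in np.unique(sex):
            b = bounds[bounds["sex"] == s].sort_values("age_lo")
            if b.empty:
                raise ReferenceLookupError(f"no reference cells for sex {s!r}")
            mask = sex == s
            pos = np.searchsorted(b["age_lo"].values, age[mask], side="right") - 1
            ok = (pos >= 0) & (age[mask] < b["age_hi"].values[np.clip(pos, 0, None)])
            if not ok.all():
                a = age[mask][~ok][0]
                raise ReferenceLookupError(
                    f"age {a} not covered by reference cells for sex {s!r}"
                )
            cell_idx[mask] = b.index.values[pos]
        return cell_idx

    def to_json(self, path=None) -> str:
        doc = json.dumps(self.table.to_dict(orient="records"), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_json(cls, path_or_str) -> "ComponentStats":
        if isinstance(path_or_str, str) and path_or_str.lstrip().startswith("["):
            records = json.loads(path_or_str)
        else:
            with open(path_or_str, encoding="utf-8") as fh:
                records = json.load(fh)
        return cls(pd.DataFrame(records))


def select_reference_population(
    cohort: pd.DataFrame, bmi_reference: BmiReferenceTable
) -> pd.DataFrame:
    """Subjects with BMI in [P5, P95) of the sex/age reference.

    These are exactly the normal-weight and overweight classes; wasting
    (< P5) and obesity (≥ P95) are excluded so the standardization is not
    driven by the distribution tails.
    """
    df = cohort
    if "weight_status" not in df.columns:
        df = df.copy()
        bmi = df["bmi"] if "bmi" in df else compute_bmi(
            df["weight_kg"].values, df["height_cm"].values / 100.0
        )
        df["weight_status"] = classify_weight_status(
            np.asarray(bmi, dtype=float), df["sex"].values, df["age_years"].values, bmi_reference
        )
    subset = df[df["weight_status"].isin(["normal", "overweight"])]
    if subset.empty:
        raise StratificationError(
            "reference population is empty: no subjects with BMI in [P5, P95)"
        )
    return subset


def _pool_bins(counts: pd.Series, min_cell_n: int) -> list[tuple[float, float]]:
    """Greedy left-to-right pooling of consecutive age bins to reach min_cell_n."""
    intervals: list[list] = []
    cur_lo, cur_hi, cur_n = None, None, 0
    for (lo, hi), n in counts.items():
        if cur_lo is None:
            cur_lo, cur_hi, cur_n = lo, hi, n
        else:
            cur_hi, cur_n = hi, cur_n + n
        if cur_n >= min_cell_n:
            intervals.append([cur_lo, cur_hi, cur_n])
            cur_lo, cur_n = None, 0
    if cur_lo is not None:
        if intervals and cur_n < min_cell_n:
            intervals[-1][1] = cur_hi
            intervals[-1][2] += cur_n
        else:
            intervals.append([cur_lo, cur_hi, cur_n])
    return [(lo, hi) for lo, hi, _ in intervals]


def estimate_component_stats(
    reference: pd.DataFrame,
    age_bin_width: float = 1.0,
    min_cell_n: int = 10,
) -> ComponentStats:
    """Sex- and age-cell-specific mean/SD of the six CMRI components.

    Must be called on the reference subset only (see
    :func:`select_reference_population`); sample SDs use the n−1
    denominator. Cells below ``min_cell_n`` are pooled with the adjacent
    bin (warning); a zero-variance cell raises
    :class:`~pedishape.exceptions.DegenerateCellError`.
    """
    if reference.empty:
        raise StratificationError("reference population is empty")
    age = reference["age_years"].to_numpy(dtype=float)
    bin_lo = 6.0 + age_bin_width * np.floor((age - 6.0) / age_bin_width)
    rows = []
    pooled_any = False
    for sex, grp in reference.groupby("sex", sort=True):
        lo_vals = bin_lo[reference["sex"].to_numpy() == sex]
        counts = (
            pd.Series(lo_vals)
            .value_counts()
            .sort_index()
        )
        counts.index = [(lo, lo + age_bin_width) for lo in counts.index]
        intervals = _pool_bins(counts, min_cell_n)
        if len(intervals) < len(counts):
            pooled_any = True
        for lo, hi in intervals:
            cell = grp[(grp["age_years"] >= lo) & (grp["age_years"] < hi)]
            if cell.empty:  # pragma: no cover - pooling guarantees non-empty
                raise StratificationError(f"empty reference cell (sex={sex}, age_bin=[{lo},{hi}))")
            for comp, col in COMPONENTS.items():
                vals = cell[col].to_numpy(dtype=float)
                sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
                if sd <= 0.0:
                    raise DegenerateCellError(
                        f"zero-variance cell (sex={sex}, age_bin=[{lo},{hi}), component={comp})"
                    )
                rows.append(
                    {
                        "sex": sex,
                        "age_lo": float(lo),
                        "age_hi": float(hi),
                        "component": comp,
                        "mean": float(np.mean(vals)),
                        "sd": sd,
                        "n_ref": int(len(vals)),
                    }
                )
    if pooled_any:
        warnings.warn(
            f"age cells below min_cell_n={min_cell_n} were pooled with adjacent bins",
            PoolingWarning,
            stacklevel=2,
        )
    return ComponentStats(pd.DataFrame(rows))


def compute_cmri(
    cohort: pd.DataFrame, stats: ComponentStats, variant: str = "full", threshold: float = 1.0
) -> pd.DataFrame:
    """Per-subject component z-scores, composite CMRI z and high-risk flag.

    ``variant`` is ``"full"`` or ``"wc_omitted"`` (the waist term dropped
    from the sum; its z-score is still reported). Subjects with missing
    components are excluded (complete case) with a warning. The high-risk
    flag is inclusive: CMRI z ≥ ``threshold``.
    """
    if variant not in ("full", "wc_omitted"):
        raise ValueError(f"unknown variant {variant!r}")
    cols = list(COMPONENTS.values())
    complete = cohort[cols].notna().all(axis=1)
    if not complete.all():
        dropped = cohort.loc[~complete, "subject_id"].tolist()
        warnings.warn(
            f"excluded {len(dropped)} subject(s) with missing CMRI components: {dropped}",
            stacklevel=2,
        )
    df = cohort.loc[complete]
    cell_idx = stats.locate(df["sex"].values, df["age_years"].values)
    # wide per-cell lookup aligned to the tidy table index
    tidy = stats.table
    out = pd.DataFrame({"subject_id": df["subject_id"].values})
    cmri = np.zeros(len(df))
    for comp, col in COMPONENTS.items():
        sub = tidy[tidy["component"] == comp]
        # map bounds-row index -> component row (same sex/age_lo/age_hi ordering)
        key = tidy[["sex", "age_lo", "age_hi"]].drop_duplicates()
        merged = key.merge(sub, on=["sex", "age_lo", "age_hi"], how="left")
        mean = merged["mean"].to_numpy()[
            np.searchsorted(key.index.values, cell_idx)
        ]
        sd = merged["sd"].to_numpy()[np.searchsorted(key.index.values, cell_idx)]
        z = (df[col].to_numpy(dtype=float) - mean) / sd
        out[f"z_{comp}"] = z
        if not (variant == "wc_omitted" and comp == "wc"):
            cmri += COMPONENT_SIGNS[comp] * z
    out["cmri_z"] = cmri
    out["high_risk"] = cmri >= threshold
    out["variant"] = variant
    return out


AGE_BANDS = [(6, 9, "6-8"), (9, 12, "9-11"), (12, 15, "12-14"), (15, 18, "15-17")]


def _age_band(age_years: np.ndarray) -> np.ndarray:
    labels = np.full(len(age_years), "", dtype=object)
    for lo, hi, lab in AGE_BANDS:
        labels[(age_years >= lo) & (age_years < hi)] = lab
    return labels


def prevalence_table(results: pd.DataFrame, by: str = "overall") -> pd.DataFrame:
    """High-risk counts and percentages by group.

    ``by`` ∈ {"overall", "sex", "weight_status", "age_band",
    "pubertal_group"}; grouping columns beyond ``high_risk`` must be
    present on ``results`` (``age_band`` is derived from ``age_years``).
    Percentages are reported to one decimal.
    """
    if results.empty:
        raise ValueError("results table is empty")
    df = results.copy()
    if by == "overall":
        df["_group"] = "overall"
    elif by == "age_band":
        df["_group"] = _age_band(df["age_years"].to_numpy(dtype=float))
    elif by in ("sex", "weight_status", "pubertal_group"):
        df["_group"] = df[by]
    else:
        raise ValueError(f"unknown grouping key {by!r}")
    rows = []
    for group, grp in df.groupby("_group", sort=True):
        n = len(grp)
        k = int(grp["high_risk"].sum())
        rows.append(
            {"group": group, "n": n, "n_high": k, "percent": round(100.0 * k / n, 1)}
        )
    return pd.DataFrame(rows)


class CmriScorer(TransformerMixin, BaseEstimator):
    """Fit reference-population component statistics; transform to CMRI.

    Parameters
    ----------
    bmi_reference : BmiReferenceTable
        Sex/age BMI percentile table used to delimit the reference
        population (BMI in [P5, P95)).
    variant : {"full", "wc_omitted"}
        Whether the waist z-score enters the composite.
    age_bin_width : float, default 1.0
        Width (years) of standardization age cells.
    min_cell_n : int, default 10
        Minimum subjects per cell before pooling with the adjacent bin.
    threshold : float, default 1.0
        High-risk cutoff on the CMRI z scale (inclusive).

    Attributes
    ----------
    component_stats_ : ComponentStats
    n_reference_ : int
        Size of the reference subset used for standardization.
    """

    def __init__(
        self,
        bmi_reference: BmiReferenceTable | None = None,
        variant: str = "full",
        age_bin_width: float = 1.0,
        min_cell_n: int = 10,
        threshold: float = 1.0,
    ):
        self.bmi_reference = bmi_reference
        self.variant = variant
        self.age_bin_width = age_bin_width
        self.min_cell_n = min_cell_n
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None):
        if self.bmi_reference is None:
            raise ValueError("CmriScorer requires a bmi_reference to fit")
        reference = select_reference_population(X, self.bmi_reference)
        self.component_stats_ = estimate_component_stats(
            reference, age_bin_width=self.age_bin_width, min_cell_n=self.min_cell_n
        )
        self.n_reference_ = len(reference)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        scores = compute_cmri(
            X, self.component_stats_, variant=self.variant, threshold=self.threshold
        )
        return X.merge(scores.drop(columns="variant"), on="subject_id", how="inner")
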