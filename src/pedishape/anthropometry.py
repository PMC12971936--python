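"""Body-shape indices and BMI-percentile weight-status classification.

Five indices are computed from basic anthropometry:

* **BMI** — weight (kg) / height (m)².
* **WHtR** — waist (cm) / height (cm).
* **WHR** — waist (cm) / hip (cm).
* **ABSI** — waist (m) / (BMI^(2/3) · height (m)^(1/2)); an allometric
  standardization of waist circumference for overall size. Pediatric values
  are typically ~0.07–0.09.
* **BRI** — 364.2 − 365.5 · sqrt(1 − (WC/(π·H))²), an elliptical-geometry
  body-roundness measure, bounded above by 364.2 (reached when the waist
  equals π × height, i.e. a sphere-like eccentricity of zero) and below by
  −1.3 in the thin-body limit. Pediatric values are typically ~1–4.

Weight status (wasting / normal / overweight / obesity) is classified
against an external sex- and age-specific BMI percentile reference with
lower-inclusive, upper-exclusive bands: wasting < P5 ≤ normal < P85 ≤
overweight < P95 ≤ obesity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import MeasurementDomainError, ReferenceLookupError

__all__ = [
    "BRI_MAX",
    "BRI_MIN",
    "WEIGHT_STATUS_ORDER",
    "compute_bmi",
    "compute_whtr",
    "compute_whr",
    "compute_absi",
    "compute_bri",
    "classify_weight_status",
    "compute_index_panel",
    "BmiReferenceTable",
    "BodyShapeIndices",
]

#: BRI at zero eccentricity (waist = pi * height) and in the waist -> 0 limit.
BRI_MAX = 364.2
BRI_MIN = 364.2 - 365.5

WEIGHT_STATUS_ORDER = ["wasting", "normal", "overweight", "obesity"]

INDEX_COLUMNS = ["bmi", "whtr", "whr", "absi", "bri"]


def _require_positive(name: str, *values) -> None:
    for v in values:
        arr = np.asarray(v, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise MeasurementDomainError(
                f"{name}: inputs must be finite and strictly positive"
            )


def compute_bmi(weight_kg, height_m):
    """Body mass index, weight (kg) divided by height (m) squared."""
    _require_positive("bmi", weight_kg, height_m)
    return np.asarray(weight_kg, dtype=float) / np.asarray(height_m, dtype=float) ** 2


def compute_whtr(waist_cm, height_cm):
    """Waist-to-height ratio (same length unit in numerator and denominator)."""
    _require_positive("whtr", waist_cm, height_cm)
    return np.asarray(waist_cm, dtype=float) / np.asarray(height_cm, dtype=float)


def compute_whr(waist_cm, hip_cm):
    """Waist-to-hip ratio."""
    _require_positive("whr", waist_cm, hip_cm)
    return np.asarray(waist_cm, dtype=float) / np.asarray(hip_cm, dtype=float)


def compute_absi(waist_m, bmi, height_m):
    """A body shape index: waist (m) / (BMI^(2/3) · sqrt(height (m)))."""
    _require_positive("absi", waist_m, bmi, height_m)
    waist_m = np.asarray(waist_m, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    height_m = np.asarray(height_m, dtype=float)
    return waist_m / (bmi ** (2.0 / 3.0) * np.sqrt(height_m))


def compute_bri(waist_m, height_m):
    """Body roundness index from waist circumference and height (both in m).

    BRI = 364.2 − 365.5·sqrt(1 − ((WC/2π) / (0.5·H))²). The argument of the
    square root is the squared complement of the eccentricity of an ellipse
    with circumference-derived minor radius WC/2π and major radius H/2; it
    requires WC ≤ π·H. Waist measurements violating that bound are flagged
    as implausible rather than silently clipped.
    """
    _require_positive("bri", waist_m, height_m)
    waist_m = np.asarray(waist_m, dtype=float)
    height_m = np.asarray(height_m, dtype=float)
    ratio = (waist_m / (2.0 * np.pi)) / (0.5 * height_m)
    if np.any(ratio > 1.0):
        raise MeasurementDomainError(
            "bri: waist exceeds pi * height; eccentricity argument negative "
            "(implausible waist/height measurement)"
        )
    return BRI_MAX - 365.5 * np.sqrt(1.0 - ratio**2)


def invert_bri(bri, height_m):
    """Waist circumference (m) giving the requested BRI at the given height.

    Exact inverse of :func:`compute_bri`; used by the synthetic generator to
    impose location shifts on the BRI scale.
    """
    bri = np.asarray(bri, dtype=float)
    if np.any(bri < BRI_MIN) or np.any(bri > BRI_MAX):
        raise MeasurementDomainError(
            f"bri: value outside the representable range [{BRI_MIN}, {BRI_MAX}]"
        )
    s = (BRI_MAX - bri) / 365.5
    return np.pi * np.asarray(height_m, dtype=float) * np.sqrt(1.0 - s**2)


class BmiReferenceTable:
    """Sex- and age-binned BMI percentile reference (P5 / P85 / P95).

    Rows carry half-open age bins ``[age_lo, age_hi)`` per sex; bins must be
    contiguous, cover the analysis age range, and satisfy p5 < p85 < p95.
    """

    REQUIRED = ["sex", "age_lo", "age_hi", "p5", "p85", "p95"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"BMI reference missing columns: {missing}")
        table = table[self.REQUIRED].copy()
        if not ((table["p5"] < table["p85"]) & (table["p85"] < table["p95"])).all():
            raise ValueError("BMI reference requires p5 < p85 < p95 in every row")
        for sex, grp in table.groupby("sex"):
            grp = grp.sort_values("age_lo")
            if not np.allclose(grp["age_hi"].values[:-1], grp["age_lo"].values[1:]):
                raise ValueError(f"BMI reference age bins not contiguous for sex={sex}")
        self.table = table.sort_values(["sex", "age_lo"]).reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "BmiReferenceTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def lookup(self, sex, age_years) -> pd.DataFrame:
        """Percentile row(s) for (sex, age); raises if age is uncovered."""
        sex = np.atleast_1d(np.asarray(sex, dtype=object))
        age = np.atleast_1d(np.asarray(age_years, dtype=float))
        out = np.empty((len(age), 3), dtype=float)
        for s in np.unique(sex):
            sub = self.table[self.table["sex"] == s]
            if sub.empty:
                raise ReferenceLookupError(f"sex {s!r} not covered by the BMI reference")
            mask = sex == s
            idx = np.searchsorted(sub["age_lo"].values, age[mask], side="right") - 1
            bad = (idx < 0) | (age[mask] >= sub["age_hi"].values[np.clip(idx, 0, None)])
            if np.any(bad):
                a = age[mask][bad][0]
                raise ReferenceLookupError(
                    f"age {a} not covered by the BMI reference for sex {s!r}"
                )
            out[mask] = sub[["p5", "p85", "p95"]].values[idx]
        return pd.DataFrame(out, columns=["p5", "p85", "p95"])


def classify_weight_status(bmi, sex, age_years, reference: BmiReferenceTable):
    """Classify BMI against the reference: bands [P5,P85) normal, [P85,P95)
    overweight, ≥P95 obesity, <P5 wasting. Lower bounds inclusive.

    Accepts scalars or aligned arrays; returns a scalar label or ndarray.
    """
    scalar = np.isscalar(bmi) or np.ndim(bmi) == 0
    bmi_a = np.atleast_1d(np.asarray(bmi, dtype=float))
    cuts = reference.lookup(sex, age_years)
    labels = np.select(
        [
            bmi_a < cuts["p5"].values,
            bmi_a < cuts["p85"].values,
            bmi_a < cuts["p95"].values,
        ],
        ["wasting", "normal", "overweight"],
        default="obesity",
    )
    return labels[0] if scalar else labels


def compute_index_panel(cohort: pd.DataFrame) -> pd.DataFrame:
    """Compute all five indices for a cohort table.

    Expects columns ``height_cm``, ``weight_kg``, ``waist_cm``, ``hip_cm``
    (cm/kg as stored in cohort files; ABSI and BRI convert to meters
    internally). Returns a copy with ``bmi``, ``whtr``, ``whr``, ``absi``
    and ``bri`` appended. Domain violations are re-raised with the
    offending subject_id attached when the column is present.
    """
    out = cohort.copy()
    height_m = out["height_cm"].to_numpy(dtype=float) / 100.0
    waist_m = out["waist_cm"].to_numpy(dtype=float) / 100.0
    try:
        out["bmi"] = compute_bmi(out["weight_kg"].to_numpy(dtype=float), height_m)
        out["whtr"] = compute_whtr(
            out["waist_cm"].to_numpy(dtype=float), out["height_cm"].to_numpy(dtype=float)
        )
        out["whr"] = compute_whr(
            out["waist_cm"].to_numpy(dtype=float), out["hip_cm"].to_numpy(dtype=float)
        )
        out["absi"] = compute_absi(waist_m, out["bmi"].to_numpy(dtype=float), height_m)
        out["bri"] = compute_bri(waist_m, height_m)
    except MeasurementDomainError as err:
        sid = ""
        if "subject_id" in out.columns:
            bad = waist_m > np.pi * height_m
            if np.any(bad):
                sid = f" (subject {out.loc[bad, 'subject_id'].iloc[0]})"
        raise MeasurementDomainError(f"{err}{sid}") from None
    return out


class BodyShapeIndices(TransformerMixin, BaseEstimator):
    """Stateless transformer appending the five body-shape indices.

    When a :class:`BmiReferenceTable` is supplied, a ``weight_status``
    column is appended as well. ``fit`` only validates the input schema, so
    the transformer composes with sklearn pipelines.
    """

    def __init__(self, bmi_reference: BmiReferenceTable | None = None):
        self.bmi_reference = bmi_reference

    def fit(self, X: pd.DataFrame, y=None):
        required = {"height_cm", "weight_kg", "waist_cm", "hip_cm"}
        missing = required.difference(X.columns)
        if missing:
            raise ValueError(f"missing anthropometry columns: {sorted(missing)}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = compute_index_panel(X)
        if self.bmi_reference is not None:
            out["weight_status"] = classify_weight_status(
                out["bmi"].values,
                out["sex"].values,
                out["age_years"].values,
                self.bmi_reference,
            )
        return out
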