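"""Seeded synthetic pediatric cohorts with known ground-truth structure.

The generator emulates a school-based cross-sectional survey of children
and adolescents aged 6–17: sex mix of roughly 55/45 boys/girls, pubertal
probability rising with age (earlier in girls), a weight-status mix of
about 4% wasting / 72% normal / 11–12% overweight / 12% obesity, and
biomarkers (blood pressure, fasting glucose, triglycerides, HDL-C) whose
means shift with central adiposity so that roughly 40% of subjects reach a
composite cardiometabolic risk z-score of 1 or more.

Mechanics
---------
* A latent adiposity z-score is mapped through a piecewise-linear
  percentile distortion so the configured weight-status proportions land
  exactly on the P5/P85/P95 bands of the exported BMI reference.
* The BMI baseline (mean/SD) is piecewise-constant over 1-year age bins,
  so classifying generated subjects against :func:`derive_bmi_reference`
  reproduces the drawn class exactly.
* Waist circumference is modelled on the waist-to-height-ratio scale:
  a base ratio plus a slope on the BMI deviation from the age-bin median,
  pubertal and sex shifts, and homoscedastic WHtR-scale noise. This keeps
  the body roundness index homoscedastic across statures, so configured
  effects are pure location shifts at every quantile.
* Biomarkers are linear in a standardized central-adiposity driver
  (``wc z``); triglycerides are Gaussian on the log scale, the others on
  the natural scale. The HDL slope is constrained negative.

A single RNG stream ordered by subject index makes output bitwise
reproducible for identical (config, seed); reproducibility across
different ``n_subjects`` is not promised.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .anthropometry import BmiReferenceTable, invert_bri
from .exceptions import CohortParseError, CohortSchemaError, ConfigurationError

__all__ = [
    "SimulationConfig",
    "default_config",
    "simulate_cohort",
    "derive_bmi_reference",
    "expected_pubertal_fraction",
    "write_cohort",
    "read_cohort",
    "SUBJECT_COLUMNS",
]

SUBJECT_COLUMNS = [
    "subject_id",
    "sex",
    "age_years",
    "tanner_stage",
    "pubertal_group",
    "pubertal_group3",
    "height_cm",
    "weight_kg",
    "waist_cm",
    "hip_cm",
    "sbp_mmHg",
    "dbp_mmHg",
    "fbg_mmol_L",
    "tg_mmol_L",
    "hdl_mmol_L",
]

MEASUREMENT_COLUMNS = SUBJECT_COLUMNS[6:]


@dataclass
class PubertyLogistic:
    """P(pubertal | age) = expit(slope · (age − midpoint_age))."""

    midpoint_age: float
    slope: float


@dataclass
class GrowthModel:
    """Linear mean height vs age with Gaussian residual."""

    height_at_6_cm: float
    height_slope_cm_per_yr: float
    height_sd_cm: float


@dataclass
class BmiBaseline:
    """Piecewise-constant (1-year bin) normal BMI baseline.

    mean(bin) = mean_at_6 + mean_slope · (bin_mid − 6);
    sd(bin) = sd_at_6 + sd_slope · (bin_mid − 6).
    """

    mean_at_6: float
    mean_slope: float
    sd_at_6: float
    sd_slope: float

    def mean(self, bin_lo):
        return self.mean_at_6 + self.mean_slope * (np.asarray(bin_lo) + 0.5 - 6.0)

    def sd(self, bin_lo):
        return self.sd_at_6 + self.sd_slope * (np.asarray(bin_lo) + 0.5 - 6.0)


@dataclass
class AdiposityModel:
    """Latent N(0,1) adiposity mapped to weight-status target proportions."""

    proportions: dict = field(
        default_factory=lambda: {
            "wasting": 0.040,
            "normal": 0.725,
            "overweight": 0.115,
            "obesity": 0.120,
        }
    )
    percentile_clip: float = 0.9995


@dataclass
class WaistModel:
    """Waist modelled on the WHtR scale.

    WHtR = base + bmi_coef·(BMI − bin median) + pubertal_coef·pubertal
    + male_coef·male + N(0, resid_sd). ``wcz_scale`` standardizes the
    adiposity-driven WHtR deviation into the biomarker driver.
    """

    whtr_base: float = 0.405
    bmi_coef: float = 0.013
    pubertal_coef: float = -0.012
    male_coef: float = 0.004
    resid_sd: float = 0.022
    wcz_scale: float = 0.035


@dataclass
class HipModel:
    """Hip from waist through a mean waist-to-hip ratio with pubertal/sex shifts."""

    whr_base: float = 0.885
    pubertal_coef: float = -0.030
    female_pubertal_coef: float = -0.020
    resid_sd_cm: float = 2.0


@dataclass
class BiomarkerModel:
    """value = intercept + age_slope·(age−6) + wc_slope·wcz + N(0, resid_sd).

    ``log_scale`` applies the linear model to log(value) (right-skewed
    markers such as triglycerides); ``floor`` keeps values physiologic.
    """

    intercept: float
    wc_slope: float
    resid_sd: float
    age_slope: float = 0.0
    log_scale: bool = False
    floor: float = 0.0


@dataclass
class EffectOverride:
    """Additive location shift on an index scale, by stratum, for recovery tests.

    ``response`` ∈ {"bri"}; ``by`` names a generated categorical column
    (e.g. ``weight_status`` or ``pubertal_group``); ``shifts`` maps level →
    shift in response units. Realized by inverting the index to a new waist
    circumference, so the shift is exact on the response scale.
    """

    response: str
    by: str
    shifts: dict


@dataclass
class SimulationConfig:
    seed: int = 0
    n_subjects: int = 4794
    male_fraction: float = 0.554
    age_range: tuple = (6.0, 18.0)
    puberty_logistic: dict = field(
        default_factory=lambda: {
            "male": PubertyLogistic(midpoint_age=10.3, slope=1.2),
            "female": PubertyLogistic(midpoint_age=9.0, slope=1.2),
        }
    )
    growth_model: dict = field(
        default_factory=lambda: {
            "male": GrowthModel(116.5, 5.4, 6.5),
            "female": GrowthModel(115.5, 4.7, 6.0),
        }
    )
    bmi_baseline: dict = field(
        default_factory=lambda: {
            "male": BmiBaseline(15.4, 0.42, 1.6, 0.11),
            "female": BmiBaseline(15.1, 0.40, 1.6, 0.11),
        }
    )
    adiposity_model: AdiposityModel = field(default_factory=AdiposityModel)
    waist_model: WaistModel = field(default_factory=WaistModel)
    hip_model: HipModel = field(default_factory=HipModel)
    biomarker_model: dict = field(
        default_factory=lambda: {
            "sbp": BiomarkerModel(97.0, 3.0, 8.0, age_slope=1.1, floor=70.0),
            "dbp": BiomarkerModel(57.0, 1.8, 6.0, age_slope=0.5, floor=40.0),
            "glu": BiomarkerModel(4.70, 0.065, 0.42, floor=2.5),
            "tg": BiomarkerModel(np.log(0.80), 0.10, 0.35, log_scale=True),
            "hdl": BiomarkerModel(1.45, -0.05, 0.24, floor=0.30),
        }
    )
    effect_overrides: list = field(default_factory=list)

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be positive")
        if not 0.0 < self.male_fraction < 1.0:
            raise ConfigurationError("male_fraction must lie in (0, 1)")
        lo, hi = self.age_range
        if not (6.0 <= lo < hi <= 18.0):
            raise ConfigurationError("age_range must satisfy 6 <= lo < hi <= 18")
        props = self.adiposity_model.proportions
        expected = {"wasting", "normal", "overweight", "obesity"}
        if set(props) != expected:
            raise ConfigurationError(f"weight-status proportions must key {sorted(expected)}")
        total = sum(props.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(
                f"weight-status proportions sum to {total:.6f}, expected 1"
            )
        if any(p <= 0 for p in props.values()):
            raise ConfigurationError("weight-status proportions must be positive")
        if self.biomarker_model["hdl"].wc_slope > 0:
            raise ConfigurationError("HDL slope on the adiposity driver must be <= 0")

    # -- JSON round-trip (for the CLI) ------------------------------------
    def to_json(self, path=None) -> str:
        doc = json.dumps(dataclasses.asdict(self), indent=2, default=float)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_json(cls, path_or_str) -> "SimulationConfig":
        if isinstance(path_or_str, str) and path_or_str.lstrip().startswith("{"):
            raw = json.loads(path_or_str)
        else:
            with open(path_or_str, encoding="utf-8") as fh:
                raw = json.load(fh)
        cfg = cls()
        for key, value in raw.items():
            if key == "puberty_logistic":
                value = {s: PubertyLogistic(**v) for s, v in value.items()}
            elif key == "growth_model":
                value = {s: GrowthModel(**v) for s, v in value.items()}
            elif key == "bmi_baseline":
                value = {s: BmiBaseline(**v) for s, v in value.items()}
            elif key == "adiposity_model":
                value = AdiposityModel(**value)
            elif key == "waist_model":
                value = WaistModel(**value)
            elif key == "hip_model":
                value = HipModel(**value)
            elif key == "biomarker_model":
                value = {k: BiomarkerModel(**v) for k, v in value.items()}
            elif key == "effect_overrides":
                value = [EffectOverride(**v) for v in value]
            elif key == "age_range":
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg


def default_config(**overrides) -> SimulationConfig:
    """A validated default configuration, with keyword overrides."""
    cfg = SimulationConfig(**overrides)
    cfg.validate()
    return cfg


def expected_pubertal_fraction(config: SimulationConfig, sex: str) -> float:
    """Closed-form age-integrated pubertal probability for one sex.

    Integrates expit(s·(a − m)) over the uniform age distribution:
    (1/(s·(hi−lo))) · [log(1+e^{s(hi−m)}) − log(1+e^{s(lo−m)})].
    """
    lo, hi = config.age_range
    p = config.puberty_logistic[sex]
    s, m = p.slope, p.midpoint_age
    return (np.logaddexp(0.0, s * (hi - m)) - np.logaddexp(0.0, s * (lo - m))) / (
        s * (hi - lo)
    )


def derive_bmi_reference(config: SimulationConfig) -> BmiReferenceTable:
    """The exact parametric BMI percentile table implied by the baseline model.

    One row per sex × 1-year bin covering the configured age range, with
    normal-quantile P5/P85/P95. Classifying a generated cohort against this
    table reproduces the drawn weight-status classes exactly.
    """
    lo, hi = config.age_range
    bins = np.arange(int(np.floor(lo)), int(np.ceil(hi)))
    rows = []
    for sex, base in config.bmi_baseline.items():
        mu, sd = base.mean(bins), base.sd(bins)
        for i, b in enumerate(bins):
            rows.append(
                {
                    "sex": sex,
                    "age_lo": float(b),
                    "age_hi": float(b + 1),
                    "p5": norm.ppf(0.05, mu[i], sd[i]),
                    "p85": norm.ppf(0.85, mu[i], sd[i]),
                    "p95": norm.ppf(0.95, mu[i], sd[i]),
                }
            )
    return BmiReferenceTable(pd.DataFrame(rows))


def _percentile_distortion(u: np.ndarray, proportions: dict) -> np.ndarray:
    """Map uniform latent percentiles so class masses hit the P5/P85/P95 bands."""
    p = proportions
    src = np.array([0.0, p["wasting"], p["wasting"] + p["normal"], 1.0 - p["obesity"], 1.0])
    dst = np.array([0.0, 0.05, 0.85, 0.95, 1.0])
    return np.interp(u, src, dst)


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate a cohort table with one row per subject.

    ``seed`` overrides ``config.seed`` when given. Output is deterministic
    for identical (config, seed) and contains every column in
    :data:`SUBJECT_COLUMNS`, all measurements strictly positive.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    lo, hi = config.age_range

    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    male = sex == "male"
    age = np.floor(rng.uniform(lo, hi, n) * 10.0) / 10.0  # 0.1-year resolution

    p_pub = np.empty(n)
    for s in ("male", "female"):
        pl = config.puberty_logistic[s]
        mask = sex == s
        p_pub[mask] = expit(pl.slope * (age[mask] - pl.midpoint_age))
    pubertal = rng.random(n) < p_pub
    tanner = np.where(pubertal, rng.integers(2, 6, n), 1)
    group3 = np.select(
        [tanner == 1, tanner <= 3], ["prepubertal", "early_middle"], default="late"
    )

    # latent adiposity -> distorted percentile -> BMI on the bin baseline
    z_adip = rng.standard_normal(n)
    u = norm.cdf(z_adip)
    clip = config.adiposity_model.percentile_clip
    v = np.clip(_percentile_distortion(u, config.adiposity_model.proportions), 1 - clip, clip)
    bin_lo = np.floor(age)
    mu = np.empty(n)
    sd = np.empty(n)
    for s in ("male", "female"):
        base = config.bmi_baseline[s]
        mask = sex == s
        mu[mask] = base.mean(bin_lo[mask])
        sd[mask] = base.sd(bin_lo[mask])
    bmi = norm.ppf(v, mu, sd)

    height = np.empty(n)
    for s in ("male", "female"):
        g = config.growth_model[s]
        mask = sex == s
        height[mask] = (
            g.height_at_6_cm
            + g.height_slope_cm_per_yr * (age[mask] - 6.0)
            + rng.normal(0.0, g.height_sd_cm, mask.sum())
        )
    height = np.maximum(height, 80.0)
    weight = bmi * (height / 100.0) ** 2

    wm = config.waist_model
    whtr_loc = (
        wm.whtr_base
        + wm.pubertal_coef * pubertal.astype(float)
        + wm.male_coef * male.astype(float)
    )
    whtr = whtr_loc + wm.bmi_coef * (bmi - mu) + rng.normal(0.0, wm.resid_sd, n)
    whtr = np.clip(whtr, 0.25, 0.95)
    waist = whtr * height
    # standardized central-adiposity driver for the biomarkers
    wcz = (whtr - whtr_loc) / wm.wcz_scale

    hm = config.hip_model
    whr_mean = (
        hm.whr_base
        + hm.pubertal_coef * pubertal.astype(float)
        + hm.female_pubertal_coef * (pubertal & ~male).astype(float)
    )
    hip = waist / whr_mean + rng.normal(0.0, hm.resid_sd_cm, n)
    hip = np.maximum(hip, waist * 0.6)

    bio = {}
    for name, bm in config.biomarker_model.items():
        val = (
            bm.intercept
            + bm.age_slope * (age - 6.0)
            + bm.wc_slope * wcz
            + rng.normal(0.0, bm.resid_sd, n)
        )
        if bm.log_scale:
            val = np.exp(val)
        bio[name] = np.maximum(val, bm.floor) if bm.floor > 0 else val
    bio["dbp"] = np.minimum(bio["dbp"], bio["sbp"] - 2.0)

    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:06d}" for i in range(n)],
            "sex": sex,
            "age_years": age,
            "tanner_stage": tanner.astype(int),
            "pubertal_group": np.where(pubertal, "pubertal", "prepubertal"),
            "pubertal_group3": group3,
            "height_cm": height,
            "weight_kg": weight,
            "waist_cm": waist,
            "hip_cm": hip,
            "sbp_mmHg": bio["sbp"],
            "dbp_mmHg": bio["dbp"],
            "fbg_mmol_L": bio["glu"],
            "tg_mmol_L": bio["tg"],
            "hdl_mmol_L": bio["hdl"],
        }
    )

    for ov in config.effect_overrides:
        cohort = _apply_override(cohort, ov, config)
    return cohort


def _apply_override(cohort: pd.DataFrame, ov: EffectOverride, config: SimulationConfig):
    """Shift an index by stratum through exact waist inversion."""
    if ov.response != "bri":
        raise ConfigurationError(f"unsupported override response {ov.response!r}")
    if ov.by == "weight_status":
        ref = derive_bmi_reference(config)
        from .anthropometry import classify_weight_status, compute_bmi

        bmi = compute_bmi(
            cohort["weight_kg"].values, cohort["height_cm"].values / 100.0
        )
        labels = classify_weight_status(
            bmi, cohort["sex"].values, cohort["age_years"].values, ref
        )
    elif ov.by in cohort.columns:
        labels = cohort[ov.by].to_numpy()
    else:
        raise ConfigurationError(f"unknown override stratum column {ov.by!r}")

    from .anthropometry import compute_bri

    height_m = cohort["height_cm"].values / 100.0
    bri = compute_bri(cohort["waist_cm"].values / 100.0, height_m)
    shift = np.zeros(len(cohort))
    for level, delta in ov.shifts.items():
        shift[labels == level] = delta
    new_waist_m = invert_bri(bri + shift, height_m)
    out = cohort.copy()
    out["waist_cm"] = new_waist_m * 100.0
    return out


# ---------------------------------------------------------------------------
# cohort file I/O
# ---------------------------------------------------------------------------

def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as UTF-8 delimited text (TSV when the suffix says so).

    Columns are emitted in canonical order; floats use shortest round-trip
    representation, so ``read_cohort(write_cohort(x)) == x`` to full
    precision.
    """
    missing = [c for c in SUBJECT_COLUMNS if c not in cohort.columns]
    if missing:
        raise CohortSchemaError(f"cohort is missing required columns: {missing}")
    cohort[SUBJECT_COLUMNS].to_csv(path, sep=_sep_for(path), index=False, lineterminator="\n")


def read_cohort(path, complete_case: bool = True) -> pd.DataFrame:
    """Read a cohort file, enforcing schema and complete-case measurements.

    Raises :class:`CohortSchemaError` naming the first missing required
    column and :class:`CohortParseError` with the (0-based) row index for
    non-numeric measurement fields. Rows with missing (NA) measurements are
    dropped under the complete-case policy; the number and row indices of
    exclusions are recorded in ``df.attrs["n_excluded"]`` /
    ``df.attrs["excluded_rows"]`` and surfaced as a warning.
    """
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {', '.join(missing)}")

    for col in MEASUREMENT_COLUMNS + ["age_years"]:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise CohortParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r} at row {row}"
            )
        df[col] = numeric

    df.attrs["n_excluded"] = 0
    df.attrs["excluded_rows"] = []
    if complete_case:
        incomplete = df[MEASUREMENT_COLUMNS + ["age_years"]].isna().any(axis=1)
        if incomplete.any():
            rows = np.flatnonzero(incomplete).tolist()
            warnings.warn(
                f"excluded {len(rows)} row(s) with missing measurements "
                f"(complete-case policy): rows {rows}",
                stacklevel=2,
            )
            df = df.loc[~incomplete].reset_index(drop=True)
            df.attrs["n_excluded"] = len(rows)
            df.attrs["excluded_rows"] = rows
    return df
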