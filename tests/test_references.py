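import numpy as np
import pandas as pd
import pytest

import pedishape as ps
from pedishape.exceptions import (
    RankDeficientDesignError,
    ReferenceLookupError,
    SmallStratumWarning,
)
from pedishape.references import TAUS, check_loss, fit_quantile_regression
from pedishape.simulate import EffectOverride

from _oracles import grid_search_binary, grid_search_intercept


def test_intercept_only_fits_recover_sample_quantiles():
    y = [1.0, 2.0, 3.0, 4.0, 5.0]
    med = fit_quantile_regression(pd.DataFrame(), y, 0.5, n_bootstrap=0)
    assert med.params["intercept"] == pytest.approx(3.0, abs=1e-8)
    q25 = fit_quantile_regression(pd.DataFrame(), y, 0.25, n_bootstrap=0)
    oracle_val, oracle_loss = grid_search_intercept(y, 0.25)
    assert q25.params["intercept"] == pytest.approx(oracle_val, abs=1e-3)
    assert q25.check_loss == pytest.approx(oracle_loss, abs=1e-3)
    assert q25.params["intercept"] == pytest.approx(2.0, abs=1e-6)


def test_binary_covariate_slope_is_difference_of_group_medians():
    design = pd.DataFrame({"g": [0, 0, 0, 1, 1, 1]})
    y = [1.0, 2.0, 3.0, 11.0, 12.0, 13.0]
    fit = fit_quantile_regression(design, y, 0.5, n_bootstrap=0)
    (b0, slope), oracle_loss = grid_search_binary(y, design["g"], 0.5)
    assert fit.params["g"] == pytest.approx(10.0, abs=1e-6)
    assert fit.params["g"] == pytest.approx(slope, abs=2e-3)
    assert fit.check_loss <= oracle_loss + 1e-3


@pytest.mark.parametrize("tau", [0.05, 0.25, 0.5, 0.75, 0.95])
def test_intercept_only_loss_matches_empirical_quantile(tau):
    """The fitted check loss can never exceed the type-7 quantile's loss."""
    rng = np.random.default_rng(42)
    y = rng.gamma(2.0, 1.5, 41)
    fit = fit_quantile_regression(pd.DataFrame(), y, tau, n_bootstrap=0)
    q = np.quantile(y, tau)
    assert fit.check_loss <= check_loss(y, np.full(41, q), tau) + 1e-9


def test_fitted_loss_never_exceeds_intercept_only():
    rng = np.random.default_rng(3)
    design = pd.DataFrame({"x": rng.integers(0, 2, 60).astype(float)})
    y = 1.0 + 0.8 * design["x"].values + rng.standard_normal(60)
    for tau in TAUS:
        full = fit_quantile_regression(design, y, tau, n_bootstrap=0)
        null = fit_quantile_regression(pd.DataFrame(), y, tau, n_bootstrap=0)
        assert full.check_loss <= null.check_loss + 1e-10


def test_collinear_design_rejected():
    design = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0, 1.0], "b": [0, 1, 0, 1, 0]})
    with pytest.raises(RankDeficientDesignError, match="a"):
        fit_quantile_regression(design, [1, 2, 3, 4, 5], 0.5, n_bootstrap=0)


def test_missing_weight_level_raises_rank_error(panel):
    cohort = panel[panel["weight_status"] != "wasting"]
    with pytest.raises(RankDeficientDesignError):
        ps.fit_determinant_models(cohort, "bri", "female", taus=(0.5,), n_bootstrap=0)


def test_tau_domain():
    with pytest.raises(ValueError):
        fit_quantile_regression(pd.DataFrame(), [1, 2, 3], 1.5, n_bootstrap=0)


def test_bootstrap_ci_seeded_and_reproducible():
    rng = np.random.default_rng(8)
    design = pd.DataFrame({"x": rng.integers(0, 2, 80).astype(float)})
    y = 2.0 + design["x"].values + rng.standard_normal(80)
    a = fit_quantile_regression(design, y, 0.5, n_bootstrap=60, seed=5)
    b = fit_quantile_regression(design, y, 0.5, n_bootstrap=60, seed=5)
    pd.testing.assert_frame_equal(a.ci95, b.ci95)
    assert a.ci95.loc["x", "lo"] < a.params["x"] < a.ci95.loc["x", "hi"]


def test_determinant_models_structure(panel):
    fits = ps.fit_determinant_models(
        panel, "absi", "male", taus=(0.25, 0.5), n_bootstrap=20, seed=1
    )
    assert set(fits) == {0.25, 0.5}
    fit = fits[0.5]
    assert list(fit.params.index) == [
        "intercept", "pubertal", "normal", "overweight", "obesity"
    ]
    assert fit.scale == 1000.0
    assert fit.params_display["obesity"] == pytest.approx(
        1000.0 * fit.params["obesity"]
    )


def test_coefficient_error_shrinks_with_sample_size():
    """Known +0.8 obesity shift on BRI: estimates tighten from n=500 to n=5000."""
    shift = {"obesity": 0.8}
    errors = {}
    for n, seed in ((500, 21), (5000, 22)):
        cfg = ps.default_config(
            n_subjects=n,
            effect_overrides=[
                EffectOverride(response="bri", by="weight_status", shifts=shift)
            ],
        )
        cfg.waist_model.bmi_coef = 0.0  # isolate the configured shift
        ref = ps.derive_bmi_reference(cfg)
        cohort = ps.simulate_cohort(cfg, seed=seed)
        panel = ps.BodyShapeIndices(bmi_reference=ref).fit(cohort).transform(cohort)
        errs = []
        for tau in (0.25, 0.5, 0.75):
            fits = ps.fit_determinant_models(
                panel, "bri", "female", taus=(tau,), n_bootstrap=0
            )
            errs.append(abs(fits[tau].params["obesity"] - 0.8))
        errors[n] = np.mean(errs)
    assert errors[5000] < errors[500]


# ---------------------------------------------------------------------------
# percentile reference tables
# ---------------------------------------------------------------------------

def _stratum_frame(values, sex="female", pubertal="pubertal"):
    n = len(values)
    return pd.DataFrame(
        {
            "sex": [sex] * n,
            "pubertal_group": [pubertal] * n,
            "weight_status": ["normal"] * n,
            "bri": values,
            "absi": values,
        }
    )


def test_median_of_19_point_stratum():
    df = _stratum_frame(np.arange(1.0, 20.0))
    with pytest.warns(SmallStratumWarning):
        table = ps.build_percentile_reference(df, "bri")
    assert table["p50"].iloc[0] == pytest.approx(10.0)
    assert table["n_stratum"].iloc[0] == 19
    assert bool(table["low_n"].iloc[0])


def test_degenerate_stratum_all_percentiles_equal():
    df = _stratum_frame(np.full(60, 2.5))
    table = ps.build_percentile_reference(df, "bri")
    assert (table[["p5", "p25", "p50", "p75", "p85", "p95"]].values == 2.5).all()


def test_reference_levels_non_crossing(scored):
    for response in ("bri", "absi"):
        table = ps.build_percentile_reference(scored, response)
        levels = table[["p5", "p25", "p50", "p75", "p85", "p95"]].values
        assert np.all(np.diff(levels, axis=1) >= 0)


def test_reference_strata_schemes(scored):
    bri = ps.build_percentile_reference(scored, "bri")
    absi = ps.build_percentile_reference(scored, "absi")
    assert set(zip(bri["sex"], bri["pubertal_group"])) == {
        ("female", "prepubertal"), ("female", "pubertal"),
        ("male", "prepubertal"), ("male", "pubertal"),
    }
    assert set(absi["pubertal_group"]) == {"all"}


def test_reference_restricted_to_normal_weight(scored):
    table = ps.build_percentile_reference(scored, "bri")
    normal = scored[scored["weight_status"] == "normal"]
    assert table["n_stratum"].sum() == len(normal)


# ---------------------------------------------------------------------------
# published-table fixture lookups
# ---------------------------------------------------------------------------

def test_lookup_published_cutoffs(published_reference):
    girls_pub_p75 = ps.lookup_cutoff(
        published_reference, "bri", "female", "pubertal", level="p75"
    )
    assert girls_pub_p75 == 2.025
    boys_pre_p5 = ps.lookup_cutoff(
        published_reference, "bri", "male", "prepubertal", level="p5"
    )
    assert boys_pre_p5 == 1.228
    absi_girls_p50 = ps.lookup_cutoff(published_reference, "absi", "female", None, "p50")
    assert absi_girls_p50 == 0.0788


def test_lookup_missing_level_and_stratum(published_reference):
    with pytest.raises(ReferenceLookupError, match="p85"):
        ps.lookup_cutoff(published_reference, "bri", "female", "pubertal", level="p85")
    with pytest.raises(ReferenceLookupError, match="stratum"):
        ps.lookup_cutoff(published_reference, "bri", "female", "late", level="p75")
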