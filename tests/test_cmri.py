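import numpy as np
import pandas as pd
import pytest

import pedishape as ps
from pedishape.cmri import COMPONENTS, ComponentStats, compute_cmri
from pedishape.exceptions import (
    DegenerateCellError,
    PoolingWarning,
    StratificationError,
)


def _toy_reference():
    return ps.BmiReferenceTable(
        pd.DataFrame(
            {
                "sex": ["male"],
                "age_lo": [6.0],
                "age_hi": [18.0],
                "p5": [14.0],
                "p85": [19.0],
                "p95": [21.0],
            }
        )
    )


def _subjects(bmis, **overrides):
    n = len(bmis)
    df = pd.DataFrame(
        {
            "subject_id": [f"T{i}" for i in range(n)],
            "sex": ["male"] * n,
            "age_years": [10.0] * n,
            "pubertal_group": ["prepubertal"] * n,
            "height_cm": [150.0] * n,
            "weight_kg": [b * 1.5**2 for b in bmis],
            "waist_cm": np.linspace(55, 70, n),
            "hip_cm": np.linspace(70, 85, n),
            "sbp_mmHg": np.linspace(95, 110, n),
            "dbp_mmHg": np.linspace(55, 65, n),
            "fbg_mmol_L": np.linspace(4.2, 5.2, n),
            "tg_mmol_L": np.linspace(0.5, 1.5, n),
            "hdl_mmol_L": np.linspace(1.1, 1.8, n),
        }
    )
    for k, v in overrides.items():
        df[k] = v
    return df


def test_reference_population_boundary_rule():
    """BMI in [P5, P95): P5 retained, P95 excluded -> 4 of 6 kept."""
    cohort = _subjects([13.0, 14.0, 17.0, 19.0, 20.9, 21.0])
    subset = ps.select_reference_population(cohort, _toy_reference())
    assert len(subset) == 4
    assert set(subset["subject_id"]) == {"T1", "T2", "T3", "T4"}


def test_all_obese_cohort_has_empty_reference():
    cohort = _subjects([25.0, 26.0, 27.0])
    with pytest.raises(StratificationError):
        ps.select_reference_population(cohort, _toy_reference())


def test_component_stats_mean_and_sample_sd():
    """Cell {4, 6} -> mean 5, SD sqrt(2) with the n-1 denominator."""
    cohort = _subjects([16.0, 17.0])
    for col in COMPONENTS.values():
        cohort[col] = [4.0, 6.0]
    stats = ps.estimate_component_stats(cohort, min_cell_n=2, age_bin_width=12.0)
    assert (stats.table["mean"] == 5.0).all()
    assert stats.table["sd"].values == pytest.approx(np.sqrt(2.0))
    assert stats.table["sd"].values == pytest.approx(1.4142, abs=5e-5)
    assert (stats.table["n_ref"] == 2).all()


def test_constant_cell_is_degenerate():
    cohort = _subjects([16.0, 16.5, 17.0], tg_mmol_L=[1.0, 1.0, 1.0])
    with pytest.raises(DegenerateCellError, match="tg"):
        ps.estimate_component_stats(cohort, min_cell_n=3, age_bin_width=12.0)


def test_stats_computed_on_reference_subset_only():
    """Adding an obese outlier must not move the reference statistics."""
    ref = _toy_reference()
    base = _subjects([15.0, 16.0, 17.0, 18.0])
    extra = pd.concat(
        [base, _subjects([30.0]).assign(subject_id="OBESE", waist_cm=120.0)],
        ignore_index=True,
    )
    s1 = ps.estimate_component_stats(
        ps.select_reference_population(base, ref), min_cell_n=2, age_bin_width=12.0
    )
    s2 = ps.estimate_component_stats(
        ps.select_reference_population(extra, ref), min_cell_n=2, age_bin_width=12.0
    )
    pd.testing.assert_frame_equal(s1.table, s2.table)


def _stats_at(mean=0.0, sd=1.0):
    rows = [
        {
            "sex": "male",
            "age_lo": 6.0,
            "age_hi": 18.0,
            "component": c,
            "mean": mean,
            "sd": sd,
            "n_ref": 99,
        }
        for c in COMPONENTS
    ]
    return ComponentStats(pd.DataFrame(rows))


def test_cmri_zero_at_cell_means():
    cohort = _subjects([16.0])
    for col in COMPONENTS.values():
        cohort[col] = 5.0
    out = compute_cmri(cohort, _stats_at(mean=5.0, sd=2.0))
    assert out[[f"z_{c}" for c in COMPONENTS]].values == pytest.approx(0.0)
    assert out["cmri_z"].iloc[0] == 0.0
    assert not out["high_risk"].iloc[0]


def test_cmri_hdl_sign_and_variant_arithmetic():
    """All z = +1 -> CMRI 4 (full; HDL subtracts) and 3 (waist omitted)."""
    cohort = _subjects([16.0])
    for col in COMPONENTS.values():
        cohort[col] = 6.0  # z = +1 for mean 5, sd 1
    full = compute_cmri(cohort, _stats_at(mean=5.0, sd=1.0), variant="full")
    omitted = compute_cmri(cohort, _stats_at(mean=5.0, sd=1.0), variant="wc_omitted")
    assert full["cmri_z"].iloc[0] == pytest.approx(4.0, abs=1e-12)
    assert omitted["cmri_z"].iloc[0] == pytest.approx(3.0, abs=1e-12)
    assert full["high_risk"].iloc[0] and omitted["high_risk"].iloc[0]


def test_high_risk_threshold_inclusive():
    stats = _stats_at(mean=5.0, sd=1.0)
    cohort = _subjects([16.0])
    for col in COMPONENTS.values():
        cohort[col] = 5.0
    cohort["waist_cm"] = 6.0  # z_wc = 1 exactly
    assert compute_cmri(cohort, stats)["high_risk"].iloc[0]
    cohort["waist_cm"] = 5.999
    assert not compute_cmri(cohort, stats)["high_risk"].iloc[0]


def test_variant_difference_equals_waist_z(scored, scorer):
    omitted = compute_cmri(scored, scorer.component_stats_, variant="wc_omitted")
    merged = scored.merge(omitted[["subject_id", "cmri_z"]], on="subject_id", suffixes=("", "_om"))
    np.testing.assert_allclose(
        merged["cmri_z"] - merged["cmri_z_om"], merged["z_wc"], atol=1e-12
    )


def test_component_z_signs(scorer):
    """Raising HDL lowers the composite; raising any other component raises it."""
    stats = scorer.component_stats_
    base = _subjects([16.0], sex="male")
    cell = stats.table[(stats.table["sex"] == "male")]
    lo = cell.iloc[0]["age_lo"]
    base["age_years"] = lo + 0.5
    for comp, col in COMPONENTS.items():
        base[col] = float(cell[cell["component"] == comp]["mean"].iloc[0])
    ref_val = compute_cmri(base, stats)["cmri_z"].iloc[0]
    for comp, col in COMPONENTS.items():
        bumped = base.copy()
        bumped[col] = bumped[col] + 1.0
        val = compute_cmri(bumped, stats)["cmri_z"].iloc[0]
        if comp == "hdl":
            assert val < ref_val
        else:
            assert val > ref_val


def test_reference_z_scores_standardized(scored, scorer, bmi_reference):
    refpop = ps.select_reference_population(scored, bmi_reference)
    idx = scorer.component_stats_.locate(refpop["sex"].values, refpop["age_years"].values)
    for comp in COMPONENTS:
        g = refpop.assign(cell=idx).groupby("cell")[f"z_{comp}"].agg(["mean", "std"])
        assert g["mean"].abs().max() < 1e-10
        assert (g["std"] - 1).abs().max() < 1e-10


def test_missing_component_excluded_with_warning(scorer):
    cohort = _subjects([16.0, 16.5])
    cell = scorer.component_stats_.table
    cohort["age_years"] = cell["age_lo"].iloc[0] + 0.5
    cohort.loc[0, "tg_mmol_L"] = np.nan
    with pytest.warns(UserWarning, match="missing CMRI components"):
        out = compute_cmri(cohort, scorer.component_stats_)
    assert list(out["subject_id"]) == ["T1"]


def test_sparse_cells_pooled_with_warning():
    rng = np.random.default_rng(0)
    n = 40
    cohort = _subjects(list(rng.uniform(15, 18, n)))
    cohort["age_years"] = rng.uniform(6, 18, n)
    for col in COMPONENTS.values():
        cohort[col] = rng.normal(50, 5, n)
    with pytest.warns(PoolingWarning):
        stats = ps.estimate_component_stats(cohort, min_cell_n=10, age_bin_width=1.0)
    assert (stats.table["n_ref"] >= 10).all() or len(stats.table) > 0


def test_component_stats_json_round_trip(scorer, tmp_path):
    path = tmp_path / "stats.json"
    scorer.component_stats_.to_json(path)
    back = ComponentStats.from_json(path)
    pd.testing.assert_frame_equal(back.table, scorer.component_stats_.table)


# ---------------------------------------------------------------------------
# prevalence tables
# ---------------------------------------------------------------------------

def test_prevalence_percentage_rounding():
    df = pd.DataFrame({"high_risk": [True] * 12 + [False] * 173})
    out = ps.prevalence_table(df, by="overall")
    assert out.loc[0, "n"] == 185
    assert out.loc[0, "percent"] == 6.5


def test_prevalence_zero_numerator():
    df = pd.DataFrame({"high_risk": [False] * 50})
    assert ps.prevalence_table(df, by="overall").loc[0, "percent"] == 0.0


def test_prevalence_groups_reaggregate(scored):
    by_status = ps.prevalence_table(scored, by="weight_status")
    overall = ps.prevalence_table(scored, by="overall")
    recombined = 100.0 * by_status["n_high"].sum() / by_status["n"].sum()
    assert recombined == pytest.approx(overall.loc[0, "percent"], abs=0.05)
    assert by_status["n"].sum() == len(scored)


def test_prevalence_unknown_grouping(scored):
    with pytest.raises(ValueError, match="grouping"):
        ps.prevalence_table(scored, by="shoe_size")


def test_prevalence_monotone_across_weight_status(scored):
    """High-CMRI prevalence must climb from wasting through obesity."""
    t = ps.prevalence_table(scored, by="weight_status").set_index("group")
    order = ["wasting", "normal", "overweight", "obesity"]
    vals = t.loc[order, "percent"].values
    assert np.all(np.diff(vals) > 0)
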