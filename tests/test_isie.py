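"""Drug-effect models, IS-IE rescaling and per-drug tests."""

import numpy as np
import pandas as pd
import pytest

from tolsig import (
    CohortConfig,
    ValidationError,
    drug_effect_tests,
    drug_variance_explained,
    fit_drug_models,
    isie_transform,
    isie_transform_heldout,
    simulate_cohort,
    simulate_expression,
)
from tolsig.dataio import DRUGS


def _design(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"),
                        columns=list(DRUGS))


def _meta_from_design(design, group="stable"):
    rows = []
    for sid in design.index:
        rows.append({"sample_id": sid, "patient_id": sid, "group": group,
                     "timepoint": "1", **design.loc[sid].to_dict()})
    return pd.DataFrame(rows)


class TestFitDrugModels:
    def test_single_binary_covariate_equals_group_means(self):
        # Pred on: mean 4, off: mean 2, within-group constant
        design = _design([[1, 0, 0, 0, 0]] * 5 + [[0, 0, 0, 0, 0]] * 5)
        expr = pd.DataFrame([[4.0] * 5 + [2.0] * 5], index=["g1"],
                            columns=design.index)
        model = fit_drug_models(expr, design)
        assert model.coef.loc["g1", "intercept"] == pytest.approx(2.0)
        assert model.coef.loc["g1", "pred"] == pytest.approx(4.0 - 2.0)
        # the other drugs never vary: non-estimable, not silent zero
        assert not model.estimable.loc["g1", "cyc"]
        resid = isie_transform(expr, _meta_from_design(design), model)
        assert np.allclose(resid.to_numpy(), 0.0, atol=1e-12)

    def test_constant_response(self, rng):
        design = _design((rng.random((12, 5)) < 0.4).astype(int))
        design["tac"] *= 1 - design["cyc"]
        design["mmf"] *= 1 - design["aza"]
        expr = pd.DataFrame(np.full((1, 12), 5.0), index=["g1"],
                            columns=design.index)
        model = fit_drug_models(expr, design)
        assert model.coef.loc["g1", "intercept"] == pytest.approx(5.0)
        est = model.coef.loc["g1", list(DRUGS)].dropna()
        assert np.allclose(est, 0.0, atol=1e-10)
        assert model.r2["g1"] == 0.0

    def test_missing_expression_complete_case(self, rng):
        cfg = CohortConfig(n_tolerant=0, n_stable=60, n_chronic=0, n_healthy=0,
                           n_genes=4, seed=5)
        meta, design = simulate_cohort(cfg)
        expr, truth = simulate_expression(meta, design, cfg)
        holes = expr.copy()
        holes.iloc[0, :10] = np.nan
        model = fit_drug_models(holes, design)
        assert model.n_used.iloc[0] == 50
        assert model.n_used.iloc[1] == 60
        # complete-case fit equals fitting the reduced matrix directly
        direct = fit_drug_models(holes.iloc[[0], 10:], design.iloc[10:])
        pd.testing.assert_series_equal(model.coef.iloc[0],
                                       direct.coef.iloc[0])

    def test_too_few_samples_rejected(self):
        design = _design([[0, 0, 0, 0, 0]] * 6)
        expr = pd.DataFrame(np.ones((1, 6)), index=["g1"], columns=design.index)
        with pytest.raises(ValidationError, match="g1"):
            fit_drug_models(expr, design)


class TestIsieTransform:
    def test_untreated_is_intercept_shift(self):
        design = _design([[1, 0, 0, 0, 0]] * 5 + [[0, 0, 0, 0, 0]] * 5)
        expr = pd.DataFrame([[4.0] * 5 + [2.0] * 5], index=["g1"],
                            columns=design.index)
        model = fit_drug_models(expr, design)
        tol = pd.DataFrame({"t1": [5.0]}, index=["g1"])
        meta = pd.DataFrame([{"sample_id": "t1", "patient_id": "t1",
                              "group": "tolerant", "timepoint": "1",
                              **dict.fromkeys(DRUGS, 0)}])
        out = isie_transform(tol, meta, model)
        assert out.loc["g1", "t1"] == pytest.approx(5.0 - 2.0)

    def test_untreated_shift_preserves_variance(self, small_cohort):
        expr, meta = small_cohort["expr"], small_cohort["meta"]
        model = fit_drug_models(expr, small_cohort["treated_design"])
        isie = isie_transform(expr, meta, model)
        untreated = meta.loc[meta["group"].isin(("tolerant", "healthy")),
                             "sample_id"]
        raw_var = expr[untreated].var(axis=1)
        isie_var = isie[untreated].var(axis=1)
        pd.testing.assert_series_equal(raw_var, isie_var)

    def test_double_residualization_is_null(self, small_cohort):
        # refitting the drug model on IS-IE values of treated samples gives
        # alpha ~ 0 and beta ~ 0
        expr = small_cohort["expr"]
        design = small_cohort["treated_design"]
        model = fit_drug_models(expr, design)
        isie = isie_transform(expr, small_cohort["meta"], model)
        refit = fit_drug_models(isie[design.index], design)
        assert np.nanmax(np.abs(refit.coef.to_numpy())) < 1e-8

    def test_heldout_never_refits(self, small_cohort):
        expr, meta = small_cohort["expr"], small_cohort["meta"]
        model = fit_drug_models(expr, small_cohort["treated_design"])
        same = isie_transform_heldout(expr, meta, model)
        pd.testing.assert_frame_equal(same, isie_transform(expr, meta, model))

    def test_flag_change_shifts_by_beta(self):
        design = _design([[1, 0, 0, 0, 0]] * 6 + [[0, 0, 0, 0, 0]] * 6)
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.normal(size=(1, 12)) + 2.0 * design["pred"].to_numpy(),
            index=["g1"], columns=design.index)
        model = fit_drug_models(expr, design)
        meta_on = _meta_from_design(design)
        meta_off = meta_on.copy()
        meta_off["pred"] = 0
        on = isie_transform_heldout(expr, meta_on, model)
        off = isie_transform_heldout(expr, meta_off, model)
        shift = (off - on).loc["g1"].to_numpy()
        expected = np.where(design["pred"] == 1, model.coef.loc["g1", "pred"], 0.0)
        assert np.allclose(shift, expected, atol=1e-12)

    def test_unknown_gene_listed(self, small_cohort):
        model = fit_drug_models(small_cohort["expr"],
                                small_cohort["treated_design"])
        alien = pd.DataFrame({"s": [1.0]}, index=["NOT_A_GENE"])
        meta = pd.DataFrame([{"sample_id": "s", "patient_id": "s",
                              "group": "tolerant", "timepoint": "1",
                              **dict.fromkeys(DRUGS, 0)}])
        with pytest.raises(ValidationError, match="NOT_A_GENE"):
            isie_transform(alien, meta, model)


class TestDrugEffectTests:
    def test_bonferroni_family_arithmetic(self, small_cohort):
        table = drug_effect_tests(small_cohort["expr"],
                                  small_cohort["treated_design"])
        ok = table[table["computable"]]
        cni = ok[ok["family"] == "cni"]
        assert np.allclose(cni["p_adj"], np.minimum(1.0, cni["p"] * 2))
        pred = ok[ok["family"] == "pred"]
        assert np.allclose(pred["p_adj"], pred["p"])
        assert (ok["p_adj"] >= ok["p"] - 1e-15).all()

    def test_power_for_strong_pred_effect(self):
        hits = 0
        reps = 40
        rng = np.random.default_rng(77)
        cfg = CohortConfig(n_tolerant=0, n_stable=150, n_chronic=50,
                           n_healthy=0, n_genes=1, noise_sd=1.0,
                           frac_drug_affected=0.0, frac_tolerance_genes=0.0)
        for _ in range(reps):
            meta, design = simulate_cohort(cfg, rng)
            expr, truth = simulate_expression(meta, design, cfg, rng)
            expr.iloc[0] += 1.5 * design["pred"].to_numpy()
            t = drug_effect_tests(expr, design)
            p = t[(t["gene"] == expr.index[0]) & (t["drug"] == "pred")]["p_adj"]
            hits += int(p.iloc[0] < 0.001)
        assert hits >= int(0.95 * reps)

    def test_r2_perfect_fit_and_reporting(self):
        design = _design([[1, 0, 0, 0, 0]] * 5 + [[0, 0, 0, 0, 0]] * 5)
        expr = pd.DataFrame([[4.0] * 5 + [2.0] * 5], index=["g1"],
                            columns=design.index)
        r2 = drug_variance_explained(expr, design)
        assert r2.loc["g1", "r2"] == pytest.approx(1.0)
        assert r2.loc["g1", "r2_percent"] == pytest.approx(100.0)
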