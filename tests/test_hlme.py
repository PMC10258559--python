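import math

import numpy as np
import pandas as pd
import pytest

from migvar import (
    DesignSpec,
    GenerativeParams,
    HLMEModelSpec,
    STUDY_MODEL,
    StructureError,
    decompose_variance,
    fit_nested_lme,
    generate_hierarchical_dataset,
    predict_random_intercepts,
)

from _oracles import dense_ml_fit, dense_neg2ll
from conftest import SCALED_DESIGN, canonical_params

TINY = DesignSpec(
    n_labs=3,
    n_persons_per_lab=1,
    n_experiments_per_person=1,
    n_replicates_per_condition=1,
    n_cells_per_replicate=2,
    n_timepoints=3,
)


def _theta_from(model):
    vals = [model.sigma2[l] for l in model.spec.levels] + [model.sigma2_residual]
    return np.log(np.maximum(vals, 1e-12))


class TestDegenerateFits:
    def test_constant_response(self):
        t, _ = generate_hierarchical_dataset(
            TINY, GenerativeParams(beta0=5.0, sigma2_residual=0.0)
        )
        m = fit_nested_lme(t, STUDY_MODEL)
        assert m.beta0 == pytest.approx(5.0)
        assert all(v == 0.0 for v in m.variances().values())

    def test_pure_fixed_effect(self):
        t, _ = generate_hierarchical_dataset(
            TINY, GenerativeParams(beta0=5.0, delta=3.0, sigma2_residual=0.0)
        )
        m = fit_nested_lme(t, STUDY_MODEL)
        assert m.beta0 == pytest.approx(5.0)
        assert m.delta == pytest.approx(3.0)
        assert all(v == 0.0 for v in m.variances().values())

    def test_delta_on_single_condition_errors(self):
        d = DesignSpec(
            n_labs=2, n_persons_per_lab=1, n_experiments_per_person=1,
            conditions=("control",), n_replicates_per_condition=2,
            n_cells_per_replicate=2, n_timepoints=3,
        )
        t, _ = generate_hierarchical_dataset(d, GenerativeParams(seed=1))
        with pytest.raises(StructureError, match="undefined"):
            fit_nested_lme(t, STUDY_MODEL)

    def test_missing_column_is_structural_error(self):
        t, _ = generate_hierarchical_dataset(TINY, GenerativeParams(seed=1))
        with pytest.raises(StructureError, match="person"):
            fit_nested_lme(t.drop(columns="person"), STUDY_MODEL)


class TestOracleEquivalence:
    def test_tiny_dataset_matches_dense_covariance_ml(self):
        p = GenerativeParams(
            beta0=2.0, delta=1.0, sigma2_lab=1.0, sigma2_cell=0.8,
            sigma2_residual=1.0, seed=3,
        )
        t, _ = generate_hierarchical_dataset(TINY, p)
        m = fit_nested_lme(t, STUDY_MODEL, compute_blups=False)
        mine = -2 * m.loglik
        # dense evaluation at my estimates equals my profiled likelihood
        at_mine = dense_neg2ll(
            t, STUDY_MODEL, "ics", m.sigma2, max(m.sigma2_residual, 1e-12)
        )
        assert abs(mine - at_mine) < 1e-6
        oracle = dense_ml_fit(t, STUDY_MODEL, "ics", [_theta_from(m), np.zeros(6)])
        assert mine - oracle <= 2e-4 and oracle - mine <= 2e-4

    def test_likelihood_never_decreases_over_accepted_iterates(self):
        p = GenerativeParams(
            sigma2_lab=2.0, sigma2_person=0.5, sigma2_cell=1.0,
            sigma2_residual=1.0, seed=5,
        )
        d = DesignSpec(
            n_labs=3, n_persons_per_lab=2, n_experiments_per_person=2,
            n_replicates_per_condition=2, n_cells_per_replicate=3, n_timepoints=4,
        )
        t, _ = generate_hierarchical_dataset(d, p)
        m = fit_nested_lme(t, STUDY_MODEL, compute_blups=False, track_history=True)
        hist = np.asarray(m.history)
        assert len(hist) >= 2
        assert np.all(np.diff(hist) <= 1e-9)

    def test_deterministic_given_data(self, scaled_table):
        t, _ = scaled_table
        m1 = fit_nested_lme(t, STUDY_MODEL, compute_blups=False)
        m2 = fit_nested_lme(t, STUDY_MODEL, compute_blups=False)
        assert m1.loglik == m2.loglik
        assert m1.variances() == m2.variances()


class TestRecovery:
    def test_scaled_design_estimates_near_truth(self, scaled_table):
        t, truth = scaled_table
        m = fit_nested_lme(t, STUDY_MODEL, compute_blups=False)
        # single-seed sanity: the well-identified inner components sit
        # close to truth; the 3-unit lab variance is checked across seeds
        # in the acceptance suite
        assert m.sigma2["cell"] == pytest.approx(2.0, rel=0.15)
        assert m.sigma2_residual == pytest.approx(2.0, rel=0.05)
        assert m.delta == pytest.approx(3.0, rel=0.1)

    def test_no_structure_data_gives_no_technical_share(self):
        p = GenerativeParams(beta0=1.0, delta=3.0, sigma2_residual=2.0, seed=21)
        t, _ = generate_hierarchical_dataset(SCALED_DESIGN, p)
        m = fit_nested_lme(t, STUDY_MODEL, compute_blups=False)
        vt = decompose_variance({"ics": m})
        assert vt.technical_share.iloc[0] <= 0.1
        # and permuting level labels cannot manufacture structure
        rng = np.random.default_rng(0)
        t2 = t.copy()
        t2["lab"] = rng.permutation(t2["lab"].to_numpy())
        m2 = fit_nested_lme(t2, STUDY_MODEL, compute_blups=False)
        assert decompose_variance({"ics": m2}).technical_share.iloc[0] <= 0.1


def test_reml_matches_balanced_anova_closed_form():
    # restricted likelihood on balanced one-level data reproduces the
    # classical ANOVA estimators (MSB - MSW)/n and MSW exactly
    rng = np.random.default_rng(0)
    m_units, n = 12, 8
    y = rng.normal(0, 2.0, m_units)[:, None] + rng.normal(0, 1.0, (m_units, n))
    t = pd.DataFrame({"unit": np.repeat(range(m_units), n), "y": y.ravel()})
    fit = fit_nested_lme(
        t, HLMEModelSpec(levels=("unit",)), value_col="y",
        reml=True, compute_blups=False,
    )
    gm = y.mean(axis=1)
    msb = n * gm.var(ddof=1)
    msw = ((y - gm[:, None]) ** 2).sum() / (m_units * (n - 1))
    assert fit.sigma2["unit"] == pytest.approx((msb - msw) / n, rel=1e-6)
    assert fit.sigma2_residual == pytest.approx(msw, rel=1e-6)
    # REML variance estimates sit above their ML counterparts
    ml = fit_nested_lme(
        t, HLMEModelSpec(levels=("unit",)), value_col="y", compute_blups=False
    )
    assert fit.sigma2["unit"] >= ml.sigma2["unit"]


class TestBLUPs:
    def test_zero_variance_level_gives_zero_blups(self):
        p = GenerativeParams(
            beta0=1.0, delta=1.0, sigma2_cell=1.0, sigma2_residual=1.0, seed=2
        )
        d = DesignSpec(
            n_labs=2, n_persons_per_lab=2, n_experiments_per_person=2,
            n_replicates_per_condition=2, n_cells_per_replicate=4, n_timepoints=6,
        )
        t, _ = generate_hierarchical_dataset(d, p)
        m = fit_nested_lme(t, STUDY_MODEL)
        for level in ("lab", "person", "experiment", "replicate"):
            if m.sigma2[level] == 0.0:
                assert (m.blups[level] == 0.0).all()
        assert any(m.sigma2[l] == 0.0 for l in ("lab", "person"))

    def test_one_level_balanced_matches_closed_form_shrinkage(self):
        # y_ij = b0 + u_i + e_ij: BLUP_i = (n*s2u/(n*s2u + s2e)) * (ybar_i - ybar)
        rng = np.random.default_rng(8)
        m_units, n = 40, 25
        u = rng.normal(0, 2.0, m_units)
        y = (u[:, None] + rng.normal(0, 1.0, (m_units, n))).ravel()
        t = pd.DataFrame({
            "unit": np.repeat([f"U{i}" for i in range(m_units)], n),
            "y": y + 10.0,
        })
        spec = HLMEModelSpec(levels=("unit",))
        fit = fit_nested_lme(t, spec, value_col="y")
        s2u, s2e = fit.sigma2["unit"], fit.sigma2_residual
        shrink = n * s2u / (n * s2u + s2e)
        gm = t.groupby("unit")["y"].mean()
        expected = shrink * (gm - fit.beta0)
        got = fit.blups["unit"].reindex(pd.MultiIndex.from_arrays([gm.index]))
        assert np.allclose(got.to_numpy(), expected.to_numpy(), atol=1e-6)

    def test_blups_track_true_intercepts(self, scaled_table):
        t, truth = scaled_table
        m = fit_nested_lme(t, STUDY_MODEL)
        # many units + weak parent-mean centring: cell-level prediction is tight
        tru = truth.intercepts["ics"]["cell"]
        est = m.blups["cell"].reindex(tru.index)
        assert np.corrcoef(tru, est)[0, 1] > 0.9
        # every active level carries real signal despite the sqrt(1-1/m)
        # ceiling from shrinkage toward the estimated parent mean
        for level in m.spec.levels:
            if m.sigma2[level] > 0 and len(truth.intercepts["ics"][level]) >= 9:
                tru = truth.intercepts["ics"][level]
                est = m.blups[level].reindex(tru.index)
                assert np.corrcoef(tru, est)[0, 1] > 0.5

    def test_blups_sum_to_zero_within_levels(self, scaled_table):
        t, _ = scaled_table
        m = fit_nested_lme(t, STUDY_MODEL)
        sd = t["ics"].std()
        for level in m.spec.levels:
            assert abs(m.blups[level].sum()) < 1e-6 * sd * len(m.blups[level])

    def test_unseen_unit_errors(self, scaled_table):
        t, _ = scaled_table
        m = fit_nested_lme(t, STUDY_MODEL)
        bad = t.head(5).copy()
        bad["lab"] = "L99"
        with pytest.raises(StructureError, match="unseen"):
            predict_random_intercepts(m, bad)


class TestVarianceDecomposition:
    def test_technical_share_arithmetic(self):
        class Dummy:
            def __init__(self, v):
                self._v = v

            def variances(self):
                return self._v

        v = {"lab": 4.0, "person": 1.0, "experiment": 0.5, "replicate": 0.5,
             "cell": 2.0, "residual": 2.0}
        vt = decompose_variance({"f": Dummy(v)})
        assert vt.technical_share["f"] == pytest.approx(0.6)
        assert vt.biological_share["f"] == pytest.approx(0.4)
        assert vt.relative.loc["f"].sum() == pytest.approx(1.0)

    def test_all_technical_zero(self):
        class Dummy:
            def variances(self):
                return {"lab": 0.0, "person": 0.0, "experiment": 0.0,
                        "replicate": 0.0, "cell": 1.0, "residual": 1.0}

        vt = decompose_variance({"f": Dummy()})
        assert vt.technical_share["f"] == 0.0

    def test_recovered_share_close_to_realized_share(self, scaled_table):
        # a single draw of 3 labs can land far from the generative sigma2_lab,
        # so compare against the dispersion of the intercepts actually drawn
        t, truth = scaled_table
        m = fit_nested_lme(t, STUDY_MODEL, compute_blups=False)
        vt = decompose_variance({"ics": m})
        realized = {
            lvl: float(np.var(truth.intercepts["ics"][lvl], ddof=1))
            for lvl in STUDY_MODEL.levels
        }
        realized["residual"] = float(np.var(truth.residuals["ics"], ddof=1))
        share = sum(
            realized[k] for k in ("lab", "person", "experiment", "replicate")
        ) / sum(realized.values())
        assert vt.technical_share["ics"] == pytest.approx(share, abs=0.05)
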