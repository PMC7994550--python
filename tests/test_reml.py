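"""REML criterion and fitter, checked against independent oracles.

The independent criterion oracle builds the full marginal covariance as a
dense matrix from scratch and evaluates the Gaussian log-density of an
orthonormal contrast basis (scipy); the independent estimate oracle is
statsmodels' general-purpose mixed-model fitter.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import null_space
from scipy.stats import multivariate_normal

from ppticc import (Design, VarianceComponents, drop_cells, fit_reml,
                    fit_reml_values, reml_criterion, simulate_dataset,
                    variance_percentages)
from ppticc.reml import (NotEstimableError, SingularCovarianceError,
                         _BalancedStats, _SubjectBlocks, _to_array)


def contrast_oracle(components: VarianceComponents, data: pd.DataFrame) -> float:
    """Brute-force REML criterion: dense covariance + orthonormal contrasts."""
    d = data.sort_values(["subject", "session", "side", "repetition"])
    y = d["ppt_n"].to_numpy(float)
    subj = d["subject"].to_numpy()
    sess = d["session"].to_numpy()
    side = d["side"].to_numpy()
    n = len(y)
    same_subj = subj[:, None] == subj[None, :]
    V = (components.sigma2_subj * same_subj
         + components.sigma2_sess * (same_subj & (sess[:, None] == sess[None, :]))
         + components.sigma2_side * (same_subj & (side[:, None] == side[None, :]))
         + components.sigma2_sss * (same_subj & (sess[:, None] == sess[None, :])
                                    & (side[:, None] == side[None, :]))
         + components.sigma2_reps * np.eye(n))
    K = null_space(np.ones((1, n)))
    return float(multivariate_normal.logpdf(K.T @ y, mean=np.zeros(n - 1),
                                            cov=K.T @ V @ K))


@pytest.fixture(scope="module")
def toy_data(toy_design, paper_components):
    return simulate_dataset(toy_design, paper_components, seed=7)


class TestCriterion:
    def test_two_point_closed_form(self):
        """Two subjects, one observation each, unit residual variance:
        the contrast is (y1-y2)/sqrt(2) ~ N(0,1), so the criterion is
        -log(2*pi)/2 - 1 at values {0, 2}."""
        data = pd.DataFrame({"subject": ["a", "b"], "session": [1, 1],
                             "side": [1, 1], "repetition": [1, 1],
                             "ppt_n": [0.0, 2.0]})
        comps = VarianceComponents(grand_mean=1.0, sigma2_subj=0, sigma2_sess=0,
                                   sigma2_side=0, sigma2_sss=0, sigma2_reps=1.0)
        expected = -0.5 * math.log(2 * math.pi) - 1.0
        assert reml_criterion(comps, data) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_relabeling_and_row_order(self, toy_data,
                                                   paper_components):
        base = reml_criterion(paper_components, toy_data)
        relabeled = toy_data.copy()
        relabeled["subject"] = relabeled["subject"].map(
            lambda s: f"Z{hash(s) % 97}")
        shuffled = relabeled.sample(frac=1.0, random_state=0)
        assert reml_criterion(paper_components, shuffled) == pytest.approx(
            base, abs=1e-9)

    @pytest.mark.parametrize("unbalance", [0.0, 0.25])
    def test_matches_dense_contrast_oracle(self, toy_data, paper_components,
                                           unbalance):
        data = (drop_cells(toy_data, unbalance, seed=3)
                if unbalance else toy_data)
        mine = reml_criterion(paper_components, data)
        assert mine == pytest.approx(contrast_oracle(paper_components, data),
                                     abs=1e-6)

    def test_balanced_and_dense_paths_agree(self, toy_data, paper_components):
        """The closed-form spectral path must equal the generic Cholesky path."""
        spectral = _BalancedStats.from_values(_to_array(toy_data))
        dense = _SubjectBlocks.from_frame(toy_data)
        for scale in (0.3, 1.0, 4.0):
            v = np.array(paper_components.variances()) * scale
            assert spectral.loglik(v) == pytest.approx(dense.loglik(v), abs=1e-8)

    def test_singular_residual_variance_is_explicit_error(self, toy_data):
        comps = VarianceComponents(grand_mean=50, sigma2_subj=10, sigma2_sess=1,
                                   sigma2_side=1, sigma2_sss=1, sigma2_reps=0)
        with pytest.raises(SingularCovarianceError):
            reml_criterion(comps, toy_data)


class TestFit:
    def test_noise_free_data_gives_zero_variances(self, study_design):
        comps = VarianceComponents(grand_mean=73.5, sigma2_subj=0, sigma2_sess=0,
                                   sigma2_side=0, sigma2_sss=0, sigma2_reps=0)
        df = simulate_dataset(study_design, comps, seed=0)
        fit = fit_reml(df)
        assert fit.components.grand_mean == 73.5
        assert all(v == 0.0 for v in fit.components.variances())
        assert all(fit.boundary_flags.values())

    def test_fit_is_deterministic(self, toy_data):
        a, b = fit_reml(toy_data), fit_reml(toy_data)
        assert a.components == b.components
        assert a.reml_loglik == b.reml_loglik

    def test_dataframe_and_array_paths_identical(self, toy_data):
        a = fit_reml(toy_data)
        b = fit_reml_values(_to_array(toy_data))
        assert a.components == b.components

    def test_shift_invariance(self, toy_data):
        shifted = toy_data.copy()
        shifted["ppt_n"] += 250.0
        a, b = fit_reml(toy_data), fit_reml(shifted)
        assert b.components.grand_mean == pytest.approx(
            a.components.grand_mean + 250.0, abs=1e-6)
        for v1, v2 in zip(a.components.variances(), b.components.variances()):
            assert v2 == pytest.approx(v1, abs=1e-4)

    def test_optimum_is_a_stationary_point(self, toy_data):
        """Numeric gradient of the criterion vanishes at interior estimates."""
        fit = fit_reml(toy_data)
        comps = fit.components
        for name, value in comps.items():
            if value == 0.0:
                continue
            h = 1e-4 * value
            up = reml_criterion(comps.replace(**{name: value + h}), toy_data)
            down = reml_criterion(comps.replace(**{name: value - h}), toy_data)
            slope = (up - down) / (2 * h)
            assert abs(slope * value) < 1e-3  # scale-free stationarity

    def test_maximized_criterion_dominates_perturbations(self, toy_data):
        fit = fit_reml(toy_data)
        for name, value in fit.components.items():
            bumped = fit.components.replace(**{name: value * 1.1 + 0.1})
            assert reml_criterion(bumped, toy_data) <= fit.reml_loglik + 1e-9

    def test_unbalanced_data_accepted(self, toy_data):
        ragged = drop_cells(toy_data, 0.3, seed=5)
        fit = fit_reml(ragged)
        assert fit.converged
        assert fit.n_obs == len(ragged)
        assert all(v >= 0 for v in fit.components.variances())

    def test_boundary_estimates_are_exact_zeros_with_flags(self):
        truth = VarianceComponents(grand_mean=40, sigma2_subj=100, sigma2_sess=0,
                                   sigma2_side=0, sigma2_sss=10, sigma2_reps=30)
        df = simulate_dataset(Design(12, 2, 2, 4), truth, seed=25)
        fit = fit_reml(df)
        for name, value in fit.components.items():
            assert fit.boundary_flags[name] == (value == 0.0)
        # truth has two null components; this draw pins both at the boundary
        assert fit.components.sigma2_sess == 0.0
        assert fit.components.sigma2_side == 0.0

    def test_single_subject_rejected(self, toy_data):
        one = toy_data[toy_data["subject"] == toy_data["subject"].iloc[0]]
        with pytest.raises(NotEstimableError, match="2 subjects"):
            fit_reml(one)

    def test_single_session_flagged_not_estimable(self, paper_components):
        df = simulate_dataset(Design(8, 1, 2, 4), paper_components, seed=2)
        fit = fit_reml(df)
        assert fit.not_estimable["sigma2_sess"]
        assert fit.not_estimable["sigma2_sss"]
        assert not fit.not_estimable["sigma2_subj"]
        assert fit.converged

    def test_serialization_carries_full_fit(self, toy_data):
        fit = fit_reml(toy_data)
        payload = fit.to_dict()
        for key in ("sigma2_subj", "sigma2_sess", "sigma2_side", "sigma2_sss",
                    "sigma2_reps", "grand_mean", "reml_loglik", "converged",
                    "boundary_flags"):
            assert key in payload
        assert payload["design_summary"]["n_subjects"] == 4


class TestOracleEquivalence:
    @pytest.mark.filterwarnings("ignore::UserWarning")
    @pytest.mark.filterwarnings(
        "ignore::statsmodels.tools.sm_exceptions.ConvergenceWarning")
    def test_estimates_match_statsmodels_mixedlm(self):
        """6-subject instance with a cleanly interior optimum: the
        general-purpose mixed-model fitter must land on the same components."""
        import statsmodels.formula.api as smf

        truth = VarianceComponents(grand_mean=50, sigma2_subj=200, sigma2_sess=30,
                                   sigma2_side=40, sigma2_sss=35, sigma2_reps=50)
        df = simulate_dataset(Design(6, 2, 2, 4), truth, seed=31)
        df = df.assign(cell=df["session"].astype(str) + "_" + df["side"].astype(str))
        md = smf.mixedlm("ppt_n ~ 1", df, groups=df["subject"], re_formula="1",
                         vc_formula={"sess": "0 + C(session)",
                                     "side": "0 + C(side)",
                                     "sss": "0 + C(cell)"})
        res = md.fit(reml=True, method=["nm", "bfgs"], maxiter=5000)
        names = list(md.exog_vc.names)
        oracle = {
            "sigma2_subj": float(res.cov_re.iloc[0, 0]),
            "sigma2_sess": float(res.vcomp[names.index("sess")]),
            "sigma2_side": float(res.vcomp[names.index("side")]),
            "sigma2_sss": float(res.vcomp[names.index("sss")]),
            "sigma2_reps": float(res.scale),
        }
        assert all(v > 1.0 for v in oracle.values())  # interior as intended
        fit = fit_reml(df)
        for name, v_oracle in oracle.items():
            assert getattr(fit.components, name) == pytest.approx(
                v_oracle, rel=1e-4)
        assert fit.components.grand_mean == pytest.approx(
            float(res.fe_params.iloc[0]), rel=1e-6)

        # the two criteria differ by the fixed contrast constant log(n)/2
        sm_equivalent = float(res.llf) + 0.5 * math.log(len(df))
        assert fit.reml_loglik >= sm_equivalent - 1e-6

    def test_maximized_criterion_beats_oracle_grid(self, toy_data):
        """fit_reml's optimum dominates an independent coarse maximisation of
        the dense contrast criterion."""
        from scipy.optimize import minimize

        fit = fit_reml(toy_data)
        s2 = toy_data["ppt_n"].var(ddof=1)

        def neg(x):
            comps = VarianceComponents(grand_mean=0.0,
                                       **dict(zip(("sigma2_subj", "sigma2_sess",
                                                   "sigma2_side", "sigma2_sss",
                                                   "sigma2_reps"), np.exp(x))))
            return -contrast_oracle(comps, toy_data)

        best = None
        for frac in ((0.6, 0.05, 0.05, 0.1, 0.2), (0.2,) * 5):
            res = minimize(neg, np.log(np.array(frac) * s2), method="Powell",
                           options={"maxiter": 4000, "xtol": 1e-10, "ftol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res
        assert fit.reml_loglik >= -best.fun - 1e-6
        np.testing.assert_allclose(
            np.array(fit.components.variances()),
            np.exp(best.x),
            rtol=2e-3, atol=1e-6 * s2)


class TestVariancePercentages:
    def test_paper_components_reproduce_published_shares(self, paper_components):
        pct = variance_percentages(paper_components)
        assert round(pct["sigma2_subj"], 1) == 70.1
        assert round(pct["sigma2_reps"], 1) == 14.4
        assert round(pct["sigma2_sss"], 1) == 10.9
        assert round(pct["sigma2_side"], 1) == 3.1
        assert round(pct["sigma2_sess"], 1) == 1.5
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_single_nonzero_component_takes_all(self):
        comps = VarianceComponents(grand_mean=0, sigma2_subj=0, sigma2_sess=0,
                                   sigma2_side=7.5, sigma2_sss=0, sigma2_reps=0)
        pct = variance_percentages(comps)
        assert pct["sigma2_side"] == 100.0
        assert sum(pct.values()) == 100.0

    def test_scale_invariance(self, paper_components):
        doubled = VarianceComponents(
            grand_mean=paper_components.grand_mean,
            **{k: 2 * v for k, v in paper_components.items()})
        assert variance_percentages(doubled) == pytest.approx(
            variance_percentages(paper_components))

    def test_all_zero_components_error(self):
        comps = VarianceComponents(grand_mean=1, sigma2_subj=0, sigma2_sess=0,
                                   sigma2_side=0, sigma2_sss=0, sigma2_reps=0)
        with pytest.raises(ValueError, match="total variance"):
            variance_percentages(comps)
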