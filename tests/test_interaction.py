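"""4x2 tables, RERI with MOVER limits, POR, and heterogeneity tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwical.cohort import CohortParams
from gwical.interaction import (
    FourByTwoTable,
    build_four_by_two,
    cohort_risk_reri,
    crude_interaction_estimate,
    fit_interaction_model,
    heterogeneity_across_strata,
    por_from_fit,
    reri_with_mover_ci,
)
from gwical.synthetic import generate_cohort

TERMS = ("gene", "exposure", "gene_x_exposure")


def minimal_frames(genotype, exposed, case):
    """Cohort + statuses frames with a single definition named 'x'."""
    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(len(genotype))],
            "genotype": genotype,
            "heard_alarms": np.asarray(exposed, dtype=bool),
        }
    )
    statuses = pd.DataFrame(
        {
            "subject_id": cohort["subject_id"],
            "x": np.asarray(case, dtype=bool),
            "is_control": ~np.asarray(case, dtype=bool),
        }
    )
    return cohort, statuses


def expand_table(table: FourByTwoTable):
    """Individual-level records realizing the table's cell counts."""
    rows = []
    for geno, cells in (
        ("QQ", ("a_qq", "b_qq", "c_qq", "d_qq")),
        ("RR", ("a_rr", "b_rr", "c_rr", "d_rr")),
    ):
        a, b, c, d = (int(getattr(table, k)) for k in cells)
        rows += [(geno, True, True)] * a + [(geno, False, True)] * b
        rows += [(geno, True, False)] * c + [(geno, False, False)] * d
    geno, exp, case = zip(*rows)
    return minimal_frames(list(geno), list(exp), list(case))


class TestBuildFourByTwo:
    def test_hand_tally_on_small_roster(self):
        genotype = ["QQ"] * 6 + ["RR"] * 4 + ["QR"] * 2
        exposed = [1, 1, 0, 1, 0, 0, 1, 0, 1, 0, 1, 1]
        case = [1, 1, 1, 0, 0, 0, 1, 1, 0, 0, 1, 0]
        cohort, statuses = minimal_frames(genotype, exposed, case)
        t = build_four_by_two(cohort, statuses, "x")
        assert (t.a_qq, t.b_qq, t.c_qq, t.d_qq) == (2, 1, 1, 2)
        assert (t.a_rr, t.b_rr, t.c_rr, t.d_rr) == (1, 1, 1, 1)  # QR excluded

    def test_excluded_definition_removed_from_cases(self, cohort, statuses):
        t = build_four_by_two(cohort, statuses, "cdc", exclude_definition="research")
        both = (statuses["cdc"] & statuses["research"]).sum()
        only = (statuses["cdc"] & ~statuses["research"]).sum()
        assert t.a_qq + t.b_qq + t.a_rr + t.b_rr <= only
        assert both > 0  # the exclusion actually removed someone

    def test_empty_case_set_raises(self):
        cohort, statuses = minimal_frames(["QQ", "RR"], [0, 1], [0, 0])
        with pytest.raises(ValueError, match="no cases"):
            build_four_by_two(cohort, statuses, "x")


class TestCrudeEstimate:
    def test_reri_identity_and_por_cross_ratio(self):
        t = FourByTwoTable(20, 30, 40, 60, 25, 10, 15, 30)
        est = crude_interaction_estimate(t)
        assert est.reri == pytest.approx(
            est.or_11 - est.or_10 - est.or_01 + 1, abs=1e-12
        )
        or_rr = (t.a_rr * t.d_rr) / (t.b_rr * t.c_rr)
        or_qq = (t.a_qq * t.d_qq) / (t.b_qq * t.c_qq)
        assert est.por == pytest.approx(or_rr / or_qq, rel=1e-12)
        assert est.reri_ci[0] <= est.reri <= est.reri_ci[1]

    def test_zero_cell_requires_explicit_continuity(self):
        t = FourByTwoTable(0, 30, 40, 60, 25, 10, 15, 30)
        with pytest.raises(ValueError, match="continuity"):
            crude_interaction_estimate(t)
        est = crude_interaction_estimate(t, continuity=0.5)
        assert math.isfinite(est.reri)

    def test_crude_model_equivalence_with_logistic_fit(self):
        t = FourByTwoTable(18, 25, 33, 47, 21, 12, 14, 28)
        cohort, statuses = expand_table(t)
        fit = fit_interaction_model(cohort, statuses, "x")
        est_fit = reri_with_mover_ci(fit.params, fit.cov)
        est_tab = crude_interaction_estimate(t)
        for attr in ("or_10", "or_01", "or_11", "reri", "por"):
            assert getattr(est_fit, attr) == pytest.approx(
                getattr(est_tab, attr), rel=1e-6
            )


class TestMoverReri:
    def _series(self, b):
        return pd.Series(b, index=TERMS)

    def _cov(self, v):
        return pd.DataFrame(v, index=TERMS, columns=TERMS)

    def test_all_unit_ors_give_zero_reri(self):
        est = reri_with_mover_ci(
            self._series([0.0, 0.0, 0.0]), self._cov(0.04 * np.eye(3))
        )
        assert est.reri == pytest.approx(0.0, abs=1e-14)
        assert est.reri_ci[0] < 0 < est.reri_ci[1]

    def test_additive_null_identity_is_exact(self):
        b1, b2 = math.log(2.0), math.log(3.0)
        b3 = math.log((2.0 + 3.0 - 1.0)) - b1 - b2  # OR11 = OR10 + OR01 - 1
        est = reri_with_mover_ci(
            self._series([b1, b2, b3]), self._cov(0.01 * np.eye(3))
        )
        assert est.reri == pytest.approx(0.0, abs=1e-12)

    def test_relabeling_gene_and_exposure_leaves_reri_unchanged(self):
        b = np.array([0.4, 0.9, 0.3])
        v = np.array([[0.04, 0.01, -0.02], [0.01, 0.05, -0.01], [-0.02, -0.01, 0.06]])
        perm = [1, 0, 2]
        est1 = reri_with_mover_ci(self._series(b), self._cov(v))
        est2 = reri_with_mover_ci(self._series(b[perm]), self._cov(v[perm][:, perm]))
        assert est1.reri == pytest.approx(est2.reri, rel=1e-12)
        assert est1.reri_ci == pytest.approx(est2.reri_ci, rel=1e-10)

    def test_independent_or_special_case_matches_hand_formula(self):
        # zero off-diagonal covariance: MOVER limits from individual CIs only
        b = np.array([0.2, 0.5, 0.4])
        se = np.array([0.15, 0.2, 0.25])
        z = stats.norm.ppf(0.975)
        w = np.array([[1, 1, 1], [1, 0, 0], [0, 1, 0]], dtype=float)
        log_est = w @ b
        log_var = (w**2) @ se**2  # independent components
        theta = np.exp(log_est)
        lo = np.exp(log_est - z * np.sqrt(log_var))
        hi = np.exp(log_est + z * np.sqrt(log_var))
        reri = theta[0] - theta[1] - theta[2] + 1
        # hand recombination with correlations of the three linear combos
        cov = np.diag(se**2)
        lc = w @ cov @ w.T
        r = lc / np.sqrt(np.outer(np.diag(lc), np.diag(lc)))
        low = reri - math.sqrt(
            (theta[0] - lo[0]) ** 2
            + (hi[1] - theta[1]) ** 2
            + (hi[2] - theta[2]) ** 2
            - 2 * r[0, 1] * (theta[0] - lo[0]) * (hi[1] - theta[1])
            - 2 * r[0, 2] * (theta[0] - lo[0]) * (hi[2] - theta[2])
            + 2 * r[1, 2] * (hi[1] - theta[1]) * (hi[2] - theta[2])
        )
        est = reri_with_mover_ci(self._series(b), self._cov(cov))
        assert est.reri == pytest.approx(reri, rel=1e-12)
        assert est.reri_ci[0] == pytest.approx(low, rel=1e-10)

    def test_mover_approaches_delta_method_near_null(self):
        b = np.array([0.01, 0.02, 0.005])
        z = stats.norm.ppf(0.975)

        def rel_gap(scale):
            cov = scale * np.eye(3)
            est = reri_with_mover_ci(self._series(b), self._cov(cov))
            e = np.exp
            grad = np.array(
                [e(b.sum()) - e(b[0]), e(b.sum()) - e(b[1]), e(b.sum())]
            )
            se = math.sqrt(grad @ cov @ grad)
            delta = (est.reri - z * se, est.reri + z * se)
            half = z * se
            return max(
                abs(est.reri_ci[0] - delta[0]), abs(est.reri_ci[1] - delta[1])
            ) / half

        # asymmetry vanishes as the ORs (and their uncertainty) approach 1
        assert rel_gap(1e-4) < 0.05
        assert rel_gap(1e-6) < 0.005
        assert rel_gap(1e-6) < rel_gap(1e-4)

    def test_non_positive_definite_covariance_raises(self):
        v = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            reri_with_mover_ci(self._series([0.1, 0.1, 0.1]), self._cov(v))


class TestPor:
    def test_zero_interaction_coefficient(self):
        por, ci = por_from_fit(np.array([0.3, 0.2, 0.0]), 0.01 * np.eye(3))
        assert por == 1.0
        assert ci[0] < 1 < ci[1]

    def test_zero_se_degenerate_ci(self):
        v = np.zeros((3, 3))
        por, ci = por_from_fit(np.array([0.0, 0.0, math.log(2)]), v)
        assert por == pytest.approx(2.0)
        assert ci == (por, por)


class TestLogisticPath:
    def test_planted_null_interaction_coefficient_near_zero(self):
        rng = np.random.default_rng(12)
        n = 6000
        genotype = rng.choice(["QQ", "RR"], n)
        exposed = rng.random(n) < 0.4
        case = rng.random(n) < 0.3  # same rate in every cell
        cohort, statuses = minimal_frames(genotype, exposed, case)
        fit = fit_interaction_model(cohort, statuses, "x")
        b3 = fit.params["gene_x_exposure"]
        se3 = math.sqrt(fit.cov.loc["gene_x_exposure", "gene_x_exposure"])
        assert abs(b3) < 4 * se3
        assert fit.converged

    def test_zero_margin_raises_named_separation_error(self):
        genotype = ["QQ"] * 40 + ["RR"] * 40
        exposed = ([1, 0] * 20) + [0] * 40  # no exposed RR subjects
        case = ([1, 1, 0, 0] * 10) + ([1, 0] * 20)
        cohort, statuses = minimal_frames(genotype, exposed, case)
        with pytest.raises(ValueError, match="a_rr"):
            fit_interaction_model(cohort, statuses, "x")

    def test_covariate_adjustment_runs_and_flags(self, cohort, statuses):
        from gwical.synthetic import draw_case_control_subsample

        sub = draw_case_control_subsample(cohort, statuses, 508, seed=4)
        from gwical.definitions import score_cohort

        sst = score_cohort(sub)
        fit = fit_interaction_model(
            sub, sst, "cdc", covariates=("age", "sex", "combat_scale")
        )
        est = reri_with_mover_ci(
            fit.params, fit.cov, adjusted=True,
            covariate_list=("age", "sex", "combat_scale"),
        )
        assert est.adjusted and est.covariate_list == ("age", "sex", "combat_scale")
        assert est.reri_ci[0] <= est.reri <= est.reri_ci[1]


class TestRiskScaleReri:
    def test_recovers_generative_target_on_one_large_cohort(self):
        params = CohortParams(n_deployed=40_000, seed=21)
        cohort = generate_cohort(params)
        est = cohort_risk_reri(cohort)
        assert est.scale == "risk-ratio"
        assert est.reri == pytest.approx(params.target_reri, rel=0.25)
        assert est.reri_ci[0] <= est.reri <= est.reri_ci[1]


class TestHeterogeneity:
    def test_single_stratum_raises(self, cohort, statuses):
        c = cohort.copy()
        c["grp"] = 0
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            heterogeneity_across_strata(c, statuses, "cdc", "grp")

    def test_strong_heterogeneity_detected_and_null_is_not(self):
        def cohort_with(target_reri, seed):
            p = CohortParams(
                n_deployed=12_000, baseline_risk=0.01, target_reri=target_reri,
                seed=seed,
            )
            c = generate_cohort(p)
            s = pd.DataFrame(
                {
                    "subject_id": c["subject_id"],
                    "x": c["true_case"],
                    "is_control": ~c["true_case"],
                }
            )
            return c, s

        c0, s0 = cohort_with(0.0, 31)
        c8, s8 = cohort_with(8.0, 32)
        c0["grp"], c8["grp"] = "a", "b"
        cohort = pd.concat([c0, c8], ignore_index=True)
        statuses = pd.concat([s0, s8], ignore_index=True)
        res = heterogeneity_across_strata(cohort, statuses, "x", "grp")
        assert set(res["estimates"]) == {"a", "b"}
        assert res["estimates"]["b"].reri > res["estimates"]["a"].reri
        assert res["p_value"] < 0.05

        # same generative parameters in both strata: no evidence expected
        c1, s1 = cohort_with(4.0, 33)
        c2, s2 = cohort_with(4.0, 34)
        c1["grp"], c2["grp"] = "a", "b"
        res_null = heterogeneity_across_strata(
            pd.concat([c1, c2], ignore_index=True),
            pd.concat([s1, s2], ignore_index=True),
            "x",
            "grp",
        )
        assert res_null["p_value"] > 0.05
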