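"""FOCE engine tests: simulation, EBEs, conditional moments, CWRES, OFV, fitting.

Oracles: the linear mixed model y_ij = theta + eta_i + eps_ij, for which the
FOCE linearization is exact and the balanced compound-symmetry ML solution
has a closed form, plus brute-force grid searches on 1-d toys.
"""

import numpy as np
import pytest

from cwresqa.engine import (
    compute_cwres,
    conditional_moments,
    estimate_ebes,
    fit_population,
    foce_ofv,
    simulate_dataset,
)
from cwresqa.models import Dataset, Design, ErrorModel, NLMEModel, SubjectData
from cwresqa.scenarios import make_ivgtt_protocol, one_compartment_model

from conftest import flat_design, make_linear_model


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

class TestSimulate:
    def test_seeded_reproducibility(self, linear_model, design5):
        a = simulate_dataset(linear_model, design5, 5, seed=7)
        b = simulate_dataset(linear_model, design5, 5, seed=7)
        c = simulate_dataset(linear_model, design5, 5, seed=8)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.y, sb.y)
        assert not np.allclose(a.subjects[0].y, c.subjects[0].y)

    def test_degenerate_noise_returns_structural_prediction(self, design5):
        model = make_linear_model(theta=2.0, omega_var=0.0, sigma_var=0.0)
        ds = simulate_dataset(model, design5, 3, seed=1)
        for s in ds:
            np.testing.assert_allclose(s.y, np.full(5, 2.0))

    def test_iiv_variance_recovery(self):
        # Monte-Carlo check of the sampling distribution of the etas
        model = one_compartment_model()
        proto = make_ivgtt_protocol().to_design()
        _, etas = simulate_dataset(model, proto, 400, seed=11, return_etas=True)
        emp = etas.var(axis=0, ddof=1)
        np.testing.assert_allclose(emp, np.diag(model.omega), rtol=0.2)

    def test_rejects_non_psd_omega(self, design5):
        with pytest.raises(ValueError, match="positive semi-definite"):
            NLMEModel(
                name="bad",
                pred=lambda th, e, d: np.zeros(d.n_obs),
                theta=np.array([1.0]),
                omega=np.array([[-1.0]]),
                errors=(ErrorModel(add_var=1.0),),
            )


# ---------------------------------------------------------------------------
# empirical Bayes estimates
# ---------------------------------------------------------------------------

class TestEBE:
    def test_closed_form_posterior_mode_single_observation(self):
        # y = theta + eta + eps, 1 obs: eta_hat = w2/(w2+s2) * (y - theta)
        w2, s2, y, theta = 0.3, 0.1, 1.7, 1.0
        model = make_linear_model(theta=theta, omega_var=w2, sigma_var=s2)
        subj = SubjectData(id=1, design=flat_design(1), y=np.array([y]))
        eta = estimate_ebes(model, subj)
        expected = w2 / (w2 + s2) * (y - theta)
        np.testing.assert_allclose(eta[0], expected, atol=1e-6)

    def test_prior_dominates_for_tiny_omega(self):
        model = make_linear_model(omega_var=1e-8, sigma_var=0.1)
        subj = SubjectData(id=1, design=flat_design(4), y=np.full(4, 3.0))
        eta = estimate_ebes(model, subj)
        assert abs(eta[0]) < 1e-4

    def test_perfect_fit_gives_zero_eta(self):
        model = make_linear_model(theta=2.5)
        subj = SubjectData(id=1, design=flat_design(6), y=np.full(6, 2.5))
        eta = estimate_ebes(model, subj)
        np.testing.assert_allclose(eta, 0.0, atol=1e-8)

    def test_matches_grid_search_on_1d_toy(self):
        # brute-force minimization of the individual objective is the oracle
        model = one_compartment_model(omega=(0.1, 1e-16, 1e-16))
        proto = make_ivgtt_protocol().to_design()
        ds = simulate_dataset(model, proto, 1, seed=3)
        subj = ds.subjects[0]
        eta = estimate_ebes(model, subj)

        def obj(e1):
            f = model.pred(model.theta, np.array([e1, 0.0, 0.0]), subj.design)
            v = model.residual_variance(f, subj.design.dvid)
            return (
                np.sum(np.log(v) + (subj.y - f) ** 2 / v) + e1**2 / 0.1
            )

        grid = np.linspace(-1.5, 1.5, 20001)
        best = grid[np.argmin([obj(g) for g in grid])]
        assert abs(eta[0] - best) < 1e-3


# ---------------------------------------------------------------------------
# conditional moments
# ---------------------------------------------------------------------------

class TestConditionalMoments:
    def test_linear_additive_hand_algebra(self):
        # E = theta * 1, COV = w2 * J + s2 * I
        w2, s2, n = 0.2, 0.05, 4
        model = make_linear_model(theta=1.5, omega_var=w2, sigma_var=s2)
        subj = SubjectData(id=1, design=flat_design(n), y=np.full(n, 2.0))
        eta = estimate_ebes(model, subj)
        cond = conditional_moments(model, subj, eta)
        np.testing.assert_allclose(cond.expectation, np.full(n, 1.5), atol=1e-8)
        expected_cov = w2 * np.ones((n, n)) + s2 * np.eye(n)
        np.testing.assert_allclose(cond.covariance, expected_cov, atol=1e-6)

    def test_proportional_error_diagonal(self):
        model = one_compartment_model(prop_var=0.02)
        proto = make_ivgtt_protocol().to_design()
        ds = simulate_dataset(model, proto, 1, seed=5)
        subj = ds.subjects[0]
        cond = conditional_moments(model, subj, np.zeros(3))
        f_pop = model.pred(model.theta, np.zeros(3), subj.design)
        np.testing.assert_allclose(cond.var_res, 0.02 * f_pop**2, rtol=1e-10)

    def test_zero_eta_gives_population_prediction(self):
        model = one_compartment_model()
        proto = make_ivgtt_protocol().to_design()
        ds = simulate_dataset(model, proto, 1, seed=5)
        subj = ds.subjects[0]
        cond = conditional_moments(model, subj, np.zeros(3))
        f_pop = model.pred(model.theta, np.zeros(3), subj.design)
        np.testing.assert_allclose(cond.expectation, f_pop, rtol=1e-8)


# ---------------------------------------------------------------------------
# CWRES
# ---------------------------------------------------------------------------

class TestCWRES:
    def test_diagonal_whitening_toy(self):
        # COV = diag(4, 1), residual (2, -1) -> CWRES (1, -1)
        design = Design(times=np.array([0.0, 1.0]), dvid=np.array([0, 1]))
        model = NLMEModel(
            name="toy",
            pred=lambda th, e, d: np.broadcast_to(
                th[0], np.asarray(e).shape[:-1] + (d.n_obs,)
            ).copy(),
            theta=np.array([5.0]),
            omega=np.array([[0.0]]),
            errors=(ErrorModel(add_var=4.0), ErrorModel(add_var=1.0)),
            dv_labels=("a", "b"),
            theta_positive=(False,),
        )
        subj = SubjectData(id=1, design=design, y=np.array([7.0, 4.0]))
        res = compute_cwres(model, Dataset(subjects=(subj,)))
        np.testing.assert_allclose(
            res.table["CWRES"].to_numpy(), [1.0, -1.0], atol=1e-10
        )

    def test_whitening_gives_identity_covariance(self):
        # empirical covariance of within-subject CWRES across many subjects ~ I
        model = make_linear_model(theta=1.0, omega_var=0.2, sigma_var=0.1)
        ds = simulate_dataset(model, flat_design(3), 2000, seed=9)
        res = compute_cwres(model, ds)
        r = res.table["CWRES"].to_numpy().reshape(2000, 3)
        emp = np.cov(r, rowvar=False)
        np.testing.assert_allclose(emp, np.eye(3), atol=0.1)

    def test_table_layout(self):
        model = one_compartment_model()
        proto = make_ivgtt_protocol().to_design()
        ds = simulate_dataset(model, proto, 3, seed=2)
        table = compute_cwres(model, ds).table
        assert list(table.columns) == ["ID", "ROW", "DVID", "TIME", "PRED_glucose", "CWRES"]
        assert len(table) == 3 * 32
        assert table["CWRES"].notna().all()
        # PRED is the population prediction, identical across subjects
        per_subject = table.groupby("ID")["PRED_glucose"].apply(tuple).unique()
        assert len(per_subject) == 1


# ---------------------------------------------------------------------------
# FOCE OFV and population fitting
# ---------------------------------------------------------------------------

def exact_cs_neg2ll(dataset, theta, w2, s2):
    """Independent oracle: direct marginal -2LL of the compound-symmetry
    model via explicit per-subject covariance matrices (2*pi term dropped)."""
    total = 0.0
    for s in dataset:
        n = s.n_obs
        V = w2 * np.ones((n, n)) + s2 * np.eye(n)
        r = s.y - theta
        sign, logdet = np.linalg.slogdet(V)
        total += logdet + r @ np.linalg.solve(V, r)
    return total


def closed_form_cs_ml(dataset):
    """Balanced one-way random-effects ML estimates in closed form."""
    Y = np.stack([s.y for s in dataset])
    N, k = Y.shape
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    ssw = np.sum((Y - subj_means[:, None]) ** 2)
    ssb_k = k * np.sum((subj_means - grand) ** 2)
    s2 = ssw / (N * (k - 1))
    w2 = max((ssb_k / N - s2) / k, 0.0)
    return grand, w2, s2


class TestFOCEOFV:
    def test_equals_exact_lmm_likelihood(self, linear_model):
        ds = simulate_dataset(linear_model, flat_design(6), 25, seed=4)
        ofv = foce_ofv(linear_model, ds)
        oracle = exact_cs_neg2ll(ds, 1.0, 0.1, 0.05)
        np.testing.assert_allclose(ofv, oracle, atol=1e-6)

    def test_additivity_when_doubling_dataset(self, linear_model):
        ds = simulate_dataset(linear_model, flat_design(4), 10, seed=6)
        doubled = Dataset(
            subjects=ds.subjects
            + tuple(
                SubjectData(id=100 + i, design=s.design, y=s.y)
                for i, s in enumerate(ds)
            )
        )
        np.testing.assert_allclose(
            foce_ofv(linear_model, doubled), 2 * foce_ofv(linear_model, ds), rtol=1e-10
        )

    def test_increases_away_from_optimum(self, linear_model):
        ds = simulate_dataset(linear_model, flat_design(5), 30, seed=8)
        fit = fit_population(linear_model, ds, fatol=1e-8, xatol=1e-6)
        for bump in (+0.3, -0.3):
            worse = fit.model.replace(theta=fit.model.theta + bump)
            assert foce_ofv(worse, ds) > fit.ofv


class TestFitPopulation:
    def test_matches_closed_form_cs_solution(self, linear_model):
        ds = simulate_dataset(linear_model, flat_design(6), 40, seed=12)
        fit = fit_population(linear_model, ds, fatol=1e-9, xatol=1e-6, maxiter=4000)
        theta, w2, s2 = closed_form_cs_ml(ds)
        oracle_ofv = exact_cs_neg2ll(ds, theta, w2, s2)
        assert fit.ofv == pytest.approx(oracle_ofv, abs=1e-4)
        assert fit.model.theta[0] == pytest.approx(theta, abs=1e-3)
        assert fit.model.omega[0, 0] == pytest.approx(w2, rel=1e-2)
        assert fit.model.errors[0].add_var == pytest.approx(s2, rel=1e-2)

    def test_parameter_recovery(self):
        model = make_linear_model(theta=1.0, omega_var=0.1, sigma_var=0.05)
        ds = simulate_dataset(model, flat_design(10), 100, seed=13)
        fit = fit_population(model, ds)
        assert fit.model.theta[0] == pytest.approx(1.0, rel=0.15)
        assert fit.model.omega[0, 0] == pytest.approx(0.1, rel=0.15)
        assert fit.model.errors[0].add_var == pytest.approx(0.05, rel=0.15)

    def test_inits_at_truth_descent(self, linear_model):
        ds = simulate_dataset(linear_model, flat_design(5), 20, seed=14)
        fit = fit_population(linear_model, ds)
        assert fit.ofv <= fit.inits_ofv + 1e-9
        assert fit.converged

    def test_interaction_flag_changes_proportional_cwres(self):
        model = one_compartment_model()
        proto = make_ivgtt_protocol().to_design()
        ds = simulate_dataset(model, proto, 5, seed=15)
        r_i = compute_cwres(model, ds, interaction=True).table["CWRES"]
        r_no = compute_cwres(model, ds, interaction=False).table["CWRES"]
        assert np.all(np.isfinite(r_i)) and np.all(np.isfinite(r_no))
        assert not np.allclose(r_i, r_no)
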