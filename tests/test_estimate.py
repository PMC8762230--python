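"""Estimation machinery: likelihood oracles, covariate tools, EBEs."""

import math

import numpy as np
import pandas as pd
import pytest

import voripk.estimate as est
from voripk import (CohortDesign, EventDataset, ModelSpec, OmegaSpec,
                    SigmaSpec, bateman_oracle, collinearity_screen,
                    covariate_transform, empirical_bayes, evaluate_ofv,
                    generate_cohort, information_criteria, ofv_foce,
                    phenotype_on_vmax)

FIT_OPTS = dict(surrogate_maxiter=12, max_sweeps=4)


class TestInformationCriteria:
    def test_printed_fit_statistics_are_consistent(self):
        # the base-model report: OFV 1320.48 with p=11 and n=427 observations
        aic, bic = information_criteria(1320.48, 11, 427)
        assert aic == pytest.approx(1342.48, abs=0.01)
        assert bic == pytest.approx(1387.11, abs=0.02)

    def test_zero_parameters_is_identity(self):
        assert information_criteria(10.0, 0, 5) == (10.0, 10.0)

    def test_domain(self):
        with pytest.raises(ValueError):
            information_criteria(1.0, -1, 10)


class TestCovariateTransform:
    def test_identities(self):
        assert covariate_transform(5.0, 70.0, 64.0, "power", 0.0) == 5.0
        assert covariate_transform(5.0, 64.0, 64.0, "power", 0.75) == 5.0
        assert covariate_transform(5.0, None, None, "categorical", 0.0) == 5.0

    @pytest.mark.parametrize("theta,reduction", [(-0.31, 26.7), (-0.61, 45.7)])
    def test_categorical_reductions(self, theta, reduction):
        adjusted = covariate_transform(1.0, None, None, "categorical", theta)
        assert (1 - adjusted) * 100 == pytest.approx(reduction, abs=0.05)

    def test_power_form_needs_positive_covariate(self):
        with pytest.raises(ValueError):
            covariate_transform(5.0, -1.0, 64.0, "power", 0.75)


def _additive_linear_dataset(sigma_add=0.3, n_subj=3, seed=0):
    """One-compartment linear kinetics with additive error, no IIV."""
    rng = np.random.default_rng(seed)
    F, ka, V1, CL = 0.895, 1.1, 207.29, 7.0
    rows, preds = [], []
    for sid in range(1, n_subj + 1):
        rows.append(dict(ID=sid, TIME=0.0, EVID=1, AMT=200.0, DV=np.nan,
                         DVID=np.nan, PHENOTYPE="NM"))
        for t in (2.0, 6.0, 11.0):
            pred = bateman_oracle(200.0, t, F, ka, CL, V1)
            dv = pred + rng.normal(0, sigma_add)
            preds.append((dv, pred))
            rows.append(dict(ID=sid, TIME=t, EVID=0, AMT=np.nan, DV=dv,
                             DVID=1, PHENOTYPE="NM"))
    return EventDataset(pd.DataFrame(rows)), preds


class TestOfvOracles:
    def test_zero_iiv_additive_error_equals_gaussian_loglik(self, fixed):
        """No random effects: the OFV is the plain Gaussian -2 log likelihood
        with predictions from the structural model's linear limit."""
        sigma_add = 0.3
        data, preds = _additive_linear_dataset(sigma_add)
        spec = ModelSpec(
            fixed_init=fixed.with_updates(CL1=7.0, Vmax=1e-12,
                                          theta_IM=0.0, theta_PM=0.0),
            omega_init=OmegaSpec(0, 0, 0, 0),
            sigma_init={"VCZ": SigmaSpec("additive", additive=sigma_add),
                        "VNO": SigmaSpec("additive", additive=sigma_add)})
        ofv = evaluate_ofv(data, spec, rtol=1e-10, atol=1e-12)
        expected = sum(math.log(2 * math.pi * sigma_add ** 2)
                       + (dv - pred) ** 2 / sigma_add ** 2
                       for dv, pred in preds)
        assert ofv == pytest.approx(expected, abs=1e-4)

    def test_linear_in_eta_model_matches_exact_marginal(self, monkeypatch,
                                                        fixed):
        """For predictions exactly linear in eta with additive error, the
        conditional-mode (Laplace) OFV equals the closed-form multivariate
        normal -2 log likelihood."""
        rng = np.random.default_rng(4)
        G = rng.normal(size=(6, 4))
        a = np.abs(rng.normal(5.0, 1.0, size=6))
        sigma_add = 0.25
        omega = OmegaSpec(30.0, 20.0, 10.0, 40.0, convention="sd_times_100")
        sds = omega.sds()
        y = a + G @ (rng.normal(size=4) * sds) + rng.normal(0, sigma_add, 6)

        def linear_predict(sub, fx, typ, eta, eta_params, rtol, atol,
                           max_steps=None):
            return a + G @ np.asarray(eta)

        monkeypatch.setattr(est, "_predict", linear_predict)
        rows = [dict(ID=1, TIME=0.0, EVID=1, AMT=200.0, DV=np.nan,
                     DVID=np.nan, PHENOTYPE="NM")]
        rows += [dict(ID=1, TIME=float(j + 1), EVID=0, AMT=np.nan, DV=yv,
                      DVID=1, PHENOTYPE="NM") for j, yv in enumerate(y)]
        data = EventDataset(pd.DataFrame(rows))
        spec = ModelSpec(
            fixed_init=fixed.with_updates(theta_IM=0.0, theta_PM=0.0),
            omega_init=omega,
            sigma_init={"VCZ": SigmaSpec("additive", additive=sigma_add),
                        "VNO": SigmaSpec("additive", additive=sigma_add)})
        ofv = evaluate_ofv(data, spec)

        V = G @ np.diag(sds ** 2) @ G.T + sigma_add ** 2 * np.eye(6)
        r = y - a
        expected = (6 * math.log(2 * math.pi) + np.linalg.slogdet(V)[1]
                    + float(r @ np.linalg.solve(V, r)))
        assert ofv == pytest.approx(expected, abs=1e-4)

    def test_ofv_invariant_to_subject_order(self, fixed, omega, sigma,
                                            final_spec):
        data, _ = generate_cohort(
            CohortDesign(n_subjects=6,
                         phenotype_counts={"NM": 2, "IM": 2, "PM": 2,
                                           "unknown": 0}),
            fixed, omega, sigma, seed=21)
        ids = data.subject_ids
        reordered = pd.concat([data.df[data.df.ID == sid]
                               for sid in reversed(ids)], ignore_index=True)
        ofv1 = evaluate_ofv(data, final_spec)
        ofv2 = evaluate_ofv(EventDataset(reordered), final_spec)
        assert ofv1 == pytest.approx(ofv2, abs=1e-6)

    def test_fit_not_worse_than_generating_parameters(self, rich_cohort,
                                                      final_spec):
        """Optimality sanity: the optimized OFV beats the OFV at the
        generating (true) parameter values."""
        data, _ = rich_cohort
        ofv_truth = evaluate_ofv(data, final_spec,
                                 init=_truth_init(final_spec))
        fit = ofv_foce(data, final_spec, **FIT_OPTS)
        assert fit.ofv <= ofv_truth + 0.1
        assert fit.n_params == 13


def _truth_init(spec):
    from voripk import reference_fixed_effects, reference_omega, reference_sigma
    packer = est._Packer(spec)
    return packer.pack(reference_fixed_effects(), [-0.31, -0.61],
                       reference_omega().sds(), reference_sigma())


class TestCollinearityScreen:
    def test_identical_columns_are_mutually_exclusive(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        table = pd.DataFrame({"WT": x, "WT2": x, "AGE": rng.normal(size=200)})
        res = collinearity_screen(table)
        assert ("WT", "WT2", 1.0) in [(a, b, round(r, 6))
                                      for a, b, r in res["excluded_pairs"]]

    def test_independent_columns_pass(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["a", "b"])
        res = collinearity_screen(table)
        assert res["excluded_pairs"] == []
        assert abs(res["correlation"].loc["a", "b"]) < 0.05

    def test_weight_and_bsa_from_generator_are_collinear(self, study_cohort):
        ds, _ = study_cohort
        per_subject = ds.df.groupby("ID")[["WT", "HT", "BSA", "AGE"]].first()
        res = collinearity_screen(per_subject)
        assert any({a, b} == {"WT", "BSA"} for a, b, _ in res["excluded_pairs"])

    def test_constant_column_flagged(self):
        table = pd.DataFrame({"a": [1.0] * 10, "b": np.arange(10.0)})
        res = collinearity_screen(table)
        assert res["constant"] == ["a"]


class TestStepwiseLogic:
    """Threshold logic checked against a stub likelihood (no ODE fitting)."""

    def _run(self, monkeypatch, dofv):
        calls = {}

        class StubFit:
            def __init__(self, ofv):
                self.ofv = ofv

        def stub_ofv(data, spec, **kwargs):
            has = len(spec.covariate_effects)
            return StubFit(100.0 - dofv * has)

        monkeypatch.setattr(est, "ofv_foce", stub_ofv)
        cand = est.CovariateEffect(parameter="CL1", covariate="WT",
                                   form="power")
        final, fit, trace = est.stepwise_covariates(None, _stub_spec(), [cand])
        return final, trace

    def test_forward_threshold_boundary(self, monkeypatch):
        _, trace = self._run(monkeypatch, 3.85)
        assert any(s["status"] == "added" for s in trace)
        _, trace = self._run(monkeypatch, 3.83)
        assert not any(s["status"] == "added" for s in trace)

    def test_backward_elimination_threshold(self, monkeypatch):
        # accepted forward at dOFV 5 but eliminated backward (needs >= 6.63)
        final, trace = self._run(monkeypatch, 5.0)
        assert any(s["status"] == "added" for s in trace)
        assert len(final.covariate_effects) == 0
        final, _ = self._run(monkeypatch, 7.0)
        assert len(final.covariate_effects) == 1


def _stub_spec():
    from voripk import reference_fixed_effects, reference_omega, reference_sigma
    return ModelSpec(fixed_init=reference_fixed_effects(),
                     omega_init=reference_omega(),
                     sigma_init=reference_sigma())


class TestEmpiricalBayes:
    def test_subject_without_observations_sits_at_prior_mode(self, fixed,
                                                             omega, sigma):
        rows = [dict(ID=1, TIME=0.0, EVID=1, AMT=200.0, DV=np.nan,
                     DVID=np.nan, PHENOTYPE="NM"),
                dict(ID=2, TIME=0.0, EVID=1, AMT=200.0, DV=np.nan,
                     DVID=np.nan, PHENOTYPE="NM"),
                dict(ID=2, TIME=23.5, EVID=0, AMT=np.nan, DV=2.0, DVID=1,
                     PHENOTYPE="NM")]
        data = EventDataset(pd.DataFrame(rows))
        spec = _stub_spec()
        fit = _evaluation_fit(
            EventDataset(data.df[data.df.ID == 2].reset_index(drop=True)), spec)
        ebe = empirical_bayes(data, spec, fit)
        assert np.all(ebe.loc[1, [f"eta_{p}" for p in spec.eta_params]] == 0.0)
        assert np.any(ebe.loc[2, [f"eta_{p}" for p in spec.eta_params]] != 0.0)

    def test_vanishing_iiv_pins_all_etas_to_zero(self, fixed, sigma,
                                                 study_cohort):
        ds, _ = study_cohort
        small = EventDataset(ds.df[ds.df.ID <= 5].copy())
        spec = ModelSpec(fixed_init=fixed, omega_init=OmegaSpec(0, 0, 0, 0),
                         sigma_init=sigma)
        fit = _evaluation_fit(small, spec)
        ebe = empirical_bayes(small, spec, fit)
        eta_cols = [f"eta_{p}" for p in spec.eta_params]
        assert np.all(ebe[eta_cols].to_numpy() == 0.0)


def _evaluation_fit(data, spec):
    return ofv_foce(data, spec, max_sweeps=0)


def test_monte_carlo_integration_confirms_laplace_approximation(fixed, sigma):
    """Brute-force Monte Carlo marginal likelihood agrees with the
    conditional-mode approximation on a small nonlinear problem."""
    from voripk import generate_rich_cohort, reference_sigma
    from voripk.estimate import mc_marginal_ofv
    om = OmegaSpec(25.0, 6.0, 20.0, 21.0)
    ds, _ = generate_rich_cohort(20, fixed, om, sigma, seed=77)
    small = EventDataset(ds.df[ds.df.ID <= 3].reset_index(drop=True))
    spec = ModelSpec(fixed_init=fixed, omega_init=om, sigma_init=sigma)
    ofv_laplace = evaluate_ofv(small, spec)
    ofv_mc = mc_marginal_ofv(small, spec, n_samples=4000, seed=1)
    assert ofv_mc == pytest.approx(ofv_laplace, rel=0.02)
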