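"""NLME layer: likelihood pieces, FOCE limits, ranking, VPC, half-lives."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm

from niacffa import (
    ObservationTable,
    default_parameters,
    foce_nll,
    individual_nll,
    sensitivity_ranking,
    turnover_half_lives,
    vpc,
)
from niacffa.parameters import replace_fields
from niacffa.population import (
    _StageProblem,
    _build_subjects,
    _freeze_context,
    default_population_model,
)

LOG2PI = math.log(2 * math.pi)


def _table(rows):
    return ObservationTable(pd.DataFrame(
        rows, columns=["id", "group", "species", "observable", "time_h", "value", "protocol"]))


def _control_table(values, observable="FFA", sid="r1", species="obese", group="g"):
    rows = [(sid, group, species, observable, float(i), float(v), "control")
            for i, v in enumerate(values)]
    return _table(rows)


class TestIndividualNLL:
    def test_zero_residual_proportional(self, obese_params):
        """Exact predictions leave only the normalization term."""
        pk, ins, ffa = obese_params
        from niacffa.pk import baseline_concentration
        Cp0 = baseline_concentration(pk)
        tab = _control_table([Cp0] * 5, observable="NiAc")
        sigma = {"prop_NiAc": 0.483, "add_insulin": 0.748, "add_FFA": 0.135}
        nll = individual_nll(tab.frame, (pk, ins, ffa), "control", sigma)
        expected = 5 * math.log(0.483 * Cp0 * math.sqrt(2 * math.pi))
        assert nll == pytest.approx(expected, rel=1e-9)

    def test_single_obs_one_sd_off(self, obese_params):
        pk, ins, ffa = obese_params
        sigma = {"prop_NiAc": 0.483, "add_insulin": 0.748, "add_FFA": 0.135}
        tab = _control_table([ins.I0 + 0.748], observable="insulin")
        nll = individual_nll(tab.frame, (pk, ins, ffa), "control", sigma)
        assert nll == pytest.approx(math.log(0.748 * math.sqrt(2 * math.pi)) + 0.5, rel=1e-9)

    def test_matches_density_oracle(self, obese_params):
        """Gaussian density from scipy.stats as an independent oracle."""
        pk, ins, ffa = obese_params
        sigma = {"prop_NiAc": 0.483, "add_insulin": 0.748, "add_FFA": 0.135}
        rng = np.random.default_rng(11)
        ys = ffa.F0 + rng.normal(0, 0.2, size=100)
        tab = _control_table(ys, observable="FFA")
        nll = individual_nll(tab.frame, (pk, ins, ffa), "control", sigma)
        oracle = -norm.logpdf(ys, loc=ffa.F0, scale=0.135).sum()
        assert nll == pytest.approx(oracle, rel=1e-9)


class TestFOCE:
    def test_omega_zero_reduces_to_pooled_nll(self, obese_params):
        """With no between-subject variability FOCE is the plain likelihood."""
        from niacffa.synthetic import make_fixture

        tab, truth = make_fixture("smoke_small")
        model = truth["model"].copy()
        model.omega = {k: 0.0 for k in model.omega}
        pooled = 0.0
        for sid in tab.subject_ids:
            obs = tab.subject(sid)
            pooled += individual_nll(obs, (model.pk, model.insulin, model.ffa),
                                     obs["protocol"].iloc[0], model.sigma)
        focenll = sum(foce_nll(tab, model, st) for st in ("pk", "insulin", "ffa"))
        assert focenll == pytest.approx(pooled, rel=1e-5)

    def test_linear_model_matches_conjugate_closed_form(self, obese_params):
        """On a linear-Gaussian toy model FOCE is exact: it must equal the
        marginal normal density with covariance sigma^2*I + omega^2*b*b'."""
        model = default_population_model("obese")
        model.omega = {"F0": 0.3}
        model.sigma = {"prop_NiAc": 0.483, "add_insulin": 0.748, "add_FFA": 0.2}
        rng = np.random.default_rng(5)
        y = 2.0 + rng.normal(0, 0.3, size=8)
        tab = _control_table(y, observable="FFA")
        subjects = _build_subjects(tab)
        _freeze_context(subjects, model, {}, upto="ffa")
        problem = _StageProblem("ffa", subjects, model)
        a, b = 2.0, 0.7  # intercept and random-effect loading

        problem.predict = lambda m, s, eta: a + b * np.atleast_1d(eta)[0] * np.ones(y.size)
        nll = problem.nll(model)
        cov = 0.2 ** 2 * np.eye(y.size) + (0.3 * b) ** 2 * np.ones((y.size, y.size))
        oracle = -multivariate_normal.logpdf(y, mean=a * np.ones(y.size), cov=cov)
        assert nll == pytest.approx(oracle, rel=1e-8)

    def test_true_study_effect_improves_likelihood(self):
        """A two-group dataset generated with a baseline shift is better
        explained when the model carries the matching fixed-study effect."""
        model = default_population_model("obese")
        model.omega = {"I0": 0.1}
        rng = np.random.default_rng(21)
        rows = []
        for g, mult in (("G1", 1.0), ("G2", 1.6)):
            for j in range(4):
                i0 = model.insulin.I0 * mult * math.exp(rng.normal(0, 0.1))
                for t in range(6):
                    rows.append((f"{g}_{j}", g, "obese", "insulin", float(t),
                                 i0 + rng.normal(0, model.sigma["add_insulin"]), "control"))
        tab = _table(rows)
        without = foce_nll(tab, model, "insulin")
        with_se = model.copy()
        with_se.study_effects = {"I0": {"G1": 1.0, "G2": 1.6}}
        with_ = foce_nll(tab, with_se, "insulin")
        assert with_ < without

    def test_ebe_shrinkage_vanishes_with_data(self):
        """The mode's shrinkage toward the prior fades as data accumulate.

        Noise-free observations isolate the shrinkage itself: with few
        observations the prior pulls the mode below the generating eta,
        and the pull decays monotonically with the observation count.
        """
        model = default_population_model("obese")
        model.omega = {"F0": 0.3}
        model.sigma = dict(model.sigma, add_FFA=0.6)  # weak data per point
        eta_true = 0.45
        value = model.ffa.F0 * math.exp(eta_true)
        shrink = []
        for n_obs in (4, 16, 64):
            tab = _control_table([value] * n_obs)
            subjects = _build_subjects(tab)
            _freeze_context(subjects, model, {}, upto="ffa")
            problem = _StageProblem("ffa", subjects, model)
            _, eta = problem.subject_nll(model, subjects[0], return_eta=True)
            shrink.append(eta_true - eta[0])
        assert shrink[0] > shrink[1] > shrink[2] > 0
        assert shrink[2] < 0.05


class TestMedianExposureFallback:
    def test_subject_without_exposure_samples_gets_median_individual(self):
        """Subjects lacking NiAc observations (the chronically infused obese
        group) are assigned the estimated median individual's exposure."""
        model = default_population_model("obese")
        rows = [("cont1", "Cont_NiAc", "obese", "FFA", t, 1.1, "Cont_NiAc")
                for t in (0.5, 1.0, 2.0)]
        subjects = _build_subjects(_table(rows))
        ebes = {"pk": {"other_subject": {"ka": 0.4}}}  # no entry for cont1
        _freeze_context(subjects, model, ebes, upto="pk")
        assert subjects[0].pk_frozen == model.pk  # zero random effects


class TestFastKernelAgainstReference:
    def test_coupled_kernel_matches_reference_simulator(self, obese_params):
        """The compiled estimation kernel and the reference simulator are the
        same model: trajectories agree to solver tolerance."""
        from niacffa import simulate_individual
        from niacffa.population import _fast_predict_ffa, _fast_predict_insulin

        pk, ins, ffa = obese_params
        tab = _table([("s", "g", "obese", "FFA", t, 0.0, "Off_12h")
                      for t in np.linspace(0.5, 17.0, 12)])
        subjects = _build_subjects(tab)
        model = default_population_model("obese")
        _freeze_context(subjects, model, {}, upto="ffa")
        s = subjects[0]
        times = s.obs["FFA"][0]
        ref = simulate_individual(s.protocol, pk, ins, ffa, t_grid=times,
                                  mode="coupled", with_actions=False)
        fast_f = _fast_predict_ffa(ffa, s, times, 1e-8, 1e-10)
        fast_i = _fast_predict_insulin(ins, s, times, 1e-8, 1e-10)
        assert np.allclose(fast_f, ref["F"], rtol=2e-4)
        assert np.allclose(fast_i, ref["I"], rtol=2e-4)


class TestSensitivityRanking:
    def test_lean_pk_ranking(self, lean_popmodel):
        """Among the parameters the study estimated, the absorption rate and
        the pathway-1 capacity outrank the catheter-dilution coefficient;
        the (literature-fixed) pathway-2 Michaelis constant dominates all
        of them because pathway 2 carries most of the elimination at the
        therapeutic exposure."""
        frame = sensitivity_ranking(lean_popmodel, "NiAc_Naive",
                                    ["ka", "delta", "Vmax1", "Km2"],
                                    observable="NiAc")
        order = list(frame["parameter"])
        assert order.index("Vmax1") < order.index("delta")
        assert order.index("ka") < order.index("delta")
        assert order[0] == "Km2"

    def test_inert_parameter_ranks_last(self, obese_popmodel):
        model = obese_popmodel.copy()
        model.ffa = replace_fields(model.ffa, kNF=1e-12)
        frame = sensitivity_ranking(model, "Off_1h", ["F0", "IC50NF", "SNF"],
                                    observable="FFA")
        assert frame["parameter"].iloc[-1] == "SNF"


class TestVPC:
    def test_degenerate_model_collapses_bands(self, obese_popmodel):
        model = obese_popmodel.copy()
        model.omega = {k: 0.0 for k in model.omega}
        model.sigma = {k: 1e-300 for k in model.sigma}
        bands = vpc(model, "Off_1h", n_sim=20, seed=1, observable="FFA",
                    times=np.linspace(0, 6, 7))
        assert np.allclose(bands["p5"], bands["p95"], rtol=1e-9)

    def test_fixed_seed_reproducible(self, obese_popmodel):
        times = np.linspace(0, 6, 5)
        a = vpc(obese_popmodel, "Off_1h", n_sim=15, seed=42, times=times)
        b = vpc(obese_popmodel, "Off_1h", n_sim=15, seed=42, times=times)
        assert (a == b).all().all()

    def test_band_coverage_of_fresh_data(self, obese_popmodel):
        """The 90% prediction band covers ~90% of fresh simulated data."""
        times = np.array([0.25, 0.75, 2.0, 4.0])
        model = obese_popmodel
        bands = vpc(model, "Off_1h", n_sim=500, seed=7, observable="FFA",
                    times=times, rtol=1e-5, atol=1e-7)
        fresh = vpc(model, "Off_1h", n_sim=500, seed=1234, observable="FFA",
                    times=times, quantiles=(50.0, 50.0, 50.0), rtol=1e-5, atol=1e-7)
        # draw fresh individual observations and count band hits
        from niacffa.population import _resolve_protocol
        from niacffa.simulate import simulate_individual

        rng = np.random.default_rng(99)
        prot = _resolve_protocol("Off_1h", "obese")
        hits = total = 0
        eta_names = [n for n, om in model.omega.items() if om > 0]
        for _ in range(500):
            eta = {n: rng.normal(0.0, model.omega[n]) for n in eta_names}
            pk_p, ins_p, ffa_p = model.individual_parameters(eta)
            traj = simulate_individual(prot, pk_p, ins_p, ffa_p, t_grid=times,
                                       mode="coupled", rtol=1e-5, atol=1e-7,
                                       with_actions=False)
            obs = traj["F"] + rng.normal(0, model.sigma["add_FFA"], size=times.size)
            hits += np.sum((obs >= bands["p5"].to_numpy())
                           & (obs <= bands["p95"].to_numpy()))
            total += times.size
        coverage = hits / total
        assert 0.86 <= coverage <= 0.94


class TestHalfLives:
    def test_unit_rate(self):
        assert math.log(2) / math.log(2) == 1.0

    def test_published_cells(self, lean_params, obese_params):
        _, ins_l, ffa_l = lean_params
        pk_o, ins_o, ffa_o = obese_params
        lean = turnover_half_lives(ins_l, ffa_l)
        assert lean.loc["biomarker", "FFA"] == pytest.approx(0.00162, abs=5e-6)
        obese = turnover_half_lives(ins_o, ffa_o, pk_o)
        assert obese.loc["controller", "FFA"] == pytest.approx(42.0, abs=0.05)
        assert np.isnan(lean.loc["NiAc action", "insulin"])  # no lean action compartment
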