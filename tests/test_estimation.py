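import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from thyropmx.cohort import CohortConfig, VirtualPatient, generate_cohort
from thyropmx.estimation import (FitSettings, estimate_individual,
                                 fit_population, individual_objective,
                                 marginal_neg2ll, marginal_neg2ll_importance)
from thyropmx.events import DoseEvent, Drug
from thyropmx.params import IndividualParameters
from thyropmx.pd import simulate_individual_ft4
from thyropmx.population import CovariateSet, Severity, Sex


def make_toy_patient(pid=1, n_days=30, daily_mg=20.0, weight=35.0,
                     obs_times=(0.0, 10.0, 20.0, 29.0),
                     observations=None, age=11.0,
                     severity=Severity.MODERATE):
    regimen = [DoseEvent(Drug.CMZ, daily_mg, float(d)) for d in range(n_days)]
    return VirtualPatient(
        id=pid,
        covariates=CovariateSet(age_dx=age, sex=Sex.F, severity=severity),
        weight_times=np.array([0.0]), weight_values=np.array([weight]),
        regimen=regimen,
        observation_times=np.asarray(obs_times, dtype=float),
        observations=(np.asarray(observations, dtype=float)
                      if observations is not None else None))


def noise_free_patient(pop, pid=1, etas=(0.0, 0.0), **kw):
    from thyropmx.population import individual_endogenous_rate

    p = make_toy_patient(pid=pid, **kw)
    ind = IndividualParameters(
        kendo=individual_endogenous_rate(pop, p.covariates, etas[0]),
        ic50=pop.pd_pop.IC50 * math.exp(etas[1]),
        fvt4=pop.pd_pop.fVT4, beta=pop.pd_pop.beta, fixed=pop.pd_pop)
    p.observations = simulate_individual_ft4(p, ind, pop.pk_pop).values
    p.truth = ind
    return p


class TestIndividualObjective:
    def test_matches_density_sum_oracle(self, default_pop):
        """Objective equals -2 log of the product of the observation and
        random-effect normal densities, computed independently."""
        pop = default_pop
        p = noise_free_patient(pop, obs_times=(0.0, 12.0, 25.0))
        p.observations = p.observations * np.array([1.1, 0.9, 1.05])
        etas = (0.12, -0.4)
        ind = IndividualParameters(
            kendo=p.truth.kendo * math.exp(etas[0]) / math.exp(0.0),
            ic50=pop.pd_pop.IC50 * math.exp(etas[1]),
            fvt4=pop.pd_pop.fVT4, beta=pop.pd_pop.beta, fixed=pop.pd_pop)
        got = individual_objective(p, ind, pop, pop.sigma_prop)

        f = simulate_individual_ft4(p, ind, pop.pk_pop).values
        loglik = stats.norm.logpdf(p.observations, loc=f,
                                   scale=pop.sigma_prop * f).sum()
        loglik += stats.norm.logpdf(etas[0], 0, pop.omega_kendo)
        loglik += stats.norm.logpdf(etas[1], 0, pop.omega_ic50)
        assert got == pytest.approx(-2.0 * loglik, rel=1e-9)

    def test_eta_penalty_is_quadratic(self, default_pop):
        """Doubling an eta quadruples its prior penalty (isolated from the
        data term by differencing against a prior-free evaluation)."""
        pop = default_pop
        p = noise_free_patient(pop)

        def penalty(eta):
            ind = IndividualParameters(
                kendo=p.truth.kendo, ic50=pop.pd_pop.IC50 * math.exp(eta),
                fvt4=pop.pd_pop.fVT4, beta=pop.pd_pop.beta, fixed=pop.pd_pop)
            with_prior = individual_objective(p, ind, pop, pop.sigma_prop,
                                              eta_set=("ic50",))
            without = individual_objective(p, ind, pop, pop.sigma_prop,
                                           eta_set=())
            log_const = math.log(2 * math.pi * pop.omega_ic50 ** 2)
            return with_prior - without - log_const

        assert penalty(0.4) == pytest.approx(4.0 * penalty(0.2), rel=1e-9)
        assert penalty(0.2) == pytest.approx(0.04 / pop.omega_ic50 ** 2,
                                             rel=1e-9)


class TestEstimateIndividual:
    def test_noise_free_truth_recovery(self, default_pop):
        """Data generated at etas = 0 without noise: MAP parameters return to
        the truth.

        The MAP is not exactly 0: with proportional error the log((sigma*f)^2)
        term rewards slightly smaller predictions, shifting eta_kendo by about
        -n_obs * omega^2 (~ -0.008 here).  The recovered parameters must agree
        with the truth to well within that prior-dominated margin.
        """
        p = noise_free_patient(default_pop,
                               obs_times=(0.0, 5.0, 10.0, 20.0, 29.0))
        pop = default_pop.copy()
        pop.sigma_prop = 0.01  # the pull scales with sigma^2
        fit = estimate_individual(p, pop)
        assert all(abs(e) < 1e-2 for e in fit.etas.values())
        assert fit.params.kendo == pytest.approx(p.truth.kendo, rel=1e-2)
        assert fit.params.ic50 == pytest.approx(p.truth.ic50, rel=2e-2)
        # at the clinical sigma the same pull is visible but bounded
        fit_clin = estimate_individual(p, default_pop)
        assert fit_clin.params.kendo == pytest.approx(p.truth.kendo, rel=0.02)
        assert fit_clin.params.ic50 == pytest.approx(p.truth.ic50, rel=0.25)

    def test_high_observations_raise_kendo(self, default_pop):
        p = noise_free_patient(default_pop,
                               obs_times=(0.0, 5.0, 10.0, 20.0, 29.0))
        p.observations = p.observations * 1.6
        fit = estimate_individual(p, default_pop)
        from thyropmx.population import individual_endogenous_rate
        assert fit.params.kendo > individual_endogenous_rate(
            default_pop, p.covariates)

    def test_tiny_omega_pins_eta_to_zero(self, default_pop):
        pop = default_pop.copy()
        pop.omega_kendo = 1e-9
        pop.omega_ic50 = 1e-9
        p = noise_free_patient(default_pop,
                               obs_times=(0.0, 5.0, 10.0, 20.0, 29.0))
        p.observations = p.observations * 1.5
        fit = estimate_individual(p, pop)
        assert all(abs(e) < 1e-4 for e in fit.etas.values())


class TestMarginalLikelihood:
    def test_collapsed_integral_closed_form(self, default_pop):
        """With omegas ~ 0 the marginal collapses to the plain normal
        -2 log-density of the observations at the typical prediction."""
        pop = default_pop.copy()
        pop.omega_kendo = pop.omega_ic50 = 1e-9
        p = noise_free_patient(pop, obs_times=(0.0, 15.0))
        p.observations = p.observations * np.array([1.08, 0.93])
        got = marginal_neg2ll([p], pop)
        ind = IndividualParameters.typical(pop.pd_pop)
        ind = dataclasses.replace(ind, kendo=p.truth.kendo)
        f = simulate_individual_ft4(p, ind, pop.pk_pop).values
        expected = -2.0 * stats.norm.logpdf(
            p.observations, loc=f, scale=pop.sigma_prop * f).sum()
        assert got == pytest.approx(expected, rel=1e-4)

    def test_additivity_over_patients(self, default_pop):
        p1 = noise_free_patient(default_pop, pid=1)
        p2 = noise_free_patient(default_pop, pid=2, daily_mg=30.0, weight=45.0,
                                severity=Severity.SEVERE)
        p1.observations = p1.observations * 1.1
        p2.observations = p2.observations * 0.9
        lone = marginal_neg2ll([p1], default_pop) + marginal_neg2ll(
            [p2], default_pop)
        joint = marginal_neg2ll([p1, p2], default_pop)
        assert joint == pytest.approx(lone, rel=1e-12)

    def test_laplace_agrees_with_importance_sampling(self, default_pop):
        """Laplace and a 10k-draw importance-sampling estimate agree within 1%
        on a small heterogeneous cohort."""
        rng = np.random.default_rng(8)
        cohort = []
        for i, (dose, sev) in enumerate(
                [(15.0, Severity.MILD), (20.0, Severity.MODERATE),
                 (30.0, Severity.SEVERE), (25.0, Severity.MODERATE),
                 (10.0, Severity.MILD)], start=1):
            p = noise_free_patient(
                default_pop, pid=i, daily_mg=dose, severity=sev,
                etas=(rng.normal(0, 0.04), rng.normal(0, 0.5)),
                obs_times=(0.0, 7.0, 14.0, 21.0, 29.0))
            p.observations = p.observations * (
                1.0 + 0.2 * rng.standard_normal(p.observations.size))
            cohort.append(p)
        lap = marginal_neg2ll(cohort, default_pop)
        is_ = marginal_neg2ll_importance(cohort, default_pop, n_draws=10_000,
                                         rng_seed=99)
        assert abs(lap - is_) / abs(is_) <= 0.01

    def test_truth_beats_perturbed_parameters_on_average(self, default_pop):
        """-2LL at the generating parameters is no worse than at a clearly
        perturbed parameter set, averaged over cohorts."""
        diffs = []
        for seed in (101, 202, 303):
            cohort = generate_cohort(
                CohortConfig(n_patients=6, followup_years_median=0.5,
                             followup_years_range=(0.4, 0.6)),
                default_pop, seed)
            wrong = default_pop.copy()
            wrong.pd_pop.kendoT4 = default_pop.pd_pop.kendoT4 * 1.6
            diffs.append(marginal_neg2ll(cohort, wrong)
                         - marginal_neg2ll(cohort, default_pop))
        assert np.mean(diffs) > 0


class TestPopulationFit:
    def test_noise_free_fixed_effect_recovery(self, default_pop):
        """omegas = 0, near-zero noise: fixed effects recovered to <1%."""
        truth = default_pop.copy()
        truth.omega_kendo = truth.omega_ic50 = 0.0
        truth.omega_fvt4 = truth.omega_beta = 0.0
        truth.sigma_prop = 1e-4
        config = CohortConfig(n_patients=8, followup_years_median=0.6,
                              followup_years_range=(0.5, 0.7))
        cohort = generate_cohort(config, truth, 77)
        init = truth.copy()
        init.pd_pop.kendoT4 *= 1.3
        init.pd_pop.IC50 *= 0.7
        init.pd_pop.fVT4 *= 1.2
        settings = FitSettings(
            estimate=("kendoT4", "IC50", "fVT4", "beta"),
            initial_pop=init, compute_rse=False, max_outer_fev=600)
        fit = fit_population(cohort, settings)
        for name in settings.estimate:
            from thyropmx.estimation import get_param
            est = get_param(fit.pop_hat, name)
            tru = get_param(truth, name)
            assert abs(est / tru - 1.0) < 0.01, name

    def test_patient_order_invariance(self, default_pop, small_cohort):
        a = marginal_neg2ll(small_cohort, default_pop)
        b = marginal_neg2ll(list(reversed(small_cohort)), default_pop)
        assert a == pytest.approx(b, rel=1e-12)

    def test_time_unit_rescaling_invariance(self, default_pop):
        """Rescaling times by c and all rates (and kendo, nmol/day) by 1/c
        leaves the likelihood unchanged."""
        pop = default_pop
        p = noise_free_patient(pop, obs_times=(0.0, 10.0, 20.0, 29.0))
        p.observations = p.observations * np.array([1.05, 0.9, 1.1, 0.97])
        c = 2.0
        pop_s = pop.copy()
        for name in ("kaT4", "kendoT4", "kelT4"):
            setattr(pop_s.pd_pop, name, getattr(pop.pd_pop, name) / c)
        for name in ("kaC", "kt", "kelM", "k12", "k21"):
            setattr(pop_s.pk_pop, name, getattr(pop.pk_pop, name) / c)
        p_s = VirtualPatient(
            id=p.id, covariates=p.covariates,
            weight_times=p.weight_times * c, weight_values=p.weight_values,
            regimen=[DoseEvent(e.drug, e.amount, e.time * c)
                     for e in p.regimen],
            observation_times=p.observation_times * c,
            observations=p.observations)
        a = marginal_neg2ll([p], pop)
        b = marginal_neg2ll([p_s], pop_s)
        assert a == pytest.approx(b, rel=1e-6)


class TestStandardErrors:
    def test_rse_tracks_replicate_spread_on_toy_problem(self, default_pop):
        """The information-matrix r.s.e. agrees with the across-replicate SD
        of the estimate on a small single-parameter problem."""
        config = CohortConfig(n_patients=4, followup_years_median=0.3,
                              followup_years_range=(0.25, 0.35))
        log_ests, rses = [], []
        for seed in range(200, 250):
            cohort = generate_cohort(config, default_pop, seed)
            fit = fit_population(cohort, FitSettings(
                estimate=("kendoT4",), rng_seed=seed, max_outer_fev=200))
            log_ests.append(math.log(fit.pop_hat.pd_pop.kendoT4))
            if np.isfinite(fit.rse.get("kendoT4", float("nan"))):
                rses.append(fit.rse["kendoT4"] / 100.0)
        sim_sd = float(np.std(log_ests, ddof=1))
        med_rse = float(np.median(rses))
        assert med_rse == pytest.approx(sim_sd, rel=0.2)

    def test_rse_definition_and_fix_rows(self, default_pop):
        from thyropmx.estimation import FitResult
        fit = FitResult(
            pop_hat=default_pop.copy(), ebes=[], neg2ll=0.0,
            rse={"kendoT4": 7.0}, converged=True, message="",
            n_outer_evals=0, estimated=("kendoT4",))
        table = fit.to_table()
        row = table[table.parameter == "kendoT4"].iloc[0]
        assert row.rse_percent == 7.0 and not row.fixed
        fixed_rows = table[table.parameter != "kendoT4"]
        assert fixed_rows.fixed.all()
        assert fixed_rows.rse_percent.isna().all()
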