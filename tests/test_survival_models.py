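import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from recurve.data_model import Cohort, CovariateSchema, CovariateSpec, SubjectRecord, ValidationError
from recurve.preprocess import AG, PWP_TT, to_counting_process
from recurve.simulate import SimulationConfig, simulate_cohort
from recurve.survival_models import (
    FitError,
    StepHazard,
    breslow_cumhaz,
    fit_cox_counting,
    jackknife_covariance,
    pool_sparse_strata,
    predict_count_ag,
    predict_count_pwp,
    predict_counts_ag,
    predict_counts_pwp,
)

from conftest import make_cohort


def single_event_cohort(seed=3, n=300):
    """Classical survival data: one terminal event or censoring per subject."""
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, n)
    z = rng.normal(0, 1, n)
    t = rng.exponential(1 / (0.02 * np.exp(0.6 * x - 0.4 * z)))
    c = rng.uniform(20, 80, n)
    obs = np.minimum(t, c)
    ev = t <= c
    schema = CovariateSchema({"x": CovariateSpec("binary"), "z": CovariateSpec("continuous")})
    recs = [
        SubjectRecord(
            f"s{i}", {"x": int(x[i]), "z": float(z[i])}, float(obs[i]), (float(obs[i]),) if ev[i] else ()
        )
        for i in range(n)
    ]
    return Cohort(tuple(recs), schema), pd.DataFrame({"T": obs, "E": ev.astype(int), "x": x, "z": z})


def four_subject_table(xz_schema):
    # binary x, events at t=1 (x=1), 2 (x=0), 3 (x=1), 4 (x=0); classical
    # single spells: each subject exits at its event
    rows = [
        ("a", {"x": 1, "z": 0.0}, 1.0, (1.0,)),
        ("b", {"x": 0, "z": 0.0}, 2.0, (2.0,)),
        ("c", {"x": 1, "z": 0.0}, 3.0, (3.0,)),
        ("d", {"x": 0, "z": 0.0}, 4.0, (4.0,)),
    ]
    cohort = make_cohort(xz_schema, rows)
    return to_counting_process(cohort, AG, 4.0, ["x"])


class TestFitCoxCounting:
    def test_brute_force_1d_oracle(self, xz_schema):
        """Golden-section maximizer of the hand-written partial likelihood."""
        table = four_subject_table(xz_schema)

        def negpl(beta):
            # risk sets at t=1: {a,b,c,d}; t=2: {b,c,d}; t=3: {c,d}; t=4: {d}
            e = math.exp(beta)
            ll = (
                beta - math.log(2 * e + 2)
                + 0.0 - math.log(e + 2)
                + beta - math.log(e + 1)
                + 0.0 - math.log(1.0)
            )
            return -ll

        res = optimize.minimize_scalar(negpl, bounds=(-5, 5), method="bounded",
                                       options={"xatol": 1e-10})
        fit = fit_cox_counting(table)
        assert fit.coefficients["x"] == pytest.approx(res.x, abs=1e-6)
        assert fit.converged

    def test_single_event_reduces_to_classical_cox(self):
        import lifelines

        cohort, df = single_event_cohort()
        table = to_counting_process(cohort, AG, 1e9)
        fit = fit_cox_counting(table)
        # no ties -> Efron == Breslow; tight precision so the oracle itself
        # sits at the optimum
        cph = lifelines.CoxPHFitter().fit(df, "T", "E", fit_options={"precision": 1e-12})
        for name in ("x", "z"):
            assert fit.coefficients[name] == pytest.approx(cph.params_[name], abs=1e-8)
        # naive SEs agree with the classical information-based SEs too
        for name in ("x", "z"):
            assert fit.naive_se()[name] == pytest.approx(cph.standard_errors_[name], rel=1e-4)

    def test_score_norm_small_at_optimum(self, xz_schema):
        from recurve.survival_models import _prepare_strata, _stratum_quantities
        from recurve._design import build_design

        table = four_subject_table(xz_schema)
        fit = fit_cox_counting(table)
        design = build_design(table.data, table.schema, ("x",))
        strata, _ = _prepare_strata(table, ["x"], design.to_numpy())
        beta = np.array([fit.coefficients["x"]])
        grad = sum(_stratum_quantities(sd, beta, False)[1] for _, sd in strata)
        assert np.linalg.norm(grad) < 1e-6

    def test_recovery_ag_3se(self):
        cfg = SimulationConfig(
            n_subjects=5000,
            covariate_spec={"x": ("bernoulli", 0.5), "z": ("normal", 0.0, 1.0)},
            beta={"x": 0.5, "z": -0.3},
            baseline_rate=0.004,
            follow_up=365.0,
            seed=7,
        )
        sim = simulate_cohort(cfg)
        fit = fit_cox_counting(to_counting_process(sim.cohort, AG, 365.0))
        se = fit.robust_se()
        for name, truth in (("x", 0.5), ("z", -0.3)):
            assert abs(fit.coefficients[name] - truth) < 3 * se[name], name

    def test_robust_ge_naive_with_frailty_clustering(self):
        # positive within-subject correlation (gamma frailty) inflates the
        # robust variance relative to the naive one
        cfg = SimulationConfig(
            n_subjects=2000,
            covariate_spec={"x": ("bernoulli", 0.5)},
            beta={"x": 0.4},
            baseline_rate=0.01,
            frailty_variance=1.0,
            follow_up=365.0,
            seed=8,
        )
        sim = simulate_cohort(cfg)
        fit = fit_cox_counting(to_counting_process(sim.cohort, AG, 365.0))
        assert fit.robust_se()["x"] > fit.naive_se()["x"]

    def test_robust_matches_exact_jackknife_small_n(self, xz_schema):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(60):
            end = 100.0
            times = tuple(float(t) for t in np.unique(rng.uniform(1, end, rng.poisson(1.5))))
            rows.append((f"s{i}", {"x": int(rng.integers(2)), "z": 0.0}, end, times))
        cohort = make_cohort(xz_schema, rows)
        table = to_counting_process(cohort, AG, 100.0, ["x"])
        fit = fit_cox_counting(table)
        jk = jackknife_covariance(table, ["x"])
        assert math.sqrt(jk.loc["x", "x"]) == pytest.approx(fit.robust_se()["x"], rel=0.15)

    def test_no_events_is_error(self, xz_schema):
        cohort = make_cohort(xz_schema, [("a", {"x": 0, "z": 0.0}, 10.0, ())])
        table = to_counting_process(cohort, AG, 10.0)
        with pytest.raises(FitError):
            fit_cox_counting(table)

    def test_monotone_likelihood_flagged(self, xz_schema):
        # perfectly separated: x=1 events all precede any x=0 exposure end
        rows = [
            ("a", {"x": 1, "z": 0.0}, 100.0, (1.0,)),
            ("b", {"x": 1, "z": 0.0}, 100.0, (2.0,)),
            ("c", {"x": 0, "z": 0.0}, 100.0, ()),
            ("d", {"x": 0, "z": 0.0}, 100.0, ()),
        ]
        table = to_counting_process(make_cohort(xz_schema, rows), AG, 100.0, ["x"])
        with pytest.warns(UserWarning):
            fit = fit_cox_counting(table)
        assert not fit.converged


class TestBreslow:
    def test_nelson_aalen_closed_form(self, xz_schema):
        # 3 subjects all followed to t=3, events at 1 and 2: jumps 1/3, 1/2
        rows = [
            ("a", {"x": 0, "z": 0.0}, 3.0, (1.0,)),
            ("b", {"x": 0, "z": 0.0}, 3.0, (2.0,)),
            ("c", {"x": 0, "z": 0.0}, 3.0, ()),
        ]
        cohort = make_cohort(xz_schema, rows)
        # single-event-per-subject layout: treat the event as terminal by
        # truncating follow-up at the event (classical survival reduction)
        recs = [
            SubjectRecord("a", {"x": 0, "z": 0.0}, 1.0, (1.0,)),
            SubjectRecord("b", {"x": 0, "z": 0.0}, 2.0, (2.0,)),
            SubjectRecord("c", {"x": 0, "z": 0.0}, 3.0, ()),
        ]
        cohort = Cohort(tuple(recs), cohort.schema)
        table = to_counting_process(cohort, AG, 10.0, ["x"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant covariate -> singular info
            fit = fit_cox_counting(table)
        fit0 = dataclasses.replace(fit, coefficients={"x": 0.0})
        H = breslow_cumhaz(fit0, table)[1]
        assert H.times.tolist() == [1.0, 2.0]
        assert H.jumps.tolist() == pytest.approx([1 / 3, 1 / 2])
        assert H(0.5) == 0.0
        assert H(1.0) == pytest.approx(1 / 3)
        assert H(5.0) == pytest.approx(1 / 3 + 1 / 2)

    def test_no_events_stratum_zero_hazard(self, xz_schema):
        # alternating event order keeps the stratum-1 likelihood interior
        rows = [
            ("a", {"x": 1, "z": 0.0}, 10.0, (1.0,)),
            ("b", {"x": 0, "z": 0.0}, 10.0, (2.0,)),
            ("c", {"x": 1, "z": 0.0}, 10.0, (3.0,)),
            ("d", {"x": 0, "z": 0.0}, 10.0, (4.0,)),
        ]
        table = to_counting_process(make_cohort(xz_schema, rows), PWP_TT, 10.0, ["x"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_cox_counting(table)
        # stratum 2 (after first event) has no events
        assert fit.baseline_cumhaz[2](10.0) == 0.0

    def test_row_doubling_invariance(self, xz_schema):
        cohort, _ = single_event_cohort(seed=9, n=80)
        table = to_counting_process(cohort, AG, 1e9, ["x"])
        fit = fit_cox_counting(table)
        doubled_df = pd.concat([table.data, table.data.assign(subject_id=table.data.subject_id + "_b")])
        doubled = dataclasses.replace(table, data=doubled_df.reset_index(drop=True))
        fit2 = fit_cox_counting(doubled)
        H1 = fit.baseline_cumhaz[1]
        H2 = fit2.baseline_cumhaz[1]
        assert np.allclose(H1.cum, H2.cum)

    def test_nondecreasing_zero_at_origin(self, xz_schema):
        cohort, _ = single_event_cohort(seed=10, n=100)
        table = to_counting_process(cohort, AG, 1e9, ["x"])
        fit = fit_cox_counting(table)
        H = fit.baseline_cumhaz[1]
        assert (np.diff(H.cum) >= 0).all()
        assert H(0.0) == 0.0


class TestPredictAG:
    def test_arithmetic(self, xz_schema):
        cohort, _ = single_event_cohort(seed=11, n=100)
        table = to_counting_process(cohort, AG, 1e9, ["x"])
        fit = fit_cox_counting(table)
        H = fit.baseline_cumhaz[1]
        tau = float(np.median(H.times))
        fake = dataclasses.replace(
            fit,
            coefficients={"x": math.log(2.0)},
            baseline_cumhaz={1: StepHazard(np.array([tau]), np.array([0.5]))},
        )
        assert predict_count_ag(fake, {"x": 1}, tau) == pytest.approx(1.0)
        assert predict_count_ag(fake, {"x": 0}, tau) == pytest.approx(0.5)

    def test_reference_subject_gets_h0(self, xz_schema):
        cohort, _ = single_event_cohort(seed=12, n=100)
        table = to_counting_process(cohort, AG, 1e9, ["x"])
        fit = fit_cox_counting(table)
        H = fit.baseline_cumhaz[1]
        tau = H.last_time
        assert predict_count_ag(fit, {"x": 0, "z": 0.0}, tau) == pytest.approx(H(tau))

    def test_martingale_mean_oracle(self):
        # mean predicted count over the fitted cohort ~ mean observed count
        cfg = SimulationConfig(
            n_subjects=5000,
            covariate_spec={"x": ("bernoulli", 0.5)},
            beta={"x": 0.4},
            baseline_rate=0.005,
            follow_up=365.0,
            seed=13,
        )
        sim = simulate_cohort(cfg)
        fit = fit_cox_counting(to_counting_process(sim.cohort, AG, 365.0))
        yhat = predict_counts_ag(fit, sim.cohort.covariate_frame(), 360.0)
        y = sim.cohort.counts(360.0)
        se = y.std() / math.sqrt(len(y))
        assert abs(yhat.mean() - y.mean()) < 3 * se

    def test_monotone_in_tau(self, xz_schema):
        cohort, _ = single_event_cohort(seed=14, n=120)
        table = to_counting_process(cohort, AG, 1e9, ["x"])
        fit = fit_cox_counting(table)
        taus = np.linspace(1, fit.baseline_cumhaz[1].last_time, 12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vals = [predict_count_ag(fit, {"x": 1, "z": 0.0}, t) for t in taus]
        assert vals == sorted(vals)

    def test_extrapolation_warns(self, xz_schema):
        cohort, _ = single_event_cohort(seed=15, n=60)
        table = to_counting_process(cohort, AG, 1e9, ["x"])
        fit = fit_cox_counting(table)
        with pytest.warns(UserWarning, match="extrapolat"):
            predict_count_ag(fit, {"x": 0, "z": 0.0}, fit.baseline_cumhaz[1].last_time + 1000)


def pwp_fit(seed=11, n=800, mult=(1.0, 3.0, 5.0)):
    cfg = SimulationConfig(
        n_subjects=n,
        covariate_spec={"x": ("bernoulli", 0.5)},
        beta={"x": 0.4},
        baseline_rate=0.003,
        event_rate_multipliers=mult,
        follow_up=365.0,
        seed=seed,
    )
    sim = simulate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pool_sparse_strata(to_counting_process(sim.cohort, PWP_TT, 365.0))
        fit = fit_cox_counting(table)
    return sim, fit


class TestPredictPWP:
    def test_tau_zero(self):
        _, fit = pwp_fit()
        assert predict_count_pwp(fit, {"x": 1}, 0.0, seed=1) == 0.0

    def test_montecarlo_requires_seed(self):
        _, fit = pwp_fit()
        with pytest.raises(ValidationError, match="seed"):
            predict_count_pwp(fit, {"x": 1}, 100.0)

    def test_single_stratum_closed_form(self):
        # with K=1 at most one event can happen: both methods equal
        # 1 - exp(-H(tau) e^{x beta})
        _, fit = pwp_fit()
        one = dataclasses.replace(fit, baseline_cumhaz={1: fit.baseline_cumhaz[1]})
        tau = 200.0
        H = one.baseline_cumhaz[1]
        for x in (0, 1):
            closed = 1 - math.exp(-H(tau) * math.exp(one.coefficients["x"] * x))
            plug = predict_count_pwp(one, {"x": x}, tau, method="plugin")
            mc = predict_count_pwp(one, {"x": x}, tau, n_draws=4000, seed=2)
            assert plug == pytest.approx(closed, rel=1e-12)
            assert mc == pytest.approx(closed, abs=3 * math.sqrt(closed * (1 - closed) / 4000))

    def test_bounded_by_strata_count(self):
        _, fit = pwp_fit()
        K = len(fit.baseline_cumhaz)
        val = predict_count_pwp(fit, {"x": 1}, 365.0, n_draws=500, seed=3)
        assert 0 <= val <= K

    def test_simulation_truth_oracle(self):
        # MC prediction at the cohort level matches the simulated ground truth
        sim, fit = pwp_fit(seed=17, n=2000)
        yhat = predict_counts_pwp(fit, sim.cohort.covariate_frame(), 365.0, n_draws=400, seed=5)
        y = sim.cohort.counts(365.0)
        se = y.std() / math.sqrt(len(y))
        assert abs(yhat.mean() - y.mean()) < 4 * se

    def test_plugin_upper_biased_when_multi_event(self):
        # ignoring sequential conditioning over-counts when K > 1
        sim, fit = pwp_fit(seed=18, n=800)
        frame = sim.cohort.covariate_frame()
        plug = predict_counts_pwp(fit, frame, 365.0, method="plugin")
        mc = predict_counts_pwp(fit, frame, 365.0, n_draws=300, seed=6)
        assert plug.mean() > mc.mean()


class TestPoolSparseStrata:
    def test_pools_and_marks(self):
        cfg = SimulationConfig(
            n_subjects=300,
            covariate_spec={"x": ("bernoulli", 0.5)},
            beta={"x": 0.3},
            baseline_rate=0.01,
            frailty_variance=1.5,
            follow_up=365.0,
            seed=19,
        )
        sim = simulate_cohort(cfg)
        table = to_counting_process(sim.cohort, PWP_TT, 365.0)
        with pytest.warns(UserWarning, match="pooling"):
            pooled = pool_sparse_strata(table, min_events=5)
        pooled.validate()
        ev = pooled.data.groupby("stratum")["event"].sum()
        assert (ev.iloc[:-1] >= 5).all()
        assert pooled.pooled_after == int(pooled.data["stratum"].max())

    def test_ag_passthrough(self, xz_schema):
        cohort, _ = single_event_cohort(seed=20, n=50)
        table = to_counting_process(cohort, AG, 1e9, ["x"])
        assert pool_sparse_strata(table) is table
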