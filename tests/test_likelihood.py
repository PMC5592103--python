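"""Marginal-likelihood checks against independent oracles.

The brute-force oracle integrates exp(l_long + l_surv) * N(u; 0, sigma_u^2)
on a dense trapezoid grid, evaluating both submodel likelihoods directly from
their densities — independent of the quadrature implementation.
"""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import trapezoid

from scljoint import (
    Association,
    JointParams,
    LongFixedEffects,
    LongitudinalRecord,
    NumericalError,
    QuadratureRule,
    SurvFixedEffects,
    dataset_from_frames,
    mean_trajectory,
    subject_marginal_loglik,
    total_loglik,
)

from conftest import make_dataset, make_subject


def brute_marginal(subject, measurements, params, n_grid=20001, half_width=8.0):
    """Dense-trapezoid integral over u in [-hw*sigma_u, hw*sigma_u]."""
    su = params.sigma_u
    u = np.linspace(-half_width * su, half_width * su, n_grid)
    ll = np.zeros_like(u)
    for m in measurements:
        mu = mean_trajectory(m.time, params.long, 0.0) + u
        ll += stats.norm.logpdf(m.y, mu, params.long.sigma)
    if subject is not None:
        x = {"ar": float(subject.ar)}
        theta = params.surv.gamma0 + params.surv.gamma.get("ar", 0.0) * x["ar"] \
            + params.assoc.alpha * u
        p = params.surv.p
        T = subject.event_time
        ll += subject.event * np.log(p * np.exp(theta) * T ** (p - 1.0))
        ll -= np.exp(theta) * T ** p
    logint = ll + stats.norm.logpdf(u, 0.0, su)
    shift = logint.max()
    return shift + np.log(trapezoid(np.exp(logint - shift), u))


def _random_case(rng):
    n_meas = int(rng.integers(0, 5))
    times = np.sort(rng.uniform(0.5, 25.0, size=n_meas))
    fx = LongFixedEffects(
        beta0=rng.normal(0, 0.5), beta1=rng.normal(0, 0.1),
        beta2=rng.normal(0, 0.01), beta3=rng.normal(0, 0.05),
        knot=10.0, sigma=rng.uniform(0.3, 1.0),
    )
    params = JointParams(
        long=fx,
        surv=SurvFixedEffects(rng.uniform(-3.0, -0.5),
                              {"ar": rng.uniform(-0.5, 0.5)},
                              rng.uniform(0.7, 1.6)),
        assoc=Association(rng.uniform(-1.0, 1.0)),
        sigma_u=rng.uniform(0.4, 1.2),
    )
    meas = tuple(
        LongitudinalRecord("S1", float(t),
                           mean_trajectory(float(t), fx) + rng.normal(0, fx.sigma))
        for t in times
    )
    subject = make_subject(event_time=float(rng.uniform(1.0, 30.0)),
                           event=int(rng.random() < 0.6),
                           ar=int(rng.random() < 0.3))
    return subject, meas, params


def test_quadrature_matches_brute_force_on_random_cases():
    rng = np.random.default_rng(2024)
    quad = QuadratureRule.gauss_hermite(20)
    for _ in range(50):
        subject, meas, params = _random_case(rng)
        gh = subject_marginal_loglik(subject, meas, params, quad)
        brute = brute_marginal(subject, meas, params)
        assert gh == pytest.approx(brute, abs=1e-6)


def test_nonadaptive_converges_to_adaptive_value():
    # prior-scaled nodes need far more points than posterior-centered ones
    rng = np.random.default_rng(7)
    dense = QuadratureRule.gauss_hermite(300)
    quad = QuadratureRule.gauss_hermite(20)
    for _ in range(10):
        subject, meas, params = _random_case(rng)
        na = subject_marginal_loglik(subject, meas, params, dense, adaptive=False)
        ad = subject_marginal_loglik(subject, meas, params, quad, adaptive=True)
        assert na == pytest.approx(ad, abs=1e-6)


def test_no_measurements_alpha_zero_reduces_to_survival_term(simple_params):
    params = simple_params
    params.assoc.alpha = 0.0
    params.surv.gamma0 = 0.0
    params.surv.gamma = {}
    params.surv.p = 1.0
    sub = make_subject(event_time=1.0, event=1)
    val = subject_marginal_loglik(sub, (), params)
    assert val == pytest.approx(-1.0, abs=1e-12)


def test_single_measurement_normal_convolution():
    # y ~ N(0, sigma^2 + sigma_u^2) marginally; at y=0 with unit variances
    # the log-density is -0.5*log(4*pi)
    params = JointParams(
        long=LongFixedEffects(0.0, 0.0, 0.0, 0.0, sigma=1.0),
        surv=SurvFixedEffects(0.0, {}, 1.0),
        assoc=Association(0.0),
        sigma_u=1.0,
    )
    val = subject_marginal_loglik(None, (LongitudinalRecord("S1", 1.0, 0.0),),
                                  params)
    assert val == pytest.approx(-0.5 * np.log(4 * np.pi), abs=1e-10)


def test_quadrature_rule_normalization():
    for n in (5, 15, 30, 50):
        assert QuadratureRule.gauss_hermite(n).normalization_defect() < 1e-10


def test_quadrature_convergence_30_vs_50_nodes():
    rng = np.random.default_rng(99)
    q30, q50 = QuadratureRule.gauss_hermite(30), QuadratureRule.gauss_hermite(50)
    for _ in range(10):
        subject, meas, params = _random_case(rng)
        a = subject_marginal_loglik(subject, meas, params, q30)
        b = subject_marginal_loglik(subject, meas, params, q50)
        assert a == pytest.approx(b, abs=1e-6)


def test_total_loglik_additivity_and_permutation(simple_params):
    ds = make_dataset(n_subjects=4, n_per_subject=3, seed=1)
    total = total_loglik(ds, simple_params)
    per_subject = sum(
        subject_marginal_loglik(s, ds.measurements_of(s.subject_id), simple_params)
        for s in ds.subjects
    )
    assert total == pytest.approx(per_subject, rel=1e-12)

    from scljoint import Dataset
    perm = Dataset(tuple(reversed(ds.subjects)), ds.measurements, ds.scale_factor)
    assert total_loglik(perm, simple_params) == pytest.approx(total, rel=1e-12)


def test_alpha_zero_factorization_closed_form(simple_params):
    """With alpha=0 the joint likelihood is (marginal Gaussian with
    compound-symmetry covariance) x (Weibull at u=0), both in closed form."""
    ds = make_dataset(n_subjects=4, n_per_subject=3, seed=2)
    params = simple_params
    params.assoc.alpha = 0.0
    expected = 0.0
    for s in ds.subjects:
        meas = ds.measurements_of(s.subject_id)
        t = np.array([m.time for m in meas])
        y = np.array([m.y for m in meas])
        mu = mean_trajectory(t, params.long)
        cov = params.long.sigma**2 * np.eye(t.size) + params.sigma_u**2
        expected += stats.multivariate_normal.logpdf(y, mu, cov)
        theta = params.surv.gamma0 + params.surv.gamma["ar"] * s.ar
        p = params.surv.p
        if s.event:
            expected += np.log(p) + theta + (p - 1) * np.log(s.event_time)
        expected -= np.exp(theta) * s.event_time ** p
    assert total_loglik(ds, params) == pytest.approx(expected, abs=1e-6)


def test_scale_invariance_up_to_jacobian(simple_params):
    """Rescaling the biomarker scale changes the log-likelihood by exactly
    n_obs*log(c) (the change-of-variable Jacobian)."""
    ds = make_dataset(n_subjects=3, n_per_subject=4, seed=3)
    c = 10.0
    mdf = ds.measurement_frame()
    mdf["y"] = mdf["y"] / c
    ds_scaled = dataset_from_frames(ds.subject_frame(), mdf,
                                    ds.scale_factor * c)
    p = simple_params
    scaled = JointParams(
        long=LongFixedEffects(p.long.beta0 / c, p.long.beta1 / c,
                              p.long.beta2 / c, p.long.beta3 / c,
                              p.long.knot, p.long.sigma / c),
        surv=SurvFixedEffects(p.surv.gamma0, dict(p.surv.gamma), p.surv.p),
        assoc=Association(p.assoc.alpha * c),
        sigma_u=p.sigma_u / c,
    )
    ll = total_loglik(ds, p)
    ll_scaled = total_loglik(ds_scaled, scaled)
    assert ll_scaled - ll == pytest.approx(ds.n_obs * np.log(c), abs=1e-6)


def test_nonfinite_integrand_raises_numerical_error():
    params = JointParams(
        long=LongFixedEffects(0.0, 0.0, 0.0, 0.0, sigma=1.0),
        surv=SurvFixedEffects(800.0, {}, 1.0),   # e^theta overflows
        assoc=Association(0.0),
        sigma_u=1.0,
    )
    sub = make_subject(event_time=10.0, event=0)
    with pytest.raises(NumericalError):
        subject_marginal_loglik(sub, (), params)
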