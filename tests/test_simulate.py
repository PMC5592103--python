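import numpy as np
import pytest
from scipy import stats

from scljoint import (
    Association,
    CohortSpec,
    CovariateModel,
    JointParams,
    LongFixedEffects,
    ScheduleRule,
    SurvFixedEffects,
    generate_covariates,
    generate_dataset,
    generate_schedule,
    mean_trajectory,
    reference_truth_params,
    write_dataset,
    read_dataset,
)


def test_reference_truth_anchored_values(truth):
    assert np.exp(truth.surv.gamma["ar"]) == pytest.approx(1.54, rel=1e-12)
    assert truth.long.beta0 == 0.36
    assert truth.long.beta1 == 0.13
    assert truth.long.beta3 == -0.02
    assert truth.assoc.alpha == -0.8
    assert truth.long.knot == 10.0


def test_reference_gamma0_calibration(truth):
    """Baseline log-rate solves for a 40% event fraction at 72 months."""
    p, g0, gar = truth.surv.p, truth.surv.gamma0, truth.surv.gamma["ar"]
    frac = sum(
        w * (1.0 - np.exp(-np.exp(g0 + gar * x) * 72.0 ** p))
        for x, w in ((0, 27 / 38), (1, 11 / 38))
    )
    assert frac == pytest.approx(0.4, abs=1e-10)


def test_covariate_margins(truth):
    spec = CohortSpec(10_000, truth, seed=5)
    df = generate_covariates(spec, np.random.default_rng(5))
    p = 28 / 38
    se = np.sqrt(p * (1 - p) / len(df))
    assert abs(df["sex"].mean() - p) < 3 * se
    assert 12.0 <= df["age"].min() and df["age"].max() <= 70.0
    assert 12.0 <= df["bmi"].min() and df["bmi"].max() <= 40.0
    assert set(df["disease"]) <= {"pulmonary_fibrosis", "bronchiectasis", "copd"}


def test_degenerate_covariate_model_constant(truth):
    cm = CovariateModel(p_male=1.0, age_sd=0.0, bmi_sd=0.0, p_ar=0.0,
                        p_cmv=1.0,
                        disease_probs={"pulmonary_fibrosis": 0.0,
                                       "bronchiectasis": 1.0, "copd": 0.0})
    spec = CohortSpec(50, truth, covariate_model=cm, seed=1)
    df = generate_covariates(spec, np.random.default_rng(1))
    assert (df["sex"] == 1).all() and (df["ar"] == 0).all() and (df["cmv"] == 1).all()
    assert df["age"].nunique() == 1 and df["bmi"].nunique() == 1
    assert (df["disease"] == "bronchiectasis").all()


def test_disease_probs_must_sum_to_one(truth):
    cm = CovariateModel(disease_probs={"pulmonary_fibrosis": 0.34,
                                       "bronchiectasis": 0.42, "copd": 0.23})
    with pytest.raises(ValueError, match="sum to 1"):
        CohortSpec(10, truth, covariate_model=cm)


def test_schedule_truncation_and_order():
    rule = ScheduleRule()
    rng = np.random.default_rng(0)
    t = generate_schedule(1.0, rule, rng)
    assert 3 <= t.size <= 5 and (t > 0).all() and (t <= 1.0).all()
    for seed in range(20):
        t = generate_schedule(12.0, rule, np.random.default_rng(seed))
        # 13 weekly + 9 monthly visits, +/- jitter losses at the edges
        assert 20 <= t.size <= 23
        assert (np.diff(t) > 0).all() and (t > 0).all()


def test_schedule_post_year_gaps():
    rule = ScheduleRule(jitter=0.0)
    t = generate_schedule(48.0, rule, np.random.default_rng(3))
    late = t[t > 12.0]
    gaps = np.diff(np.concatenate([[12.0], late]))
    assert (gaps >= 1.0 - 1e-9).all() and (gaps <= 4.0 + 1e-9).all()


def test_same_seed_bit_identical(truth):
    spec = CohortSpec(20, truth, seed=77)
    ds1, t1 = generate_dataset(spec)
    ds2, t2 = generate_dataset(CohortSpec(20, truth, seed=77))
    assert ds1 == ds2
    assert t1.equals(t2)


def test_noise_free_cohort_lies_on_trajectory():
    truth = reference_truth_params()
    noise_free = JointParams(
        long=LongFixedEffects(truth.long.beta0, truth.long.beta1,
                              truth.long.beta2, truth.long.beta3,
                              truth.long.knot, sigma=0.0),
        surv=truth.surv, assoc=Association(0.0), sigma_u=0.0,
    )
    ds, _ = generate_dataset(CohortSpec(20, noise_free, seed=2))
    for m in ds.measurements:
        assert m.y == pytest.approx(
            mean_trajectory(m.time, noise_free.long), abs=1e-12)


def test_event_fraction_from_closed_form_inversion():
    # gamma0 chosen so S(72) = 0.5 for every subject (no covariates, alpha=0)
    p = 1.2
    gamma0 = float(np.log(np.log(2.0)) - p * np.log(72.0))
    tr = JointParams(
        long=reference_truth_params().long,
        surv=SurvFixedEffects(gamma0, {}, p),
        assoc=Association(0.0), sigma_u=0.1,
    )
    n = 2000
    ds, _ = generate_dataset(CohortSpec(n, tr, seed=8, admin_censor_time=72.0))
    frac = ds.subject_frame()["event"].mean()
    se = np.sqrt(0.25 / n)
    assert abs(frac - 0.5) < 3 * se


def test_latent_event_times_match_analytic_survival():
    # all subjects share theta (u fixed at 0, no covariate effects)
    p = 1.2
    gamma0 = -5.0
    tr = JointParams(
        long=reference_truth_params().long,
        surv=SurvFixedEffects(gamma0, {}, p),
        assoc=Association(0.0), sigma_u=0.0,
    )
    # short horizon: latent times are recorded uncensored in the truth table
    _, latent = generate_dataset(CohortSpec(5000, tr, seed=31,
                                            admin_censor_time=1.0))
    T = np.sort(latent["latent_event_time"].to_numpy())
    ecdf = np.arange(1, T.size + 1) / T.size
    F = 1.0 - np.exp(-np.exp(gamma0) * T ** p)
    assert np.max(np.abs(ecdf - F)) < 0.03


def test_informative_dropout_correlation_sign(truth):
    """Stronger negative alpha links high latent intercepts to long survival."""
    strong = truth.copy()
    strong.assoc.alpha = -2.0
    strong.sigma_u = 0.3
    ds, _ = generate_dataset(CohortSpec(2000, strong, seed=13,
                                        admin_censor_time=72.0))
    sdf = ds.subject_frame()
    mdf = ds.measurement_frame()
    mu0 = mean_trajectory(mdf["time"].to_numpy(), strong.long)
    resid = (mdf["y"].to_numpy() - mu0)
    mean_resid = (
        mdf.assign(r=resid).groupby("subject_id")["r"].mean()
        .reindex(sdf["subject_id"]).to_numpy()
    )
    keep = np.isfinite(mean_resid)
    r = stats.spearmanr(mean_resid[keep], sdf["event_time"].to_numpy()[keep]).statistic
    assert r > 0.05  # sign of -alpha


def test_generated_cohort_round_trips_and_validates(tmp_path, small_cohort):
    ds, _ = small_cohort
    ds.validate()
    lp, sp = tmp_path / "l.csv", tmp_path / "s.csv"
    write_dataset(ds, lp, sp)
    back = read_dataset(lp, sp, ds.scale_factor)
    assert back.n_dropped_post_event == 0
    assert back.n_subjects == ds.n_subjects and back.n_obs == ds.n_obs


def test_cohort_shape_resembles_study(small_cohort):
    """Measurement counts per subject span roughly the study's 4-64 range."""
    ds, _ = small_cohort
    counts = np.array(list(ds.counts_per_subject().values()))
    assert counts.max() <= 70
    assert np.median(counts) > 10


def test_cohort_spec_yaml_round_trip(tmp_path, truth):
    spec = CohortSpec(25, truth, seed=3, admin_censor_time=60.0)
    path = tmp_path / "spec.yaml"
    spec.to_yaml(path)
    back = CohortSpec.from_yaml(path)
    assert back.n_subjects == 25 and back.seed == 3
    assert back.truth.to_dict() == truth.to_dict()
    ds1, _ = generate_dataset(spec)
    ds2, _ = generate_dataset(back)
    assert ds1 == ds2
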