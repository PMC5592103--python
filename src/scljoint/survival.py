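"""Weibull proportional-hazards submodel with a shared random effect.

The hazard for subject i at time t (months) is

    h_i(t) = p * exp(theta_i) * t^(p-1),
    theta_i = gamma0 + sum_k gamma_k x_ik + alpha * u_i,

i.e. a Weibull baseline with shape p, log-hazard covariate coefficients gamma
(so HR for covariate k is e^{gamma_k}) and the shared random intercept u_i
entering through the association parameter alpha.  The same model in its
accelerated-failure-time (AFT) parameterization has coefficients beta_aft with
gamma = -beta_aft * p; ``hr_from_aft`` performs that conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import DISEASE_LEVELS, DISEASE_REFERENCE, SubjectRecord

#: dummy columns a 3-level disease factor expands to (reference dropped)
DISEASE_DUMMIES = tuple(
    f"disease_{level}" for level in DISEASE_LEVELS if level != DISEASE_REFERENCE
)


@dataclass
class SurvFixedEffects:
    """Log-baseline intercept, covariate log-hazard coefficients, shape p."""

    gamma0: float
    gamma: dict[str, float] = field(default_factory=dict)
    p: float = 1.0

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise ValueError("Weibull shape p must be > 0")


@dataclass
class Association:
    """Coefficient of the shared random effect in the log hazard."""

    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite")


def expand_covariates(subject: SubjectRecord | Mapping[str, object]) -> dict[str, float]:
    """Numeric covariate vector with the disease factor reference-coded."""
    if isinstance(subject, SubjectRecord):
        values = {c: getattr(subject, c) for c in ("sex", "age", "bmi", "ar", "cmv", "disease")}
    else:
        values = dict(subject)
    out: dict[str, float] = {}
    for name, v in values.items():
        if name == "disease":
            for dummy in DISEASE_DUMMIES:
                out[dummy] = 1.0 if f"disease_{v}" == dummy else 0.0
        else:
            out[name] = float(v)
    return out


def survival_design(subject_df: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str]]:
    """Design matrix (no intercept column) for the named covariates.

    ``disease`` expands to reference-coded dummies; returns the matrix and the
    expanded column names in order.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov == "disease":
            for dummy in DISEASE_DUMMIES:
                level = dummy.removeprefix("disease_")
                cols.append((subject_df["disease"] == level).to_numpy(dtype=float))
                names.append(dummy)
        else:
            if cov not in subject_df.columns:
                raise KeyError(f"covariate {cov!r} not in subject table")
            cols.append(subject_df[cov].to_numpy(dtype=float))
            names.append(cov)
    X = np.column_stack(cols) if cols else np.empty((len(subject_df), 0))
    return X, names


def linear_predictor(
    x: Mapping[str, float] | SubjectRecord,
    sfx: SurvFixedEffects,
    assoc: Association,
    u: float = 0.0,
) -> float:
    """Log-rate theta = gamma0 + sum_k gamma_k x_k + alpha*u."""
    xv = expand_covariates(x) if isinstance(x, SubjectRecord) else dict(x)
    theta = sfx.gamma0
    for name, coef in sfx.gamma.items():
        if name not in xv:
            raise KeyError(f"covariate {name!r} required by the model is missing")
        theta += coef * float(xv[name])
    return theta + assoc.alpha * u


def hazard(t, theta: float, p: float):
    """Weibull hazard p*e^theta*t^(p-1); strictly positive for t > 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("hazard is defined for t > 0")
    if p <= 0:
        raise ValueError("shape p must be > 0")
    out = p * np.exp(theta) * t ** (p - 1.0)
    return float(out) if out.ndim == 0 else out


def cumulative_hazard(t, theta: float, p: float):
    """H(t) = e^theta * t^p (closed form)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("cumulative hazard is defined for t >= 0")
    out = np.exp(theta) * t ** p
    return float(out) if out.ndim == 0 else out


def survival(t, theta: float, p: float):
    """S(t) = exp(-H(t)); S(0) = 1, nonincreasing."""
    out = np.exp(-cumulative_hazard(t, theta, p))
    return float(out) if np.ndim(out) == 0 else out


def surv_loglik_given_u(
    subject: SubjectRecord,
    sfx: SurvFixedEffects,
    assoc: Association,
    u: float = 0.0,
) -> float:
    """Censored-data log-likelihood: event*log h(T) - H(T)."""
    theta = linear_predictor(subject, sfx, assoc, u)
    T = subject.event_time
    ll = -cumulative_hazard(T, theta, sfx.p)
    if subject.event:
        ll += np.log(hazard(T, theta, sfx.p))
    return float(ll)


def hr_from_aft(beta_aft: float, p: float) -> float:
    """Hazard ratio e^(-beta_aft*p) for a Weibull AFT-scale coefficient.

    Equivalent to e^gamma under the identity gamma = -beta_aft*p relating the
    AFT and proportional-hazards parameterizations of the same Weibull model.
    """
    if p <= 0:
        raise ValueError("shape p must be > 0")
    return float(np.exp(-beta_aft * p))


def sample_event_time(theta, p: float, rng: np.random.Generator, size=None):
    """Inverse-CDF Weibull draw(s): T = (E/e^theta)^(1/p), E ~ Exp(1).

    The resulting survival function is exp(-e^theta * t^p).
    """
    if p <= 0:
        raise ValueError("shape p must be > 0")
    E = rng.exponential(1.0, size=size)
    out = (E / np.exp(theta)) ** (1.0 / p)
    return float(out) if np.ndim(out) == 0 else out
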