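"""Full parameter set of the joint model, with YAML-friendly (de)serialization."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .longitudinal import LongFixedEffects
from .survival import Association, SurvFixedEffects


@dataclass
class JointParams:
    """All parameters of the joint model.

    ``sigma_u`` is the SD of the shared random intercept u_i ~ N(0, sigma_u^2)
    (model-scale units).  A value of exactly 0 is allowed only for the reduced
    model without a random effect.
    """

    long: LongFixedEffects
    surv: SurvFixedEffects
    assoc: Association
    sigma_u: float

    def __post_init__(self) -> None:
        if self.sigma_u < 0 or not np.isfinite(self.sigma_u):
            raise ValueError("sigma_u must be finite and >= 0")

    def copy(self) -> "JointParams":
        return JointParams(
            long=replace(self.long),
            surv=SurvFixedEffects(self.surv.gamma0, dict(self.surv.gamma), self.surv.p),
            assoc=Association(self.assoc.alpha),
            sigma_u=self.sigma_u,
        )

    def to_dict(self) -> dict:
        return {
            "long": {
                "beta0": self.long.beta0,
                "beta1": self.long.beta1,
                "beta2": self.long.beta2,
                "beta3": self.long.beta3,
                "knot": self.long.knot,
                "sigma": self.long.sigma,
            },
            "surv": {
                "gamma0": self.surv.gamma0,
                "gamma": dict(self.surv.gamma),
                "p": self.surv.p,
            },
            "alpha": self.assoc.alpha,
            "sigma_u": self.sigma_u,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "JointParams":
        return cls(
            long=LongFixedEffects(**d["long"]),
            surv=SurvFixedEffects(
                gamma0=d["surv"]["gamma0"],
                gamma=dict(d["surv"].get("gamma", {})),
                p=d["surv"]["p"],
            ),
            assoc=Association(d.get("alpha", 0.0)),
            sigma_u=d["sigma_u"],
        )
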