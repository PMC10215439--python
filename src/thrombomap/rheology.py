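"""Carreau-Yasuda shear-thinning viscosity model for blood.

The model interpolates between a zero-shear plateau ``mu_0`` and an
infinite-shear plateau ``mu_inf``:

    mu(g) = mu_inf + (mu_0 - mu_inf) * (1 + (lambda*g)**a) ** ((n - 1) / a)

with relaxation time ``lambda`` (s), Yasuda exponent ``a`` and power index
``n``; ``n < 1`` gives shear-thinning behaviour. Default constants are the
blood parameter set commonly used in abdominal-aortic CFD studies.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RheologyParams", "BLOOD", "carreau_yasuda_viscosity"]


@dataclass(frozen=True)
class RheologyParams:
    """Carreau-Yasuda material constants.

    mu_inf, mu_0 in Pa*s; lam in s; a, n dimensionless.
    """

    mu_inf: float = 0.00345
    mu_0: float = 0.056
    lam: float = 1.902
    a: float = 1.25
    n: float = 0.22

    def __post_init__(self) -> None:
        if not (self.mu_0 > self.mu_inf > 0):
            raise ValueError("require mu_0 > mu_inf > 0")
        if self.lam <= 0:
            raise ValueError("relaxation time lambda must be positive")
        if self.a <= 0:
            raise ValueError("Yasuda exponent a must be positive")
        if not (0 < self.n < 1):
            raise ValueError("power index n must lie in (0, 1) for shear-thinning")


#: Blood at 37 deg C, the default parameter set.
BLOOD = RheologyParams()


def carreau_yasuda_viscosity(gamma_dot, params: RheologyParams = BLOOD):
    """Evaluate the Carreau-Yasuda viscosity at shear rate ``gamma_dot`` (1/s).

    Vectorises over arrays. Returns Pa*s; a scalar input yields a scalar.

    Raises
    ------
    ValueError
        If any shear rate is negative.
    """
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be nonnegative")
    mu = params.mu_inf + (params.mu_0 - params.mu_inf) * (
        1.0 + (params.lam * g) ** params.a
    ) ** ((params.n - 1.0) / params.a)
    if np.isscalar(gamma_dot):
        return float(mu)
    return mu
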