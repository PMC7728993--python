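"""Balloon/windkessel hemodynamic model and BOLD observation equation.

Each region carries four hemodynamic states downstream of its neuronal
activity z: a vasodilatory signal s, normalized inflow f, normalized venous
volume v, and normalized deoxyhemoglobin content q,

    ds/dt = z - kappa*s - gamma*(f - 1)
    df/dt = s
    dv/dt = (f - v**(1/alpha_g)) / tau_h
    dq/dt = (f*E(f, rho)/rho - v**(1/alpha_g) * q/v) / tau_h

with oxygen extraction E(f, rho) = 1 - (1 - rho)**(1/f), and the BOLD
signal (in % change from baseline)

    y = V0 * (k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v)).

The resting fixed point is (s, f, v, q) = (0, 1, 1, 1) with y = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError, StateDomainError

__all__ = ["HemodynamicParams", "balloon_drift", "bold_observe"]


@dataclass
class HemodynamicParams:
    """Balloon-model constants (classical 1.5 T defaults).

    kappa : rate of vasodilatory signal decay (1/s)
    gamma : rate of flow-dependent autoregulation (1/s)
    tau_h : mean venous transit time (s)
    alpha_g : Grubb's vessel stiffness exponent
    rho : resting oxygen extraction fraction
    V0 : resting venous blood volume fraction
    k1, k2, k3 : BOLD observation coefficients; defaults k1 = 7*rho,
        k2 = 2, k3 = 2*rho - 0.2.
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau_h: float = 2.0
    alpha_g: float = 0.32
    rho: float = 0.32
    V0: float = 0.04
    k1: float | None = None
    k2: float = 2.0
    k3: float | None = None

    def __post_init__(self):
        if self.k1 is None:
            self.k1 = 7.0 * self.rho
        if self.k3 is None:
            self.k3 = 2.0 * self.rho - 0.2
        for name in ("kappa", "gamma", "tau_h", "V0"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if not 0 < self.alpha_g < 1:
            raise InvalidParameterError("alpha_g must lie in (0, 1)")
        if not 0 < self.rho < 1:
            raise InvalidParameterError("rho must lie in (0, 1)")


def balloon_drift(h, z, p: HemodynamicParams, kappa=None, tau_h=None):
    """Hemodynamic drift (ds, df, dv, dq) for state ``h = (s, f, v, q)``.

    ``h`` may be a flat 4-vector or an array whose last axis has length 4
    (vectorized over regions). ``kappa`` / ``tau_h`` optionally override the
    shared constants element-wise (used for per-region estimated scalings).
    """
    h = np.asarray(h, dtype=float)
    s, f, v, q = h[..., 0], h[..., 1], h[..., 2], h[..., 3]
    if np.any(f <= 0) or np.any(v <= 0) or np.any(q <= 0):
        raise StateDomainError("hemodynamic states f, v, q must stay positive")
    kappa = p.kappa if kappa is None else kappa
    tau_h = p.tau_h if tau_h is None else tau_h
    E = 1.0 - (1.0 - p.rho) ** (1.0 / f)
    fv = v ** (1.0 / p.alpha_g)  # outflow
    ds = z - kappa * s - p.gamma * (f - 1.0)
    df = s
    dv = (f - fv) / tau_h
    dq = (f * E / p.rho - fv * q / v) / tau_h
    return np.stack([ds, df, dv, dq], axis=-1)


def bold_observe(h, p: HemodynamicParams):
    """BOLD signal (% change) from hemodynamic state(s) ``h = (s, f, v, q)``."""
    h = np.asarray(h, dtype=float)
    v, q = h[..., 2], h[..., 3]
    if np.any(v <= 0) or np.any(q <= 0):
        raise StateDomainError("v and q must be positive")
    return p.V0 * (p.k1 * (1.0 - q) + p.k2 * (1.0 - q / v) + p.k3 * (1.0 - v))
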