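"""Model parameters and the pointwise nonlinearities of the gated RNN.

The network couples three population variables per unit: an internal state
``h``, an update-gate drive ``z`` and an output-gate drive ``r``.  The
activation is ``phi(x) = tanh(g_h x + beta_h)`` and the gates are logistic
sigmoids ``sigma(x) = 1 / (1 + exp(-alpha x + beta))``.  Gate gains may be
``math.inf``, in which case the gate is a Heaviside step (value 1/2 exactly
at the threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "NetworkParams",
    "gate_value",
    "gate_deriv",
    "activation",
    "activation_deriv",
]


class ParameterError(ValueError):
    """Raised for invalid model parameters."""


@dataclass(frozen=True)
class NetworkParams:
    """Scalar parameters of the gated RNN.

    Attributes
    ----------
    n_units:
        Network size ``N`` (at least 2).
    g_h:
        Gain of the activation ``phi(x) = tanh(g_h x + beta_h)``.
    alpha_z, alpha_r:
        Gate gains; nonnegative, ``math.inf`` selects a binary (Heaviside)
        gate.
    beta_h, beta_z, beta_r:
        Biases of the activation and the two gates.
    tau_z, tau_r:
        Gate time constants in units of the ``h`` time constant (which is 1).
    seed:
        Root seed; all randomness (couplings, initial conditions, inputs,
        trial ensembles) is derived from it through named substreams.
    """

    n_units: int
    g_h: float
    alpha_z: float = 0.0
    alpha_r: float = 0.0
    beta_h: float = 0.0
    beta_z: float = 0.0
    beta_r: float = 0.0
    tau_z: float = 1.0
    tau_r: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_units) < 2:
            raise ParameterError(f"n_units must be >= 2, got {self.n_units}")
        if self.tau_z <= 0 or self.tau_r <= 0:
            raise ParameterError("gate time constants must be positive")
        if self.g_h < 0:
            raise ParameterError("g_h must be nonnegative")
        for name in ("alpha_z", "alpha_r"):
            a = getattr(self, name)
            if not (a >= 0):  # also rejects NaN
                raise ParameterError(f"{name} must be nonnegative or inf")

    def replace(self, **kwargs) -> "NetworkParams":
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        d = {
            "n_units": int(self.n_units),
            "g_h": float(self.g_h),
            "alpha_z": self.alpha_z,
            "alpha_r": self.alpha_r,
            "beta_h": float(self.beta_h),
            "beta_z": float(self.beta_z),
            "beta_r": float(self.beta_r),
            "tau_z": float(self.tau_z),
            "tau_r": float(self.tau_r),
            "seed": int(self.seed),
        }
        # JSON has no inf literal; serialize as string flag
        for k in ("alpha_z", "alpha_r"):
            d[k] = "inf" if math.isinf(d[k]) else float(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        d = dict(d)
        for k in ("alpha_z", "alpha_r"):
            if isinstance(d.get(k), str):
                d[k] = math.inf
        return cls(**d)


def gate_value(x, alpha: float, beta: float = 0.0):
    """Sigmoidal gate ``sigma(x) = [1 + exp(-alpha x + beta)]**-1``.

    For ``alpha = inf`` the gate is the Heaviside step with threshold at
    ``x = 0`` (the ``beta/alpha -> 0`` limit) and the tie value 1/2 exactly
    at the threshold.
    """
    x = np.asarray(x, dtype=float)
    if math.isinf(alpha):
        out = np.where(x > 0, 1.0, np.where(x < 0, 0.0, 0.5))
        return out if out.ndim else float(out)
    # overflow-safe logistic
    u = alpha * x - beta
    out = np.empty_like(x)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out if out.ndim else float(out)


def gate_deriv(x, alpha: float, beta: float = 0.0):
    """Derivative of :func:`gate_value` with respect to ``x``.

    For ``alpha = inf`` the derivative is zero everywhere except the
    threshold, where the distributional delta is replaced by zero (the
    measure-zero point cannot be represented pointwise).
    """
    x = np.asarray(x, dtype=float)
    if math.isinf(alpha):
        out = np.zeros_like(x)
        return out if out.ndim else float(out)
    s = gate_value(x, alpha, beta)
    out = alpha * s * (1.0 - s)
    return out if np.ndim(out) else float(out)


def activation(x, g_h: float, beta_h: float = 0.0):
    """Activation ``phi(x) = tanh(g_h x + beta_h)``."""
    return np.tanh(g_h * np.asarray(x, dtype=float) + beta_h)


def activation_deriv(x, g_h: float, beta_h: float = 0.0):
    """``phi'(x) = g_h sech^2(g_h x + beta_h)``."""
    t = np.tanh(g_h * np.asarray(x, dtype=float) + beta_h)
    return g_h * (1.0 - t * t)
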