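"""Kinetic models of the repressilator and its light-controllable variant.

The repressilator is a ring of three transcription factors (LacI, TetR, cI in
the classic *E. coli* implementation) in which each protein represses the
production of the next.  In the protein-only description the concentrations
``x, y, z`` — measured in units of the promoter dissociation constant K — obey

    dx/dt = beta / (1 + z**n) - alpha * x
    dy/dt = beta / (1 + x**n) - alpha * y
    dz/dt = beta / (1 + y**n) - alpha * z

with ``alpha`` the dilution rate set by cell growth, ``beta`` the maximal
production rate and ``n`` the Hill cooperativity.  For steep repression the
system has a limit cycle; in the digital limit (n -> inf, beta/alpha >> 1) the
oscillation is a relaxation cycle with amplitude ``beta/alpha`` and period
``3 ln(beta/alpha) / alpha``.

The optorepressilator adds a fourth node: a second copy of the first repressor
(``x_prime``) expressed from a light-driven promoter at rate ``beta_prime``.
``x`` and ``x_prime`` add up to repress ``y``; ``x_prime`` itself is decoupled
from the ring and relaxes to ``beta_prime / alpha`` under steady light:

    dy/dt       = beta / (1 + (x + x_prime)**n) - alpha * y
    dx_prime/dt = beta_prime - alpha * x_prime

When ``beta_prime / alpha > 1`` (in the digital approximation) the extra
repressor breaks the limit cycle and the system collapses to the fixed point
``(x, y, z) = (0, 0, beta/alpha)`` — the basis for optical phase resetting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "RepressilatorParams",
    "OptoParams",
    "make_state",
    "repressilator_rhs",
    "optorepressilator_rhs",
    "digital_period",
    "digital_amplitude",
    "symmetric_fixed_point",
    "green_fixed_point",
    "limit_cycle_broken",
]


@dataclass(frozen=True)
class RepressilatorParams:
    """Kinetic constants of the three-node ring.

    Parameters
    ----------
    alpha : float
        Dilution/decay rate in 1/h.  Defaults to the experimentally measured
        mean growth rate 0.75 1/h.
    beta : float
        Maximal production rate in K-units per hour.  The default 300 1/h
        places the free-running period near 17.5 h at ``n = 3``.
    n : float
        Hill cooperativity of repression (dimensionless, >= 1).
    """

    alpha: float = 0.75
    beta: float = 300.0
    n: float = 3.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not (self.beta > 0):
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not (self.n >= 1):
            raise ValueError(f"n must be >= 1, got {self.n}")


@dataclass(frozen=True)
class OptoParams:
    """Parameters of the four-node light-controllable ring.

    ``beta_prime_on`` is the production rate of the light-inducible repressor
    copy under green light; ``beta_prime_off`` the residual rate under red
    light (zero by default: the final construct's leakage is below
    background).
    """

    base: RepressilatorParams = field(default_factory=RepressilatorParams)
    beta_prime_on: float = 80.0
    beta_prime_off: float = 0.0

    def __post_init__(self) -> None:
        if self.beta_prime_on < 0 or self.beta_prime_off < 0:
            raise ValueError("beta_prime rates must be >= 0")
        if self.beta_prime_off > self.beta_prime_on:
            raise ValueError("beta_prime_off must not exceed beta_prime_on")

    @property
    def alpha(self) -> float:
        return self.base.alpha

    @property
    def beta(self) -> float:
        return self.base.beta

    @property
    def n(self) -> float:
        return self.base.n

    # -- flat key/value serialization -------------------------------------
    def to_dict(self) -> dict:
        return {
            "alpha": self.base.alpha,
            "beta": self.base.beta,
            "n": self.base.n,
            "beta_prime_on": self.beta_prime_on,
            "beta_prime_off": self.beta_prime_off,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OptoParams":
        known = {"alpha", "beta", "n", "beta_prime_on", "beta_prime_off"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        base = RepressilatorParams(
            alpha=float(d.get("alpha", 0.75)),
            beta=float(d.get("beta", 300.0)),
            n=float(d.get("n", 3.0)),
        )
        return cls(
            base=base,
            beta_prime_on=float(d.get("beta_prime_on", 80.0)),
            beta_prime_off=float(d.get("beta_prime_off", 0.0)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "OptoParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def make_state(x: float, y: float, z: float, x_prime: float = 0.0) -> np.ndarray:
    """Pack repressor concentrations into the (x, y, z, x_prime) state vector."""
    state = np.array([x, y, z, x_prime], dtype=float)
    if np.any(state < 0):
        raise ValueError("concentrations must be >= 0")
    return state


def _check_finite(state: np.ndarray) -> None:
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state passed to rhs")


def repressilator_rhs(state, params: RepressilatorParams) -> np.ndarray:
    """Time derivative of the three-node ring at ``state = (x, y, z)``."""
    s = np.asarray(state, dtype=float)
    if s.shape != (3,):
        raise ValueError(f"expected state of shape (3,), got {s.shape}")
    _check_finite(s)
    x, y, z = s
    a, b, n = params.alpha, params.beta, params.n
    return np.array(
        [
            b / (1.0 + z**n) - a * x,
            b / (1.0 + x**n) - a * y,
            b / (1.0 + y**n) - a * z,
        ]
    )


def optorepressilator_rhs(state, params: OptoParams, beta_prime: float) -> np.ndarray:
    """Time derivative of the four-node ring at ``state = (x, y, z, x_prime)``.

    ``beta_prime`` is the instantaneous light-driven production rate; the
    ``y`` equation sees the summed repressor ``x + x_prime`` while the
    ``x_prime`` equation is fully decoupled from the ring.
    """
    s = np.asarray(state, dtype=float)
    if s.shape != (4,):
        raise ValueError(f"expected state of shape (4,), got {s.shape}")
    _check_finite(s)
    if beta_prime < 0:
        raise ValueError("beta_prime must be >= 0")
    x, y, z, w = s
    a, b, n = params.alpha, params.beta, params.n
    return np.array(
        [
            b / (1.0 + z**n) - a * x,
            b / (1.0 + (x + w) ** n) - a * y,
            b / (1.0 + y**n) - a * z,
            beta_prime - a * w,
        ]
    )


def digital_period(params: RepressilatorParams) -> float:
    """Relaxation-oscillation period ``3 ln(beta/alpha) / alpha`` (digital limit)."""
    ratio = params.beta / params.alpha
    if ratio <= 1:
        raise ValueError("digital period requires beta/alpha > 1")
    return 3.0 * math.log(ratio) / params.alpha


def digital_amplitude(params: RepressilatorParams) -> float:
    """Relaxation-oscillation amplitude ``beta/alpha`` (digital limit)."""
    ratio = params.beta / params.alpha
    if ratio <= 1:
        raise ValueError("digital amplitude requires beta/alpha > 1")
    return ratio


def symmetric_fixed_point(params: RepressilatorParams, tol: float = 1e-10) -> float:
    """Concentration ``s*`` solving ``beta / (1 + s**n) = alpha * s``.

    At ``x = y = z = s*`` the three-node rhs vanishes; for steep repression
    this fixed point is unstable and surrounded by the limit cycle.
    """
    a, b, n = params.alpha, params.beta, params.n

    def f(s: float) -> float:
        return b / (1.0 + s**n) - a * s

    hi = b / a  # f(hi) < 0 whenever b/a > 0
    return float(brentq(f, 0.0, hi, xtol=tol))


def green_fixed_point(params: OptoParams) -> np.ndarray:
    """Stationary state under constant green light, ``(0, 0, beta/alpha, beta'/alpha)``.

    Exact in the digital limit; at finite ``n`` the x-equation keeps a Hill
    leak ``beta / (1 + (beta/alpha)**n)`` which is negligible for the default
    parameters.
    """
    if not limit_cycle_broken(params):
        raise ValueError(
            "green light does not break the limit cycle (beta_prime_on/alpha <= 1)"
        )
    a = params.alpha
    return np.array([0.0, 0.0, params.beta / a, params.beta_prime_on / a])


def limit_cycle_broken(params: OptoParams) -> bool:
    """Digital-approximation criterion for green light arresting oscillation."""
    return params.beta_prime_on / params.alpha > 1.0
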