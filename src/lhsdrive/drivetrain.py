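"""Mechanistic chain from community transmission to cycle velocities.

The engine-drivetrain model treats the translational hub as an engine
whose capacity is converted into motion of four learning cycles --
clinical care, education, research, governance -- through a variable
transmission set by community-empowerment maturity M (the CTI, 0-1):

* transmission efficiency ``T(M) = 1 / (1 + exp(-a (M - m0)))`` is the
  proportion of institutional capacity converted into translational
  effort (logistic in M);
* friction reduction ``R(M) = r_max * M^eta / (M^eta + c^eta)`` is the
  fractional reduction of contextual friction (Hill-type saturation);
* the direct drive of cycle j is the saturating resource balance
  ``f_j = v_max_j * E_j T / (E_j T + F_j (1 - R))`` where E_j is engine
  power allocated to the cycle and F_j contextual friction;
* cross-cycle learning spillovers K (rows receive, columns influence,
  zero diagonal, spectral radius < 1) couple the cycles, and the
  realized velocities solve ``v = (I - K)^{-1} f``.

All velocity vectors use the fixed cycle order
(clinical, education, research, governance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import StabilityError, ValidationError

N_WHEELS = 4
WHEELS = ("clinical", "education", "research", "governance")


@dataclass(frozen=True)
class TransmissionParams:
    """Constants of the transmission and friction-reduction curves.

    a : logistic slope (dimensionless), > 0
    m0 : logistic midpoint on the CTI scale, in [0, 1]
    r_max : maximum attainable friction reduction, in [0, 1)
    eta : Hill exponent, > 0
    c : Hill half-saturation constant on the CTI scale, in (0, 1]
    """

    a: float
    m0: float
    r_max: float
    eta: float
    c: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValidationError(f"logistic slope a must be > 0 (got {self.a})")
        if not 0.0 <= self.m0 <= 1.0:
            raise ValidationError(f"midpoint m0 must lie in [0, 1] (got {self.m0})")
        if not 0.0 <= self.r_max < 1.0:
            raise ValidationError(f"r_max must lie in [0, 1) (got {self.r_max})")
        if not self.eta > 0:
            raise ValidationError(f"Hill exponent eta must be > 0 (got {self.eta})")
        if not self.c > 0:
            raise ValidationError(f"half-saturation c must be > 0 (got {self.c})")


@dataclass(frozen=True)
class WheelAllocation:
    """Per-cycle engine power, contextual friction, and velocity ceiling.

    E and F are in arbitrary (but common) positive resource units; only
    their ratio enters the drive.  v_max is in month^-1.
    """

    engine_power: tuple[float, float, float, float]
    friction: tuple[float, float, float, float]
    v_max: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for name, vec in (("engine_power", self.engine_power),
                          ("friction", self.friction), ("v_max", self.v_max)):
            if len(vec) != N_WHEELS:
                raise ValidationError(f"{name} must have {N_WHEELS} entries")
            if any(not x > 0 for x in vec):
                raise ValidationError(f"{name} entries must all be > 0 (got {vec})")


class CouplingMatrix:
    """Nonnegative 4x4 cross-cycle spillover matrix.

    ``K[i, j]`` is the proportional acceleration of receiving cycle i
    produced by activity in influencing cycle j.  The diagonal is zero
    (cycles do not self-amplify) and the spectral radius must be < 1
    for the coupled fixed point to exist.
    """

    def __init__(self, K: np.ndarray | list):
        K = np.asarray(K, dtype=float)
        if K.shape != (N_WHEELS, N_WHEELS):
            raise ValidationError(f"coupling matrix must be 4x4, got {K.shape}")
        if np.any(K < 0):
            raise ValidationError("coupling matrix entries must be nonnegative")
        if np.any(np.diag(K) != 0):
            raise ValidationError("coupling matrix diagonal must be zero")
        rho = spectral_radius(K)
        if rho >= 1.0:
            raise StabilityError(
                f"coupling matrix spectral radius {rho:.4f} >= 1: unstable"
            )
        self.K = K
        self.rho = rho

    def __array__(self, dtype=None, copy=None):
        return np.array(self.K, dtype=dtype)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CouplingMatrix(rho={self.rho:.4f})\n{self.K!r}"


def spectral_radius(K: np.ndarray | CouplingMatrix) -> float:
    """Largest eigenvalue modulus of a square matrix."""
    K = np.asarray(K, dtype=float)
    return float(np.max(np.abs(np.linalg.eigvals(K))))


def transmission_T(M, p: TransmissionParams):
    """Logistic transmission efficiency T(M) in (0, 1).

    Accepts a scalar or array of CTI values; strictly increasing in M
    with T(m0) = 1/2.
    """
    M = np.asarray(M, dtype=float)
    out = 1.0 / (1.0 + np.exp(-p.a * (M - p.m0)))
    return float(out) if out.ndim == 0 else out


def friction_R(M, p: TransmissionParams):
    """Hill-type friction reduction R(M) in [0, r_max).

    R(0) = 0, R(c) = r_max / 2, and R approaches r_max as M -> 1.
    """
    M = np.asarray(M, dtype=float)
    Me = np.power(M, p.eta)
    out = p.r_max * Me / (Me + p.c ** p.eta)
    return float(out) if out.ndim == 0 else out


def wheel_drive(M, alloc: WheelAllocation, p: TransmissionParams) -> np.ndarray:
    """Direct translational drive f of the four cycles, in month^-1.

    For scalar M returns shape (4,); for an array of n CTI values
    returns shape (n, 4).  Each f_j lies strictly inside (0, v_max_j).
    """
    M = np.asarray(M, dtype=float)
    E = np.asarray(alloc.engine_power, dtype=float)
    F = np.asarray(alloc.friction, dtype=float)
    vmax = np.asarray(alloc.v_max, dtype=float)
    T = np.atleast_1d(transmission_T(M, p))[..., None]
    R = np.atleast_1d(friction_R(M, p))[..., None]
    num = E * T
    den = num + F * (1.0 - R)
    if np.any(den <= 0):
        raise ValidationError("degenerate allocation: zero drive denominator")
    f = vmax * num / den
    return f[0] if M.ndim == 0 else f


def coupled_velocities(f: np.ndarray, K: CouplingMatrix | np.ndarray) -> np.ndarray:
    """Coupled cycle velocities solving (I - K) v = f.

    ``f`` may be a single 4-vector or an (n, 4) stack of drives; the
    same spillover matrix is applied to each row.  Refuses any K with
    spectral radius >= 1.
    """
    if not isinstance(K, CouplingMatrix):
        K = CouplingMatrix(K)  # validates nonnegativity, diagonal, stability
    f = np.asarray(f, dtype=float)
    if f.shape[-1] != N_WHEELS:
        raise ValidationError(f"drive vector must have {N_WHEELS} entries")
    A = np.eye(N_WHEELS) - K.K
    v = np.linalg.solve(A, f[..., None])[..., 0]
    return v
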