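"""Economic layer: innovation throughput, revenue, cost, and ROI.

Each cycle converts velocity into innovation counts through a
truncated-linear throughput function N_j = max(0, b0_j + b1_j v_j),
and into money through parameterized revenue and cost functions:

    R_j = rho0_j + rho1_j v_j + rho2_j N_j
    E_j = kappa0_j + kappa1_j v_j + kp PDCA_p + kd PDCA_d + ki PDCA_i

where the PDCA terms price the practice, data-analysis and
implementation phases of the improvement cycle at configurable
intensities (default 1 each).  ROI is revenue over expense, per cycle
and globally (ratio of sums); the mean of per-unit ratios is also
reported since the two differ for heterogeneous portfolios.  Currency
is abstract dollars, with no discounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drivetrain import N_WHEELS
from .errors import ValidationError


@dataclass(frozen=True)
class EconParams:
    """Per-cycle coefficients of the innovation, revenue and cost models.

    Arrays are in the cycle order (clinical, education, research,
    governance).  Revenue/cost units are dollars per period.
    """

    innovation_intercept: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    innovation_slope: tuple[float, ...] = (10.0, 10.0, 10.0, 10.0)
    revenue_base: tuple[float, ...] = (2000.0, 2000.0, 2000.0, 2000.0)
    revenue_velocity: tuple[float, ...] = (20000.0, 20000.0, 20000.0, 20000.0)
    revenue_innovation: tuple[float, ...] = (2000.0, 2000.0, 2000.0, 2000.0)
    cost_base: tuple[float, ...] = (5000.0, 5000.0, 5000.0, 5000.0)
    cost_velocity: tuple[float, ...] = (9000.0, 9000.0, 9000.0, 9000.0)
    pdca_practice_cost: float = 1000.0
    pdca_data_cost: float = 1000.0
    pdca_implementation_cost: float = 1000.0
    pdca_intensity: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("innovation_intercept", "innovation_slope", "revenue_base",
                     "revenue_velocity", "revenue_innovation", "cost_base",
                     "cost_velocity"):
            vec = getattr(self, name)
            if len(vec) != N_WHEELS:
                raise ValidationError(f"{name} must have {N_WHEELS} entries")
        if any(k < 0 for k in (self.pdca_practice_cost, self.pdca_data_cost,
                               self.pdca_implementation_cost)):
            raise ValidationError("PDCA phase costs must be nonnegative")
        if any(i < 0 for i in self.pdca_intensity):
            raise ValidationError("PDCA intensities must be nonnegative")


@dataclass
class EconResult:
    """Per-cycle and global economic outcomes for one project."""

    N: np.ndarray
    revenue: np.ndarray
    expense: np.ndarray
    roi: np.ndarray
    global_N: float = field(init=False)
    global_revenue: float = field(init=False)
    global_expense: float = field(init=False)
    global_roi: float = field(init=False)

    def __post_init__(self) -> None:
        self.global_N = float(np.sum(self.N))
        self.global_revenue = float(np.sum(self.revenue))
        self.global_expense = float(np.sum(self.expense))
        self.global_roi = (self.global_revenue / self.global_expense
                           if self.global_expense > 0 else 0.0)


def innovation_throughput(v: np.ndarray, params: EconParams) -> np.ndarray:
    """Expected innovation counts per cycle, truncated at zero.

    Counts are reported as reals (expected values) so downstream
    correlations stay smooth.  Vectorized over leading axes of ``v``.
    """
    v = np.asarray(v, dtype=float)
    b0 = np.asarray(params.innovation_intercept)
    b1 = np.asarray(params.innovation_slope)
    return np.maximum(0.0, b0 + b1 * v)


def revenues(v: np.ndarray, N: np.ndarray, params: EconParams) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    N = np.asarray(N, dtype=float)
    return (np.asarray(params.revenue_base)
            + np.asarray(params.revenue_velocity) * v
            + np.asarray(params.revenue_innovation) * N)


def expenses(v: np.ndarray, params: EconParams) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    ip, id_, ii = params.pdca_intensity
    pdca = (params.pdca_practice_cost * ip + params.pdca_data_cost * id_
            + params.pdca_implementation_cost * ii)
    return (np.asarray(params.cost_base)
            + np.asarray(params.cost_velocity) * v + pdca)


def wheel_economics(v: np.ndarray, N: np.ndarray, params: EconParams) -> EconResult:
    """Full economic outcome of one project's velocity profile.

    Per-cycle ROI is R_j / E_j; the global ROI is the ratio of summed
    revenue to summed expense.  A cycle with zero expense but nonzero
    revenue has no defined ROI and is rejected.
    """
    R = revenues(v, N, params)
    E = expenses(v, params)
    if np.any(R < 0) or np.any(E < 0):
        raise ValidationError("negative revenue or expense under these coefficients")
    roi = np.zeros_like(R)
    zero = E == 0
    if np.any(zero & (R > 0)):
        raise ValidationError("zero expense with nonzero revenue: ROI undefined")
    roi[~zero] = R[~zero] / E[~zero]
    return EconResult(N=np.asarray(N, dtype=float), revenue=R, expense=E, roi=roi)


def incremental_efficiency(v_before: np.ndarray, v_after: np.ndarray,
                           e_before: float, e_after: float,
                           weights=None) -> float:
    """Velocity gain per marginal dollar, Delta Vmean / Delta E.

    Uses the mission-weighted mean velocity; antisymmetric in the
    direction of the expense change.
    """
    from .metrics import MissionWeights
    weights = weights or MissionWeights()
    de = e_after - e_before
    if de == 0:
        raise ValidationError("zero expense delta: incremental efficiency undefined")
    alpha = np.asarray(weights.alpha)
    dv = float(np.dot(alpha, np.asarray(v_after, dtype=float))
               - np.dot(alpha, np.asarray(v_before, dtype=float)))
    return dv / de
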