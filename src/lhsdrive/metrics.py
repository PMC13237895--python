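"""Velocity-derived performance measures and system typology.

Two complementary efficiency indices summarize a four-cycle velocity
profile.  The gain index TEI-G = ||v||_W / ||f||_W measures the
amplification produced by cross-cycle spillovers (weighted Euclidean
norm by default; a weighted 1-norm, i.e. a ratio of weighted means, is
selectable).  The bottleneck index TEI-B = min_j v_j / sum_j alpha_j v_j
measures how far the slowest cycle drags the system below its
mission-weighted mean; it is at most 1, with equality exactly when all
cycles run at the same speed.  The global index is their product,
TEI = TEI-G x TEI-B.

Systems are classified into four states on the (TEI-G, TEI-B) plane:
Fragmented (low/low), Emerging (high G, low B), Functional (low G,
high B) and FullyIntegrated (high/high), using either fixed cuts or a
median split of the cohort; values at the cut classify as "high".

Milestone-level latencies are attributed to cycles through a
row-stochastic interpretation-weight matrix (8 milestones x 4 cycles),
which conserves total latency by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .drivetrain import N_WHEELS, WHEELS
from .errors import ValidationError

N_MILESTONES = 8
MILESTONES = tuple(f"K{i}" for i in range(1, N_MILESTONES + 1))

STATES = ("Fragmented", "Emerging", "Functional", "FullyIntegrated")

#: Interpretation weights of the eight canonical translational
#: milestones (community priority identification, design finalized,
#: regulatory approval, pilot launch, pilot evaluation, scale decision,
#: broad implementation, sustained integration) over the four cycles.
#: Rows sum to 1.
MILESTONE_WEIGHT_TABLE: dict[str, tuple[float, float, float, float]] = {
    "K1": (0.20, 0.15, 0.25, 0.40),
    "K2": (0.10, 0.25, 0.50, 0.15),
    "K3": (0.05, 0.05, 0.70, 0.20),
    "K4": (0.45, 0.20, 0.25, 0.10),
    "K5": (0.35, 0.30, 0.25, 0.10),
    "K6": (0.25, 0.15, 0.20, 0.40),
    "K7": (0.50, 0.20, 0.15, 0.15),
    "K8": (0.30, 0.20, 0.15, 0.35),
}


@dataclass(frozen=True)
class MissionWeights:
    """Nonnegative cycle weights alpha summing to one."""

    alpha: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if len(self.alpha) != N_WHEELS:
            raise ValidationError(f"expected {N_WHEELS} mission weights")
        if any(a < 0 for a in self.alpha):
            raise ValidationError("mission weights must be nonnegative")
        if abs(sum(self.alpha) - 1.0) > 1e-9:
            raise ValidationError(
                f"mission weights must sum to 1 (got {sum(self.alpha):.12f})"
            )


@dataclass(frozen=True)
class EfficiencyScores:
    tei_g: float
    tei_b: float
    tei: float


@dataclass(frozen=True)
class TypologyThresholds:
    """Cut points separating 'high' from 'low' TEI-G / TEI-B.

    mode 'fixed' uses the supplied cuts; mode 'median-split' derives
    the cuts as cohort medians at classification time.
    """

    teig_cut: float = 1.0
    teib_cut: float = 0.8
    mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "median-split"):
            raise ValidationError(f"unknown typology mode {self.mode!r}")
        if self.mode == "fixed" and (self.teig_cut <= 0 or self.teib_cut <= 0):
            raise ValidationError("typology cuts must be > 0")


@dataclass(frozen=True)
class ScalingAnchors:
    """5th/95th percentile anchors for percentile scaling of a velocity."""

    q5: float
    q95: float

    def __post_init__(self) -> None:
        if not self.q95 > self.q5:
            raise ValidationError(
                f"degenerate anchors: q95 ({self.q95}) must exceed q5 ({self.q5})"
            )


class MilestoneWeights:
    """Row-stochastic milestone-to-cycle interpretation weights."""

    def __init__(self, matrix: np.ndarray | list):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (N_MILESTONES, N_WHEELS):
            raise ValidationError(
                f"milestone weights must be {N_MILESTONES}x{N_WHEELS}, got {m.shape}"
            )
        if np.any(m < 0):
            raise ValidationError("milestone weights must be nonnegative")
        bad = np.where(np.abs(m.sum(axis=1) - 1.0) > 1e-9)[0]
        if bad.size:
            raise ValidationError(
                "milestone weight rows must sum to 1; offending milestones: "
                + ", ".join(MILESTONES[i] for i in bad)
            )
        self.matrix = m

    @classmethod
    def default(cls) -> "MilestoneWeights":
        return cls([MILESTONE_WEIGHT_TABLE[k] for k in MILESTONES])


def velocity_from_latency(latency_months: float) -> float:
    """Translational velocity (month^-1) as inverse latency to sustainment."""
    if not latency_months > 0:
        raise ValidationError(f"latency must be > 0 months (got {latency_months})")
    return 1.0 / latency_months


def _weighted_norm(x: np.ndarray, alpha: np.ndarray, norm: str) -> np.ndarray:
    if norm == "euclidean":
        return np.sqrt(np.sum(alpha * x * x, axis=-1))
    if norm == "l1":
        return np.sum(alpha * np.abs(x), axis=-1)
    raise ValidationError(f"unknown norm {norm!r} (expected 'euclidean' or 'l1')")


def tei_g(v: np.ndarray, f: np.ndarray, weights: MissionWeights | None = None,
          norm: str = "euclidean"):
    """Gain-based efficiency: ratio of weighted norms of v over f.

    Equals 1 when v = f (no spillovers) and exceeds 1 whenever the
    coupling amplifies every cycle.  Vectorized over leading axes.
    """
    weights = weights or MissionWeights()
    alpha = np.asarray(weights.alpha)
    v = np.asarray(v, dtype=float)
    f = np.asarray(f, dtype=float)
    nf = _weighted_norm(f, alpha, norm)
    if np.any(nf == 0):
        raise ValidationError("TEI-G undefined: drive vector has zero norm")
    out = _weighted_norm(v, alpha, norm) / nf
    return float(out) if out.ndim == 0 else out


def tei_b(v: np.ndarray, weights: MissionWeights | None = None):
    """Bottleneck efficiency: slowest cycle over the weighted mean.

    Lies in (0, 1]; equals 1 iff all cycle velocities coincide (for
    strictly positive weights).  Vectorized over leading axes.
    """
    weights = weights or MissionWeights()
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValidationError("TEI-B requires strictly positive velocities")
    out = v.min(axis=-1) / np.sum(np.asarray(weights.alpha) * v, axis=-1)
    return float(out) if out.ndim == 0 else out


def tei(tei_g_value, tei_b_value):
    """Global translational efficiency: TEI = TEI-G x TEI-B."""
    return tei_g_value * tei_b_value


def efficiency_scores(v: np.ndarray, f: np.ndarray,
                      weights: MissionWeights | None = None,
                      norm: str = "euclidean") -> EfficiencyScores:
    g = tei_g(v, f, weights, norm)
    b = tei_b(v, weights)
    return EfficiencyScores(tei_g=g, tei_b=b, tei=tei(g, b))


def system_velocities(v: np.ndarray, weights: MissionWeights | None = None
                      ) -> tuple[float, float]:
    """(bottleneck, weighted-mean) system speed of a velocity profile."""
    weights = weights or MissionWeights()
    v = np.asarray(v, dtype=float)
    return float(v.min()), float(np.dot(weights.alpha, v))


def scale_percentile(V: float, anchors: ScalingAnchors) -> tuple[float, bool]:
    """Percentile-scale a velocity against 5th/95th anchors.

    Returns ``(scaled, in_range)``; values outside [0, 1] are returned
    unclamped with ``in_range=False`` so out-of-anchor performance
    stays visible.
    """
    scaled = (V - anchors.q5) / (anchors.q95 - anchors.q5)
    return float(scaled), bool(0.0 <= scaled <= 1.0)


def classify_typology(scores: EfficiencyScores | Sequence[EfficiencyScores],
                      thr: TypologyThresholds | None = None):
    """Assign each (TEI-G, TEI-B) pair to one of the four system states.

    In median-split mode the cuts are the cohort medians of TEI-G and
    TEI-B, requiring a cohort of at least 2.  Values >= the cut are
    'high'.
    """
    thr = thr or TypologyThresholds()
    single = isinstance(scores, EfficiencyScores)
    cohort = [scores] if single else list(scores)
    if thr.mode == "median-split":
        if len(cohort) < 2:
            raise ValidationError("median-split typology needs a cohort of >= 2")
        gcut = float(np.median([s.tei_g for s in cohort]))
        bcut = float(np.median([s.tei_b for s in cohort]))
    else:
        gcut, bcut = thr.teig_cut, thr.teib_cut
    labels = [_quadrant(s.tei_g >= gcut, s.tei_b >= bcut) for s in cohort]
    return labels[0] if single else labels


def classify_typology_arrays(teig: np.ndarray, teib: np.ndarray,
                             thr: TypologyThresholds | None = None) -> np.ndarray:
    """Vectorized typology over parallel TEI-G / TEI-B arrays."""
    thr = thr or TypologyThresholds()
    teig = np.asarray(teig, dtype=float)
    teib = np.asarray(teib, dtype=float)
    if thr.mode == "median-split":
        if teig.size < 2:
            raise ValidationError("median-split typology needs a cohort of >= 2")
        gcut, bcut = float(np.median(teig)), float(np.median(teib))
    else:
        gcut, bcut = thr.teig_cut, thr.teib_cut
    idx = 2 * (teig >= gcut).astype(int) + (teib >= bcut).astype(int)
    lut = np.array([STATES[0], STATES[2], STATES[1], STATES[3]])
    return lut[idx]


def _quadrant(high_g: bool, high_b: bool) -> str:
    if high_g and high_b:
        return "FullyIntegrated"
    if high_g:
        return "Emerging"
    if high_b:
        return "Functional"
    return "Fragmented"


def hub_tei_g(per_project_teig: Sequence[float]) -> float:
    """Hub-level gain efficiency: median over projects and periods."""
    vals = np.asarray(list(per_project_teig), dtype=float)
    if vals.size == 0:
        raise ValidationError("hub TEI-G requires at least one project value")
    return float(np.median(vals))


def attribute_milestones(milestone_latencies: Sequence[float],
                         mw: MilestoneWeights | None = None) -> np.ndarray:
    """Allocate milestone latencies to cycles via interpretation weights.

    Cycle j receives sum_k m[k, j] * latency_k.  Because rows of the
    weight matrix sum to 1, the grand total equals the total latency.
    """
    mw = mw or MilestoneWeights.default()
    lat = np.asarray(milestone_latencies, dtype=float)
    if lat.shape != (N_MILESTONES,):
        raise ValidationError(f"expected {N_MILESTONES} milestone latencies")
    return lat @ mw.matrix
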