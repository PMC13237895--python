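"""Community Transmission Index (CTI) instrument.

The CTI quantifies structural community empowerment in a learning health
system on a 0-1 scale.  Each project is scored quarterly across eight
domains (D1 shared governance, D2 bidirectional accountability, D3 data
transparency, D4 participatory data governance, D5 feedback closure, D6
co-production depth, D7 trust capital, D8 equity integration) on a 0-4
ordinal rubric by three raters: an academic representative (A), a health
system representative (H), and a community evaluator (C).  Ratings are
normalized to [0, 1], averaged over raters, and combined with domain
weights into the composite index, which maps to one of five maturity
bands from Transactional to Community-Anchored.

Inter-rater reliability is assessed with weighted Cohen's kappa
(target >= 0.75); domains where raters diverge by two or more rubric
points are flagged for consensus review.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import cohen_kappa_score

from .errors import UndefinedStatisticError, ValidationError

N_DOMAINS = 8
DOMAINS = tuple(f"D{i}" for i in range(1, N_DOMAINS + 1))
RATERS = ("A", "H", "C")
RATING_LEVELS = (0, 1, 2, 3, 4)

#: Balanced-drivetrain default domain weights.
DEFAULT_WEIGHTS: dict[str, float] = {
    "D1": 0.16, "D2": 0.10, "D3": 0.12, "D4": 0.10,
    "D5": 0.16, "D6": 0.12, "D7": 0.12, "D8": 0.12,
}

#: Maturity bands over the composite score: [lo, hi) except the last,
#: which is closed at 1.0.
BANDS = (
    (0.00, 0.25, "Transactional"),
    (0.25, 0.50, "Advisory"),
    (0.50, 0.70, "Collaborative"),
    (0.70, 0.85, "SharedGovernance"),
    (0.85, 1.00, "CommunityAnchored"),
)
BAND_NAMES = tuple(name for _, _, name in BANDS)


@dataclass(frozen=True)
class RaterSheet:
    """One rater's 0-4 ratings for one project in one period."""

    project_id: str
    period: str
    rater: str
    ratings: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.rater not in RATERS:
            raise ValidationError(
                f"project {self.project_id!r} period {self.period!r}: "
                f"unknown rater tag {self.rater!r} (expected one of {RATERS})"
            )
        if len(self.ratings) != N_DOMAINS:
            raise ValidationError(
                f"project {self.project_id!r} period {self.period!r} rater "
                f"{self.rater}: expected {N_DOMAINS} ratings, got {len(self.ratings)}"
            )
        for d, r in zip(DOMAINS, self.ratings):
            if r not in RATING_LEVELS:
                raise ValidationError(
                    f"project {self.project_id!r} domain {d} rater {self.rater}: "
                    f"rating {r!r} outside the 0-4 rubric"
                )


@dataclass(frozen=True)
class DomainWeights:
    """Nonnegative domain weights summing to one."""

    w: tuple[float, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.w) != N_DOMAINS:
            raise ValidationError(f"expected {N_DOMAINS} weights, got {len(self.w)}")
        if any(wi < 0 for wi in self.w):
            raise ValidationError("domain weights must be nonnegative")
        if abs(sum(self.w) - 1.0) > 1e-9:
            raise ValidationError(
                f"domain weights must sum to 1 (got {sum(self.w):.12f})"
            )

    @classmethod
    def from_mapping(cls, m: Mapping[str, float], name: str = "custom") -> "DomainWeights":
        missing = [d for d in DOMAINS if d not in m]
        if missing:
            raise ValidationError(f"weight mapping missing domains {missing}")
        extra = [k for k in m if k not in DOMAINS]
        if extra:
            raise ValidationError(f"weight mapping has unknown keys {extra}")
        return cls(tuple(float(m[d]) for d in DOMAINS), name=name)

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(DOMAINS, self.w))


@dataclass(frozen=True)
class CTIResult:
    """Scored instrument for one project/period."""

    project_id: str
    period: str
    domain_scores: tuple[float, ...]
    cti: float
    band: str


@dataclass
class ReliabilityReport:
    """Pairwise weighted-kappa summary plus consensus-review flags.

    ``kappas`` maps (rater_x, rater_y, domain) -> kappa, with domain
    "pooled" for the all-domain pooled estimate; a value of ``nan``
    marks a pair/domain where kappa is undefined (constant marginals).
    """

    kappas: dict[tuple[str, str, str], float]
    scheme: str
    threshold: float
    flags: list[tuple[str, str]] = field(default_factory=list)

    def below_target(self) -> list[tuple[str, str, str]]:
        """Pairs/domains whose kappa is defined but below the target."""
        return [k for k, v in self.kappas.items()
                if np.isfinite(v) and v < self.threshold]


def default_weights() -> DomainWeights:
    """Balanced-drivetrain weight preset."""
    return DomainWeights.from_mapping(DEFAULT_WEIGHTS, name="default")


def equity_forward_weights() -> DomainWeights:
    """Equity-forward preset: D8 raised to 0.20, the increase taken out
    of D2-D4 proportionally so the total stays 1."""
    w = dict(DEFAULT_WEIGHTS)
    delta = 0.20 - w["D8"]
    pool = w["D2"] + w["D3"] + w["D4"]
    scale = (pool - delta) / pool
    w["D8"] = 0.20
    for d in ("D2", "D3", "D4"):
        w[d] *= scale
    return DomainWeights.from_mapping(w, name="equity_forward")


def normalize_rating(r: int, *, project_id: str = "?", domain: str = "?",
                     rater: str = "?") -> float:
    """Map a 0-4 rubric rating to [0, 1] by dividing by 4."""
    if r not in RATING_LEVELS:
        raise ValidationError(
            f"project {project_id!r} domain {domain} rater {rater}: "
            f"rating {r!r} outside the 0-4 rubric"
        )
    return r / 4.0


def aggregate_raters(sheets: Sequence[RaterSheet]) -> tuple[float, ...]:
    """Average the three raters' normalized ratings per domain.

    Requires exactly one sheet per rater tag A, H, C, all for the same
    project and period.  Returns the eight domain scores S in [0, 1].
    """
    if len(sheets) != 3:
        raise ValidationError(f"expected 3 rater sheets, got {len(sheets)}")
    tags = sorted(s.rater for s in sheets)
    if tags != sorted(RATERS):
        raise ValidationError(
            f"expected one sheet per rater {RATERS}, got tags {tags}"
        )
    keys = {(s.project_id, s.period) for s in sheets}
    if len(keys) != 1:
        raise ValidationError(f"sheets mix projects/periods: {sorted(keys)}")
    arr = np.array([[normalize_rating(r, project_id=s.project_id, domain=d,
                                      rater=s.rater)
                     for d, r in zip(DOMAINS, s.ratings)] for s in sheets])
    return tuple(float(x) for x in arr.mean(axis=0))


def composite_cti(domain_scores: Sequence[float], weights: DomainWeights) -> float:
    """Weighted sum of the eight domain scores; lies in [0, 1]."""
    s = np.asarray(domain_scores, dtype=float)
    if s.shape != (N_DOMAINS,):
        raise ValidationError(f"expected {N_DOMAINS} domain scores, got {s.shape}")
    if s.min() < -1e-12 or s.max() > 1 + 1e-12:
        raise ValidationError("domain scores must lie in [0, 1]")
    return float(np.dot(weights.w, s))


def classify_cti_band(cti: float) -> str:
    """Map a composite score to its maturity band.

    Intervals are left-closed; the top band includes 1.0 exactly.
    """
    if not 0.0 <= cti <= 1.0:
        raise ValidationError(f"CTI {cti!r} outside [0, 1]")
    for lo, hi, name in BANDS:
        if lo <= cti < hi:
            return name
    return BANDS[-1][2]  # cti == 1.0


def score_sheets(sheets: Iterable[RaterSheet],
                 weights: DomainWeights | None = None) -> list[CTIResult]:
    """Score every (project, period) group present in ``sheets``.

    Groups are scored independently with a single fixed weight vector;
    results are ordered by (project_id, period).
    """
    weights = weights or default_weights()
    groups: dict[tuple[str, str], list[RaterSheet]] = {}
    for s in sheets:
        groups.setdefault((s.project_id, s.period), []).append(s)
    results = []
    for (pid, period), grp in sorted(groups.items()):
        scores = aggregate_raters(grp)
        cti = composite_cti(scores, weights)
        results.append(CTIResult(pid, period, scores, cti, classify_cti_band(cti)))
    return results


def weighted_kappa(ratings_x: Sequence[int], ratings_y: Sequence[int],
                   scheme: str = "quadratic") -> float:
    """Weighted Cohen's kappa between two raters on the 0-4 rubric.

    ``scheme`` selects linear or quadratic disagreement weights;
    quadratic is the default, conventional for ordinal rubrics.
    Raises :class:`UndefinedStatisticError` when chance-expected
    disagreement is zero (both raters constant), where kappa is 0/0.
    """
    if scheme not in ("linear", "quadratic"):
        raise ValidationError(f"unknown kappa scheme {scheme!r}")
    x = np.asarray(ratings_x, dtype=int)
    y = np.asarray(ratings_y, dtype=int)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError("paired rating vectors of equal length >= 2 required")
    for v in np.concatenate([x, y]):
        if v not in RATING_LEVELS:
            raise ValidationError(f"rating {v} outside the 0-4 rubric")
    if len(set(x)) == 1 and len(set(y)) == 1:
        raise UndefinedStatisticError(
            "weighted kappa undefined: both raters constant (0/0)"
        )
    with np.errstate(all="ignore"):
        k = cohen_kappa_score(x, y, labels=list(RATING_LEVELS), weights=scheme)
    if not np.isfinite(k):
        raise UndefinedStatisticError(
            "weighted kappa undefined on this input (degenerate marginals)"
        )
    return float(k)


def reliability_report(sheets: Iterable[RaterSheet], threshold: float = 0.75,
                       scheme: str = "quadratic") -> ReliabilityReport:
    """Pairwise inter-rater reliability across a set of sheets.

    Kappas are computed per rater pair per domain (pooling projects and
    periods as the rating units) and pooled over all domains.  Any
    (project, domain) where the raw ratings spread over two or more
    rubric points is flagged as a major discrepancy for consensus
    review; flags are never auto-resolved.
    """
    by_group: dict[tuple[str, str], dict[str, RaterSheet]] = {}
    for s in sheets:
        by_group.setdefault((s.project_id, s.period), {})[s.rater] = s
    for key, grp in by_group.items():
        if len(grp) < 2:
            raise ValidationError(f"project/period {key} has fewer than 2 raters")

    raters_present = sorted({r for grp in by_group.values() for r in grp})
    pairs = [(a, b) for i, a in enumerate(raters_present)
             for b in raters_present[i + 1:]]

    kappas: dict[tuple[str, str, str], float] = {}
    for a, b in pairs:
        shared = [grp for grp in by_group.values() if a in grp and b in grp]
        for di, d in enumerate(DOMAINS):
            xs = [g[a].ratings[di] for g in shared]
            ys = [g[b].ratings[di] for g in shared]
            try:
                kappas[(a, b, d)] = weighted_kappa(xs, ys, scheme)
            except UndefinedStatisticError:
                kappas[(a, b, d)] = float("nan")
        xs = [g[a].ratings[di] for g in shared for di in range(N_DOMAINS)]
        ys = [g[b].ratings[di] for g in shared for di in range(N_DOMAINS)]
        try:
            kappas[(a, b, "pooled")] = weighted_kappa(xs, ys, scheme)
        except UndefinedStatisticError:
            kappas[(a, b, "pooled")] = float("nan")

    flags = []
    for (pid, period), grp in sorted(by_group.items()):
        for di, d in enumerate(DOMAINS):
            vals = [s.ratings[di] for s in grp.values()]
            if max(vals) - min(vals) >= 2:
                flags.append((pid, d))
    return ReliabilityReport(kappas=kappas, scheme=scheme,
                             threshold=threshold, flags=flags)
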