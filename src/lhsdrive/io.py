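"""File formats and fixture generation.

All tabular artifacts are plain UTF-8 CSV with "." decimals and no
thousands separators.  The ratings format has the exact header
``project_id,period,rater,D1,...,D8`` with integer 0-4 cells and rater
tags A/H/C; scored output uses ``project_id,period,S1..S8,cti,band``.

The fixture generator produces synthetic rater sheets with a
controllable inter-rater agreement regime and optional target maturity
band, for tests and demonstrations; fixtures are byte-identical under
a fixed seed.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cti import (BANDS, CTIResult, DOMAINS, N_DOMAINS, RATERS, RaterSheet,
                  default_weights)
from .errors import ValidationError
from .metrics import MilestoneWeights, MILESTONES
from .drivetrain import WHEELS

RATINGS_HEADER = ["project_id", "period", "rater", *DOMAINS]
CTI_HEADER = ["project_id", "period", *[f"S{i}" for i in range(1, 9)],
              "cti", "band"]
MILESTONE_HEADER = ["milestone", *WHEELS]


def read_ratings(path: str | Path) -> list[RaterSheet]:
    """Read and validate a rater-sheet CSV.

    Errors name the offending line; an empty file yields an empty list
    with a warning.
    """
    path = Path(path)
    sheets: list[RaterSheet] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            warnings.warn(f"{path}: empty ratings file", stacklevel=2)
            return []
        if header != RATINGS_HEADER:
            raise ValidationError(
                f"{path}:1: malformed header {header!r}; "
                f"expected {','.join(RATINGS_HEADER)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(RATINGS_HEADER):
                raise ValidationError(
                    f"{path}:{lineno}: expected {len(RATINGS_HEADER)} cells, "
                    f"got {len(row)}"
                )
            pid, period, rater, *cells = [c.strip() for c in row]
            ratings = []
            for d, c in zip(DOMAINS, cells):
                try:
                    ratings.append(int(c))
                except ValueError:
                    raise ValidationError(
                        f"{path}:{lineno}: non-integer rating {c!r} in {d}"
                    ) from None
            try:
                sheets.append(RaterSheet(pid, period, rater, tuple(ratings)))
            except ValidationError as e:
                raise ValidationError(f"{path}:{lineno}: {e}") from None
    if not sheets:
        warnings.warn(f"{path}: no rating rows", stacklevel=2)
    return sheets


def write_ratings(sheets: Sequence[RaterSheet], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(RATINGS_HEADER)
        for s in sheets:
            w.writerow([s.project_id, s.period, s.rater, *s.ratings])


def write_cti_results(results: Sequence[CTIResult], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CTI_HEADER)
        for r in results:
            w.writerow([r.project_id, r.period,
                        *[f"{s:.6f}" for s in r.domain_scores],
                        f"{r.cti:.6f}", r.band])


def read_cti_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != CTI_HEADER:
        raise ValidationError(f"{path}: malformed scored-CTI header")
    return df


def read_milestone_weights(path: str | Path) -> MilestoneWeights:
    """Load a milestone-to-cycle weight CSV and validate row sums."""
    df = pd.read_csv(path)
    if list(df.columns) != MILESTONE_HEADER:
        raise ValidationError(
            f"{path}: malformed header; expected {','.join(MILESTONE_HEADER)}"
        )
    if list(df["milestone"]) != list(MILESTONES):
        raise ValidationError(f"{path}: milestones must be K1..K8 in order")
    return MilestoneWeights(df[list(WHEELS)].to_numpy(dtype=float))


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for synthetic rater sheets.

    agreement : 'perfect' (all raters identical), 'high' (raters jitter
        by at most 1 point), or 'noisy' (independent +-2 jitter).
    band : optional maturity band the generated composites should fall
        in (under default weights); None draws consensus ratings
        uniformly.
    """

    n_projects: int = 6
    n_periods: int = 2
    agreement: str = "high"
    band: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.agreement not in ("perfect", "high", "noisy"):
            raise ValidationError(f"unknown agreement regime {self.agreement!r}")
        if self.band is not None and self.band not in [b[2] for b in BANDS]:
            raise ValidationError(f"unknown band {self.band!r}")


_JITTER = {"perfect": 0, "high": 1, "noisy": 2}


def generate_fixtures(spec: FixtureSpec) -> list[RaterSheet]:
    """Generate synthetic rater sheets under an agreement regime.

    When a target band is set, consensus ratings are drawn so that the
    default-weight composite of the consensus sheet lands inside the
    band; rater jitter is then applied symmetrically (clipped to 0-4),
    which perturbs but rarely escapes the band for the non-noisy
    regimes.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.band is not None:
        lo, hi = next((lo, hi) for lo, hi, name in BANDS if name == spec.band)
    weights = np.asarray(default_weights().w)
    sheets = []
    for p in range(spec.n_projects):
        pid = f"P{p + 1:03d}"
        for q in range(spec.n_periods):
            period = f"2026-Q{q + 1}"
            if spec.band is None:
                consensus = rng.integers(0, 5, size=N_DOMAINS)
            else:
                # rejection-sample a consensus sheet whose composite
                # falls strictly inside the target band
                margin = 0.0 if spec.agreement == "perfect" else 0.02
                upper = 1.0 if hi == 1.0 else hi - max(margin, 1e-9)
                for _ in range(10_000):
                    consensus = rng.integers(0, 5, size=N_DOMAINS)
                    cti = float(weights @ (consensus / 4.0))
                    if lo + margin <= cti <= upper:
                        break
                else:  # pragma: no cover
                    raise ValidationError(f"cannot hit band {spec.band!r}")
            for rater in RATERS:
                jit = _JITTER[spec.agreement]
                noise = rng.integers(-jit, jit + 1, size=N_DOMAINS) if jit else 0
                ratings = np.clip(consensus + noise, 0, 4)
                sheets.append(RaterSheet(pid, period, rater,
                                         tuple(int(r) for r in ratings)))
    return sheets
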