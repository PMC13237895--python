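"""Run configuration: schema, validation, and YAML loading.

A run configuration gathers every model block in one document:
``transmission`` (logistic a, m0), ``friction`` (Hill r_max, eta, c),
``wheels`` (v_max ceilings), ``coupling`` (the 4x4 spillover matrix,
axis order clinical/education/research/governance, rows receive),
``cti_beta`` (beta shapes of the project CTI distribution), ``engine``
and ``friction_env`` (per-wheel log-normal moments of engine power and
contextual friction), ``economics`` (innovation/revenue/cost
coefficients), ``monte_carlo`` (iteration counts, portfolio-size spec,
uniform hyperparameter ranges, coupling scale range, typology mode,
TEI-G norm, mission weights), and ``seed``.

Unknown keys anywhere are errors, not warnings: a typo in a parameter
name must never silently fall back to a default.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .drivetrain import CouplingMatrix, TransmissionParams, N_WHEELS
from .economics import EconParams
from .errors import ValidationError
from .metrics import MissionWeights, TypologyThresholds


@dataclass(frozen=True)
class PortfolioSizeSpec:
    """Number of projects per iteration: a constant, or a rounded
    normal(mean, sd) draw clipped below at 2."""

    constant: int | None = None
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.constant is not None:
            if self.constant < 0:
                raise ValidationError("n_projects constant must be >= 0")
        elif self.mean is None or self.sd is None:
            raise ValidationError("n_projects needs a constant or mean+sd")
        elif self.mean < 2 or self.sd < 0:
            raise ValidationError("n_projects normal spec needs mean >= 2, sd >= 0")

    def draw(self, rng: np.random.Generator) -> int:
        if self.constant is not None:
            return self.constant
        return max(2, int(round(rng.normal(self.mean, self.sd))))


@dataclass(frozen=True)
class SamplingConfig:
    """Stochastic layers of the Monte Carlo sweep."""

    cti_beta: tuple[float, float]
    engine_log_mean: tuple[float, ...]
    engine_log_sd: tuple[float, ...]
    friction_log_mean: tuple[float, ...]
    friction_log_sd: tuple[float, ...]
    hyper_ranges: dict[str, tuple[float, float]]
    k_scale_range: tuple[float, float]
    n_iterations: int
    n_projects: PortfolioSizeSpec
    seed: int

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.cti_beta):
            raise ValidationError("beta shapes must be > 0")
        for name in ("engine_log_sd", "friction_log_sd"):
            if any(s <= 0 for s in getattr(self, name)):
                raise ValidationError(f"{name} entries must be > 0")
        for name, vec in (("engine_log_mean", self.engine_log_mean),
                          ("engine_log_sd", self.engine_log_sd),
                          ("friction_log_mean", self.friction_log_mean),
                          ("friction_log_sd", self.friction_log_sd)):
            if len(vec) != N_WHEELS:
                raise ValidationError(f"{name} must have {N_WHEELS} entries")
        expected = {"a", "m0", "r_max", "eta", "c"}
        if set(self.hyper_ranges) != expected:
            raise ValidationError(
                f"hyper_ranges must define exactly {sorted(expected)}"
            )
        for k, (lo, hi) in self.hyper_ranges.items():
            if not lo <= hi:
                raise ValidationError(f"hyper range for {k}: low must be <= high")
        lo, hi = self.k_scale_range
        if not 0 <= lo <= hi:
            raise ValidationError("k_scale_range must satisfy 0 <= low <= high")
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Fully validated configuration for deterministic and Monte Carlo runs."""

    transmission: TransmissionParams
    v_max: tuple[float, ...]
    coupling: CouplingMatrix
    econ: EconParams
    sampling: SamplingConfig
    mission_weights: MissionWeights = field(default_factory=MissionWeights)
    typology: TypologyThresholds = field(default_factory=TypologyThresholds)
    norm: str = "euclidean"

    def content_hash(self) -> str:
        """Stable SHA-256 of the resolved configuration document."""
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    def to_dict(self) -> dict:
        s = self.sampling
        np_spec: Any = (s.n_projects.constant if s.n_projects.constant is not None
                        else {"mean": s.n_projects.mean, "sd": s.n_projects.sd})
        return {
            "transmission": {"a": self.transmission.a, "m0": self.transmission.m0},
            "friction": {"r_max": self.transmission.r_max,
                         "eta": self.transmission.eta, "c": self.transmission.c},
            "wheels": {"v_max": list(self.v_max)},
            "coupling": {"matrix": self.coupling.K.tolist()},
            "cti_beta": {"shape1": s.cti_beta[0], "shape2": s.cti_beta[1]},
            "engine": {"log_mean": list(s.engine_log_mean),
                       "log_sd": list(s.engine_log_sd)},
            "friction_env": {"log_mean": list(s.friction_log_mean),
                             "log_sd": list(s.friction_log_sd)},
            "economics": {
                "innovation_intercept": list(self.econ.innovation_intercept),
                "innovation_slope": list(self.econ.innovation_slope),
                "revenue_base": list(self.econ.revenue_base),
                "revenue_velocity": list(self.econ.revenue_velocity),
                "revenue_innovation": list(self.econ.revenue_innovation),
                "cost_base": list(self.econ.cost_base),
                "cost_velocity": list(self.econ.cost_velocity),
                "pdca_practice_cost": self.econ.pdca_practice_cost,
                "pdca_data_cost": self.econ.pdca_data_cost,
                "pdca_implementation_cost": self.econ.pdca_implementation_cost,
                "pdca_intensity": list(self.econ.pdca_intensity),
            },
            "monte_carlo": {
                "n_iterations": s.n_iterations,
                "n_projects": np_spec,
                "hyper_ranges": {k: list(v) for k, v in s.hyper_ranges.items()},
                "k_scale_range": list(s.k_scale_range),
                "typology": {"mode": self.typology.mode,
                             "teig_cut": self.typology.teig_cut,
                             "teib_cut": self.typology.teib_cut},
                "norm": self.norm,
                "mission_weights": list(self.mission_weights.alpha),
            },
            "seed": s.seed,
        }


_TOP_KEYS = {"transmission", "friction", "wheels", "coupling", "cti_beta",
             "engine", "friction_env", "economics", "monte_carlo", "seed"}


def _check_keys(block: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValidationError(f"unknown keys in {where}: {sorted(unknown)}")
    missing = allowed - set(block)
    if missing:
        raise ValidationError(f"missing keys in {where}: {sorted(missing)}")


def config_from_dict(doc: Mapping[str, Any]) -> RunConfig:
    """Validate a parsed configuration document into a :class:`RunConfig`."""
    if not isinstance(doc, Mapping):
        raise ValidationError("configuration document must be a mapping")
    _check_keys(doc, _TOP_KEYS, "config")

    _check_keys(doc["transmission"], {"a", "m0"}, "transmission")
    _check_keys(doc["friction"], {"r_max", "eta", "c"}, "friction")
    params = TransmissionParams(a=float(doc["transmission"]["a"]),
                                m0=float(doc["transmission"]["m0"]),
                                r_max=float(doc["friction"]["r_max"]),
                                eta=float(doc["friction"]["eta"]),
                                c=float(doc["friction"]["c"]))

    _check_keys(doc["wheels"], {"v_max"}, "wheels")
    v_max = tuple(float(x) for x in doc["wheels"]["v_max"])
    if len(v_max) != N_WHEELS or any(x <= 0 for x in v_max):
        raise ValidationError("wheels.v_max must be 4 positive values")

    _check_keys(doc["coupling"], {"matrix"}, "coupling")
    coupling = CouplingMatrix(doc["coupling"]["matrix"])

    _check_keys(doc["cti_beta"], {"shape1", "shape2"}, "cti_beta")
    _check_keys(doc["engine"], {"log_mean", "log_sd"}, "engine")
    _check_keys(doc["friction_env"], {"log_mean", "log_sd"}, "friction_env")

    econ_keys = {"innovation_intercept", "innovation_slope", "revenue_base",
                 "revenue_velocity", "revenue_innovation", "cost_base",
                 "cost_velocity", "pdca_practice_cost", "pdca_data_cost",
                 "pdca_implementation_cost", "pdca_intensity"}
    _check_keys(doc["economics"], econ_keys, "economics")
    e = doc["economics"]
    econ = EconParams(
        innovation_intercept=tuple(map(float, e["innovation_intercept"])),
        innovation_slope=tuple(map(float, e["innovation_slope"])),
        revenue_base=tuple(map(float, e["revenue_base"])),
        revenue_velocity=tuple(map(float, e["revenue_velocity"])),
        revenue_innovation=tuple(map(float, e["revenue_innovation"])),
        cost_base=tuple(map(float, e["cost_base"])),
        cost_velocity=tuple(map(float, e["cost_velocity"])),
        pdca_practice_cost=float(e["pdca_practice_cost"]),
        pdca_data_cost=float(e["pdca_data_cost"]),
        pdca_implementation_cost=float(e["pdca_implementation_cost"]),
        pdca_intensity=tuple(map(float, e["pdca_intensity"])),
    )

    mc_keys = {"n_iterations", "n_projects", "hyper_ranges", "k_scale_range",
               "typology", "norm", "mission_weights"}
    _check_keys(doc["monte_carlo"], mc_keys, "monte_carlo")
    mc = doc["monte_carlo"]
    np_spec = mc["n_projects"]
    if isinstance(np_spec, Mapping):
        _check_keys(np_spec, {"mean", "sd"}, "monte_carlo.n_projects")
        portfolio = PortfolioSizeSpec(mean=float(np_spec["mean"]),
                                      sd=float(np_spec["sd"]))
    else:
        portfolio = PortfolioSizeSpec(constant=int(np_spec))
    hyper = {k: (float(v[0]), float(v[1]))
             for k, v in dict(mc["hyper_ranges"]).items()}

    sampling = SamplingConfig(
        cti_beta=(float(doc["cti_beta"]["shape1"]),
                  float(doc["cti_beta"]["shape2"])),
        engine_log_mean=tuple(map(float, doc["engine"]["log_mean"])),
        engine_log_sd=tuple(map(float, doc["engine"]["log_sd"])),
        friction_log_mean=tuple(map(float, doc["friction_env"]["log_mean"])),
        friction_log_sd=tuple(map(float, doc["friction_env"]["log_sd"])),
        hyper_ranges=hyper,
        k_scale_range=(float(mc["k_scale_range"][0]),
                       float(mc["k_scale_range"][1])),
        n_iterations=int(mc["n_iterations"]),
        n_projects=portfolio,
        seed=int(doc["seed"]),
    )

    _check_keys(mc["typology"], {"mode", "teig_cut", "teib_cut"},
                "monte_carlo.typology")
    typology = TypologyThresholds(teig_cut=float(mc["typology"]["teig_cut"]),
                                  teib_cut=float(mc["typology"]["teib_cut"]),
                                  mode=str(mc["typology"]["mode"]))
    alpha = tuple(map(float, mc["mission_weights"]))
    norm = str(mc["norm"])
    if norm not in ("euclidean", "l1"):
        raise ValidationError(f"monte_carlo.norm must be euclidean or l1, got {norm!r}")

    return RunConfig(transmission=params, v_max=v_max, coupling=coupling,
                     econ=econ, sampling=sampling,
                     mission_weights=MissionWeights(alpha),
                     typology=typology, norm=norm)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def default_config(seed: int | None = None, **overrides: Any) -> RunConfig:
    """The shipped default configuration, optionally re-seeded.

    ``overrides`` may patch top-level scalar blocks before validation,
    e.g. ``default_config(seed=7, monte_carlo={"n_iterations": 10})``
    (mappings are merged one level deep).
    """
    text = resources.files("lhsdrive.data").joinpath("default_config.yaml").read_text()
    doc = yaml.safe_load(text)
    if seed is not None:
        doc["seed"] = int(seed)
    for key, val in overrides.items():
        if key not in doc:
            raise ValidationError(f"unknown config block {key!r}")
        if isinstance(val, Mapping) and isinstance(doc[key], dict):
            doc[key].update(val)
        else:
            doc[key] = val
    return config_from_dict(doc)
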