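"""Portfolio simulation and the Monte Carlo hyperparameter sweep.

A *deterministic* run simulates one portfolio of projects under fixed
model parameters: each project draws a CTI maturity from a beta
distribution and per-wheel engine power and contextual friction from
log-normal distributions, then the drivetrain equations produce direct
drives, coupled velocities, efficiency indices, a typology state, and
economic outcomes.  Conditional on those draws the computation is
exact, which is what makes per-iteration results reproducible.

The *Monte Carlo* sweep repeats this across iterations, re-sampling
the transmission/friction hyperparameters from uniform ranges and
re-scaling the spillover matrix by a stochastic factor (rescaled onto
spectral radius 0.95 and flagged whenever a draw would destabilize the
coupled system).  Summary statistics and 95% simulation intervals
(2.5th-97.5th percentiles) across iterations quantify the expected
range of system behaviour under parameter uncertainty.

Randomness follows one master seed; each iteration runs on its own
child stream keyed by iteration index, so results do not depend on
execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import economics as econmod
from .config import RunConfig, SamplingConfig
from .cti import BANDS
from .drivetrain import (CouplingMatrix, TransmissionParams, WheelAllocation,
                         coupled_velocities, spectral_radius, transmission_T,
                         friction_R, N_WHEELS)
from .errors import ValidationError
from .metrics import (MissionWeights, TypologyThresholds, STATES,
                      classify_typology_arrays, tei_b, tei_g)

#: Spectral radius that destabilizing coupling draws are rescaled onto.
STABILITY_RHO = 0.95

PROJECT_COLUMNS = (
    ["iteration", "project", "cti", "band"]
    + [f"f{j}" for j in range(1, 5)] + [f"v{j}" for j in range(1, 5)]
    + ["v_bottleneck", "v_mean", "tei_g", "tei_b", "tei", "state"]
    + [f"N{j}" for j in range(1, 5)] + [f"R{j}" for j in range(1, 5)]
    + [f"E{j}" for j in range(1, 5)]
    + ["revenue", "expense", "roi"]
)


@dataclass
class McSummary:
    """Monte Carlo output bundle.

    per_iteration : one row per iteration (sampled hyperparameters and
        iteration-level summary statistics).
    aggregates : cross-iteration mean/sd/median/2.5th/97.5th percentile
        for every numeric per-iteration column.
    state_proportions : share of all project records in each LHS state.
    """

    per_iteration: pd.DataFrame
    aggregates: pd.DataFrame
    state_proportions: dict[str, float]
    n_iterations: int


def sample_hyperparameters(cfg: SamplingConfig, rng: np.random.Generator
                           ) -> tuple[TransmissionParams, float]:
    """Draw transmission/friction constants and the coupling scale
    factor from their uniform ranges."""
    r = {k: rng.uniform(lo, hi) if hi > lo else float(lo)
         for k, (lo, hi) in cfg.hyper_ranges.items()}
    lo, hi = cfg.k_scale_range
    k_scale = rng.uniform(lo, hi) if hi > lo else float(lo)
    return TransmissionParams(a=r["a"], m0=r["m0"], r_max=r["r_max"],
                              eta=r["eta"], c=r["c"]), k_scale


def scale_coupling(K_base: CouplingMatrix | np.ndarray, factor: float
                   ) -> tuple[CouplingMatrix, bool]:
    """Scale the spillover matrix elementwise, enforcing stability.

    Returns ``(K, flagged)``; a draw whose spectral radius would reach
    1 is rescaled onto radius ``STABILITY_RHO`` and flagged rather
    than rejected.
    """
    if factor < 0:
        raise ValidationError("coupling scale factor must be >= 0")
    K = np.asarray(K_base, dtype=float) * factor
    rho = spectral_radius(K)
    flagged = False
    if rho >= 1.0:
        K = K * (STABILITY_RHO / rho)
        flagged = True
    return CouplingMatrix(K), flagged


def _classify_bands(cti: np.ndarray) -> np.ndarray:
    edges = [hi for _, hi, _ in BANDS[:-1]]
    names = np.array([name for _, _, name in BANDS])
    return names[np.searchsorted(edges, cti, side="right")]


def simulate_portfolio(n_projects: int, params: TransmissionParams,
                       K: CouplingMatrix, econ: econmod.EconParams,
                       cfg: RunConfig, rng: np.random.Generator,
                       iteration: int = 0) -> pd.DataFrame:
    """Simulate one portfolio under fixed hyperparameters.

    Draws project CTIs (beta) and per-wheel engine/friction resources
    (log-normal), pushes them through the drivetrain, efficiency,
    typology and economic layers, and returns one row per project.
    """
    s = cfg.sampling
    if n_projects == 0:
        return pd.DataFrame(columns=PROJECT_COLUMNS)
    M = rng.beta(s.cti_beta[0], s.cti_beta[1], size=n_projects)
    E = rng.lognormal(np.asarray(s.engine_log_mean),
                      np.asarray(s.engine_log_sd), size=(n_projects, N_WHEELS))
    F = rng.lognormal(np.asarray(s.friction_log_mean),
                      np.asarray(s.friction_log_sd), size=(n_projects, N_WHEELS))

    T = transmission_T(M, params)[:, None]
    R = friction_R(M, params)[:, None]
    vmax = np.asarray(cfg.v_max)
    f = vmax * E * T / (E * T + F * (1.0 - R))
    v = coupled_velocities(f, K)

    weights = cfg.mission_weights
    g = tei_g(v, f, weights, cfg.norm)
    b = tei_b(v, weights)
    t_idx = g * b
    if n_projects >= 2 or cfg.typology.mode == "fixed":
        state = classify_typology_arrays(g, b, cfg.typology)
    else:  # a single project cannot be median-split
        state = classify_typology_arrays(
            g, b, TypologyThresholds(cfg.typology.teig_cut,
                                     cfg.typology.teib_cut, "fixed"))

    N = econmod.innovation_throughput(v, econ)
    R_dollars = econmod.revenues(v, N, econ)
    E_dollars = econmod.expenses(v, econ)
    revenue = R_dollars.sum(axis=1)
    expense = E_dollars.sum(axis=1)
    roi = np.divide(revenue, expense, out=np.zeros_like(revenue),
                    where=expense > 0)

    alpha = np.asarray(weights.alpha)
    df = pd.DataFrame({"iteration": iteration, "project": np.arange(n_projects),
                       "cti": M, "band": _classify_bands(M)})
    for j in range(N_WHEELS):
        df[f"f{j + 1}"] = f[:, j]
    for j in range(N_WHEELS):
        df[f"v{j + 1}"] = v[:, j]
    df["v_bottleneck"] = v.min(axis=1)
    df["v_mean"] = v @ alpha
    df["tei_g"] = g
    df["tei_b"] = b
    df["tei"] = t_idx
    df["state"] = state
    for j in range(N_WHEELS):
        df[f"N{j + 1}"] = N[:, j]
    for j in range(N_WHEELS):
        df[f"R{j + 1}"] = R_dollars[:, j]
    for j in range(N_WHEELS):
        df[f"E{j + 1}"] = E_dollars[:, j]
    df["revenue"] = revenue
    df["expense"] = expense
    df["roi"] = roi
    return df[list(PROJECT_COLUMNS)]


def _iteration_summary(df: pd.DataFrame, params: TransmissionParams,
                       k_scale: float, rho: float, flagged: bool,
                       iteration: int) -> dict:
    out = {"iteration": iteration, "n_projects": len(df),
           "a": params.a, "m0": params.m0, "r_max": params.r_max,
           "eta": params.eta, "c": params.c, "k_scale": k_scale,
           "rho": rho, "stability_flagged": float(flagged),
           "mean_cti": df["cti"].mean()}
    for j in range(1, 5):
        out[f"mean_v{j}"] = df[f"v{j}"].mean()
    out["mean_bottleneck"] = df["v_bottleneck"].mean()
    out["mean_vmean"] = df["v_mean"].mean()
    out["median_tei_g"] = df["tei_g"].median()
    out["median_tei_b"] = df["tei_b"].median()
    out["median_tei"] = df["tei"].median()
    out["total_N"] = df[[f"N{j}" for j in range(1, 5)]].to_numpy().sum()
    out["total_revenue"] = df["revenue"].sum()
    out["total_expense"] = df["expense"].sum()
    out["global_roi"] = (out["total_revenue"] / out["total_expense"]
                         if out["total_expense"] > 0 else 0.0)
    out["mean_roi"] = df["roi"].mean()
    for a, b in (("cti", "tei"), ("cti", "roi")):
        x, y = df[a].to_numpy(), df[b].to_numpy()
        if len(df) >= 3 and np.std(x) > 0 and np.std(y) > 0:
            out[f"pearson_{a}_{b}"] = float(np.corrcoef(x, y)[0, 1])
            out[f"spearman_{a}_{b}"] = float(sps.spearmanr(x, y).statistic)
        else:
            out[f"pearson_{a}_{b}"] = np.nan
            out[f"spearman_{a}_{b}"] = np.nan
    counts = df["state"].value_counts()
    for st in STATES:
        out[f"prop_{st}"] = counts.get(st, 0) / max(len(df), 1)
    return out


def run_monte_carlo(cfg: RunConfig, n_iterations: int | None = None,
                    n_projects: int | None = None, seed: int | None = None,
                    keep_projects: bool = True
                    ) -> tuple[McSummary, pd.DataFrame]:
    """Run the full Monte Carlo sweep.

    ``n_iterations``, ``n_projects`` and ``seed`` override the
    configured values when given (``n_projects`` as a constant).
    Returns the summary bundle and the concatenated project table
    (empty when ``keep_projects`` is false).
    """
    s = cfg.sampling
    iters = n_iterations if n_iterations is not None else s.n_iterations
    master = seed if seed is not None else s.seed
    children = np.random.SeedSequence(master).spawn(iters)

    rows, tables = [], []
    for i in range(iters):
        rng = np.random.default_rng(children[i])
        params, k_scale = sample_hyperparameters(s, rng)
        K, flagged = scale_coupling(cfg.coupling, k_scale)
        n = n_projects if n_projects is not None else s.n_projects.draw(rng)
        df = simulate_portfolio(n, params, K, cfg.econ, cfg, rng, iteration=i)
        if len(df):
            rows.append(_iteration_summary(df, params, k_scale, K.rho,
                                           flagged, i))
        if keep_projects:
            tables.append(df)

    per_iter = pd.DataFrame(rows)
    aggregates = _cross_iteration_aggregates(per_iter)
    projects = (pd.concat(tables, ignore_index=True) if tables
                else pd.DataFrame(columns=PROJECT_COLUMNS))
    if len(projects):
        counts = projects["state"].value_counts(normalize=True)
        props = {st: float(counts.get(st, 0.0)) for st in STATES}
    else:
        props = {st: 0.0 for st in STATES}
    summary = McSummary(per_iteration=per_iter, aggregates=aggregates,
                        state_proportions=props, n_iterations=iters)
    return summary, projects


def _cross_iteration_aggregates(per_iter: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD, median and the 95% simulation interval per statistic.

    With a single iteration the SD is undefined and reported as NaN;
    the simulation interval then collapses to the point value.
    """
    num = per_iter.select_dtypes(include=[np.number]).drop(
        columns=["iteration"], errors="ignore")
    if num.empty:
        return pd.DataFrame()
    agg = pd.DataFrame({
        "mean": num.mean(),
        "sd": num.std(ddof=1),  # NaN when n_iterations == 1
        "median": num.median(),
        "q2.5": num.quantile(0.025),
        "q97.5": num.quantile(0.975),
    })
    agg.index.name = "statistic"
    return agg
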