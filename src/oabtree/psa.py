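"""Probabilistic sensitivity analysis, acceptability frontiers and EVPI.

Each Monte Carlo iteration draws one joint realisation of every model
parameter (Beta for probabilities and utilities, Gamma for costs,
Dirichlet for the diagnosis mix) and evaluates all strategy trees on
that same draw, so per-iteration comparisons between strategies are
coherent. Parameters use independent, name-keyed random substreams:
growing the iteration count extends each stream without altering the
draws already taken, and re-running a single strategy with the same seed
reproduces its column exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CONDITIONS
from .econ import annuity_factor, nmb
from .parameters import ParameterSet
from .tree import STRATEGIES, build_strategy_tree, evaluate

__all__ = [
    "PsaSamples",
    "sample_environment",
    "run_psa",
    "ceaf",
    "evpi_per_person",
    "evpi_curve",
    "population_evpi",
]


@dataclass
class PsaSamples:
    """Per-iteration strategy outcomes under parameter uncertainty."""

    cost: pd.DataFrame       # iterations x strategies
    qalys: pd.DataFrame
    success: pd.DataFrame
    parameters: pd.DataFrame  # the sampled parameter vectors
    seed: int = 0

    @property
    def n_iterations(self) -> int:
        return len(self.cost)

    @property
    def strategies(self) -> list[str]:
        return list(self.cost.columns)

    def effect(self, effect_kind: str) -> pd.DataFrame:
        if effect_kind == "qaly":
            return self.qalys
        if effect_kind == "success":
            return self.success
        raise ValueError(f"effect_kind must be 'qaly' or 'success', got {effect_kind!r}")

    def mean_outcomes(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cost": self.cost.mean(),
                "qalys": self.qalys.mean(),
                "success": self.success.mean(),
            }
        )


def sample_environment(ps: ParameterSet, n_iterations: int, seed: int) -> dict[str, np.ndarray]:
    """One joint draw of every parameter per iteration.

    Every parameter owns an independent substream spawned from the seed
    and its name, so draws are reproducible parameter-by-parameter and
    invariant to the iteration count for the indices already drawn.
    """
    from .distributions import sample

    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    env: dict[str, np.ndarray] = {}
    for name in sorted(ps.dists):
        d = ps.dists[name]
        child = np.random.SeedSequence(seed, spawn_key=(hash_name(name),))
        rng = np.random.default_rng(child)
        try:
            draw = sample(d, rng, size=n_iterations)
        except Exception as exc:
            raise RuntimeError(f"sampling parameter {name!r} failed: {exc}") from exc
        if np.ndim(draw) == 2:  # simplex-valued (Dirichlet or its point mass)
            for j, cond in enumerate(CONDITIONS):
                env[f"{name}.{cond}"] = draw[:, j]
        else:
            env[name] = draw
    return env


def hash_name(name: str) -> int:
    """Stable non-negative 32-bit key for a parameter name."""
    h = 2166136261
    for ch in name.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h


def run_psa(
    ps: ParameterSet,
    strategies=STRATEGIES,
    n_iterations: int | None = None,
    seed: int = 0,
) -> PsaSamples:
    """Monte Carlo propagation of parameter uncertainty through all trees.

    Defaults to the configured iteration count (10,000). All strategies
    see the same parameter draw within an iteration.
    """
    n = int(n_iterations if n_iterations is not None else ps.econ.psa_iterations)
    env = sample_environment(ps, n, seed)
    cost, qalys, success = {}, {}, {}
    for strat in strategies:
        tree = build_strategy_tree(strat, ps)
        out = evaluate(tree, env, ps.econ)
        cost[strat] = np.broadcast_to(out.expected_cost, (n,)).copy()
        qalys[strat] = np.broadcast_to(out.expected_qalys, (n,)).copy()
        success[strat] = np.broadcast_to(out.p_success, (n,)).copy()
    params = pd.DataFrame({k: np.broadcast_to(v, (n,)) for k, v in env.items()})
    return PsaSamples(
        cost=pd.DataFrame(cost),
        qalys=pd.DataFrame(qalys),
        success=pd.DataFrame(success),
        parameters=params,
        seed=seed,
    )


def _nmb_matrix(samples: PsaSamples, wtp: float, effect_kind: str) -> np.ndarray:
    return nmb(samples.cost.to_numpy(), samples.effect(effect_kind).to_numpy(), wtp)


def ceaf(samples: PsaSamples, wtp_grid, effect_kind: str = "qaly") -> pd.DataFrame:
    """Cost-effectiveness acceptability frontier.

    At each willingness-to-pay the optimal strategy is the one with the
    highest *mean* net monetary benefit; the frontier probability is the
    fraction of iterations in which that strategy attains the maximal
    NMB, with exact ties split equally.
    """
    wtp_grid = np.atleast_1d(np.asarray(wtp_grid, dtype=float))
    if wtp_grid.size == 0:
        raise ValueError("wtp grid is empty")
    strategies = samples.strategies
    rows = []
    for wtp in wtp_grid:
        m = _nmb_matrix(samples, wtp, effect_kind)
        means = m.mean(axis=0)
        opt = int(np.argmax(means))
        best = m.max(axis=1, keepdims=True)
        is_max = m >= best - 1e-9 * np.maximum(1.0, np.abs(best))
        share = is_max[:, opt] / is_max.sum(axis=1)
        rows.append(
            {
                "wtp": wtp,
                "optimal_strategy": strategies[opt],
                "probability_optimal_cost_effective": float(share.mean()),
            }
        )
    return pd.DataFrame(rows)


def evpi_per_person(samples: PsaSamples, wtp: float, effect_kind: str = "qaly") -> float:
    """Expected value of perfect information per woman treated.

    E over iterations of the best attainable NMB, minus the best
    expected NMB under current information; tiny negative floating
    residue is clipped at zero.
    """
    m = _nmb_matrix(samples, wtp, effect_kind)
    value = float(m.max(axis=1).mean() - m.mean(axis=0).max())
    return max(value, 0.0)


def population_evpi(per_person: float, incidence_per_year: float, years: int, rate: float) -> float:
    """Scale per-person EVPI to the population that research could inform:
    the yearly incident cohort over the research-relevance horizon, the
    first year undiscounted and later years discounted annually."""
    if per_person < 0 or incidence_per_year <= 0 or years <= 0:
        raise ValueError("population EVPI inputs must be positive")
    return per_person * incidence_per_year * annuity_factor(years, rate)


def evpi_curve(
    samples: PsaSamples,
    wtp_grid,
    effect_kind: str,
    incidence_per_year: float,
    years: int,
    rate: float,
) -> pd.DataFrame:
    """Per-person and population EVPI over a willingness-to-pay grid."""
    rows = []
    for wtp in np.atleast_1d(np.asarray(wtp_grid, dtype=float)):
        per = evpi_per_person(samples, wtp, effect_kind)
        rows.append(
            {
                "wtp": wtp,
                "evpi_per_person": per,
                "evpi_population": population_evpi(per, incidence_per_year, years, rate)
                if per > 0
                else 0.0,
            }
        )
    return pd.DataFrame(rows)
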