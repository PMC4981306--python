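"""Parameter distributions for the decision model.

Probabilities and utilities are represented by Beta distributions, unit
costs by Gamma distributions, and multinomial splits (diagnosis mix) by
Dirichlet distributions. Point masses are supported for deterministic
scenario analysis. Fitting helpers recover distribution parameters either
from event counts or from a reported mean and 95% confidence interval,
the two conventions used by the model's source tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BetaParams",
    "GammaParams",
    "DirichletParams",
    "PointParams",
    "FittedDistribution",
    "beta_dist",
    "gamma_dist",
    "dirichlet_dist",
    "point_mass",
    "fit_beta_from_counts",
    "fit_beta_from_mean_ci",
    "fit_gamma_from_mean_ci",
    "fit_gamma_dispersed",
    "dist_mean",
    "sample",
]


@dataclass(frozen=True)
class BetaParams:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(f"Beta shapes must be positive, got ({self.alpha}, {self.beta})")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class GammaParams:
    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError(f"Gamma parameters must be positive, got ({self.shape}, {self.scale})")

    @property
    def mean(self) -> float:
        return self.shape * self.scale


@dataclass(frozen=True)
class DirichletParams:
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.concentrations) < 2:
            raise ValueError("Dirichlet needs at least two categories")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError(f"Dirichlet concentrations must be positive: {self.concentrations}")

    @property
    def mean(self) -> tuple[float, ...]:
        total = sum(self.concentrations)
        return tuple(c / total for c in self.concentrations)


@dataclass(frozen=True)
class PointParams:
    """Degenerate distribution; a tuple value is a point on the simplex
    (the degenerate counterpart of a Dirichlet)."""

    value: float | tuple[float, ...]

    @property
    def mean(self) -> float | tuple[float, ...]:
        return self.value


_PARAM_TYPES = {
    "beta": BetaParams,
    "gamma": GammaParams,
    "dirichlet": DirichletParams,
    "point": PointParams,
}


@dataclass(frozen=True)
class FittedDistribution:
    """A distribution kind, its parameters and the cached analytic mean."""

    kind: str
    params: BetaParams | GammaParams | DirichletParams | PointParams
    mean: float | tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in _PARAM_TYPES:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if not isinstance(self.params, _PARAM_TYPES[self.kind]):
            raise TypeError(f"params {type(self.params).__name__} do not match kind {self.kind!r}")
        analytic = self.params.mean
        if self.mean is None:
            object.__setattr__(self, "mean", analytic)
        else:
            err = np.max(np.abs(np.asarray(self.mean) - np.asarray(analytic)))
            if err > 1e-9:
                raise ValueError(f"cached mean {self.mean} != analytic mean {analytic}")


def beta_dist(alpha: float, beta: float) -> FittedDistribution:
    return FittedDistribution("beta", BetaParams(alpha, beta))


def gamma_dist(shape: float, scale: float) -> FittedDistribution:
    return FittedDistribution("gamma", GammaParams(shape, scale))


def dirichlet_dist(concentrations) -> FittedDistribution:
    return FittedDistribution("dirichlet", DirichletParams(tuple(concentrations)))


def point_mass(value: float) -> FittedDistribution:
    return FittedDistribution("point", PointParams(value))


def fit_beta_from_counts(successes: float, failures: float, *, add_uniform_prior: bool = False) -> BetaParams:
    """Beta parameters from observed success/failure counts.

    With ``add_uniform_prior`` a Beta(1, 1) prior is added, giving the
    posterior under a uniform prior; by default the counts are used
    directly as shapes, the convention of sources reporting numbers of
    patients effectively treated.
    """
    if successes < 0 or failures < 0:
        raise ValueError("counts must be non-negative")
    if successes + failures == 0:
        raise ValueError("cannot identify a Beta distribution from zero counts")
    offset = 1.0 if add_uniform_prior else 0.0
    alpha, beta = successes + offset, failures + offset
    if alpha <= 0 or beta <= 0:
        raise ValueError(
            "counts with a zero cell need add_uniform_prior=True to give a proper distribution"
        )
    return BetaParams(alpha, beta)


def _refined_search(objective, log_lo: float, log_hi: float, n_grid: int = 200) -> float:
    """Coarse geometric grid over one positive parameter, then a bounded
    golden-section refinement around every local minimum of the grid
    (the quantile objective can have several basins for extreme shapes).
    Returns the parameter on its natural (not log) scale."""
    grid = np.linspace(log_lo, log_hi, n_grid)
    vals = np.array([objective(g) for g in grid])
    candidates = {int(np.argmin(vals))}
    for i in range(1, n_grid - 1):
        if vals[i] <= vals[i - 1] and vals[i] <= vals[i + 1]:
            candidates.add(i)
    best_x, best_f = grid[int(np.argmin(vals))], float(np.min(vals))
    for i in candidates:
        lo, hi = grid[max(0, i - 2)], grid[min(n_grid - 1, i + 2)]
        res = optimize.minimize_scalar(
            objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
        )
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
    return float(np.exp(best_x))


def fit_beta_from_mean_ci(
    mean: float, ci_low: float, ci_high: float, *, constrain_mean: bool = True
) -> BetaParams:
    """Fit a Beta distribution to a mean and equal-tailed 95% interval.

    By default the analytic mean is constrained exactly (beta =
    alpha(1-mean)/mean) and alpha chosen to minimise the summed squared
    deviation of the 2.5%/97.5% quantiles from (ci_low, ci_high). With
    ``constrain_mean=False`` all three values are fitted jointly.
    """
    if not (0 < ci_low < mean < ci_high < 1):
        raise ValueError(
            f"need 0 < ci_low < mean < ci_high < 1, got ({ci_low}, {mean}, {ci_high})"
        )

    def quantile_sse(alpha: float, beta: float) -> float:
        d = stats.beta(alpha, beta)
        return (d.ppf(0.025) - ci_low) ** 2 + (d.ppf(0.975) - ci_high) ** 2

    if constrain_mean:
        ratio = (1 - mean) / mean

        def objective(log_alpha: float) -> float:
            a = np.exp(log_alpha)
            return quantile_sse(a, a * ratio)

        alpha = _refined_search(objective, np.log(1e-3), np.log(1e6), n_grid=400)
        fit = BetaParams(alpha, alpha * ratio)
    else:
        scale = (ci_high - ci_low) / 2

        def joint(x) -> float:
            a, b = np.exp(x)
            d = BetaParams(a, b)
            return quantile_sse(a, b) + ((d.mean - mean) / scale) ** 2 * scale**2

        start = fit_beta_from_mean_ci(mean, ci_low, ci_high)
        res = optimize.minimize(joint, np.log([start.alpha, start.beta]), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-14})
        fit = BetaParams(*np.exp(res.x))

    if not np.isfinite(fit.alpha) or not np.isfinite(fit.beta):
        raise RuntimeError(f"no feasible Beta fit for mean={mean}, ci=({ci_low}, {ci_high})")
    if constrain_mean and abs(fit.mean - mean) > 1e-3:
        raise RuntimeError(f"Beta fit mean {fit.mean} deviates from target {mean}")
    return fit


def fit_gamma_from_mean_ci(
    mean: float, ci_low: float, ci_high: float, *, constrain_mean: bool = True
) -> GammaParams:
    """Fit a Gamma distribution to a mean cost and 95% interval.

    The mean is constrained via scale = mean/shape and shape chosen by
    quantile least squares, mirroring the Beta fit.
    """
    if not (0 < ci_low < mean < ci_high):
        raise ValueError(f"need 0 < ci_low < mean < ci_high, got ({ci_low}, {mean}, {ci_high})")

    def quantile_sse(shape: float, scale: float) -> float:
        d = stats.gamma(shape, scale=scale)
        return (d.ppf(0.025) - ci_low) ** 2 + (d.ppf(0.975) - ci_high) ** 2

    if constrain_mean:

        def objective(log_shape: float) -> float:
            s = np.exp(log_shape)
            return quantile_sse(s, mean / s)

        shape = _refined_search(objective, np.log(1e-3), np.log(1e5), n_grid=400)
        fit = GammaParams(shape, mean / shape)
    else:
        start = fit_gamma_from_mean_ci(mean, ci_low, ci_high)

        def joint(x) -> float:
            s, sc = np.exp(x)
            return quantile_sse(s, sc) + (s * sc - mean) ** 2

        res = optimize.minimize(joint, np.log([start.shape, start.scale]), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        fit = GammaParams(*np.exp(res.x))

    if constrain_mean and abs(fit.mean - mean) > 0.005 * mean:
        raise RuntimeError(f"Gamma fit mean {fit.mean} deviates from target {mean}")
    return fit


def fit_gamma_dispersed(mean: float) -> GammaParams:
    """Gamma for a cost reported without an interval: shape 1, scale = mean.

    The source tables describe these rows as method-of-moments fits with
    dispersion equal to the mean; shape 1 (standard deviation = mean)
    reproduces both printed parameterisations exactly.
    """
    if mean <= 0:
        raise ValueError(f"mean cost must be positive, got {mean}")
    return GammaParams(1.0, mean)


def dist_mean(d: FittedDistribution):
    """Analytic mean of a fitted distribution (vector for Dirichlet)."""
    return d.params.mean


def sample(d: FittedDistribution, rng: np.random.Generator, size: int | None = None):
    """Draw from a fitted distribution using the supplied generator.

    For a Dirichlet, returns an array with the category axis last.
    """
    if d.kind == "beta":
        return rng.beta(d.params.alpha, d.params.beta, size=size)
    if d.kind == "gamma":
        return rng.gamma(d.params.shape, d.params.scale, size=size)
    if d.kind == "dirichlet":
        draws = rng.dirichlet(d.params.concentrations, size=size)
        return draws
    if d.kind == "point":
        v = d.params.value
        if size is None:
            return np.asarray(v) if isinstance(v, tuple) else v
        if isinstance(v, tuple):
            return np.tile(np.asarray(v), (size, 1))
        return np.full(size, v)
    raise ValueError(f"unknown kind {d.kind!r}")  # pragma: no cover
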