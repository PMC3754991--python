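"""Approximate Bayesian computation by sequential Monte Carlo.

Likelihood-free inference for the weaning parameters: candidate
parameter sets are drawn from the prior, pushed through the forward
model, and kept when the mean squared distance between simulated and
observed d15N falls within a tolerance that shrinks over successive
particle populations.  Particles failing the current tolerance are
resampled from the previous weighted population and perturbed until they
pass (partial rejection control); importance weights carry the usual
kernel correction, and the population is resampled outright when the
effective sample size collapses.

The sampler core is generic --- it takes any batched simulator mapping a
parameter matrix to distances --- so it can be validated on analytically
tractable toy problems and reused unchanged for the weaning model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .forward_model import PopulationData, simulate_batch
from .turnover import QPModel, default_qp

__all__ = [
    "PriorSpec",
    "SMCConfig",
    "ParticleSystem",
    "TruncatedNormalPrior",
    "ess",
    "sample_prior",
    "run_abc_smc",
    "weaning_prior",
    "run_smc",
    "WEANING_PARAM_NAMES",
]

WEANING_PARAM_NAMES = ("t1", "t2", "enrichment", "d15n_wnfood")

#: Default prior location/scale for (t1, t2, E); the fourth mean is
#: population-specific (the all-adult d15N mean).
DEFAULT_PRIOR_MEANS = (0.5, 3.0, 1.9)
DEFAULT_PRIOR_SDS = (3.0, 3.0, 0.9, 3.0)


def _weaning_constraint(theta: np.ndarray) -> np.ndarray:
    return (theta[:, 0] >= 0.0) & (theta[:, 1] >= theta[:, 0])


class TruncatedNormalPrior:
    """Independent normal priors truncated to an arbitrary support.

    ``constraint`` maps a (B, d) parameter matrix to a boolean mask;
    draws violating it are rejected and redrawn, and the density is zero
    outside the support (the truncation normalizer is constant and
    cancels in the importance weights).
    """

    def __init__(
        self,
        means: Sequence[float],
        sds: Sequence[float],
        constraint: Callable[[np.ndarray], np.ndarray] | None = None,
    ):
        self.means = np.asarray(means, dtype=float)
        self.sds = np.asarray(sds, dtype=float)
        if self.means.shape != self.sds.shape:
            raise ValueError("means and sds must have the same length")
        if np.any(self.sds < 0):
            raise ValueError("prior SDs must be non-negative")
        self.constraint = constraint
        self.dim = len(self.means)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n <= 0:
            raise ValueError("n must be positive")
        out = np.empty((0, self.dim))
        while len(out) < n:
            draw = rng.normal(self.means, self.sds, size=(2 * n, self.dim))
            if self.constraint is not None:
                draw = draw[self.constraint(draw)]
            out = np.vstack([out, draw])
        return out[:n]

    def pdf(self, theta: np.ndarray) -> np.ndarray:
        """Unnormalized density on the support (zero outside)."""
        theta = np.atleast_2d(theta)
        dens = np.ones(len(theta))
        for j in range(self.dim):
            if self.sds[j] == 0:
                dens *= (theta[:, j] == self.means[j]).astype(float)
            else:
                z = (theta[:, j] - self.means[j]) / self.sds[j]
                dens *= np.exp(-0.5 * z**2) / self.sds[j]
        if self.constraint is not None:
            dens = np.where(self.constraint(theta), dens, 0.0)
        return dens


@dataclass(frozen=True)
class SMCConfig:
    """Sampler settings.

    ``tolerance_schedule`` may fix the per-stage tolerances explicitly;
    by default each stage's tolerance is the weighted ``quantile`` (the
    median) of the previous stage's distances.  ``n_stages`` counts the
    initial prior stage, so seven stages mean six tolerance reductions.
    """

    n_particles: int = 10000
    n_stages: int = 7
    tolerance_schedule: tuple[float, ...] | None = None
    quantile: float = 0.5
    kernel_scale: float = 1.0
    seed: int = 0
    min_acceptance: float = 1e-3
    max_proposals_per_particle: int = 5000

    def __post_init__(self):
        if self.n_particles <= 0 or self.n_stages <= 0:
            raise ValueError("particle and stage counts must be positive")
        if self.tolerance_schedule is not None:
            sched = tuple(float(t) for t in self.tolerance_schedule)
            if any(b >= a for a, b in zip(sched, sched[1:])):
                raise ValueError("tolerance schedule must strictly decrease")
            object.__setattr__(self, "tolerance_schedule", sched)


@dataclass
class ParticleSystem:
    """Weighted posterior particles with per-stage diagnostics."""

    particles: np.ndarray
    weights: np.ndarray
    distances: np.ndarray
    tolerance: float
    tolerance_history: tuple[float, ...]
    acceptance_history: tuple[float, ...]
    param_names: tuple[str, ...] = WEANING_PARAM_NAMES

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be normalized")

    def __len__(self) -> int:
        return len(self.particles)

    def marginal(self, name: str) -> np.ndarray:
        return self.particles[:, self.param_names.index(name)]

    def weighted_mean(self) -> np.ndarray:
        return self.weights @ self.particles

    def weighted_var(self) -> np.ndarray:
        mu = self.weighted_mean()
        return self.weights @ (self.particles - mu) ** 2

    def ess(self) -> float:
        return ess(self.weights)


def ess(weights) -> float:
    """Effective sample size 1 / sum(w^2) of normalized weights."""
    w = np.asarray(weights, dtype=float)
    return float(1.0 / np.sum(w**2))


def sample_prior(n: int, prior: TruncatedNormalPrior, seed: int) -> np.ndarray:
    """Independent draws from the truncated prior (deterministic in seed)."""
    return prior.sample(n, np.random.default_rng(seed))


def _weighted_quantile(values, q, weights) -> float:
    order = np.argsort(values)
    cw = np.cumsum(weights[order])
    idx = np.searchsorted(cw, q * cw[-1])
    return float(values[order][min(idx, len(values) - 1)])


def _systematic_resample(weights, rng) -> np.ndarray:
    n = len(weights)
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions)


def _kernel_density_at(theta, prev_particles, prev_weights, kernel_sd) -> np.ndarray:
    """sum_j w_j K(theta_i | theta_j) for a component-wise normal kernel,
    evaluated in blocks to bound memory."""
    out = np.empty(len(theta))
    block = max(1, int(2e6 // max(len(prev_particles), 1)))
    for lo in range(0, len(theta), block):
        chunk = theta[lo : lo + block]
        logk = np.zeros((len(chunk), len(prev_particles)))
        for j in range(theta.shape[1]):
            z = (chunk[:, j, None] - prev_particles[None, :, j]) / kernel_sd[j]
            logk -= 0.5 * z**2
        out[lo : lo + block] = np.exp(logk) @ prev_weights
    return out / np.prod(kernel_sd)


def run_abc_smc(
    simulate: Callable[[np.ndarray, np.random.Generator], np.ndarray],
    prior: TruncatedNormalPrior,
    config: SMCConfig,
    param_names: tuple[str, ...] | None = None,
) -> ParticleSystem:
    """Generic ABC-SMC sampler.

    ``simulate`` maps a (B, d) parameter matrix (and an RNG, for
    stochastic simulators) to a length-B vector of distances to the
    observations.  Returns the final weighted particle population.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_particles

    theta = prior.sample(n, rng)
    dist = np.asarray(simulate(theta, rng), dtype=float)
    weights = np.full(n, 1.0 / n)
    tolerances: list[float] = [float("inf")]
    acceptances: list[float] = [1.0]

    for stage in range(1, config.n_stages):
        if config.tolerance_schedule is not None:
            if stage - 1 >= len(config.tolerance_schedule):
                break
            eps = config.tolerance_schedule[stage - 1]
        else:
            eps = _weighted_quantile(dist, config.quantile, weights)
            prev = tolerances[-1]
            if np.isfinite(prev):
                eps = min(eps, np.nextafter(prev, 0.0))
        if not np.isfinite(eps):
            tolerances.append(eps)
            acceptances.append(1.0)
            continue

        var = weights @ (theta - weights @ theta) ** 2
        kernel_sd = config.kernel_scale * np.sqrt(2.0 * np.maximum(var, 1e-20))

        prev_theta, prev_weights = theta, weights
        new_theta = theta.copy()
        new_dist = dist.copy()
        pending = np.flatnonzero(new_dist > eps)
        proposed = accepted = 0
        while len(pending) > 0:
            # oversample proposals by the inverse running acceptance so
            # sparse acceptance still fills slots in few vectorized rounds
            rate = accepted / proposed if proposed else 1.0
            factor = int(np.clip(np.ceil(1.0 / max(rate, 0.05)), 1, 20))
            m = min(len(pending) * factor, 4 * n)
            anc = rng.choice(n, size=m, p=prev_weights)
            cand = prev_theta[anc] + rng.normal(size=(m, prior.dim)) * kernel_sd
            proposed += m
            valid = prior.pdf(cand) > 0.0
            if np.any(valid):
                cand = cand[valid]
                d_cand = np.asarray(simulate(cand, rng), dtype=float)
                ok = np.flatnonzero(d_cand <= eps)[: len(pending)]
                accepted += len(ok)
                new_theta[pending[: len(ok)]] = cand[ok]
                new_dist[pending[: len(ok)]] = d_cand[ok]
                pending = pending[len(ok) :]
            if proposed > 50 * n and accepted / proposed < config.min_acceptance:
                raise RuntimeError(
                    f"SMC stage {stage + 1} acceptance "
                    f"{accepted / proposed:.2e} below floor at tolerance {eps:.6g}"
                )
            if proposed > config.max_proposals_per_particle * n:
                raise RuntimeError(
                    f"SMC stage {stage + 1} stalled at tolerance {eps:.6g} "
                    f"after {proposed} proposals"
                )

        theta, dist = new_theta, new_dist
        denom = _kernel_density_at(theta, prev_theta, prev_weights, kernel_sd)
        weights = prior.pdf(theta) / np.maximum(denom, 1e-300)
        total = weights.sum()
        if total <= 0:
            raise RuntimeError("all particle weights vanished")
        weights = weights / total

        if ess(weights) < n / 2:
            idx = _systematic_resample(weights, rng)
            theta, dist = theta[idx], dist[idx]
            weights = np.full(n, 1.0 / n)

        tolerances.append(float(eps))
        acceptances.append(accepted / max(proposed, 1))

    return ParticleSystem(
        particles=theta,
        weights=weights,
        distances=dist,
        tolerance=tolerances[-1],
        tolerance_history=tuple(tolerances),
        acceptance_history=tuple(acceptances),
        param_names=param_names
        or tuple(f"p{i}" for i in range(prior.dim)),
    )


def weaning_prior(
    data: PopulationData | None = None,
    means: Sequence[float] | None = None,
    sds: Sequence[float] | None = None,
) -> TruncatedNormalPrior:
    """The standard four-parameter weaning prior.

    Means default to (0.5, 3.0, 1.9, all-adult mean) years/permil and
    SDs to (3.0, 3.0, 0.9, 3.0); the support is truncated to t1 >= 0 and
    t2 >= t1.  Pass explicit means/sds for population-specific overrides.
    """
    if means is None:
        if data is None:
            raise ValueError("need data (for the adult mean) or explicit means")
        means = (*DEFAULT_PRIOR_MEANS, data.d15n_adult)
    sds = DEFAULT_PRIOR_SDS if sds is None else sds
    return TruncatedNormalPrior(means, sds, constraint=_weaning_constraint)


def run_smc(
    data: PopulationData,
    prior: TruncatedNormalPrior | None = None,
    config: SMCConfig | None = None,
    qp: QPModel | None = None,
) -> ParticleSystem:
    """Fit the weaning parameters to one population by ABC-SMC.

    The simulator is the deterministic forward model evaluated at the
    observed ages-at-death; the distance is the mean squared d15N
    difference across subadult individuals.
    """
    prior = prior or weaning_prior(data)
    config = config or SMCConfig()
    qp = qp or default_qp()
    obs = data.d15n
    mother = data.d15n_mother

    def simulate(theta, rng):
        sim = simulate_batch(data.ages, theta, mother, qp)
        return np.mean((sim - obs[None, :]) ** 2, axis=1)

    return run_abc_smc(simulate, prior, config, param_names=WEANING_PARAM_NAMES)
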