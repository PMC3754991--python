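"""Forward simulation of bone-collagen d15N through breastfeeding and weaning.

The diet signal recorded by *newly synthesized* collagen is controlled by
four weaning parameters: exclusively breastfed infants form collagen at
the maternal value plus a trophic enrichment E; after weaning ends the
signal equals the value of collagen synthesized entirely from weaning
foods; in between it moves exponentially from one plateau to the other.

Bulk bone collagen lags this signal because only a fraction of the
skeleton is replaced per unit time.  Over an age step the existing pool
relaxes toward the current diet signal at the age-dependent turnover
rate, so bone d15N at death is a turnover-weighted average of the diet
history --- the quantity actually measured in a skeletal assemblage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .turnover import QPModel, RATE_FLOOR, default_qp

__all__ = [
    "WeaningParams",
    "PopulationData",
    "Trajectory",
    "synthesized_d15n",
    "simulate_bone_d15n",
    "simulate_batch",
    "trajectory",
    "distance",
    "euler_oracle",
]

#: Dimensionless decay constant of the weaning curve: the unrescaled
#: exponential has dropped to exp(-3) ~ 5% of the plateau gap at the end
#: of weaning, and the curve is rescaled to hit both plateaus exactly.
WEANING_SHAPE = 3.0

#: Internal integration step (years).  Must resolve rates > 1/yr in infancy.
DEFAULT_STEP = 0.02

MAX_SIM_AGE = 20.0


@dataclass(frozen=True)
class WeaningParams:
    """The four-parameter description of a weaning process.

    t1, t2 : ages (years) at the start and end of weaning
    enrichment : maternal-to-infant d15N trophic enrichment E (permil)
    d15n_wnfood : d15N of collagen synthesized entirely from weaning
        foods (permil)
    """

    t1: float
    t2: float
    enrichment: float
    d15n_wnfood: float

    def __post_init__(self):
        if self.t1 < 0:
            raise ValueError("t1 must be non-negative")
        if self.t2 < self.t1:
            raise ValueError("t2 must not precede t1")

    def as_array(self) -> np.ndarray:
        return np.array([self.t1, self.t2, self.enrichment, self.d15n_wnfood])


@dataclass(frozen=True)
class PopulationData:
    """Cross-sectional skeletal data for one population.

    Subadults are (age-at-death, bone-collagen d15N) records with ages in
    [0, 10); the maternal d15N is taken from the adult-female mean, with
    the all-adult mean as fallback (and vice versa for the all-adult
    mean used to standardize the weaning-food value).
    """

    ages: np.ndarray
    d15n: np.ndarray
    ids: tuple[str, ...] | None = None
    adult_female_mean: float | None = None
    adult_female_sd: float | None = None
    adult_all_mean: float | None = None
    adult_all_sd: float | None = None
    name: str = ""

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        d15n = np.asarray(self.d15n, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "d15n", d15n)
        if ages.shape != d15n.shape:
            raise ValueError("ages and d15n must have the same length")
        if len(ages) == 0:
            raise ValueError("population has no subadults")
        if np.any(ages < 0) or np.any(ages >= 10):
            raise ValueError("subadult ages must lie in [0, 10)")
        if self.adult_female_mean is None and self.adult_all_mean is None:
            raise ValueError("at least one adult reference mean is required")
        if len(ages) <= 6:
            warnings.warn(
                f"population {self.name!r} has {len(ages)} subadults; "
                "fewer than the inclusion criterion (more than six)",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.ages)

    @property
    def d15n_mother(self) -> float:
        """Maternal reference: adult-female mean, all-adult fallback."""
        if self.adult_female_mean is not None:
            return self.adult_female_mean
        return self.adult_all_mean

    @property
    def d15n_adult(self) -> float:
        """All-adult mean (adult-female fallback), used for delta_wnfood."""
        if self.adult_all_mean is not None:
            return self.adult_all_mean
        return self.adult_female_mean


@dataclass(frozen=True)
class Trajectory:
    """Diet signal and bulk-bone d15N on an age grid."""

    ages: np.ndarray
    synthesized: np.ndarray
    bone: np.ndarray


def synthesized_d15n(age, params: WeaningParams, d15n_mother: float):
    """d15N of collagen newly synthesized at ``age``.

    Plateau at mother+E before t1, at the weaning-food value after t2,
    and a rescaled exponential between the two (continuous at both
    endpoints; a step function when t1 == t2).
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    pre = d15n_mother + params.enrichment
    wf = params.d15n_wnfood
    if params.t2 == params.t1:
        return np.where(age < params.t1, pre, wf)
    u = np.clip((age - params.t1) / (params.t2 - params.t1), 0.0, 1.0)
    c = WEANING_SHAPE
    phi = (np.exp(-c * u) - np.exp(-c)) / (1.0 - np.exp(-c))
    return wf + (pre - wf) * phi


def _synth_segment_integral(a, b, t1, t2, pre, wf):
    """Vectorized closed-form integral of the diet signal over [a, b].

    ``a``/``b`` are scalars; the parameter arrays share one shape.
    """
    c = WEANING_SHAPE
    len_pre = np.clip(np.minimum(b, t1) - a, 0.0, None)
    len_post = np.clip(b - np.maximum(a, t2), 0.0, None)
    total = pre * len_pre + wf * len_post

    dur = t2 - t1
    lo = np.clip(np.maximum(a, t1), None, None)
    hi = np.minimum(b, t2)
    mid = (hi > lo) & (dur > 0)
    if np.any(mid):
        dur_m = np.where(mid, dur, 1.0)
        v1 = np.clip((lo - t1) / dur_m, 0.0, 1.0)
        v2 = np.clip((hi - t1) / dur_m, 0.0, 1.0)
        denom = 1.0 - np.exp(-c)
        # antiderivative of phi(v) = (exp(-c v) - exp(-c)) / denom
        prim = lambda v: (-np.exp(-c * v) / c - np.exp(-c) * v) / denom
        seg = wf * (hi - lo) + (pre - wf) * dur_m * (prim(v2) - prim(v1))
        total = total + np.where(mid, seg, 0.0)
    return total


def _integrate(nodes, theta, d15n_mother, qp: QPModel):
    """March the bone pool over consecutive ``nodes`` for a parameter
    batch; returns bone d15N at every node, shape (B, len(nodes))."""
    t1, t2, enr, wf = (theta[:, i] for i in range(4))
    pre = d15n_mother + enr
    bone = np.full(theta.shape[0], float(d15n_mother))
    out = np.empty((theta.shape[0], len(nodes)))
    out[:, 0] = bone
    anti = qp._antideriv
    for k in range(len(nodes) - 1):
        a, b = nodes[k], nodes[k + 1]
        h = b - a
        turn = max(float(anti(b) - anti(a)), RATE_FLOOR * h)
        s_mean = _synth_segment_integral(a, b, t1, t2, pre, wf) / h
        bone = s_mean + (bone - s_mean) * np.exp(-turn)
        out[:, k + 1] = bone
    return out


def _node_grid(ages: np.ndarray, step: float) -> np.ndarray:
    top = float(ages.max()) if len(ages) else 0.0
    grid = np.arange(0.0, top + step, step)
    return np.unique(np.concatenate([grid[grid <= top], ages, [0.0]]))


def simulate_batch(
    ages,
    theta: np.ndarray,
    d15n_mother: float,
    qp: QPModel | None = None,
    step: float = DEFAULT_STEP,
) -> np.ndarray:
    """Simulated bone d15N at each age for a (B, 4) parameter batch."""
    qp = qp or default_qp()
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if np.any(ages < 0) or np.any(ages > MAX_SIM_AGE):
        raise ValueError(f"ages must lie within [0, {MAX_SIM_AGE}]")
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    nodes = _node_grid(ages, step)
    bone = _integrate(nodes, theta, d15n_mother, qp)
    idx = np.searchsorted(nodes, ages)
    return bone[:, idx]


def simulate_bone_d15n(
    ages,
    params: WeaningParams,
    d15n_mother: float,
    qp: QPModel | None = None,
    step: float = DEFAULT_STEP,
) -> np.ndarray:
    """Bulk bone-collagen d15N at each requested age-at-death.

    The pool starts at the maternal value (collagen formed in utero and
    at birth carries the mother's signal) and relaxes toward the current
    diet signal at the age-dependent turnover rate.
    """
    return simulate_batch(ages, params.as_array()[None, :], d15n_mother, qp, step)[0]


def trajectory(
    params: WeaningParams,
    d15n_mother: float,
    qp: QPModel | None = None,
    max_age: float = 10.0,
    step: float = DEFAULT_STEP,
) -> Trajectory:
    """Full diet-signal and bone curves on a regular age grid."""
    ages = np.round(np.arange(0.0, max_age + step / 2, step), 10)
    bone = simulate_bone_d15n(ages, params, d15n_mother, qp, step)
    synth = synthesized_d15n(ages, params, d15n_mother)
    return Trajectory(ages=ages, synthesized=synth, bone=bone)


def distance(observed, simulated) -> float:
    """Mean squared difference between observed and simulated d15N."""
    obs = observed.d15n if isinstance(observed, PopulationData) else np.asarray(
        observed, dtype=float
    )
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape:
        raise ValueError("observed and simulated must have equal length")
    if obs.size == 0:
        raise ValueError("empty input")
    return float(np.mean((obs - sim) ** 2))


def euler_oracle(
    ages,
    params: WeaningParams,
    d15n_mother: float,
    qp: QPModel | None = None,
    step: float = 0.001,
) -> np.ndarray:
    """Brute-force fine-step Euler integration of the same mixing rule.

    Independent check for the production integrator: per step the pool
    mixes in newly synthesized collagen at fraction min(rate*dt, 1).
    """
    qp = qp or default_qp()
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    out = np.empty_like(ages)
    for j, target in enumerate(ages):
        n = int(np.ceil(target / step)) if target > 0 else 0
        ts = np.linspace(0.0, target, n + 1)
        dt = target / n if n else 0.0
        fracs = np.minimum(qp.rate(ts[:-1]) * dt, 1.0).tolist()
        synth = synthesized_d15n(ts[:-1], params, d15n_mother).tolist() if n else []
        bone = float(d15n_mother)
        for f, s in zip(fracs, synth):
            bone += f * (s - bone)
        out[j] = bone
    return out
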