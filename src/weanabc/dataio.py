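"""Readers, writers, and run configuration.

The population CSV is a single diff-able text file: a block of
``# key: value`` header lines carrying the adult reference statistics,
followed by one subadult per row (``id,age,d15n``).  Data-exclusion
decisions (ages at or above 10 years, adult-mean fallbacks) are logged,
never silent.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .abc_smc import (
    DEFAULT_PRIOR_MEANS,
    DEFAULT_PRIOR_SDS,
    ParticleSystem,
    SMCConfig,
    WEANING_PARAM_NAMES,
)
from .forward_model import PopulationData
from .posterior import (
    JOINT_PROB_THRESHOLD,
    MARGINAL_PROB_THRESHOLD,
    PosteriorSummary,
    flag_suspect_fit,
)

__all__ = [
    "RunConfig",
    "read_population_csv",
    "write_population_csv",
    "read_particles_csv",
    "write_results",
]

log = logging.getLogger("weanabc")

_HEADER_KEYS = (
    "adult_female_mean",
    "adult_female_sd",
    "adult_all_mean",
    "adult_all_sd",
)


@dataclass(frozen=True)
class RunConfig:
    """Everything a fit needs besides the data.

    ``prior_means``/``prior_sds`` follow the (t1, t2, E, wnfood) order;
    a ``None`` fourth prior mean is filled with the population's
    all-adult d15N mean at fit time.
    """

    prior_means: tuple = (*DEFAULT_PRIOR_MEANS, None)
    prior_sds: tuple = DEFAULT_PRIOR_SDS
    n_particles: int = 10000
    n_stages: int = 7
    tolerance_schedule: tuple | None = None
    kernel_scale: float = 1.0
    seed: int = 0
    joint_prob_threshold: float = JOINT_PROB_THRESHOLD
    marginal_prob_threshold: float = MARGINAL_PROB_THRESHOLD
    credible_level: float = 0.95

    def __post_init__(self):
        for thr in (self.joint_prob_threshold, self.marginal_prob_threshold):
            if not 0.0 <= thr <= 1.0:
                raise ValueError("probability thresholds must lie in [0, 1]")

    def smc_config(self) -> SMCConfig:
        return SMCConfig(
            n_particles=self.n_particles,
            n_stages=self.n_stages,
            tolerance_schedule=self.tolerance_schedule,
            kernel_scale=self.kernel_scale,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "prior_means" in raw:
            raw["prior_means"] = tuple(raw["prior_means"])
        if "prior_sds" in raw:
            raw["prior_sds"] = tuple(raw["prior_sds"])
        if raw.get("tolerance_schedule") is not None:
            raw["tolerance_schedule"] = tuple(raw["tolerance_schedule"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "prior_means": list(self.prior_means),
            "prior_sds": list(self.prior_sds),
            "n_particles": self.n_particles,
            "n_stages": self.n_stages,
            "tolerance_schedule": (
                None
                if self.tolerance_schedule is None
                else list(self.tolerance_schedule)
            ),
            "kernel_scale": self.kernel_scale,
            "seed": self.seed,
            "joint_prob_threshold": self.joint_prob_threshold,
            "marginal_prob_threshold": self.marginal_prob_threshold,
            "credible_level": self.credible_level,
        }


def read_population_csv(path) -> PopulationData:
    """Parse a population file into validated :class:`PopulationData`.

    Subadults at or above 10 years are dropped (with a logged count); a
    missing adult-female mean falls back to the all-adult mean (logged),
    and vice versa inside :class:`PopulationData`.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    meta: dict[str, float] = {}
    name = path.stem
    for line in text.splitlines():
        if not line.startswith("#"):
            continue
        body = line.lstrip("#").strip()
        if ":" not in body:
            continue
        key, _, value = body.partition(":")
        key = key.strip()
        if key == "name":
            name = value.strip()
        elif key in _HEADER_KEYS:
            try:
                meta[key] = float(value)
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric header value {line!r}") from exc
    frame = pd.read_csv(io.StringIO(text), comment="#")
    missing = {"id", "age", "d15n"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("age", "d15n"):
        frame[col] = pd.to_numeric(frame[col], errors="raise")
    usable = frame[frame["age"] < 10.0]
    dropped = len(frame) - len(usable)
    if dropped:
        log.info("%s: excluded %d subadult(s) aged 10 years or older", path, dropped)
    if len(usable) == 0:
        raise ValueError(f"{path}: no usable subadults below 10 years")
    if meta.get("adult_female_mean") is None and meta.get("adult_all_mean") is not None:
        log.info("%s: no adult-female mean; using the all-adult mean instead", path)
    return PopulationData(
        ages=usable["age"].to_numpy(),
        d15n=usable["d15n"].to_numpy(),
        ids=tuple(usable["id"].astype(str)),
        adult_female_mean=meta.get("adult_female_mean"),
        adult_female_sd=meta.get("adult_female_sd"),
        adult_all_mean=meta.get("adult_all_mean"),
        adult_all_sd=meta.get("adult_all_sd"),
        name=name,
    )


def write_population_csv(pop: PopulationData, path) -> None:
    path = Path(path)
    lines = [f"# name: {pop.name}"]
    for key in _HEADER_KEYS:
        value = getattr(pop, key)
        if value is not None:
            lines.append(f"# {key}: {value}")
    lines.append("id,age,d15n")
    ids = pop.ids or tuple(f"S{i + 1:03d}" for i in range(len(pop)))
    for pid, age, d15n in zip(ids, pop.ages, pop.d15n):
        lines.append(f"{pid},{age},{d15n}")
    path.write_text("\n".join(lines) + "\n")


def _particles_frame(ps: ParticleSystem) -> pd.DataFrame:
    frame = pd.DataFrame(ps.particles, columns=list(ps.param_names))
    frame["weight"] = ps.weights
    frame["distance"] = ps.distances
    return frame


def read_particles_csv(path) -> ParticleSystem:
    frame = pd.read_csv(path)
    names = [c for c in frame.columns if c not in ("weight", "distance")]
    return ParticleSystem(
        particles=frame[names].to_numpy(),
        weights=frame["weight"].to_numpy(),
        distances=frame["distance"].to_numpy(),
        tolerance=float("nan"),
        tolerance_history=(),
        acceptance_history=(),
        param_names=tuple(names),
    )


def write_results(
    summary: PosteriorSummary,
    ps: ParticleSystem,
    outdir,
    config: RunConfig | None = None,
    mkdir: bool = True,
) -> dict:
    """Write particles.csv, summary.json, and a reproducibility manifest.

    Returns the manifest (seed, config hash, package version, tolerance
    and acceptance histories); re-running with the manifest's seed and
    config reproduces the outputs.
    """
    from . import __version__

    outdir = Path(outdir)
    if mkdir:
        outdir.mkdir(parents=True, exist_ok=True)
    elif not outdir.is_dir():
        raise FileNotFoundError(f"output directory {outdir} does not exist")

    _particles_frame(ps).to_csv(outdir / "particles.csv", index=False)

    config = config or RunConfig()
    payload = summary.to_dict()
    payload["flags"] = flag_suspect_fit(
        summary,
        joint_threshold=config.joint_prob_threshold,
        marginal_threshold=config.marginal_prob_threshold,
    )
    (outdir / "summary.json").write_text(json.dumps(payload, indent=2) + "\n")

    config_blob = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "package": "weanabc",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "final_tolerance": ps.tolerance,
        "tolerance_history": list(ps.tolerance_history),
        "acceptance_history": list(ps.acceptance_history),
        "n_particles": len(ps),
        "ess": ps.ess(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
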