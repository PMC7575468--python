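"""Synthetic cohorts: per-participant diffusion parameters for two groups.

A scenario is a between-groups design point.  Group A draws its drift and
boundary from the base distributions; group B's mean drift is shifted up by
``delta_drift`` and its mean boundary down by ``delta_boundary`` (negative
values encode a raised boundary, i.e. a more conservative group B).  Equal
within-group standard deviations make the declared drift effect size
``delta_drift / within_sd_drift`` exact by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

from .diffusion import DiffusionParams

__all__ = [
    "GroupSpec",
    "ScenarioSpec",
    "sample_group",
    "build_scenario",
    "null_counterpart",
    "scenario_preset",
    "PRESETS",
]


@dataclass(frozen=True)
class GroupSpec:
    """Sampling distribution for one group's participants."""

    mean_drift: float
    sd_drift: float
    mean_boundary: float
    sd_boundary: float
    non_decision_time: float
    n_participants: int
    n_trials: int

    def __post_init__(self) -> None:
        if self.sd_drift < 0 or self.sd_boundary < 0:
            raise ValueError("standard deviations must be >= 0")
        if not self.mean_boundary > 0:
            raise ValueError("mean_boundary must be > 0")
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class ScenarioSpec:
    """A between-groups design point.

    Defaults are the study conditions: base drift and boundary 2 with
    within-group SD 0.05, non-decision time 0.3 s, 40 trials per
    participant, two-sided tests at alpha = 0.05.
    """

    delta_drift: float = 0.0
    delta_boundary: float = 0.0
    base_drift: float = 2.0
    base_boundary: float = 2.0
    within_sd_drift: float = 0.05
    within_sd_boundary: float = 0.05
    non_decision_time: float = 0.3
    n_per_group: int = 100
    n_trials: int = 40
    alpha: float = 0.05
    name: str = "scenario"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def declared_effect_size(self) -> float:
        """Cohen's d built into the drift distributions."""
        return self.delta_drift / self.within_sd_drift

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioSpec":
        return cls.from_dict(yaml.safe_load(text))


def build_scenario(spec: ScenarioSpec) -> tuple[GroupSpec, GroupSpec]:
    """Expand a scenario into the two group sampling distributions."""
    b_boundary = spec.base_boundary - spec.delta_boundary
    if b_boundary <= 0:
        raise ValueError(
            f"group B mean boundary {b_boundary} <= 0; reduce delta_boundary"
        )
    common = dict(
        sd_drift=spec.within_sd_drift,
        sd_boundary=spec.within_sd_boundary,
        non_decision_time=spec.non_decision_time,
        n_participants=spec.n_per_group,
        n_trials=spec.n_trials,
    )
    group_a = GroupSpec(
        mean_drift=spec.base_drift, mean_boundary=spec.base_boundary, **common
    )
    group_b = GroupSpec(
        mean_drift=spec.base_drift + spec.delta_drift,
        mean_boundary=b_boundary,
        **common,
    )
    return group_a, group_b


def _sample_group_arrays(
    spec: GroupSpec, rng: np.random.Generator, size: tuple | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (drift, boundary) arrays; boundary draws <= 0 are resampled."""
    shape = (spec.n_participants,) if size is None else size
    drift = rng.normal(spec.mean_drift, spec.sd_drift, shape)
    boundary = rng.normal(spec.mean_boundary, spec.sd_boundary, shape)
    while True:
        bad = boundary <= 0
        if not bad.any():
            break
        boundary[bad] = rng.normal(spec.mean_boundary, spec.sd_boundary, int(bad.sum()))
    return drift, boundary


def sample_group(
    spec: GroupSpec,
    rng: np.random.Generator,
    noise: float = 1.0,
    dt: float = 0.001,
) -> list[DiffusionParams]:
    """Draw one participant parameter set per group member.

    Drift and boundary are independent normal draws (boundary rejected and
    resampled at <= 0, which at mean 2 / SD 0.05 essentially never fires);
    the start is pinned to the midpoint and the non-decision time is fixed.
    """
    drift, boundary = _sample_group_arrays(spec, rng)
    return [
        DiffusionParams(
            drift=float(v),
            boundary=float(a),
            non_decision_time=spec.non_decision_time,
            noise=noise,
            dt=dt,
        )
        for v, a in zip(drift, boundary)
    ]


def null_counterpart(spec: ScenarioSpec) -> ScenarioSpec:
    """The matched false-alarm scenario: same design, zero drift difference."""
    return dataclasses.replace(spec, delta_drift=0.0, name=spec.name + "_null")


#: Bundled design points.  `no_sato`: a pure drift difference.
#: `sato_lowered`/`sato_raised`: the same drift difference confounded with a
#: lowered / raised group-B boundary of equal declared effect size.
#: `null`: no true difference of any kind.
PRESETS: dict[str, ScenarioSpec] = {
    "no_sato": ScenarioSpec(delta_drift=0.1, delta_boundary=0.0, name="no_sato"),
    "sato_lowered": ScenarioSpec(delta_drift=0.1, delta_boundary=0.1, name="sato_lowered"),
    "sato_raised": ScenarioSpec(delta_drift=0.1, delta_boundary=-0.1, name="sato_raised"),
    "null": ScenarioSpec(delta_drift=0.0, delta_boundary=0.0, name="null"),
}


def scenario_preset(name: str, **overrides) -> ScenarioSpec:
    """Look up a bundled preset, optionally overriding fields."""
    try:
        spec = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return dataclasses.replace(spec, **overrides) if overrides else spec
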