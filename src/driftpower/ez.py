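"""EZ-diffusion closed-form parameter recovery.

The EZ method inverts three summary statistics of a participant's data —
proportion correct ``Pc``, and the mean ``MRT`` and variance ``VRT`` of the
correct-trial response times — into estimates of drift, boundary separation
and non-decision time, assuming an unbiased start and no inter-trial
parameter variability.  With ``L = logit(Pc)``:

    v_hat  = sign(Pc - 1/2) * s * [ L (Pc^2 L - Pc L + Pc - 1/2) / VRT ]^(1/4)
    a_hat  = s^2 L / v_hat
    MDT    = (a_hat / 2 v_hat) * tanh(v_hat a_hat / (2 s^2))
    ter^   = MRT - MDT

``Pc`` values of 0, 1/2 or 1 make the logit degenerate and are nudged by
the half-count rule before inversion.  A negative recovered non-decision
time is possible in finite samples and is returned as-is; clamping would
bias group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .diffusion import DEFAULT_NOISE, TrialSet

__all__ = [
    "SummaryStats",
    "EZEstimate",
    "UnfittableError",
    "summarize_trial_set",
    "edge_correct_accuracy",
    "ez_inverse",
]


class UnfittableError(ValueError):
    """Too few usable trials to form the EZ summary statistics."""


@dataclass(frozen=True)
class SummaryStats:
    """Per-participant inputs to the EZ inversion."""

    p_correct: float
    mean_rt: float  # seconds, correct trials
    var_rt: float   # seconds^2, correct trials
    n_trials: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_correct <= 1.0:
            raise ValueError("p_correct must be in [0, 1]")
        if self.var_rt < 0:
            raise ValueError("var_rt must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class EZEstimate:
    """Recovered diffusion parameters."""

    drift: float
    boundary: float
    non_decision_time: float


def summarize_trial_set(trials: TrialSet, correct_only: bool = True) -> SummaryStats:
    """Reduce a trial set to (Pc, MRT, VRT).

    RT moments are taken over correct trials only by default, the standard
    EZ practice at high accuracy (set ``correct_only=False`` to pool all
    trials).  Raises :class:`UnfittableError` when fewer than two trials
    enter the moments, since the variance is then undefined.
    """
    correct = trials.correct
    rt = trials.rt
    n = len(trials)
    sel = rt[correct] if correct_only else rt
    if sel.size < 2:
        raise UnfittableError(
            f"{sel.size} usable trial(s); need >= 2 for an RT variance"
        )
    return SummaryStats(
        p_correct=float(correct.sum()) / n,
        mean_rt=float(sel.mean()),
        var_rt=float(sel.var(ddof=1)),
        n_trials=n,
    )


def edge_correct_accuracy(p_correct: float, n_trials: int) -> float:
    """Half-count nudge keeping logit(Pc) finite and nonzero.

    1 -> 1 - 1/(2n);  0 -> 1/(2n);  1/2 -> 1/2 + 1/(2n);  otherwise
    unchanged.
    """
    if not 0.0 <= p_correct <= 1.0:
        raise ValueError("p_correct must be in [0, 1]")
    half = 1.0 / (2.0 * n_trials)
    if p_correct == 1.0:
        return 1.0 - half
    if p_correct == 0.0:
        return half
    if p_correct == 0.5:
        return 0.5 + half
    return p_correct


def _ez_drift_boundary_arrays(
    pc: np.ndarray, var_rt: np.ndarray, noise: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized core of the inversion; ``pc`` must be edge-corrected."""
    s = noise
    logit = np.log(pc / (1.0 - pc))
    x = logit * (pc * pc * logit - pc * logit + pc - 0.5) / var_rt
    # x > 0 whenever pc != 1/2 (both factors change sign together at 1/2)
    drift = np.sign(pc - 0.5) * s * np.abs(x) ** 0.25
    boundary = s * s * logit / drift
    return drift, boundary


def ez_inverse(stats: SummaryStats, noise: float = DEFAULT_NOISE) -> EZEstimate:
    """Invert summary statistics into an :class:`EZEstimate`.

    The accuracy is edge-corrected internally; the identity
    ``v_hat * a_hat == s^2 * logit(Pc_corrected)`` holds exactly.
    """
    if stats.var_rt <= 0.0:
        raise UnfittableError("var_rt must be > 0 for the EZ inversion")
    pc = edge_correct_accuracy(stats.p_correct, stats.n_trials)
    drift_arr, boundary_arr = _ez_drift_boundary_arrays(
        np.asarray(pc, dtype=float), np.asarray(stats.var_rt, dtype=float), noise
    )
    v, a = float(drift_arr), float(boundary_arr)
    va = v * a / noise**2
    mdt = (a / (2.0 * v)) * (1.0 - math.exp(-va)) / (1.0 + math.exp(-va))
    return EZEstimate(
        drift=v, boundary=a, non_decision_time=stats.mean_rt - mdt
    )
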