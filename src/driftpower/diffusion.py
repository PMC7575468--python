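"""Trial-level simulation of the two-boundary drift-diffusion process.

A decision is modelled as a Wiener process with drift ``v`` that starts at
``z`` between two absorbing boundaries at 0 and ``a``; crossing the upper
boundary is the correct response, crossing the lower one an error.  The
response time is the first-passage time plus a fixed non-decision component
``t_er``.  Two samplers are provided:

* an Euler–Maruyama path simulator (``method="euler"``), the transparent
  reference implementation, with an optional continuity correction for the
  O(sqrt(dt)) boundary-crossing bias; and
* an exact sampler (``method="exact"``) that draws the choice from the
  closed-form absorption probability and the decision time by numerically
  inverting the large-time series expansion of the first-passage CDF.
  For an unbiased start the conditional decision-time distribution is the
  same at both boundaries and depends on the parameters only through
  ``mu = v * a / s**2`` after rescaling time by ``a**2 / s**2``.

Closed-form expressions for the choice probability and (unbiased-start)
mean decision time are exposed as oracles so that both samplers can be
validated against them.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

logger = logging.getLogger(__name__)

#: intra-trial noise convention: evidence-unit diffusion coefficient.
#: With drift and boundary near 2 this yields response times of order 1 s.
DEFAULT_NOISE = 1.0
#: Euler integration step (seconds).
DEFAULT_DT = 0.001
#: non-termination guard for the Euler path simulator.
MAX_STEPS = 1_000_000
#: zeta(1/2)/sqrt(2*pi) — boundary shift of the Broadie–Glasserman–Kou
#: continuity correction for discrete monitoring of a continuous barrier.
EULER_BOUNDARY_SHIFT = 0.5826


class SimulationError(RuntimeError):
    """A diffusion path failed to terminate within the step budget."""


@dataclass(frozen=True)
class DiffusionParams:
    """Generative parameters of one decision-maker.

    Parameters
    ----------
    drift:
        Mean evidence-accumulation rate ``v`` (evidence units / s), signed
        toward the correct (upper) boundary.
    boundary:
        Boundary separation ``a`` (evidence units), > 0.
    start:
        Starting point ``z`` (evidence units from the lower boundary).
        ``None`` (default) places the start midway, the unbiased setting.
    non_decision_time:
        Fixed encoding/motor latency ``t_er`` (s), >= 0.
    noise:
        Intra-trial diffusion coefficient ``s`` (evidence units / sqrt(s)).
    dt:
        Euler step (s); only used by the path simulator.
    """

    drift: float
    boundary: float
    start: float | None = None
    non_decision_time: float = 0.3
    noise: float = DEFAULT_NOISE
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        if self.start is None:
            object.__setattr__(self, "start", self.boundary / 2.0)
        if not self.boundary > 0:
            raise ValueError(f"boundary must be > 0, got {self.boundary}")
        if not 0 < self.start < self.boundary:
            raise ValueError(
                f"start must lie strictly between the boundaries: "
                f"z={self.start}, a={self.boundary}"
            )
        if self.non_decision_time < 0:
            raise ValueError("non_decision_time must be >= 0")
        if not self.noise > 0:
            raise ValueError("noise must be > 0")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")

    @property
    def unbiased(self) -> bool:
        return math.isclose(self.start, self.boundary / 2.0, rel_tol=1e-12)


@dataclass(frozen=True)
class TrialOutcome:
    """One simulated decision: correctness and response time (s)."""

    correct: bool
    rt: float


@dataclass(frozen=True)
class TrialSet:
    """Ordered trials from one simulated participant."""

    outcomes: tuple[TrialOutcome, ...]
    params: DiffusionParams

    def __len__(self) -> int:
        return len(self.outcomes)

    @property
    def correct(self) -> np.ndarray:
        return np.array([o.correct for o in self.outcomes], dtype=bool)

    @property
    def rt(self) -> np.ndarray:
        return np.array([o.rt for o in self.outcomes], dtype=float)

    def to_frame(self, participant_id: int = 0) -> pd.DataFrame:
        """Trial dump with columns participant_id, trial, correct, rt_s."""
        return pd.DataFrame(
            {
                "participant_id": participant_id,
                "trial": np.arange(len(self)),
                "correct": self.correct.astype(int),
                "rt_s": self.rt,
            }
        )


# ---------------------------------------------------------------------------
# closed-form oracles
# ---------------------------------------------------------------------------

def analytic_choice_probability(params: DiffusionParams) -> float:
    """Probability of absorption at the upper (correct) boundary.

    ``(1 - exp(-2 v z / s^2)) / (1 - exp(-2 v a / s^2))``, continued as
    ``z / a`` at ``v = 0``.  For the unbiased start this reduces to the
    logistic function of ``v a / s^2``.
    """
    v, a, z, s2 = params.drift, params.boundary, params.start, params.noise**2
    if abs(v) < 1e-12:
        return z / a
    # expm1 keeps precision for small exponents
    return math.expm1(-2.0 * v * z / s2) / math.expm1(-2.0 * v * a / s2)


def analytic_mean_decision_time(params: DiffusionParams) -> float:
    """Mean first-passage time for an unbiased start (either boundary).

    ``(a / 2v) * tanh(v a / (2 s^2))``; the ``v -> 0`` limit is
    ``a^2 / (4 s^2)``.  Only valid at ``z = a/2``.
    """
    if not params.unbiased:
        raise ValueError("mean decision-time formula requires z = a/2")
    v, a, s2 = params.drift, params.boundary, params.noise**2
    if abs(v) < 1e-12:
        return a * a / (4.0 * s2)
    return (a / (2.0 * v)) * math.tanh(v * a / (2.0 * s2))


# ---------------------------------------------------------------------------
# exact first-passage sampler
# ---------------------------------------------------------------------------
#
# Rescaling X -> X/a, t -> t s^2/a^2 maps the problem onto boundaries {0, 1}
# with unit diffusion and drift mu = v a / s^2.  With an unbiased start the
# decision time conditional on the chosen boundary has CDF
#
#   F(T) = 1 - 2 pi cosh(mu/2) * sum_{k odd} (-1)^((k-1)/2) k e^(-lam_k T)/lam_k
#
# with lam_k = (mu^2 + k^2 pi^2)/2, which depends on mu only through mu^2
# (correct and error responses share one distribution).  The kernel solves
# F(T) = u per trial with safeguarded Newton iterations; the series needs
# only a handful of terms except in the extreme left tail, which carries
# mass exp(-1/(8T)) and is cut off at T = 2e-3 scaled units.

_T_FLOOR = 2e-3
_PI2 = math.pi * math.pi


@njit(cache=True)
def _fpt_quantile_kernel(musq: np.ndarray, u: np.ndarray) -> np.ndarray:  # pragma: no cover
    n = musq.size
    out = np.empty(n)
    for i in range(n):
        m2 = musq[i]
        ui = min(max(u[i], 1e-16), 1.0 - 1e-16)
        amp = 2.0 * np.pi * np.cosh(np.sqrt(m2) / 2.0)
        target = 1.0 - ui  # solve amp * S(T) = 1 - u, S the tail series
        mu = np.sqrt(m2)
        t0 = np.tanh(mu / 2.0) / (2.0 * mu) if mu > 1e-8 else 0.25
        lo = _T_FLOOR
        hi = t0
        for _ in range(200):  # expand upper bracket
            s_tail = 0.0
            k = 1.0
            sgn = 1.0
            while k < 400.0:
                lam = 0.5 * (m2 + k * k * _PI2)
                e = np.exp(-lam * hi)
                s_tail += sgn * k * e / lam
                if k > 3.0 and k * e < 1e-15:
                    break
                sgn = -sgn
                k += 2.0
            if amp * s_tail <= target:
                break
            lo = hi
            hi *= 2.0
        t = 0.5 * (lo + hi)
        for _ in range(100):
            s_tail = 0.0
            dens = 0.0
            k = 1.0
            sgn = 1.0
            while k < 400.0:
                lam = 0.5 * (m2 + k * k * _PI2)
                e = sgn * k * np.exp(-lam * t)
                s_tail += e / lam
                dens += e
                if k > 3.0 and k * np.exp(-lam * t) < 1e-15:
                    break
                sgn = -sgn
                k += 2.0
            g = amp * s_tail - target  # decreasing in t
            if g > 0.0:
                lo = t
            else:
                hi = t
            f = amp * dens
            t_new = t + g / f if f > 1e-300 else 0.5 * (lo + hi)
            if t_new <= lo or t_new >= hi:
                t_new = 0.5 * (lo + hi)
            if abs(t_new - t) < 1e-12 * (t + 1e-3):
                t = t_new
                break
            t = t_new
        out[i] = t
    return out


def conditional_decision_time_quantile(mu: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Quantile function of the scaled conditional decision time.

    ``mu`` is the scaled drift ``v a / s^2`` (the result depends only on its
    square); ``u`` the probability level in (0, 1).  Returns times in scaled
    units; multiply by ``a^2 / s^2`` for seconds.
    """
    mu = np.ascontiguousarray(np.asarray(mu, dtype=float) ** 2)
    u = np.ascontiguousarray(u, dtype=float)
    return _fpt_quantile_kernel(mu, u)


def sample_trials_exact(
    drift: np.ndarray,
    boundary: np.ndarray,
    noise: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-trial draws for unbiased-start diffusion.

    ``drift`` and ``boundary`` are broadcastable arrays with one entry per
    trial.  Returns ``(correct, decision_time)``; non-decision time is not
    added here.
    """
    drift = np.asarray(drift, dtype=float)
    boundary = np.asarray(boundary, dtype=float)
    mu = drift * boundary / noise**2
    p_correct = 1.0 / (1.0 + np.exp(-mu))
    correct = rng.random(mu.shape) < p_correct
    u = rng.random(mu.shape)
    t_scaled = _fpt_quantile_kernel(
        np.ascontiguousarray((mu * mu).ravel()), np.ascontiguousarray(u.ravel())
    ).reshape(mu.shape)
    return correct, t_scaled * boundary**2 / noise**2


# ---------------------------------------------------------------------------
# Euler–Maruyama path simulator
# ---------------------------------------------------------------------------

def _euler_batch(
    params: DiffusionParams,
    n_trials: int,
    rng: np.random.Generator,
    boundary_correction: bool = True,
    max_steps: int = MAX_STEPS,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n_trials`` paths; returns (correct, rt) including t_er.

    The crossing rule is the first step at which the accumulator reaches a
    boundary.  With ``boundary_correction`` both boundaries are pulled in by
    ``0.5826 * s * sqrt(dt)``, cancelling the leading O(sqrt(dt)) bias of
    discretely monitored crossings.
    """
    v, a, z = params.drift, params.boundary, params.start
    s, dt = params.noise, params.dt
    shift = EULER_BOUNDARY_SHIFT * s * math.sqrt(dt) if boundary_correction else 0.0
    lower, upper = shift, a - shift
    if not lower < z < upper:
        raise ValueError("start lies outside the corrected boundaries; reduce dt")
    x = np.full(n_trials, z, dtype=float)
    rt = np.empty(n_trials)
    correct = np.empty(n_trials, dtype=bool)
    alive = np.arange(n_trials)
    step_sd = s * math.sqrt(dt)
    for step in range(1, max_steps + 1):
        x[alive] += v * dt + step_sd * rng.standard_normal(alive.size)
        xa = x[alive]
        done = (xa >= upper) | (xa <= lower)
        if done.any():
            idx = alive[done]
            rt[idx] = step * dt + params.non_decision_time
            correct[idx] = x[idx] >= upper
            alive = alive[~done]
            if alive.size == 0:
                return correct, rt
    raise SimulationError(
        f"{alive.size} path(s) unfinished after {max_steps} steps for {params}"
    )


def simulate_trial(
    params: DiffusionParams,
    rng: np.random.Generator,
    boundary_correction: bool = True,
    max_steps: int = MAX_STEPS,
) -> TrialOutcome:
    """Simulate a single decision by Euler–Maruyama path integration."""
    correct, rt = _euler_batch(
        params, 1, rng, boundary_correction=boundary_correction, max_steps=max_steps
    )
    return TrialOutcome(correct=bool(correct[0]), rt=float(rt[0]))


def simulate_trial_set(
    params: DiffusionParams,
    n_trials: int,
    rng: np.random.Generator,
    method: str = "exact",
    boundary_correction: bool = True,
    max_steps: int = MAX_STEPS,
) -> TrialSet:
    """Simulate one participant's trials.

    ``method="exact"`` (default) uses the series-inversion sampler and
    requires an unbiased start; ``method="euler"`` integrates paths and
    supports any start.  Both converge to the same first-passage law.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    if method == "euler":
        correct, rt = _euler_batch(
            params, n_trials, rng,
            boundary_correction=boundary_correction, max_steps=max_steps,
        )
    elif method == "exact":
        if not params.unbiased:
            raise ValueError("exact sampler requires an unbiased start (z = a/2)")
        correct, t_dec = sample_trials_exact(
            np.full(n_trials, params.drift),
            np.full(n_trials, params.boundary),
            params.noise,
            rng,
        )
        rt = t_dec + params.non_decision_time
    else:
        raise ValueError(f"unknown method {method!r}")
    outcomes = tuple(
        TrialOutcome(correct=bool(c), rt=float(t)) for c, t in zip(correct, rt)
    )
    return TrialSet(outcomes=outcomes, params=params)


def sato_boundary_sweep(
    base: DiffusionParams,
    boundary_mean: float,
    boundary_sd: float,
    n_draws: int,
    n_trials: int,
    rng: np.random.Generator,
    method: str = "exact",
) -> pd.DataFrame:
    """Speed–accuracy trade-off visualization data.

    Draws ``n_draws`` boundary values from ``Normal(boundary_mean,
    boundary_sd)`` (non-positive draws are rejected and resampled), keeps
    every other parameter at ``base`` with the start pinned to the midpoint,
    and simulates ``n_trials`` trials per draw.  Returns one row per draw
    with columns ``boundary``, ``mean_rt``, ``accuracy``; the scatter traces
    the curvilinear trade-off between speed and accuracy as the decision
    criterion varies.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    boundaries = rng.normal(boundary_mean, boundary_sd, n_draws)
    while True:
        bad = boundaries <= 0
        if not bad.any():
            break
        boundaries[bad] = rng.normal(boundary_mean, boundary_sd, int(bad.sum()))
    rows = []
    for b in boundaries:
        p = dataclasses.replace(base, boundary=float(b), start=None)
        ts = simulate_trial_set(p, n_trials, rng, method=method)
        rows.append((float(b), float(ts.rt.mean()), float(ts.correct.mean())))
    return pd.DataFrame(rows, columns=["boundary", "mean_rt", "accuracy"])
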