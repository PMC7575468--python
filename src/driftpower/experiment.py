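"""One virtual experiment, end to end.

Sample two groups of participants under a scenario, simulate their trials,
reduce each participant to the three competing measures — mean correct RT,
accuracy, and the EZ-recovered drift — and test the group difference on
each with a pooled two-sample t-test.  A vectorized batch engine runs many
replications of the same scenario at once; the scalar path exposes
per-participant records for inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import ScenarioSpec, _sample_group_arrays, build_scenario
from .diffusion import DEFAULT_NOISE, sample_trials_exact
from .ez import _ez_drift_boundary_arrays, edge_correct_accuracy

logger = logging.getLogger(__name__)

__all__ = [
    "ParticipantRecord",
    "ExperimentResult",
    "two_sample_t_test",
    "cohens_d_observed",
    "run_experiment",
    "run_experiment_batch",
]

MEASURES = ("rt", "accuracy", "drift")


@dataclass(frozen=True)
class ParticipantRecord:
    """One simulated participant's observed measures."""

    group: str
    accuracy: float
    mean_correct_rt: float  # NaN when no correct trials
    drift_estimate: float   # NaN when unfittable
    fit_ok: bool


@dataclass(frozen=True)
class ExperimentResult:
    """Group-difference tests for one virtual experiment."""

    p_rt: float
    p_accuracy: float
    p_drift: float
    sig_rt: bool
    sig_accuracy: bool
    sig_drift: bool
    observed_d_rt: float
    observed_d_accuracy: float
    observed_d_drift: float
    n_excluded_rt: int
    n_excluded_drift: int
    alpha: float


def two_sample_t_test(
    xs, ys, equal_var: bool = True
) -> tuple[float, float]:
    """Pooled-variance (Student) two-sided t-test; Welch behind a flag.

    Degenerate inputs follow explicit conventions: if both samples have
    zero variance and equal means the test is maximally inconclusive
    (t = 0, p = 1); zero pooled variance with unequal means is an error.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 2 or ys.size < 2:
        raise ValueError("each sample needs >= 2 values")
    if equal_var and xs.var(ddof=1) == 0.0 and ys.var(ddof=1) == 0.0:
        if xs.mean() == ys.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    res = sps.ttest_ind(xs, ys, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def cohens_d_observed(xs, ys) -> float:
    """Standardized mean difference ``(mean(ys) - mean(xs)) / pooled SD``."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    nx, ny = xs.size, ys.size
    pooled_var = (
        (nx - 1) * xs.var(ddof=1) + (ny - 1) * ys.var(ddof=1)
    ) / (nx + ny - 2)
    if pooled_var <= 0.0:
        raise ValueError("zero pooled SD; Cohen's d undefined")
    return float((ys.mean() - xs.mean()) / np.sqrt(pooled_var))


# ---------------------------------------------------------------------------
# vectorized engine
# ---------------------------------------------------------------------------

def _simulate_measures(
    spec: ScenarioSpec,
    n_reps: int,
    rng: np.random.Generator,
    noise: float,
) -> dict[str, np.ndarray]:
    """Per-participant measures for a block of replications.

    Returns arrays of shape ``(n_reps, 2, n_per_group)`` (axis 1: group A,
    group B): ``rt`` (mean correct RT, NaN without a correct trial),
    ``accuracy``, ``drift`` (EZ estimate, NaN when unfittable).
    """
    group_a, group_b = build_scenario(spec)
    n, n_trials = spec.n_per_group, spec.n_trials
    shape = (n_reps, 2, n)
    drift = np.empty(shape)
    boundary = np.empty(shape)
    for g, gs in enumerate((group_a, group_b)):
        drift[:, g, :], boundary[:, g, :] = _sample_group_arrays(
            gs, rng, size=(n_reps, n)
        )

    trial_shape = shape + (n_trials,)
    correct, t_dec = sample_trials_exact(
        np.broadcast_to(drift[..., None], trial_shape),
        np.broadcast_to(boundary[..., None], trial_shape),
        noise,
        rng,
    )
    rt = t_dec + spec.non_decision_time

    n_correct = correct.sum(axis=-1)
    safe = np.maximum(n_correct, 1)
    mean_crt = np.where(correct, rt, 0.0).sum(axis=-1) / safe
    var_crt = np.where(
        correct, (rt - mean_crt[..., None]) ** 2, 0.0
    ).sum(axis=-1) / np.maximum(n_correct - 1, 1)
    accuracy = n_correct / n_trials

    # EZ on edge-corrected accuracy; moments over correct trials only
    half = 1.0 / (2.0 * n_trials)
    pc = np.where(
        accuracy == 1.0, 1.0 - half,
        np.where(accuracy == 0.0, half,
                 np.where(accuracy == 0.5, 0.5 + half, accuracy)),
    )
    fittable = (n_correct >= 2) & (var_crt > 0.0)
    ez_drift, _ = _ez_drift_boundary_arrays(pc, np.where(fittable, var_crt, 1.0), noise)

    return {
        "rt": np.where(n_correct >= 1, mean_crt, np.nan),
        "accuracy": accuracy,
        "drift": np.where(fittable, ez_drift, np.nan),
    }


def _group_tests(measure: np.ndarray, alpha: float) -> dict[str, np.ndarray]:
    """Pooled t-tests and Cohen's d per replication, NaN-excluding.

    ``measure`` has shape (R, 2, n).  Raises if any group drops below two
    usable participants.
    """
    valid = ~np.isnan(measure)
    counts = valid.sum(axis=2)  # (R, 2)
    if (counts < 2).any():
        raise RuntimeError("a group has fewer than 2 usable participants")
    x = np.where(valid, measure, 0.0)
    means = x.sum(axis=2) / counts
    sq = np.where(valid, (measure - means[..., None]) ** 2, 0.0)
    variances = sq.sum(axis=2) / (counts - 1)
    na, nb = counts[:, 0], counts[:, 1]
    pooled_var = ((na - 1) * variances[:, 0] + (nb - 1) * variances[:, 1]) / (
        na + nb - 2
    )
    diff = means[:, 1] - means[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
        t = diff / se
        d = diff / np.sqrt(pooled_var)
    df = na + nb - 2
    p = 2.0 * sps.t.sf(np.abs(t), df)
    degenerate = pooled_var == 0.0
    if degenerate.any():  # all-identical measures: inconclusive by convention
        p = np.where(degenerate & (diff == 0.0), 1.0, p)
        d = np.where(degenerate & (diff == 0.0), 0.0, d)
        if (degenerate & (diff != 0.0)).any():
            raise RuntimeError("zero pooled variance with unequal group means")
    n_excluded = (~valid).sum(axis=(1, 2))
    return {
        "p": p, "sig": p < alpha, "d": d, "n_excluded": n_excluded,
    }


def run_experiment_batch(
    spec: ScenarioSpec,
    n_reps: int,
    rng: np.random.Generator,
    noise: float = DEFAULT_NOISE,
    max_chunk_trials: int = 4_000_000,
) -> pd.DataFrame:
    """Run ``n_reps`` independent experiments under one scenario.

    Returns one row per replication with p-values, significance flags at
    ``spec.alpha``, observed Cohen's d and exclusion counts for each of the
    three measures.  Replications are processed in chunks sized to keep at
    most ``max_chunk_trials`` trials in memory.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    per_rep = 2 * spec.n_per_group * spec.n_trials
    chunk = max(1, max_chunk_trials // per_rep)
    frames = []
    done = 0
    while done < n_reps:
        r = min(chunk, n_reps - done)
        measures = _simulate_measures(spec, r, rng, noise)
        cols: dict[str, np.ndarray] = {}
        for name in MEASURES:
            res = _group_tests(measures[name], spec.alpha)
            cols[f"p_{name}"] = res["p"]
            cols[f"sig_{name}"] = res["sig"]
            cols[f"d_{name}"] = res["d"]
            cols[f"n_excluded_{name}"] = res["n_excluded"]
        frames.append(pd.DataFrame(cols))
        done += r
    return pd.concat(frames, ignore_index=True)


def run_experiment(
    spec: ScenarioSpec,
    rng: np.random.Generator,
    noise: float = DEFAULT_NOISE,
    return_participants: bool = False,
):
    """Run a single virtual experiment.

    Returns an :class:`ExperimentResult`, or ``(result, records)`` with a
    per-participant :class:`pandas.DataFrame` when ``return_participants``
    is set.
    """
    measures = _simulate_measures(spec, 1, rng, noise)
    per_measure = {name: _group_tests(measures[name], spec.alpha) for name in MEASURES}
    result = ExperimentResult(
        p_rt=float(per_measure["rt"]["p"][0]),
        p_accuracy=float(per_measure["accuracy"]["p"][0]),
        p_drift=float(per_measure["drift"]["p"][0]),
        sig_rt=bool(per_measure["rt"]["sig"][0]),
        sig_accuracy=bool(per_measure["accuracy"]["sig"][0]),
        sig_drift=bool(per_measure["drift"]["sig"][0]),
        observed_d_rt=float(per_measure["rt"]["d"][0]),
        observed_d_accuracy=float(per_measure["accuracy"]["d"][0]),
        observed_d_drift=float(per_measure["drift"]["d"][0]),
        n_excluded_rt=int(per_measure["rt"]["n_excluded"][0]),
        n_excluded_drift=int(per_measure["drift"]["n_excluded"][0]),
        alpha=spec.alpha,
    )
    if not return_participants:
        return result
    n = spec.n_per_group
    records = pd.DataFrame(
        {
            "group": ["A"] * n + ["B"] * n,
            "accuracy": measures["accuracy"][0].ravel(),
            "mean_correct_rt": measures["rt"][0].ravel(),
            "drift_estimate": measures["drift"][0].ravel(),
            "fit_ok": ~np.isnan(measures["drift"][0].ravel()),
        }
    )
    return result, records
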