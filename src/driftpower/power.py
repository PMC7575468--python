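"""Power surfaces: hit rates, false-alarm rates, d' and required sample sizes.

A measure's hit rate at a design point is the fraction of simulated
experiments whose test rejects when the drift difference is real; its
false-alarm rate is the same fraction under the matched null scenario
(zero drift difference, any boundary confound kept).  The two combine into
the bias-free sensitivity

    d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate),

with rates of exactly 0 or 1 pulled in by the half-count rule before the
probit.  Replication sets for hits and false alarms are independent, and
every (scenario, sample size, role, chunk) cell draws from its own
deterministic substream of the master seed, so results do not depend on
execution order.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import ScenarioSpec, null_counterpart
from .diffusion import DEFAULT_NOISE
from .experiment import MEASURES, run_experiment_batch

logger = logging.getLogger(__name__)

__all__ = [
    "SCALED_N_GRID",
    "PAPER_N_GRID",
    "RequiredN",
    "dprime",
    "run_scenario_batch",
    "required_sample_size",
    "effect_size_conversion",
    "substream",
]

#: default grid of the scaled profile (per-group sample sizes)
SCALED_N_GRID: tuple[int, ...] = tuple(range(10, 151, 10))
#: the full study grid: steps of 10 below 150, steps of 50 above
PAPER_N_GRID: tuple[int, ...] = tuple(range(10, 150, 10)) + tuple(range(150, 401, 50))


def substream(
    seed: int, scenario: str, n_per_group: int, role: str
) -> np.random.Generator:
    """Deterministic child stream keyed by (scenario, n, role).

    The key enters the numpy ``SeedSequence`` spawn key, so any cell can be
    regenerated in isolation and the full sweep is reproducible under any
    execution order or worker count.
    """
    key = (zlib.crc32(scenario.encode()), n_per_group, zlib.crc32(role.encode()))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def dprime(hit_rate: float, fa_rate: float, n_reps: int) -> float:
    """Sensitivity of a measure from its hit and false-alarm rates.

    Rates of exactly 0 or 1 are replaced by ``1/(2 n_reps)`` and
    ``1 - 1/(2 n_reps)`` so the probit stays finite.
    """
    hr = np.asarray(hit_rate, dtype=float)
    far = np.asarray(fa_rate, dtype=float)
    if ((hr < 0) | (hr > 1) | (far < 0) | (far > 1)).any():
        raise ValueError("rates must lie in [0, 1]")
    half = 1.0 / (2.0 * n_reps)
    hr = np.clip(hr, half, 1.0 - half)
    far = np.clip(far, half, 1.0 - half)
    out = sps.norm.ppf(hr) - sps.norm.ppf(far)
    return float(out) if out.ndim == 0 else out


def _rejection_rates(
    spec: ScenarioSpec, n_reps: int, rng: np.random.Generator, noise: float
) -> dict[str, float]:
    reps = run_experiment_batch(spec, n_reps, rng, noise=noise)
    return {m: float(reps[f"sig_{m}"].mean()) for m in MEASURES}


def run_scenario_batch(
    true_spec: ScenarioSpec,
    null_spec: ScenarioSpec,
    n_grid,
    n_reps: int,
    seed: int,
    noise: float = DEFAULT_NOISE,
    hits_only: bool = False,
) -> pd.DataFrame:
    """Sweep sample sizes for one scenario pair.

    For every ``n`` in ``n_grid``, runs ``n_reps`` experiments under
    ``true_spec`` (hit rates) and, unless ``hits_only``, ``n_reps`` under
    ``null_spec`` (false-alarm rates), on independent substreams.  Returns
    one row per (n, measure) with columns ``scenario, measure, n_per_group,
    n_reps, hit_rate, fa_rate, dprime, seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if null_counterpart(true_spec).to_dict() != dataclasses.replace(
        null_spec, name=true_spec.name + "_null"
    ).to_dict():
        raise ValueError("true_spec and null_spec must differ only in delta_drift")
    rows = []
    for n in n_grid:
        t0 = time.perf_counter()
        spec_n = dataclasses.replace(true_spec, n_per_group=int(n))
        hit = _rejection_rates(
            spec_n, n_reps, substream(seed, true_spec.name, int(n), "hits"), noise
        )
        if hits_only:
            fa = {m: np.nan for m in MEASURES}
        else:
            null_n = dataclasses.replace(null_spec, n_per_group=int(n))
            fa = _rejection_rates(
                null_n, n_reps, substream(seed, true_spec.name, int(n), "fa"), noise
            )
        for m in MEASURES:
            dp = np.nan if hits_only else dprime(hit[m], fa[m], n_reps)
            rows.append(
                (true_spec.name, m, int(n), n_reps, hit[m], fa[m], dp, seed)
            )
        logger.info(
            "scenario=%s n=%d done in %.1fs", true_spec.name, n,
            time.perf_counter() - t0,
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scenario", "measure", "n_per_group", "n_reps",
            "hit_rate", "fa_rate", "dprime", "seed",
        ],
    )


@dataclass(frozen=True)
class RequiredN:
    """Sample size needed to reach a target power on a grid.

    ``grid_n`` is the smallest grid point whose hit rate meets the target
    (None when never reached); ``interp_n`` linearly interpolates between
    the bracketing grid points and is reported separately.
    """

    grid_n: int | None
    interp_n: float | None
    reached: bool
    max_hit_rate: float


def required_sample_size(cells: pd.DataFrame, target: float = 0.8) -> RequiredN:
    """Read the required per-group sample size off a power curve.

    ``cells`` is a slice of a power table for a single measure with columns
    ``n_per_group`` and ``hit_rate`` over an increasing grid.
    """
    cells = cells.sort_values("n_per_group")
    ns = cells["n_per_group"].to_numpy()
    hr = cells["hit_rate"].to_numpy()
    if len(np.unique(ns)) != len(ns):
        raise ValueError("duplicate grid points; pass a single-measure slice")
    meets = hr >= target
    if not meets.any():
        return RequiredN(None, None, False, float(hr.max()))
    i = int(np.argmax(meets))
    if i == 0:
        return RequiredN(int(ns[0]), float(ns[0]), True, float(hr.max()))
    # first crossing from below, linear in hit rate
    frac = (target - hr[i - 1]) / (hr[i] - hr[i - 1])
    interp = ns[i - 1] + frac * (ns[i] - ns[i - 1])
    return RequiredN(int(ns[i]), float(interp), True, float(hr.max()))


def effect_size_conversion(
    delta_grid,
    template: ScenarioSpec,
    n_reps: int,
    seed: int,
    noise: float = DEFAULT_NOISE,
) -> pd.DataFrame:
    """How declared drift differences convert to observed effect sizes.

    For each drift difference in ``delta_grid``, runs ``n_reps``
    experiments at the template's sample size and averages the observed
    between-group Cohen's d of mean correct RT and of accuracy.  Returns
    columns ``delta_drift, declared_d, observed_d_rt, observed_d_accuracy,
    observed_d_drift``.
    """
    if template.within_sd_drift <= 0:
        raise ValueError("within_sd_drift must be > 0")
    rows = []
    for delta in delta_grid:
        spec = dataclasses.replace(
            template, delta_drift=float(delta), name=template.name
        )
        rng = substream(seed, f"{template.name}_conv_{delta:g}", spec.n_per_group, "hits")
        reps = run_experiment_batch(spec, n_reps, rng, noise=noise)
        rows.append(
            (
                float(delta),
                spec.declared_effect_size,
                float(reps["d_rt"].mean()),
                float(reps["d_accuracy"].mean()),
                float(reps["d_drift"].mean()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "delta_drift", "declared_d",
            "observed_d_rt", "observed_d_accuracy", "observed_d_drift",
        ],
    )
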