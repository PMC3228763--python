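"""Individual-based stochastic simulation of the first compartments.

Standard Gillespie algorithm on integer cell counts: the total event
propensity is ``r0*N0`` (stem events, when stem flux is on) plus
``sum_k r_k n_k``; waiting times are exponential and the acting compartment
is drawn proportionally to its propensity.  A dividing non-stem cell
differentiates (remove 1 from k, add 2 to k+1) with probability ``eps_k``,
dies with probability ``d_k``, and self-renews (add 1) otherwise.  A stem
event adds ``influx_factor`` cells to compartment 1 and leaves the stem pool
untouched (asymmetric stem divisions).

Only the first ``K_sim`` compartments are tracked; cells differentiating out
of compartment ``K_sim`` are tallied as overflow.  One simulation time unit
is ``N0`` stem events, which for ``r0 = 1`` per year averages to one year,
so simulated times are reported directly in years.

The deterministic cascade is the exact expectation of this branching
process, so ensemble means converge to the analytic solutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CloneInit, CompartmentModel, derived_rates, validate_model

__all__ = [
    "SimPath",
    "EnsembleSummary",
    "ExtinctionSample",
    "InsufficientRealizationsWarning",
    "HorizonTooShortError",
    "simulate",
    "ensemble",
    "empirical_extinction_times",
]


class InsufficientRealizationsWarning(UserWarning):
    """Ensemble too small for a meaningful dispersion estimate."""


class HorizonTooShortError(RuntimeError):
    """Too many realizations still alive at the simulation horizon."""


@dataclass
class SimPath:
    """One realization sampled on a grid, plus event bookkeeping tallies."""

    times: np.ndarray
    counts: np.ndarray  # (n_times, K_sim) integers
    overflow: int  # cells differentiated beyond compartment K_sim
    deaths: int
    stem_events: int
    n_events: int
    seed: int
    event_log: pd.DataFrame | None = None


@dataclass
class EnsembleSummary:
    """Per-grid-point mean and standard deviation over realizations."""

    times: np.ndarray
    mean_counts: np.ndarray
    sd_counts: np.ndarray
    n_realizations: int
    master_seed: int

    def standard_error(self) -> np.ndarray:
        return self.sd_counts / np.sqrt(self.n_realizations)

    def to_frame(self) -> pd.DataFrame:
        n, K = self.mean_counts.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, K),
                "compartment": np.tile(np.arange(1, K + 1), n),
                "mean": self.mean_counts.ravel(),
                "sd": self.sd_counts.ravel(),
                "n": self.n_realizations,
            }
        )


@dataclass
class ExtinctionSample:
    """Empirical extinction times of one ensemble."""

    times: np.ndarray  # realizations where the clone colonized compartment k
    n_no_colonization: int  # runs where compartment k was never reached
    n_survivors: int  # runs still alive at the horizon (excluded)


def _rng_for_run(master_seed: int, run_index: int) -> np.random.Generator:
    """Independent, order-invariant stream per realization."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(run_index,))
    )


def _check_initial(initial_counts: np.ndarray, K_sim: int) -> np.ndarray:
    arr = np.asarray(initial_counts)
    if len(arr) != K_sim:
        raise ValueError(f"initial state length {len(arr)} != K_sim {K_sim}")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("initial cell counts must be non-negative integers")
    return np.round(arr).astype(np.int64)


def simulate(
    model: CompartmentModel,
    initial_counts,
    K_sim: int,
    horizon: float,
    seed: int,
    *,
    stem_flux: bool = True,
    sample_times=None,
    log_events: bool = False,
    run_index: int = 0,
) -> SimPath:
    """Run one Gillespie realization up to ``horizon`` years.

    ``sample_times`` defaults to 50 evenly spaced points on [0, horizon].
    The RNG stream is derived from ``(seed, run_index)``, so ensembles can
    hand out independent, order-invariant streams per realization.
    """
    validate_model(model)
    if not 1 <= K_sim <= model.n_compartments:
        raise ValueError(f"K_sim {K_sim} outside 1..{model.n_compartments}")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rr = derived_rates(model)
    if stem_flux and model.influx_factor != int(model.influx_factor):
        raise ValueError(
            "the simulator requires an integer influx_factor (cells per stem event)"
        )
    influx = int(model.influx_factor)
    n = _check_initial(initial_counts, K_sim)
    rates = model.rates[:K_sim]
    eps = model.diff_prob[:K_sim]
    death = model.death_prob[:K_sim]
    stem_propensity = model.stem_rate * model.stem_count if stem_flux else 0.0

    grid = (
        np.linspace(0.0, horizon, 50)
        if sample_times is None
        else np.asarray(sample_times, dtype=float)
    )
    counts_out = np.zeros((len(grid), K_sim), dtype=np.int64)
    rng = _rng_for_run(seed, run_index)

    t = 0.0
    gi = 0  # next grid index to fill
    overflow = deaths = stem_events = n_events = 0
    log: list[tuple[float, int, str]] | None = [] if log_events else None

    while True:
        total = stem_propensity + float(rates @ n)
        if total <= 0.0:
            break
        dt = rng.exponential(1.0 / total)
        if t + dt > horizon:
            break
        t += dt
        while gi < len(grid) and grid[gi] < t:
            counts_out[gi] = n
            gi += 1
        u = rng.uniform(0.0, total)
        n_events += 1
        if u < stem_propensity:
            n[0] += influx
            stem_events += 1
            if log is not None:
                log.append((t, 0, "stem_influx"))
            continue
        u -= stem_propensity
        k = int(np.searchsorted(np.cumsum(rates * n), u, side="right"))
        v = rng.uniform()
        if v < eps[k]:
            n[k] -= 1
            if k + 1 < K_sim:
                n[k + 1] += 2
                kind = "differentiation"
            else:
                overflow += 2
                kind = "differentiation_overflow"
        elif v < eps[k] + death[k]:
            n[k] -= 1
            deaths += 1
            kind = "death"
        else:
            n[k] += 1
            kind = "self_renewal"
        if log is not None:
            log.append((t, k + 1, kind))

    counts_out[gi:] = n  # state is constant after the last event
    event_log = (
        pd.DataFrame(log, columns=["time", "compartment", "event_type"])
        if log is not None
        else None
    )
    return SimPath(
        times=grid,
        counts=counts_out,
        overflow=overflow,
        deaths=deaths,
        stem_events=stem_events,
        n_events=n_events,
        seed=seed,
        event_log=event_log,
    )


def _clone_initial(clone: CloneInit, K_sim: int) -> np.ndarray:
    init = np.zeros(K_sim, dtype=np.int64)
    if clone.origin >= 1:
        if clone.origin > K_sim:
            raise ValueError(f"clone origin {clone.origin} beyond K_sim {K_sim}")
        init[clone.origin - 1] = int(round(clone.initial_count))
    return init


def ensemble(
    model: CompartmentModel,
    clone: CloneInit,
    K_sim: int,
    grid,
    n_runs: int,
    seed: int,
) -> EnsembleSummary:
    """Mean/SD summary over ``n_runs`` independent realizations.

    ``clone.origin == 0`` simulates stem-driven filling (stem flux on, empty
    start); ``origin >= 1`` simulates a mutant clone without stem support.
    Each realization uses an RNG stream derived from ``(seed, run_index)``,
    so the summary is reproducible and independent of execution order.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if n_runs < 2:
        warnings.warn(
            "insufficient realizations for a dispersion estimate; SD reported as 0",
            InsufficientRealizationsWarning,
            stacklevel=2,
        )
    grid = np.asarray(grid, dtype=float)
    stem_flux = clone.origin == 0
    init = _clone_initial(clone, K_sim)
    total = np.zeros((len(grid), K_sim))
    total_sq = np.zeros((len(grid), K_sim))
    for i in range(n_runs):
        path = _run_indexed(model, init, K_sim, grid, seed, i, stem_flux)
        total += path
        total_sq += path.astype(float) ** 2
    mean = total / n_runs
    var = np.maximum(total_sq / n_runs - mean**2, 0.0)
    sd = np.sqrt(var) if n_runs > 1 else np.zeros_like(mean)
    return EnsembleSummary(
        times=grid,
        mean_counts=mean,
        sd_counts=sd,
        n_realizations=n_runs,
        master_seed=seed,
    )


def _run_indexed(model, init, K_sim, grid, master_seed, run_index, stem_flux):
    """Single realization on the (master_seed, run_index) stream; grid counts."""
    path = simulate(
        model,
        init,
        K_sim,
        horizon=float(grid[-1]) + 1e-12,
        seed=master_seed,
        stem_flux=stem_flux,
        sample_times=grid,
        run_index=run_index,
    )
    return path.counts


def empirical_extinction_times(
    model: CompartmentModel,
    clone: CloneInit,
    k: int,
    K_sim: int,
    n_runs: int,
    seed: int,
    horizon: float = 200.0,
) -> ExtinctionSample:
    """Per-realization time at which the last clone cell leaves compartment ``k``.

    Extinction is scored as the moment the compartment-``k`` count reaches 0
    while no cells remain upstream (so recolonization is impossible), which
    matches the washout semantics of the deterministic model.  Runs where the
    clone never colonizes compartment ``k`` are reported separately.  If more
    than 1% of runs are still alive at ``horizon`` the sample is biased and
    :class:`HorizonTooShortError` is raised.
    """
    validate_model(model)
    clone.validate(model.n_compartments)
    c = clone.origin
    if c < 1:
        raise ValueError("empirical extinction is defined for non-stem clones")
    if not c <= k <= K_sim <= model.n_compartments:
        raise ValueError(f"need origin {c} <= k {k} <= K_sim {K_sim} <= K")
    rr = derived_rates(model)
    if np.any(rr.gamma[c - 1 : K_sim] <= 0):
        raise ValueError("washout regime requires gamma > 0 in compartments c..K_sim")
    rates = model.rates[:K_sim]
    eps = model.diff_prob[:K_sim]
    death = model.death_prob[:K_sim]
    times: list[float] = []
    no_colonization = 0
    survivors = 0
    for i in range(n_runs):
        rng = _rng_for_run(seed, i)
        n = _clone_initial(clone, K_sim)
        t = 0.0
        colonized = n[k - 1] > 0
        extinction = t if colonized else None
        while True:
            total = float(rates @ n)
            if total <= 0.0:
                break
            t += rng.exponential(1.0 / total)
            if t > horizon:
                survivors += 1
                extinction = None
                colonized = True  # counted as survivor, not as no-colonization
                break
            u = rng.uniform(0.0, total)
            j = int(np.searchsorted(np.cumsum(rates * n), u, side="right"))
            v = rng.uniform()
            if v < eps[j]:
                n[j] -= 1
                if j + 1 < K_sim:
                    n[j + 1] += 2
            elif v < eps[j] + death[j]:
                n[j] -= 1
            else:
                n[j] += 1
            if n[k - 1] > 0:
                colonized = True
            if colonized and n[k - 1] == 0 and n[: k - 1].sum() == 0:
                extinction = t
                break
        if not colonized:
            no_colonization += 1
        elif extinction is not None:
            times.append(extinction)
    if survivors > 0.01 * n_runs:
        raise HorizonTooShortError(
            f"{survivors}/{n_runs} runs still alive at horizon {horizon:g} years"
        )
    return ExtinctionSample(
        times=np.asarray(times),
        n_no_colonization=no_colonization,
        n_survivors=survivors,
    )
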