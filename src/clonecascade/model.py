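"""Parameter containers and basic algebra of the hierarchical compartment model.

The tissue is modelled as a chain of compartments: compartment 0 is a
stem-cell pool of constant size ``N0`` whose cells divide asymmetrically at
rate ``r0``, exporting cells into compartment 1.  Each downstream compartment
``k`` (1-based, ``k = 1..K``) holds cells that divide at rate ``r_k``; a
division differentiates both daughters into compartment ``k+1`` with
probability ``eps_k``, kills the cell with probability ``d_k``, and
self-renews (two daughters stay in ``k``) otherwise.

The mean-field dynamics are a linear cascade

    dN_1/dt = phi - b_1 N_1
    dN_k/dt = a_k N_{k-1} - b_k N_k        (k >= 2)

with net-loss parameter ``gamma_k = 2 (eps_k + d_k) - 1``, decay coefficient
``b_k = gamma_k r_k``, inflow coefficient ``a_k = 2 eps_{k-1} r_{k-1}`` and
stem flux ``phi = influx_factor * r0 * N0``.  ``gamma_k > 0`` means the
compartment loses cells on balance and needs upstream influx to persist.

All rates are per year; times are in years throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CompartmentModel",
    "DerivedRates",
    "CloneInit",
    "Trajectory",
    "ModelValidationError",
    "NoEquilibriumError",
    "validate_model",
    "derived_rates",
    "equilibrium",
]


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant.

    The message lists *every* violated invariant, with compartment indices.
    """


class NoEquilibriumError(ValueError):
    """Raised when a homeostatic equilibrium does not exist (some gamma_k <= 0)."""


@dataclass(frozen=True)
class CompartmentModel:
    """Full parameterization of the differentiation hierarchy.

    Parameters
    ----------
    rates
        Division rates ``r_1..r_K`` (divisions per cell per year).
    diff_prob
        Symmetric-differentiation probabilities ``eps_1..eps_K``.
    death_prob
        Death probabilities ``d_1..d_K``.
    stem_count
        Constant stem-cell pool size ``N0``.
    stem_rate
        Stem-cell division rate ``r0`` (per cell per year).
    influx_factor
        Cells exported to compartment 1 per stem division.  The default 1
        corresponds to strictly asymmetric stem divisions; 2*eps0 would model
        a symmetrically differentiating stem pool.
    """

    rates: np.ndarray
    diff_prob: np.ndarray
    death_prob: np.ndarray
    stem_count: float
    stem_rate: float
    influx_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rates", "diff_prob", "death_prob"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))

    @property
    def n_compartments(self) -> int:
        """Number of non-stem compartments K."""
        return len(self.rates)

    K = n_compartments

    @classmethod
    def constant(
        cls,
        n_compartments: int,
        *,
        eps: float,
        d: float = 0.0,
        r1: float = 1.0,
        rate_ratio: float = 1.0,
        stem_count: float = 1.0,
        stem_rate: float = 1.0,
        influx_factor: float = 1.0,
    ) -> "CompartmentModel":
        """Constant-parameter family: ``eps_k = eps``, ``d_k = d`` and a
        geometrically increasing division rate ``r_k = r1 * rate_ratio**(k-1)``."""
        k = np.arange(n_compartments)
        return cls(
            rates=r1 * rate_ratio**k,
            diff_prob=np.full(n_compartments, float(eps)),
            death_prob=np.full(n_compartments, float(d)),
            stem_count=float(stem_count),
            stem_rate=float(stem_rate),
            influx_factor=float(influx_factor),
        )

    def with_(self, **kwargs) -> "CompartmentModel":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def truncated(self, n_compartments: int) -> "CompartmentModel":
        """Keep only the first ``n_compartments`` downstream compartments."""
        if not 1 <= n_compartments <= self.n_compartments:
            raise ValueError(f"cannot truncate K={self.n_compartments} model to {n_compartments}")
        return replace(
            self,
            rates=self.rates[:n_compartments],
            diff_prob=self.diff_prob[:n_compartments],
            death_prob=self.death_prob[:n_compartments],
        )


@dataclass(frozen=True)
class DerivedRates:
    """Coefficients of the linear cascade derived from a :class:`CompartmentModel`.

    ``gamma``, ``decay`` (b) and ``inflow`` (a) are arrays of length K indexed
    by compartment - 1; ``inflow[0]`` is 0 by convention (compartment 1 is fed
    by the stem flux ``phi``, not by an upstream compartment).
    """

    gamma: np.ndarray
    decay: np.ndarray
    inflow: np.ndarray
    stem_flux: float

    def b(self, k: int) -> float:
        """Decay coefficient b_k (1-based compartment index)."""
        return float(self.decay[k - 1])

    def a(self, k: int) -> float:
        """Inflow coefficient a_k (1-based, k >= 2)."""
        if k < 2:
            raise IndexError("inflow coefficient a_k is defined for k >= 2")
        return float(self.inflow[k - 1])


@dataclass(frozen=True)
class CloneInit:
    """Initial condition of a clone.

    ``origin = 0`` is the stem-driven case (all non-stem compartments start
    empty and are filled by the constant stem flux); ``origin = c >= 1`` is a
    mutant arising as ``initial_count`` cells in compartment ``c`` with no
    stem-cell support.
    """

    origin: int
    initial_count: float = 1.0

    def validate(self, n_compartments: int) -> "CloneInit":
        if not 0 <= self.origin <= n_compartments:
            raise ValueError(
                f"clone origin {self.origin} outside 0..{n_compartments}"
            )
        if self.initial_count <= 0:
            raise ValueError("initial_count must be positive")
        return self


@dataclass
class Trajectory:
    """Deterministic average cell counts on a time grid.

    ``counts[i, k-1]`` is the average number of cells in compartment ``k`` at
    ``times[i]``.  Counts are means of the underlying branching process, so
    fractional values are expected.
    """

    times: np.ndarray
    counts: np.ndarray
    scenario: str = "trajectory"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if self.counts.shape[0] != len(self.times):
            raise ValueError("counts must have one row per time point")

    @property
    def n_compartments(self) -> int:
        return self.counts.shape[1]

    def compartment(self, k: int) -> np.ndarray:
        """Counts of compartment ``k`` (1-based) over the grid."""
        return self.counts[:, k - 1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: time, compartment, count, scenario."""
        n, K = self.counts.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, K),
                "compartment": np.tile(np.arange(1, K + 1), n),
                "count": self.counts.ravel(),
                "scenario": self.scenario,
            }
        )


def validate_model(model: CompartmentModel) -> CompartmentModel:
    """Check every structural invariant, collecting all violations.

    Returns the model unchanged when valid; raises
    :class:`ModelValidationError` whose message lists each violation with the
    offending compartment index.
    """
    problems: list[str] = []
    K = model.n_compartments
    if K < 1:
        problems.append("model must have at least one non-stem compartment (K >= 1)")
    if not (len(model.diff_prob) == len(model.death_prob) == K):
        problems.append(
            f"rates/diff_prob/death_prob lengths differ: "
            f"{K}/{len(model.diff_prob)}/{len(model.death_prob)}"
        )
    else:
        for k in range(1, K + 1):
            r, e, d = model.rates[k - 1], model.diff_prob[k - 1], model.death_prob[k - 1]
            if not r > 0:
                problems.append(f"non-positive rate r={r:g} in compartment {k}")
            if not 0.0 <= e <= 1.0:
                problems.append(f"eps={e:g} outside [0,1] in compartment {k}")
            if not 0.0 <= d <= 1.0:
                problems.append(f"d={d:g} outside [0,1] in compartment {k}")
            if e + d > 1.0 + 1e-15:
                problems.append(f"eps+d>1 in compartment {k} (eps={e:g}, d={d:g})")
    if not model.stem_rate > 0:
        problems.append(f"non-positive stem rate r0={model.stem_rate:g}")
    if not model.stem_count >= 1:
        problems.append(f"stem count N0={model.stem_count:g} must be >= 1")
    if model.influx_factor < 0:
        problems.append(f"negative influx factor {model.influx_factor:g}")
    if problems:
        raise ModelValidationError("; ".join(problems))
    return model


def derived_rates(model: CompartmentModel) -> DerivedRates:
    """Net-loss gamma_k, decay b_k, inflow a_k and stem flux phi."""
    validate_model(model)
    gamma = 2.0 * (model.diff_prob + model.death_prob) - 1.0
    decay = gamma * model.rates
    inflow = np.zeros(model.n_compartments)
    inflow[1:] = 2.0 * model.diff_prob[:-1] * model.rates[:-1]
    phi = model.influx_factor * model.stem_rate * model.stem_count
    return DerivedRates(gamma=gamma, decay=decay, inflow=inflow, stem_flux=phi)


def equilibrium(model: CompartmentModel) -> np.ndarray:
    """Homeostatic steady state of the stem-driven cascade.

    ``N*_1 = phi / b_1`` and ``N*_k = a_k N*_{k-1} / b_k`` for ``k >= 2``.
    Requires every ``gamma_k > 0``: a compartment that does not lose cells on
    balance cannot settle at a finite occupancy under constant influx.
    """
    rr = derived_rates(model)
    nonpos = np.flatnonzero(rr.gamma <= 0)
    if len(nonpos):
        raise NoEquilibriumError(
            "no homeostatic equilibrium: gamma <= 0 in compartment "
            f"{nonpos[0] + 1} (gamma={rr.gamma[nonpos[0]]:g})"
        )
    nstar = np.empty(model.n_compartments)
    nstar[0] = rr.stem_flux / rr.decay[0]
    for k in range(1, model.n_compartments):
        nstar[k] = rr.inflow[k] * nstar[k - 1] / rr.decay[k]
    return nstar
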