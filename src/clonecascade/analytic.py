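"""Closed-form solutions of the compartment cascade.

Because the cascade is a linear chain, every compartment's mean count is a
hypoexponential (Bateman-type) expression

    N_k(t) = N_inf + sum_j A_j exp(-b_j t)

with one decay rate per upstream compartment and partial-fraction amplitudes

    A_j = (prefactor * prod_i a_i) / prod_{i != j} (b_i - b_j).

Three clone families are covered:

* stem-driven filling: constant stem flux phi into an initially empty
  hierarchy; N_inf is the homeostatic equilibrium and the transient decays
  at rates b_1..b_k,
* a mutant founder in a downstream compartment c (homogeneous system): the
  clone rises by differentiation pressure, peaks, and is washed out whenever
  every gamma_j > 0,
* a "stem-like" mutant with gamma_c = 0 exactly: compartment c keeps its
  founder count forever and plays the role of a private stem pool for the
  compartments below it (the solution is the stem-driven one with indices
  shifted by c).

Amplitudes alternate in sign and can cancel catastrophically for deep
compartments, so they are kept as (sign, log magnitude) pairs; whenever the
floating-point sum loses more than ``CANCEL_DIGITS`` decimal digits the term
is re-evaluated in arbitrary-precision arithmetic directly from the rate
coefficients.  Exactly coincident decay rates (confluent case, terms of the
form t*exp(-bt)) are not representable in this basis; such solutions are
flagged and evaluated through the ODE integrator instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import mpmath
import numpy as np
from scipy.optimize import brentq

from .model import CloneInit, CompartmentModel, derived_rates, equilibrium, validate_model

__all__ = [
    "ExponentialSum",
    "ExtinctionEstimate",
    "DecayRateResult",
    "ConfluentRatesWarning",
    "DecayRateTieWarning",
    "ThresholdNeverReachedError",
    "stem_driven_solution",
    "mutant_solution",
    "stationary_clone_solution",
    "long_run_decay_rate",
    "extinction_time",
]

# relative gap below which two decay rates are treated as coincident
CONFLUENCE_RTOL = 1e-9
# digits of cancellation tolerated on the fast floating-point path
CANCEL_DIGITS = 6
MP_DPS = 100
STATIONARY_GAMMA_ATOL = 1e-12


class ConfluentRatesWarning(UserWarning):
    """Two decay rates coincide; evaluation switched to the ODE oracle."""


class DecayRateTieWarning(UserWarning):
    """The slowest decay rate is not unique; asymptotics mix two exponentials."""


class ThresholdNeverReachedError(RuntimeError):
    """The clone's average count never reaches the extinction threshold."""


@dataclass
class ExtinctionEstimate:
    """An extinction time: when the average count in ``compartment`` drops
    below ``threshold`` cells for good."""

    compartment: int
    origin: int
    tau: float
    method: str
    threshold: float = 1.0


@dataclass
class DecayRateResult:
    """Slowest decay rate of a washed-out clone and where it lives."""

    rate: float
    compartment: int
    tied: bool


class ExponentialSum:
    """``constant + sum_j sign_j exp(log_amp_j - rate_j t)`` for one compartment.

    ``numerator`` holds the multiplicative factors of the shared amplitude
    numerator and ``per_term_divisor`` an optional extra per-term divisor
    (b_j itself, for the integrated stem-driven form); both are retained so
    the amplitudes can be rebuilt losslessly in arbitrary precision.
    """

    def __init__(
        self,
        *,
        constant_term: float,
        rates: np.ndarray,
        numerator: np.ndarray,
        global_sign: float = 1.0,
        per_term_divisor: np.ndarray | None = None,
        compartment: int,
        origin: int,
        oracle=None,
        confluent: bool = False,
    ) -> None:
        self.constant_term = float(constant_term)
        self.rates = np.asarray(rates, dtype=float)
        self.compartment = int(compartment)
        self.origin = int(origin)
        self.confluent = bool(confluent)
        self._numerator = np.asarray(numerator, dtype=float)
        self._global_sign = float(global_sign)
        self._per_term_divisor = (
            None if per_term_divisor is None else np.asarray(per_term_divisor, dtype=float)
        )
        self._oracle = oracle
        self._log_amps, self._signs = self._float_amplitudes()

    # -- amplitude construction -------------------------------------------------

    def _float_amplitudes(self) -> tuple[np.ndarray, np.ndarray]:
        m = len(self.rates)
        log_amps = np.full(m, -np.inf)
        signs = np.zeros(m)
        if m == 0 or self.confluent:
            return log_amps, signs
        log_num = np.sum(np.log(np.abs(self._numerator)))
        num_sign = np.prod(np.sign(self._numerator)) * self._global_sign
        for j in range(m):
            diffs = np.delete(self.rates, j) - self.rates[j]
            s = num_sign * (np.prod(np.sign(diffs)) if len(diffs) else 1.0)
            la = log_num - (np.sum(np.log(np.abs(diffs))) if len(diffs) else 0.0)
            if self._per_term_divisor is not None:
                la -= np.log(np.abs(self._per_term_divisor[j]))
                s *= np.sign(self._per_term_divisor[j])
            log_amps[j] = la
            signs[j] = s
        return log_amps, signs

    def _mp_amplitudes(self):
        if getattr(self, "_mp_amp_cache", None) is not None:
            return self._mp_amp_cache
        num = mpmath.mpf(1)
        for f in self._numerator:
            num *= mpmath.mpf(f)
        num *= self._global_sign
        amps = []
        for j, bj in enumerate(self.rates):
            den = mpmath.mpf(1)
            for i, bi in enumerate(self.rates):
                if i != j:
                    den *= mpmath.mpf(bi) - mpmath.mpf(bj)
            if self._per_term_divisor is not None:
                den *= mpmath.mpf(self._per_term_divisor[j])
            amps.append(num / den)
        self._mp_amp_cache = amps
        return amps

    @property
    def amplitudes(self) -> np.ndarray:
        """Signed amplitudes A_j (may overflow to inf for deep hierarchies;
        use :attr:`log_amplitudes` for audit in that case)."""
        with np.errstate(over="ignore"):
            return self._signs * np.exp(self._log_amps)

    @property
    def log_amplitudes(self) -> np.ndarray:
        return self._log_amps.copy()

    @property
    def signs(self) -> np.ndarray:
        return self._signs.copy()

    def terms(self) -> list[tuple[float, float]]:
        """(amplitude, decay rate) pairs for export."""
        return list(zip(self.amplitudes, self.rates))

    # -- evaluation --------------------------------------------------------------

    def _mp_value(self, t: float, derivative: bool = False) -> float:
        with mpmath.workdps(MP_DPS):
            amps = self._mp_amplitudes()
            total = mpmath.mpf(0) if derivative else mpmath.mpf(self.constant_term)
            for a, b in zip(amps, self.rates):
                term = a * mpmath.exp(-mpmath.mpf(b) * mpmath.mpf(t))
                if derivative:
                    term *= -mpmath.mpf(b)
                total += term
            return float(total)

    def _evaluate(self, t: np.ndarray, derivative: bool) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        tt = np.atleast_1d(t)
        if self.confluent:
            out = self._oracle(tt, derivative)
            return float(out[0]) if scalar else out
        if len(self.rates) == 0:
            base = 0.0 if derivative else self.constant_term
            out = np.full(tt.shape, base)
            return float(out[0]) if scalar else out
        # term logs, with the constant folded in as a zero-rate term so that
        # the cancellation estimate sees the full sum
        logs = self._log_amps[None, :] - self.rates[None, :] * tt[:, None]
        signs = np.tile(self._signs, (len(tt), 1))
        if derivative:
            logs = logs + np.log(np.abs(self.rates))[None, :]
            signs = -signs * np.sign(self.rates)[None, :]
        elif self.constant_term != 0.0:
            logs = np.concatenate(
                [logs, np.full((len(tt), 1), np.log(abs(self.constant_term)))], axis=1
            )
            signs = np.concatenate(
                [signs, np.full((len(tt), 1), np.sign(self.constant_term))], axis=1
            )
        m = logs.max(axis=1, keepdims=True)
        scaled = np.exp(logs - m) * signs
        total = scaled.sum(axis=1)
        gross = np.abs(scaled).sum(axis=1)
        out = total * np.exp(m[:, 0])
        bad = np.abs(total) < 10.0**-CANCEL_DIGITS * gross
        for i in np.flatnonzero(bad):
            out[i] = self._mp_value(tt[i], derivative=derivative)
        return float(out[0]) if scalar else out

    def value(self, t) -> float | np.ndarray:
        """Average cell count at time(s) ``t`` (years)."""
        return self._evaluate(t, derivative=False)

    __call__ = value

    def derivative(self, t) -> float | np.ndarray:
        """Time derivative of the average count at ``t``."""
        return self._evaluate(t, derivative=True)

    # -- shape helpers -----------------------------------------------------------

    @property
    def slowest_rate_index(self) -> int:
        return int(np.argmin(self.rates))

    def time_of_maximum(self) -> float:
        """Location of the interior maximum, found from the sign pattern of the
        analytic derivative (0.0 for monotone-decaying sums)."""
        if len(self.rates) == 0:
            return 0.0
        bmin = float(np.min(np.abs(self.rates)))
        grid = np.geomspace(1e-8 / bmin, 50.0 / bmin, 240)
        dsign = np.sign(self.derivative(grid))
        pos = np.flatnonzero(dsign > 0)
        if len(pos) == 0:
            return 0.0  # monotone decaying from t=0
        neg_after = np.flatnonzero((np.arange(len(grid)) > pos[-1]) & (dsign < 0))
        if len(neg_after) == 0:
            raise RuntimeError(
                "derivative never turns negative: trajectory has no interior "
                "maximum in the search window"
            )
        lo, hi = grid[pos[-1]], grid[neg_after[0]]
        return brentq(self.derivative, lo, hi, xtol=1e-14, rtol=8.9e-16)

    def last_crossing(self, level: float) -> float:
        """Last time the sum crosses below ``level`` (bracketed after the maximum)."""
        tmax = self.time_of_maximum()
        if self.value(tmax) <= level:
            raise ThresholdNeverReachedError(
                f"maximum {self.value(tmax):g} never reaches level {level:g} "
                f"in compartment {self.compartment}"
            )
        bmin = float(np.min(np.abs(self.rates)))
        hi = tmax + 20.0 / bmin
        for _ in range(200):
            if self.value(hi) < level:
                break
            hi *= 2.0
        else:
            raise ThresholdNeverReachedError("no down-crossing found in search window")
        return brentq(lambda t: self.value(t) - level, tmax, hi, xtol=1e-12, rtol=8.9e-16)

    def first_crossing(self, level: float) -> float:
        """First up-crossing of ``level`` on the rising branch."""
        tmax = self.time_of_maximum()
        if self.value(tmax) <= level:
            raise ThresholdNeverReachedError(
                f"maximum {self.value(tmax):g} never reaches level {level:g}"
            )
        if self.value(0.0) >= level:
            return 0.0
        return brentq(lambda t: self.value(t) - level, 0.0, tmax, xtol=1e-12, rtol=8.9e-16)


# -- constructors ----------------------------------------------------------------


def _confluent(rates: np.ndarray) -> bool:
    if len(rates) < 2:
        return False
    sorted_r = np.sort(rates)
    return bool(np.min(np.diff(sorted_r)) < CONFLUENCE_RTOL * np.max(np.abs(rates)))


def _ode_oracle(model: CompartmentModel, initial: np.ndarray, stem_flux: bool, k: int):
    """Lazy ODE-based evaluator used when decay rates are confluent."""

    def evaluate(tt: np.ndarray, derivative: bool) -> np.ndarray:
        from .ode import OdeProblem, cascade_matrix, integrate
        from .model import derived_rates as _dr

        uniq, inverse = np.unique(tt, return_inverse=True)
        prepended = uniq[0] > 0.0
        grid = np.concatenate([[0.0], uniq]) if prepended else uniq
        traj = integrate(OdeProblem(model, initial, stem_flux, grid))
        counts = (traj.counts[1:] if prepended else traj.counts)[inverse]
        if not derivative:
            return counts[:, k - 1]
        A = cascade_matrix(model)
        phi = _dr(model).stem_flux if stem_flux else 0.0
        deriv = counts @ A.T
        deriv[:, 0] += phi
        return deriv[:, k - 1]

    return evaluate


def stem_driven_solution(model: CompartmentModel, k: int) -> ExponentialSum:
    """Filling of compartment ``k`` from empty initial conditions under the
    constant stem flux phi.

    The constant term is the homeostatic equilibrium N*_k (when every
    gamma_j > 0); the transient carries decay rates b_1..b_k with amplitudes
    -phi * prod(a) / (b_j * prod_{i != j}(b_i - b_j)).
    """
    validate_model(model)
    if not 1 <= k <= model.n_compartments:
        raise ValueError(f"compartment {k} outside 1..{model.n_compartments}")
    rr = derived_rates(model)
    b = rr.decay[:k]
    if np.any(b == 0.0):
        raise ValueError(
            "gamma=0 compartment upstream: no pure-exponential stem-driven form; "
            "use the ODE oracle or stationary_clone_solution"
        )
    numerator = np.concatenate([[rr.stem_flux], rr.inflow[1:k]])
    constant = float(np.prod(np.sign(numerator)) * np.prod(np.sign(b))) * np.exp(
        np.sum(np.log(np.abs(numerator))) - np.sum(np.log(np.abs(b)))
    )
    if _confluent(b):
        warnings.warn(
            f"confluent decay rates among b_1..b_{k}; evaluating via ODE oracle",
            ConfluentRatesWarning,
            stacklevel=2,
        )
        init = np.zeros(model.n_compartments)
        return ExponentialSum(
            constant_term=constant,
            rates=b,
            numerator=numerator,
            global_sign=-1.0,
            per_term_divisor=b,
            compartment=k,
            origin=0,
            oracle=_ode_oracle(model, init, True, k),
            confluent=True,
        )
    return ExponentialSum(
        constant_term=constant,
        rates=b,
        numerator=numerator,
        global_sign=-1.0,
        per_term_divisor=b,
        compartment=k,
        origin=0,
    )


def mutant_solution(model: CompartmentModel, clone: CloneInit, k: int) -> ExponentialSum:
    """Average count in compartment ``k`` of a clone founded by
    ``clone.initial_count`` cells in compartment ``c = clone.origin`` with no
    stem-cell support (homogeneous cascade).

    For ``k < c`` the clone never appears (no upstream flow): the zero
    function is returned.  For ``k >= c`` the solution carries rates
    b_c..b_k with amplitudes
    initial_count * prod(a_{c+1}..a_k) / prod_{i != j}(b_i - b_j).
    """
    validate_model(model)
    clone.validate(model.n_compartments)
    c = clone.origin
    if c < 1:
        raise ValueError("mutant_solution needs a non-stem origin (c >= 1); "
                         "use stem_driven_solution for stem-driven clones")
    if not 1 <= k <= model.n_compartments:
        raise ValueError(f"compartment {k} outside 1..{model.n_compartments}")
    if k < c:
        return ExponentialSum(
            constant_term=0.0, rates=np.empty(0), numerator=np.empty(0),
            compartment=k, origin=c,
        )
    rr = derived_rates(model)
    b = rr.decay[c - 1 : k]
    numerator = np.concatenate([[clone.initial_count], rr.inflow[c:k]])
    if _confluent(b):
        warnings.warn(
            f"confluent decay rates among b_{c}..b_{k}; evaluating via ODE oracle",
            ConfluentRatesWarning,
            stacklevel=2,
        )
        init = np.zeros(model.n_compartments)
        init[c - 1] = clone.initial_count
        return ExponentialSum(
            constant_term=0.0,
            rates=b,
            numerator=numerator,
            compartment=k,
            origin=c,
            oracle=_ode_oracle(model, init, False, k),
            confluent=True,
        )
    return ExponentialSum(
        constant_term=0.0, rates=b, numerator=numerator, compartment=k, origin=c
    )


def stationary_clone_solution(
    model: CompartmentModel, clone: CloneInit, k: int
) -> ExponentialSum:
    """Clone whose origin compartment has gamma_c = 0 exactly (self-renewal
    exactly balances loss): compartment c holds its founder count forever and
    feeds the compartments below like a private stem pool.

    The downstream time course is the stem-driven solution with indices
    shifted by c and effective flux a_{c+1} * initial_count; the fixed point
    is initial_count * prod_{j=c+1..k} (a_j / b_j).
    """
    validate_model(model)
    clone.validate(model.n_compartments)
    c = clone.origin
    if c < 1:
        raise ValueError("stationary clone needs a non-stem origin")
    rr = derived_rates(model)
    if abs(rr.gamma[c - 1]) > STATIONARY_GAMMA_ATOL:
        raise ValueError(
            f"gamma_c must be 0 for a stationary clone; compartment {c} has "
            f"gamma={rr.gamma[c - 1]:g}"
        )
    if not c <= k <= model.n_compartments:
        raise ValueError(f"compartment {k} outside {c}..{model.n_compartments}")
    if k == c:
        return ExponentialSum(
            constant_term=clone.initial_count, rates=np.empty(0),
            numerator=np.empty(0), compartment=k, origin=c,
        )
    if np.any(rr.gamma[c:k] <= 0):
        raise ValueError("stationary fixed point needs gamma_j > 0 downstream of c")
    b = rr.decay[c:k]
    phi_eff = rr.inflow[c] * clone.initial_count
    numerator = np.concatenate([[phi_eff], rr.inflow[c + 1 : k]])
    constant = float(np.exp(np.sum(np.log(numerator)) - np.sum(np.log(b))))
    if _confluent(b):
        warnings.warn(
            f"confluent decay rates among b_{c + 1}..b_{k}; evaluating via ODE oracle",
            ConfluentRatesWarning,
            stacklevel=2,
        )
        init = np.zeros(model.n_compartments)
        init[c - 1] = clone.initial_count
        return ExponentialSum(
            constant_term=constant, rates=b, numerator=numerator,
            global_sign=-1.0, per_term_divisor=b, compartment=k, origin=c,
            oracle=_ode_oracle(model, init, False, k), confluent=True,
        )
    return ExponentialSum(
        constant_term=constant, rates=b, numerator=numerator,
        global_sign=-1.0, per_term_divisor=b, compartment=k, origin=c,
    )


def long_run_decay_rate(model: CompartmentModel, clone: CloneInit) -> DecayRateResult:
    """Rate of the slowest decaying exponential of a washed-out clone.

    This is min_j b_j over j >= c; in the common situation of constant eps
    and increasing rates the minimum sits at the origin and equals
    gamma_c * r_c.  A tie (within relative tolerance) is flagged because the
    long-run asymptotics then mix two exponentials.
    """
    validate_model(model)
    clone.validate(model.n_compartments)
    c = clone.origin
    if c < 1:
        raise ValueError("long-run decay rate is defined for non-stem clones")
    rr = derived_rates(model)
    if np.any(rr.gamma[c - 1 :] <= 0):
        j = c + int(np.flatnonzero(rr.gamma[c - 1 :] <= 0)[0])
        raise ValueError(f"clone is not washed out: gamma <= 0 in compartment {j}")
    b = rr.decay[c - 1 :]
    jmin = int(np.argmin(b))
    gaps = np.abs(np.delete(b, jmin) - b[jmin])
    tied = bool(len(gaps)) and bool(np.min(gaps) < CONFLUENCE_RTOL * np.max(b))
    if tied:
        warnings.warn(
            "slowest decay rate is not unique; long-run asymptotics mix "
            "two exponentials",
            DecayRateTieWarning,
            stacklevel=2,
        )
    return DecayRateResult(rate=float(b[jmin]), compartment=c + jmin, tied=tied)


def extinction_time(
    model: CompartmentModel,
    clone: CloneInit,
    k: int,
    method: str = "asymptotic",
    threshold: float = 1.0,
) -> ExtinctionEstimate:
    """Time until the average clone count in compartment ``k`` drops below
    ``threshold`` cells (default 1).

    ``method="asymptotic"`` solves A_min exp(-b_min tau) = threshold using
    only the slowest term of the mutant solution and requires ``k > c`` (at
    the origin itself the slowest-term amplitude does not dominate early
    enough for the approximation to be meaningful).  ``method="root_finding"``
    brackets the last threshold crossing of the full exponential sum after
    the trajectory maximum, and is the exact deterministic answer.
    """
    sol = mutant_solution(model, clone, k)
    c = clone.origin
    if method == "asymptotic":
        if k <= c:
            raise ValueError(
                "asymptotic extinction time needs k > c; the compartment of "
                "origin requires root_finding or simulation"
            )
        j = sol.slowest_rate_index
        if sol.signs[j] <= 0:
            raise ThresholdNeverReachedError(
                "slowest term has non-positive amplitude; asymptote approaches "
                "zero from below"
            )
        tau = (sol.log_amplitudes[j] - np.log(threshold)) / sol.rates[j]
        if tau <= 0:
            raise ThresholdNeverReachedError(
                f"slowest-term amplitude {np.exp(sol.log_amplitudes[j]):g} is "
                f"below threshold {threshold:g}"
            )
        return ExtinctionEstimate(k, c, float(tau), "asymptotic", threshold)
    if method == "root_finding":
        tau = sol.last_crossing(threshold)
        return ExtinctionEstimate(k, c, float(tau), "root_finding", threshold)
    raise ValueError(f"unknown method {method!r}; use 'asymptotic' or 'root_finding'")
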