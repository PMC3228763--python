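"""Direct numerical integration of the compartment cascade.

This is the ground-truth evaluation path: a straightforward adaptive
integration of the linear system

    dN_1/dt = phi * [stem flux on] - b_1 N_1
    dN_k/dt = a_k N_{k-1} - b_k N_k

used to cross-check every closed-form solution and as the fallback when the
closed forms degenerate (confluent decay rates).  The system is linear with a
constant (lower-bidiagonal) matrix, so the exact Jacobian is supplied and
LSODA handles the wide rate spread of deep hierarchies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model import CompartmentModel, Trajectory, derived_rates, validate_model

__all__ = ["OdeProblem", "integrate", "superpose", "cascade_matrix", "IntegrationError"]

RTOL = 1e-10
ATOL = 1e-12


class IntegrationError(RuntimeError):
    """Integrator failure or a trajectory that went meaningfully negative."""


@dataclass
class OdeProblem:
    """An initial-value problem on the cascade.

    ``include_stem_flux=True`` gives the inhomogeneous (stem-driven) system
    with constant influx phi into compartment 1; ``False`` gives the
    homogeneous system obeyed by a mutant clone without stem support.
    """

    model: CompartmentModel
    initial_counts: np.ndarray
    include_stem_flux: bool
    time_grid: np.ndarray

    def __post_init__(self) -> None:
        validate_model(self.model)
        self.initial_counts = np.asarray(self.initial_counts, dtype=float)
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if len(self.initial_counts) != self.model.n_compartments:
            raise ValueError(
                f"initial_counts has length {len(self.initial_counts)}, "
                f"expected K={self.model.n_compartments}"
            )
        if len(self.time_grid) == 0:
            raise ValueError("empty time grid")
        if np.any(np.diff(self.time_grid) < 0):
            raise ValueError("time grid must be non-decreasing")
        if np.any(self.initial_counts < 0):
            raise ValueError("negative initial counts")


def cascade_matrix(model: CompartmentModel) -> np.ndarray:
    """The constant system matrix A with A[k,k] = -b_{k+1}, A[k,k-1] = a_{k+1}."""
    rr = derived_rates(model)
    K = model.n_compartments
    A = np.zeros((K, K))
    A[np.diag_indices(K)] = -rr.decay
    if K > 1:
        A[np.arange(1, K), np.arange(K - 1)] = rr.inflow[1:]
    return A


def integrate(problem: OdeProblem, rtol: float = RTOL, atol: float = ATOL) -> Trajectory:
    """Solve the cascade on the problem's time grid (rtol 1e-10, atol 1e-12 by
    default; pass tighter tolerances when the trajectory serves as an oracle).

    Values in (-atol*10, 0) arising from round-off are clamped to zero; larger
    negative excursions raise :class:`IntegrationError`.
    """
    A = cascade_matrix(problem.model)
    phi = derived_rates(problem.model).stem_flux if problem.include_stem_flux else 0.0
    forcing = np.zeros(problem.model.n_compartments)
    forcing[0] = phi

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return A @ y + forcing

    t0, t1 = problem.time_grid[0], problem.time_grid[-1]
    if t1 == t0:
        counts = np.tile(problem.initial_counts, (len(problem.time_grid), 1))
        return Trajectory(times=problem.time_grid.copy(), counts=counts)
    sol = solve_ivp(
        rhs,
        (t0, t1),
        problem.initial_counts,
        t_eval=problem.time_grid,
        method="LSODA",
        jac=lambda t, y: A,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"integrator failed: {sol.message}")
    counts = sol.y.T.copy()
    tiny = counts < 0
    if np.any(counts < -10 * max(atol, ATOL)):
        raise IntegrationError(
            f"trajectory went negative (min {counts.min():g}); "
            "this should not happen for non-negative initial conditions"
        )
    counts[tiny] = 0.0
    return Trajectory(times=problem.time_grid.copy(), counts=counts)


def superpose(traj_a: Trajectory, traj_b: Trajectory) -> Trajectory:
    """Pointwise sum of two trajectories on the same grid.

    By linearity this equals integrating the summed initial conditions, which
    is how co-occurring independent clones are combined.
    """
    if traj_a.counts.shape != traj_b.counts.shape or not np.array_equal(
        traj_a.times, traj_b.times
    ):
        raise ValueError("trajectories must share the same time grid and K")
    return Trajectory(
        times=traj_a.times.copy(),
        counts=traj_a.counts + traj_b.counts,
        scenario=f"{traj_a.scenario}+{traj_b.scenario}",
    )
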