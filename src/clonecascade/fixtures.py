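"""Programmatic fixture generation for tests and demos.

Everything is generated at run time: small valid and intentionally invalid
scenario configs, a hand-checkable 4-compartment toy model, random valid
models for property testing, and an ODE-integrated oracle table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import ScenarioConfig, save_config
from .model import CompartmentModel
from .ode import OdeProblem, integrate

__all__ = [
    "toy_model",
    "random_valid_model",
    "generate_fixtures",
    "INVALID_CONFIGS",
]

# each invalid config carries the diagnostic fragment its validation must emit
INVALID_CONFIGS = {
    "invalid_eps_plus_d.yaml": (
        {"model": {"K": 2, "eps": 0.9, "d": 0.2}},
        "eps+d>1 in compartment 1",
    ),
    "invalid_rate.yaml": (
        {"model": {"K": 2, "r1": 0.0}},
        "non-positive rate",
    ),
    "invalid_origin.yaml": (
        {"model": {"K": 2}, "clone": {"origin": 7}},
        "outside 0..2",
    ),
}


def toy_model(stem_count: float = 5.0) -> CompartmentModel:
    """4-compartment toy hierarchy with hand-checkable coefficients.

    eps=0.85, d=0 give gamma=0.7 everywhere; rates 1, 1.26, 1.26^2, 1.26^3
    give b = [0.7, 0.882, ...] and a = [-, 1.7, 2.142, ...].
    """
    return CompartmentModel.constant(
        4, eps=0.85, d=0.0, r1=1.0, rate_ratio=1.26, stem_count=stem_count
    )


def random_valid_model(
    rng: np.random.Generator,
    max_compartments: int = 8,
    washout_only: bool = True,
) -> CompartmentModel:
    """Random valid model with well-separated decay rates.

    ``washout_only`` keeps every gamma in (0.1, 1); otherwise gamma may dip
    negative in one compartment.  Rates are redrawn until all pairwise decay
    coefficients differ by at least 1e-3 relatively, so closed forms stay
    far from the confluent regime.
    """
    K = int(rng.integers(2, max_compartments + 1))
    for _ in range(100):
        if washout_only:
            gamma = rng.uniform(0.1, 0.98, size=K)
        else:
            gamma = rng.uniform(-0.3, 0.98, size=K)
        eps_plus_d = (gamma + 1.0) / 2.0
        death = rng.uniform(0.0, 0.3, size=K) * eps_plus_d
        eps = eps_plus_d - death
        rates = rng.uniform(0.3, 3.0, size=K)
        b = gamma * rates
        gaps = np.abs(b[:, None] - b[None, :])[np.triu_indices(K, 1)]
        if np.min(gaps) > 1e-3 * np.max(np.abs(b)) and np.all(np.abs(b) > 1e-3):
            break
    else:  # pragma: no cover - rejection loop essentially always succeeds
        raise RuntimeError("could not draw a well-separated model")
    return CompartmentModel(
        rates=rates,
        diff_prob=eps,
        death_prob=death,
        stem_count=float(rng.integers(1, 50)),
        stem_rate=float(rng.uniform(0.5, 2.0)),
    )


def generate_fixtures(seed: int, out_dir) -> list[Path]:
    """Write fixture files (configs + ODE oracle table) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    valid = ScenarioConfig(
        model={"K": 4, "N0": 5.0, "eps": 0.85, "d": 0.0, "r1": 1.0, "rate_ratio": 1.26},
        clone={"origin": 1, "initial_count": 1.0},
        run={"horizon": 5.0, "seed": int(seed), "K_sim": 4},
    )
    path = out / "toy_valid.yaml"
    save_config(valid, path)
    written.append(path)

    for name, (payload, _diagnostic) in INVALID_CONFIGS.items():
        path = out / name
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
        written.append(path)

    # oracle table: stem-driven filling and a c=1 mutant on the toy model
    model = toy_model()
    grid = np.linspace(0.0, 5.0, 26)
    rows = []
    fill = integrate(OdeProblem(model, np.zeros(4), True, grid))
    fill.scenario = "stem_driven_fill"
    init = np.zeros(4)
    init[0] = 1.0
    mut = integrate(OdeProblem(model, init, False, grid))
    mut.scenario = "mutant_c1"
    frame = pd.concat([fill.to_frame(), mut.to_frame()], ignore_index=True)
    path = out / "oracle_trajectories.csv"
    with open(path, "w") as fh:
        fh.write("# ODE-integrated oracle trajectories on the 4-compartment toy model\n")
        fh.write("# columns: time [years], compartment [1..4], count [cells], scenario\n")
        frame.to_csv(fh, index=False, float_format="%.12g")
    written.append(path)
    return written
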