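"""Monte Carlo uncertainty quantification of treatment outcome.

Uncertain inputs are sampled from truncated normal distributions
X ~ μ + σ·N(0, 1); each sample reruns the full simulation with a derived
seed and the final cancer fraction f_c is recorded. The propagation of
uncertainty is summarised by the empirical distribution of f_c and the
Pearson sample correlation between each sampled input and f_c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .engine import SimulationConfig, run_simulation

__all__ = [
    "ParameterSpec",
    "EnsembleResult",
    "sample_parameters",
    "correlation",
    "empirical_cdf",
    "run_ensemble",
    "TABLE2_SPECS",
    "TIMING_SPECS",
]

#: config keys that each samplable symbol maps onto
_PARAM_KEYS = {
    "F": "force",
    "D_c": "chemokine_diffusivity",
    "beta": "mobility_coeff",
    "k": "k_init",
    "trigger_fraction": "trigger_fraction",
    "drug_duration": "drug_duration",
}


@dataclass
class ParameterSpec:
    """A samplable input: name, normal moments and truncation bounds."""

    name: str
    mean: float
    sd: float
    lower: Optional[float] = None
    upper: Optional[float] = None

    def __post_init__(self) -> None:
        if self.name not in _PARAM_KEYS:
            raise ValueError(f"unknown parameter {self.name!r}; valid: "
                             f"{sorted(_PARAM_KEYS)}")
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")
        if self.lower is None:
            # physical parameters floored at 1% of the mean
            if self.name == "trigger_fraction":
                self.lower = 0.05
            else:
                self.lower = 0.01 * abs(self.mean)
        if self.upper is None and self.name == "trigger_fraction":
            self.upper = 0.95


#: published sampling distributions of the four uncertain model inputs
TABLE2_SPECS = (
    ParameterSpec("F", 30.0, 3.0),
    ParameterSpec("D_c", 5000.0, 500.0),
    ParameterSpec("beta", 60.0, 6.0),
    ParameterSpec("k", 0.3, 0.1),
)

#: treatment-timing study: start fraction and drug injection interval τ
TIMING_SPECS = (
    ParameterSpec("trigger_fraction", 0.5, 0.1),
    ParameterSpec("drug_duration", 2.0, 1.0),
)


@dataclass
class EnsembleResult:
    """Sampled inputs, outcomes and summary statistics of an ensemble."""

    table: pd.DataFrame            # sample, sampled X columns, f_c, ...
    n_samples: int
    horizon: float
    scenario: str
    correlations: dict = field(default_factory=dict)
    failures: int = 0

    @property
    def f_c(self) -> np.ndarray:
        return self.table["f_c"].to_numpy()


def sample_parameters(specs, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``n`` independent samples of each spec, truncated to bounds."""
    if n < 1:
        raise ValueError("need at least one sample")
    out = {}
    for spec in specs:
        x = spec.mean + spec.sd * rng.standard_normal(n)
        if spec.lower is not None:
            x = np.maximum(x, spec.lower)
        if spec.upper is not None:
            x = np.minimum(x, spec.upper)
        out[spec.name] = x
    return pd.DataFrame(out)


def correlation(x, y) -> float:
    """Pearson sample correlation coefficient between two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    dx = x - x.mean()
    dy = y - y.mean()
    den = math.sqrt(float(np.sum(dx * dx)) * float(np.sum(dy * dy)))
    if den == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.sum(dx * dy) / den)


def empirical_cdf(values, threshold: float) -> float:
    """Proportion of values ≤ threshold (right-continuous empirical CDF)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    return float(np.mean(values <= threshold))


def _sample_seed(master_seed: int, j: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(j),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_ensemble(base_config: SimulationConfig, specs, n: int,
                 horizon: float, scenario: str, master_seed: int,
                 workers: int = 1) -> EnsembleResult:
    """Run an ``n``-sample Monte Carlo ensemble.

    Per sample: the sampled keys overwrite the base config, the simulation
    runs with a seed derived from ``(master_seed, sample index)``, and the
    final cancer fraction is recorded. Reduced-n reruns with the same master
    seed are prefixes of larger runs.
    """
    rng = np.random.default_rng(int(master_seed) % (2 ** 31))
    samples = sample_parameters(specs, n, rng)
    rows = []
    failures = 0
    base = base_config.model_dump()
    base.update(scenario=scenario, t_end=float(horizon), store_cells=False)

    def _one(j: int):
        d = dict(base)
        for spec in specs:
            d[_PARAM_KEYS[spec.name]] = float(samples[spec.name].iloc[j])
        d["seed"] = _sample_seed(master_seed, j)
        try:
            return run_simulation(SimulationConfig(**d))
        except RuntimeError:
            return None

    if workers > 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=workers)(delayed(_one)(j) for j in range(n))
    else:
        results = (_one(j) for j in range(n))

    for j, traj in enumerate(results):
        if traj is None:
            failures += 1
            continue
        s = traj.summary
        row = {"sample": j, "seed": s["seed"], "f_c": s["f_c"],
               "n_cancer_final": s["n_cancer_final"], "t0_h": s["t0_h"]}
        for spec in specs:
            row[spec.name] = float(samples[spec.name].iloc[j])
        rows.append(row)

    table = pd.DataFrame(rows)
    corr = {}
    for spec in specs:
        try:
            corr[spec.name] = correlation(table[spec.name], table["f_c"])
        except ValueError:
            corr[spec.name] = float("nan")
    return EnsembleResult(table=table, n_samples=n, horizon=float(horizon),
                          scenario=scenario, correlations=corr,
                          failures=failures)
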