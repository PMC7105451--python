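"""Canonical scenario configurations and hand-checkable toy states.

Every test and experiment in the package is runnable from a named scenario
plus a seed: the three study scenarios (no treatment, PEGPH20 only,
PEGPH20 + gemcitabine) carry the published input values and the package's
calibrated free constants, and the toy scenarios give tiny deterministic
states whose first-step updates can be verified by hand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .engine import SimulationConfig

__all__ = ["Scenario", "SCENARIO_NAMES", "make_scenario"]

SCENARIO_NAMES = ("no_treatment", "pegph20_only", "combo", "toy_two_cell",
                  "toy_annulus")


@dataclass
class Scenario:
    name: str
    config: SimulationConfig
    description: str


def make_scenario(name: str, seed: int = 0) -> Scenario:
    """Build a fully-populated, validated scenario configuration."""
    if name == "no_treatment":
        cfg = SimulationConfig(seed=seed, scenario="none", t_end=150.0)
        desc = ("Untreated tumour islet: initiating mutation, growth to the "
                "islet capacity, T-lymphocytes trapped in the stroma.")
    elif name == "pegph20_only":
        cfg = SimulationConfig(seed=seed, scenario="pegph20", t_end=150.0,
                               trigger_fraction=0.35)
        desc = ("Single 1-h PEGPH20 injection when the cancer fraction "
                "exceeds 35%; stromal anisotropy decays and T-lymphocytes "
                "infiltrate.")
    elif name == "combo":
        cfg = SimulationConfig(seed=seed, scenario="combo", t_end=150.0,
                               trigger_fraction=0.35, drug_lag=10.0,
                               drug_duration=1.0)
        desc = ("PEGPH20 at the 35% trigger plus a 1-h gemcitabine "
                "injection 10 h later suppressing cancer proliferation.")
    elif name == "toy_two_cell":
        cfg = SimulationConfig(seed=seed, scenario="none", t_end=0.01,
                               dt=0.01, eta=0.0, n_epithelial=2,
                               n_tcells=0, mutation_trigger_rate=0.0,
                               mutation_rate=0.0, division_rate=0.0,
                               death_rate=0.0, signal_threshold=0.0,
                               snapshot_every=0.01,
                               initial_positions=[[-10.0, 0.0], [10.0, 0.0]])
        desc = ("Two epithelial cells 20 μm apart, no noise: the "
                "first-step displacement is hand-computable from the "
                "strain-energy drift.")
    elif name == "toy_annulus":
        cfg = SimulationConfig(seed=seed, scenario="none", t_end=1.0,
                               dt=0.01, n_epithelial=5, n_tcells=3,
                               mutation_trigger_rate=1e4,
                               mutation_rate=0.0, division_rate=0.0,
                               death_rate=0.0, kill_on_contact=False)
        desc = ("Five epithelial cells and three T-lymphocytes for quick "
                "annulus/locomotion checks; runs in well under a second.")
    else:
        raise ValueError(f"unknown scenario {name!r}; valid: "
                         f"{SCENARIO_NAMES}")
    return Scenario(name=name, config=cfg, description=desc)
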