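"""Stochastic cell fate events: mutation, division, death, T-cell killing.

All discrete events are exponential waiting-time processes: an event with
rate λ fires within a time step Δt with probability 1 − exp(−λΔt), decided
against a uniform draw ξ ∈ [0, 1]. Gemcitabine suppresses cancer
proliferation and mutation by scaling the rate with exp(−A·c_drug).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fields import InjectionEvent, Species, injected_concentration
from .mechanics import CellState, MechanicsParams, Phenotype, total_signal

__all__ = [
    "FateRates",
    "event_probability",
    "drug_modulated_rate",
    "draw_event",
    "step_fates",
]


@dataclass
class FateRates:
    """Event rates (1/h) and drug response for the fate processes."""

    mutation_trigger_rate: float = 100.0   # initiating epithelial mutation
    mutation_rate: float = 5e-4            # subsequent epithelial mutations
    division_rate: float = 0.15            # cancer division λ0
    death_rate: float = 0.005              # cancer death
    kill_on_contact: bool = True
    kill_rate: float = 0.3                 # engulfment rate while impinging
    drug_sensitivity: float = 6.0          # A, per concentration unit
    division_signal_min: float = 0.0       # strain-energy gate on division
    division_signal_max: float = 0.05

    def __post_init__(self) -> None:
        for name in ("mutation_trigger_rate", "mutation_rate",
                     "division_rate", "death_rate", "kill_rate",
                     "drug_sensitivity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def event_probability(rate: float, dt: float) -> float:
    """P(event in Δt) = 1 − exp(−λΔt) for an exponential waiting time."""
    if rate < 0 or dt < 0:
        raise ValueError("rate and time step must be non-negative")
    return -math.expm1(-rate * dt)


def drug_modulated_rate(rate0: float, sensitivity: float,
                        c_drug: float) -> float:
    """Effective rate λ0·exp(−A·c_drug) under drug concentration c_drug."""
    if rate0 < 0 or sensitivity < 0 or c_drug < 0:
        raise ValueError("arguments must be non-negative")
    return rate0 * math.exp(-sensitivity * c_drug)


def draw_event(xi: float, p: float) -> bool:
    """Event fires iff the uniform sample ξ falls at or below p."""
    if not 0.0 <= xi <= 1.0:
        raise ValueError("xi must lie in [0, 1]")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return xi <= p


def _drug_concentration(pos, t, drug_events, exclusion_radius):
    c = 0.0
    for ev in drug_events:
        if ev.species is Species.DRUG:
            c += injected_concentration(pos, t, ev, exclusion_radius)
    return c


def step_fates(cells, rates: FateRates, dt: float, rng: np.random.Generator,
               params: MechanicsParams | None = None, drug_events=(),
               t: float = 0.0, placement_slack: float = 0.5,
               max_placement_tries: int = 8):
    """Apply one step of the stochastic fate processes to a cell list.

    Per live cell, in id order: epithelial→cancer mutation (drug-modulated
    trigger rate), cancer division (drug-modulated rate, gated on the total
    strain-energy signal, daughter placed tangent at a random angle subject
    to space), cancer death, and T-lymphocyte contact killing (rate-based
    engulfment while impinging). Dead cells are removed immediately.

    Returns ``(cells, events)`` where events are
    ``(time_h, cell_id, event, x_um, y_um)`` rows with event in
    {"mutation", "division", "death", "kill"}.
    """
    params = params or MechanicsParams()
    events = []
    cells = sorted([c for c in cells if c.alive], key=lambda c: c.id)
    next_id = max((c.id for c in cells), default=-1) + 1
    born = []
    dead_ids = set()

    for cell in cells:
        if cell.id in dead_ids:
            continue
        c_drug = _drug_concentration(cell.position, t, drug_events,
                                     cell.radius)
        if cell.phenotype is Phenotype.EPITHELIAL:
            lam = drug_modulated_rate(rates.mutation_trigger_rate,
                                      rates.drug_sensitivity, c_drug)
            if draw_event(rng.uniform(), event_probability(lam, dt)):
                cell.phenotype = Phenotype.CANCER
                events.append((t, cell.id, "mutation",
                               cell.position[0], cell.position[1]))
                continue
        elif cell.phenotype is Phenotype.CANCER:
            lam = drug_modulated_rate(rates.division_rate,
                                      rates.drug_sensitivity, c_drug)
            if draw_event(rng.uniform(), event_probability(lam, dt)):
                sig = total_signal(cell, cells, params)
                if rates.division_signal_min <= sig <= rates.division_signal_max:
                    daughter = _place_daughter(cell, cells + born, rng,
                                               placement_slack,
                                               max_placement_tries)
                    if daughter is not None:
                        daughter.id = next_id
                        daughter.birth_time = t
                        next_id += 1
                        born.append(daughter)
                        events.append((t, daughter.id, "division",
                                       daughter.position[0],
                                       daughter.position[1]))
            if draw_event(rng.uniform(),
                          event_probability(rates.death_rate, dt)):
                cell.alive = False
                dead_ids.add(cell.id)
                events.append((t, cell.id, "death",
                               cell.position[0], cell.position[1]))
        elif cell.phenotype is Phenotype.TLYMPHOCYTE and rates.kill_on_contact:
            for other in cells:
                if (other.phenotype is Phenotype.CANCER and other.alive
                        and other.id not in dead_ids):
                    d = np.linalg.norm(cell.position - other.position)
                    if d < cell.radius + other.radius:
                        p = event_probability(rates.kill_rate, dt)
                        if draw_event(rng.uniform(), p):
                            other.alive = False
                            dead_ids.add(other.id)
                            events.append((t, other.id, "kill",
                                           other.position[0],
                                           other.position[1]))
                            break

    out = [c for c in cells if c.alive] + born
    return out, events


def _place_daughter(parent: CellState, cells, rng, slack, tries):
    """Tangent placement with resampling; None if no admissible site."""
    for _ in range(tries):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        pos = parent.position + (2.0 * parent.radius) * np.array(
            [math.cos(phi), math.sin(phi)])
        ok = True
        for other in cells:
            if not other.alive or other.id == parent.id:
                continue
            overlap = (other.radius + parent.radius
                       - np.linalg.norm(pos - other.position))
            if overlap > slack * parent.radius:
                ok = False
                break
        if ok:
            return CellState(id=-1, phenotype=Phenotype.CANCER, position=pos,
                             radius=parent.radius, force=parent.force,
                             elasticity=parent.elasticity)
    return None
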