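"""Chemokine and injected enzyme/drug concentration fields.

Cancer cells secrete a generic chemokine modelled as steady-state 2-D point
sources; only the gradient is needed (the 2-D steady concentration itself is
log-divergent), and it has the closed form of a sum of 1/r terms. Therapy
injections (PEGPH20 enzyme, gemcitabine drug) are finite-duration point
sources of the transient diffusion equation; their concentration is the
time integral of the 2-D heat kernel, evaluated in closed form with the
exponential integral E1.

Distances are clamped below at an exclusion radius (a cell radius by
default) because ideal point-source fields diverge at the source.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "Species",
    "ChemokineField",
    "InjectionEvent",
    "chemokine_gradient",
    "injection_rate",
    "injected_concentration",
    "concentration_at_subdomains",
    "exp1",
]

_EULER_GAMMA = 0.5772156649015328606


@njit(cache=True)
def _exp1(x):
    """Exponential integral E1(x) for x > 0.

    Power series for x <= 1, modified Lentz continued fraction otherwise;
    relative accuracy ~1e-13 over the range used here.
    """
    if x <= 0.0:
        return np.inf
    if x <= 1.0:
        # E1(x) = -γ - ln x + Σ_{k>=1} (-1)^{k+1} x^k / (k·k!)
        s = 0.0
        term = 1.0
        for k in range(1, 40):
            term *= -x / k
            add = -term / k
            s += add
            if abs(add) < 1e-17 * max(abs(s), 1e-300):
                break
        return -_EULER_GAMMA - math.log(x) + s
    # continued fraction: E1(x) = e^{-x} / (x + 1/(1 + 1/(x + 2/(1 + ...))))
    tiny = 1e-300
    b = x + 1.0
    c = 1.0 / tiny
    d = 1.0 / b
    h = d
    for i in range(1, 200):
        a = -1.0 * i * i
        b += 2.0
        d = 1.0 / (a * d + b)
        c = b + a / c
        if c == 0.0:
            c = tiny
        delta = c * d
        h *= delta
        if abs(delta - 1.0) < 1e-15:
            break
    return h * math.exp(-x)


def exp1(x: float) -> float:
    """Exponential integral E1 evaluated by the internal compiled kernel."""
    if x < 0:
        raise ValueError("E1 is evaluated for non-negative arguments only")
    return float(_exp1(float(x)))


class Species(enum.Enum):
    ENZYME = "enzyme"
    DRUG = "drug"


@dataclass
class ChemokineField:
    """Steady-state chemokine emitted by the current cancer-cell set."""

    diffusivity: float = 5e3                  # D_c, μm²/h
    secretion_rate: float = 5e6               # γ, mol/(h·μm³), per source
    source_positions: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 2)))

    def __post_init__(self) -> None:
        self.source_positions = np.atleast_2d(
            np.asarray(self.source_positions, dtype=float))
        if self.source_positions.size == 0:
            self.source_positions = np.zeros((0, 2))
        if self.diffusivity <= 0:
            raise ValueError("chemokine diffusivity must be positive")
        if self.secretion_rate < 0:
            raise ValueError("secretion rate must be non-negative")


@dataclass
class InjectionEvent:
    """A finite-duration point injection of enzyme or drug."""

    species: Species
    site: np.ndarray            # 2-vector, μm
    t_start: float              # h
    t_end: float                # h
    rate: float = 5e6           # γ0, mol/(h·μm³)
    diffusivity: float = 1e4    # μm²/h

    def __post_init__(self) -> None:
        self.site = np.asarray(self.site, dtype=float)
        if not self.t_start < self.t_end:
            raise ValueError("injection requires t_start < t_end")
        if self.rate < 0:
            raise ValueError("injection rate must be non-negative")
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be positive")


@njit(cache=True)
def _chemokine_gradient(probe, sources, rate, diffusivity, exclusion_radius):
    g = np.zeros(2)
    pref = rate / (2.0 * np.pi * diffusivity)
    for j in range(sources.shape[0]):
        dx = probe[0] - sources[j, 0]
        dy = probe[1] - sources[j, 1]
        d2 = dx * dx + dy * dy
        r2min = exclusion_radius * exclusion_radius
        if d2 < r2min:
            d2 = r2min
        g[0] -= pref * dx / d2
        g[1] -= pref * dy / d2
    return g


def chemokine_gradient(probe, fieldspec: ChemokineField,
                       exclusion_radius: float = 8.0) -> np.ndarray:
    """∇c at a probe point: −Σ_j γ/(2π D_c) · (r − r_j)/‖r − r_j‖².

    Points toward each source. Distances are clamped below at
    ``exclusion_radius`` to regularise the point-source singularity.
    """
    probe = np.asarray(probe, dtype=float)
    if not np.all(np.isfinite(probe)):
        raise ValueError("probe position must be finite")
    return _chemokine_gradient(probe, fieldspec.source_positions,
                               fieldspec.secretion_rate,
                               fieldspec.diffusivity,
                               float(exclusion_radius))


def injection_rate(t: float, event: InjectionEvent) -> float:
    """γ(t): the constant rate γ0 on the half-open interval (t_start, t_end]."""
    if event.t_start < t <= event.t_end:
        return event.rate
    return 0.0


@njit(cache=True)
def _injected_concentration(rho, t, t_start, t_end, rate, diffusivity,
                            exclusion_radius):
    """Closed-form heat-kernel time integral of a finite-duration source.

    c(ρ, t) = γ0/(4πD) · [E1(ρ²/(4D(t−t_start))) − E1(ρ²/(4D(t−t_end)))],
    the second term present only once the source has switched off.
    """
    if t <= t_start:
        return 0.0
    if rho < exclusion_radius:
        rho = exclusion_radius
    q = rho * rho / (4.0 * diffusivity)
    val = _exp1(q / (t - t_start))
    if t > t_end:
        val -= _exp1(q / (t - t_end))
    return rate / (4.0 * np.pi * diffusivity) * val


def injected_concentration(probe, t: float, event: InjectionEvent,
                           exclusion_radius: float = 8.0) -> float:
    """Concentration at ``probe`` and time ``t`` from one injection event."""
    if t < 0:
        raise ValueError("time must be non-negative")
    probe = np.asarray(probe, dtype=float)
    rho = float(np.linalg.norm(probe - event.site))
    return float(_injected_concentration(rho, float(t), event.t_start,
                                         event.t_end, event.rate,
                                         event.diffusivity,
                                         float(exclusion_radius)))


def concentration_at_subdomains(t: float, events, midpoints,
                                species: Species | None = None,
                                exclusion_radius: float = 8.0) -> np.ndarray:
    """Concentration sensed at each subdomain midpoint.

    Sums over the given injection events (optionally restricted to one
    species) at every midpoint; returns a vector of length N.
    """
    midpoints = np.atleast_2d(np.asarray(midpoints, dtype=float))
    out = np.zeros(midpoints.shape[0])
    for ev in events:
        if species is not None and ev.species is not species:
            continue
        for i in range(midpoints.shape[0]):
            out[i] += injected_concentration(midpoints[i], t, ev,
                                             exclusion_radius)
    return out
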