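"""Strain-energy-density mechanics of epithelial and cancer cells.

Cells exert a contraction force on the substrate and thereby deform it; the
stored elastic energy per unit volume (the strain energy density M) acts as a
long-range mechanical signal. Each cell senses the attenuated signals of its
neighbours, migrates along the resultant direction, and is repelled on contact
through Hertz impingement mechanics. All quantities use the μm / h / kg unit
system: forces in kg·μm/h², moduli in kg/(μm·h²).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "Phenotype",
    "CellState",
    "MechanicsParams",
    "strain_energy_density",
    "attenuated_signal",
    "total_signal",
    "migration_direction",
    "velocity_parameter",
    "hertz_repulsion",
    "contact_overlap",
]

#: below this distance (μm) two cells are treated as coincident and the
#: jitter rule applies (the interconnecting unit vector is undefined).
COINCIDENCE_TOL = 1e-6
#: magnitude of the deterministic de-coincidence jitter (μm).
JITTER = 1e-3
#: ‖z‖ below this is treated as a vanishing resultant (no drift direction).
DIRECTION_TOL = 1e-14

HERTZ_PREFACTOR = 4.0 / (15.0 * math.sqrt(2.0))


class Phenotype(enum.Enum):
    EPITHELIAL = "epithelial"
    CANCER = "cancer"
    TLYMPHOCYTE = "tlymphocyte"


@dataclass
class CellState:
    """One agent: a circular cell with fixed radius and traction force."""

    id: int
    phenotype: Phenotype
    position: np.ndarray          # 2-vector, μm
    radius: float                 # μm
    force: float                  # contraction force, kg·μm/h²
    elasticity: float             # Young's modulus of the cell, kg/(μm·h²)
    alive: bool = True
    birth_time: float = 0.0       # h

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.radius <= 0:
            raise ValueError("cell radius must be positive")
        if self.force < 0:
            raise ValueError("contraction force must be non-negative")
        if self.elasticity <= 0:
            raise ValueError("cell elasticity must be positive")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("cell position must be finite")


@dataclass
class MechanicsParams:
    """Substrate and motility constants shared by epithelial/cancer cells."""

    substrate_modulus: float = 5.0    # E_s, kg/(μm·h²)
    cell_modulus: float = 0.5         # E_c, kg/(μm·h²)
    mobility_coeff: float = 60.0      # β_i, 1/h
    friction_coeff: float = 0.2       # μ, dimensionless
    random_walk_scale: float = 2.0    # η, μm/√h

    def __post_init__(self) -> None:
        for name in ("substrate_modulus", "cell_modulus", "mobility_coeff",
                     "friction_coeff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.random_walk_scale < 0:
            raise ValueError("random_walk_scale must be non-negative")

    @property
    def attenuation(self) -> float:
        """λ = E_s / E_c, the signal attenuation factor."""
        return self.substrate_modulus / self.cell_modulus


@njit(cache=True)
def _sed(force, substrate_modulus, radius):
    return force * force / (2.0 * np.pi ** 2 * substrate_modulus * radius ** 4)


def strain_energy_density(force: float, substrate_modulus: float,
                          radius: float) -> float:
    """Strain energy density M⁰ = F² / (2π² E_s R⁴) generated by one cell.

    ``force`` may be zero (an immotile cell deposits no energy); the modulus
    and radius must be strictly positive.
    """
    if substrate_modulus <= 0:
        raise ValueError("substrate modulus must be strictly positive")
    if radius <= 0:
        raise ValueError("radius must be strictly positive")
    if force < 0:
        raise ValueError("force must be non-negative")
    return float(_sed(force, substrate_modulus, radius))


def attenuated_signal(source_density: float, attenuation: float,
                      source_pos, probe_pos, radius: float) -> float:
    """Signal of a source cell felt at a probe point.

    M(r) = M⁰ exp(−λ ‖r_src − r‖ / R): exponential decay of the mechanical
    signal with the centre-to-centre distance measured in cell radii.
    """
    if radius <= 0:
        raise ValueError("radius must be strictly positive")
    if attenuation < 0:
        raise ValueError("attenuation must be non-negative")
    d = float(np.linalg.norm(np.asarray(probe_pos, float) -
                             np.asarray(source_pos, float)))
    return float(source_density * math.exp(-attenuation * d / radius))


def _wc_cells(cells):
    return [c for c in cells
            if c.alive and c.phenotype is not Phenotype.TLYMPHOCYTE]


def total_signal(probe_cell: CellState, all_cells, params: MechanicsParams,
                 threshold: float = 0.0) -> float:
    """Total strain energy density sensed by ``probe_cell``.

    The cell's own M⁰ plus the attenuated signals of every other live
    epithelial/cancer cell (T-lymphocytes neither emit nor sense mechanical
    signals). Neighbour contributions below ``threshold`` are not sensed.
    """
    lam = params.attenuation
    total = strain_energy_density(probe_cell.force, params.substrate_modulus,
                                  probe_cell.radius)
    for other in _wc_cells(all_cells):
        if other is probe_cell or other.id == probe_cell.id:
            continue
        m0 = strain_energy_density(other.force, params.substrate_modulus,
                                   other.radius)
        sig = attenuated_signal(m0, lam, other.position, probe_cell.position,
                                other.radius)
        if sig >= threshold:
            total += sig
    return total


def _dejitter_direction(seed_ints) -> np.ndarray:
    """Deterministic unit vector for the coincident-position jitter rule."""
    rng = np.random.default_rng(abs(int(seed_ints)) % (2 ** 31))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([math.cos(phi), math.sin(phi)])


def migration_direction(probe_cell: CellState, all_cells,
                        params: MechanicsParams,
                        threshold: float = 0.0) -> np.ndarray:
    """Unit migration direction ẑ of an epithelial/cancer cell.

    z = Σ_j M_j(r_i) ê_ij with ê_ij the unit vector pointing from neighbour j
    to the probe cell i, so cells move away from strong mechanical sources.
    Returns the zero vector when the resultant is below tolerance. Coincident
    neighbours are displaced by a deterministic 1e-3 μm jitter before the
    interconnecting vector is formed.
    """
    lam = params.attenuation
    z = np.zeros(2)
    pos_i = np.asarray(probe_cell.position, float)
    for other in _wc_cells(all_cells):
        if other is probe_cell or other.id == probe_cell.id:
            continue
        pos_j = np.asarray(other.position, float)
        diff = pos_i - pos_j
        d = float(np.linalg.norm(diff))
        if d < COINCIDENCE_TOL:
            diff = JITTER * _dejitter_direction(probe_cell.id * 1000003
                                                + other.id)
            d = JITTER
        m0 = strain_energy_density(other.force, params.substrate_modulus,
                                   other.radius)
        sig = m0 * math.exp(-lam * d / other.radius)
        if sig >= threshold:
            z += sig * diff / d
    nz = float(np.linalg.norm(z))
    if nz < DIRECTION_TOL:
        return np.zeros(2)
    return z / nz


@njit(cache=True)
def _alpha(mobility_coeff, radius, friction_coeff, force):
    return mobility_coeff * radius ** 3 / (friction_coeff * force)


def velocity_parameter(mobility_coeff: float, radius: float,
                       friction_coeff: float, force: float) -> float:
    """Velocity parameter α = β R³ / (μ F) converting signal to speed."""
    if friction_coeff <= 0:
        raise ValueError("friction coefficient must be strictly positive")
    if force <= 0:
        raise ValueError("force must be strictly positive (immotile cells "
                         "need F > 0 for a finite velocity parameter)")
    if radius <= 0 or mobility_coeff <= 0:
        raise ValueError("radius and mobility coefficient must be positive")
    return float(_alpha(mobility_coeff, radius, friction_coeff, force))


@njit(cache=True)
def _hertz(elasticity, overlap, radius):
    if overlap <= 0.0:
        return 0.0
    return (HERTZ_PREFACTOR * elasticity / np.pi
            * (overlap / radius) ** 2.5)


def hertz_repulsion(cell_elasticity: float, overlap: float,
                    radius: float) -> float:
    """Hertz impingement magnitude M^ij = 4/(15√2) · E/π · (h/R)^{5/2}.

    ``overlap`` is the impingement depth h = max(R_i + R_j − ‖r_ij‖, 0);
    for unequal radii ``radius`` should be the mean radius.
    """
    if radius <= 0:
        raise ValueError("radius must be strictly positive")
    if cell_elasticity <= 0:
        raise ValueError("elasticity must be strictly positive")
    return float(_hertz(cell_elasticity, max(overlap, 0.0), radius))


def contact_overlap(pos_i, pos_j, radius_i: float, radius_j: float) -> float:
    """Impingement depth h = max(R_i + R_j − ‖r_i − r_j‖, 0) in μm."""
    d = float(np.linalg.norm(np.asarray(pos_i, float)
                             - np.asarray(pos_j, float)))
    return max(radius_i + radius_j - d, 0.0)
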