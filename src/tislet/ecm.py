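"""Desmoplastic ECM annulus: geometry, orientation tensor, enzymatic decay.

The stroma around the tumour islet is an annulus R1 < ‖r‖ < R2 whose collagen
is circumferentially aligned. A symmetric orientation tensor

    Ψ = v0·e^{−k s}·λ1 · w1 w1ᵀ + v0·λ2 · w2 w2ᵀ

(w1 radial, w2 tangential, s the penetration depth from the outer boundary)
biases T-lymphocyte displacement: λ2 ≫ λ1 means fast tangential gliding and
suppressed radial penetration, which e^{−ks} suppresses further with depth.
The annulus is split into N angular subdomains whose midpoints sense the
enzyme concentration; per-subdomain λ2 relaxes toward λ1 and k decays toward
zero under PEGPH20 exposure (forward-Euler updates of first-order kinetics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EcmAnnulus",
    "subdomain_midpoints",
    "locate_subdomain",
    "orientation_tensor",
    "update_lambda2",
    "update_k",
]


def subdomain_midpoints(inner_radius: float, outer_radius: float,
                        n_subdomains: int) -> np.ndarray:
    """Midpoints of the N angular subdomains, at radius (R1+R2)/2.

    Subdomain i (1-based) spans angles [(i−1)·2π/N, i·2π/N); its midpoint is
    placed at angle 2π(i−1)/N following the published construction.
    """
    if not 0 < inner_radius < outer_radius:
        raise ValueError("annulus requires 0 < R1 < R2")
    if n_subdomains < 1:
        raise ValueError("need at least one subdomain")
    rm = 0.5 * (inner_radius + outer_radius)
    ang = 2.0 * np.pi * np.arange(n_subdomains) / n_subdomains
    return np.column_stack([rm * np.cos(ang), rm * np.sin(ang)])


@dataclass
class EcmAnnulus:
    """Annular stroma with per-subdomain anisotropy state."""

    inner_radius: float = 120.0       # R1, μm
    outer_radius: float = 200.0       # R2, μm
    n_subdomains: int = 10
    lambda1: float = 1.0              # radial weight (isotropic target)
    lambda2_init: float = 10.0        # initial tangential weight
    k_init: float = 0.3               # initial radial attenuation rate, 1/μm
    v0: float = 1.0                   # boundary speed scale
    decay_rate: float = 0.7           # L, per concentration unit per h
    lambda2: np.ndarray = field(default=None)  # per-subdomain, time-varying
    k: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("annulus requires 0 < R1 < R2")
        if self.n_subdomains < 1:
            raise ValueError("need at least one subdomain")
        if self.lambda2 is None:
            self.lambda2 = np.full(self.n_subdomains, float(self.lambda2_init))
        else:
            self.lambda2 = np.asarray(self.lambda2, dtype=float)
        if self.k is None:
            self.k = np.full(self.n_subdomains, float(self.k_init))
        else:
            self.k = np.asarray(self.k, dtype=float)

    def midpoints(self) -> np.ndarray:
        return subdomain_midpoints(self.inner_radius, self.outer_radius,
                                   self.n_subdomains)


def locate_subdomain(position, annulus: EcmAnnulus):
    """Subdomain index (1..N) containing ``position``, or None outside.

    Membership requires R1 < ‖r‖ < R2 strictly; the index follows from the
    full-circle polar angle θ ∈ [0, 2π) via j = 1 + floor(θ N / 2π).
    """
    position = np.asarray(position, dtype=float)
    r = float(np.linalg.norm(position))
    if not annulus.inner_radius < r < annulus.outer_radius:
        return None
    theta = float(np.arctan2(position[1], position[0])) % (2.0 * np.pi)
    j = 1 + int(theta * annulus.n_subdomains / (2.0 * np.pi))
    return min(j, annulus.n_subdomains)


def orientation_tensor(position, annulus: EcmAnnulus,
                       subdomain_index: int) -> np.ndarray:
    """The 2×2 symmetric orientation tensor Ψ at a point in the annulus.

    Eigenpairs: (v0·e^{−k_j s}·λ1, radial) and (v0·λ2_j, tangential), with
    penetration depth s = R2 − ‖r‖ clamped to [0, R2 − R1].
    """
    position = np.asarray(position, dtype=float)
    r = float(np.linalg.norm(position))
    if r == 0.0:
        raise ValueError("orientation tensor undefined at the origin "
                         "(no radial direction)")
    j = int(subdomain_index) - 1
    if not 0 <= j < annulus.n_subdomains:
        raise ValueError("invalid subdomain index")
    s = min(max(annulus.outer_radius - r, 0.0),
            annulus.outer_radius - annulus.inner_radius)
    w1 = position / r                       # radial
    w2 = np.array([-w1[1], w1[0]])          # tangential
    ev_rad = annulus.v0 * np.exp(-annulus.k[j] * s) * annulus.lambda1
    ev_tan = annulus.v0 * annulus.lambda2[j]
    return ev_rad * np.outer(w1, w1) + ev_tan * np.outer(w2, w2)


def update_lambda2(lambda2_current, lambda1: float, decay_rate: float,
                   c_en: float, dt: float):
    """Forward-Euler relaxation λ2 ← λ2 + L (λ1 − λ2) c_en Δt.

    The fixed point is λ2 = λ1. If the explicit step would overshoot
    (L·c_en·Δt > 1) the update is clamped onto the interval between the
    current value and λ1, preserving monotone approach.
    """
    lam2 = np.asarray(lambda2_current, dtype=float)
    step = np.minimum(decay_rate * np.asarray(c_en, dtype=float) * dt, 1.0)
    new = lam2 + (lambda1 - lam2) * step
    return new if new.shape else float(new)


def update_k(k_current, decay_rate: float, c_en: float, dt: float):
    """Forward-Euler decay k ← k − L k c_en Δt, clamped at the absorbing 0."""
    k = np.asarray(k_current, dtype=float)
    step = np.minimum(decay_rate * np.asarray(c_en, dtype=float) * dt, 1.0)
    new = k * (1.0 - step)
    return new if new.shape else float(new)
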