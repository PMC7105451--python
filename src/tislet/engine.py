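"""Time-stepping simulator for the tumour-islet therapy model.

One simulation advances an off-lattice population of epithelial cells,
cancer cells and T-lymphocytes with Euler–Maruyama position updates,
exponential-waiting-time fate events, an anisotropic stromal annulus, and a
therapy schedule (a 1-h PEGPH20 injection triggered when the cancer fraction
exceeds a threshold, optionally followed 10 h later by a gemcitabine
injection). The inner loop is compiled with numba; thin Python functions
mirror the single-step updates for verification.

Epithelial and cancer cells (Euler–Maruyama step)::

    r ← r + Δt·α·(M·ẑ + Σ_contacts M^ij ê_ij) + η·ΔW

with M the sensed strain-energy signal, ẑ the resultant signal direction and
M^ij the Hertz impingement magnitudes. T-lymphocytes follow chemotaxis::

    r ← r + β∇c·Δt + η·ΔW + Σ M^ij ê_ij Δt            (outside the stroma)
    r ← r + μ_j·Ψ·(β∇c·Δt + η·ΔW) + Σ M^ij ê_ij Δt    (inside the stroma)

Units: μm, h, kg. The deterministic displacement per step is capped at
``max_det_step`` so the realised step always respects the stability bound
Δt ≤ R / (2·max‖v‖).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from numba import njit
from pydantic import BaseModel, ConfigDict, model_validator

from .fields import (ChemokineField, InjectionEvent, Species, _exp1,
                     _injected_concentration, chemokine_gradient)
from .mechanics import HERTZ_PREFACTOR, MechanicsParams
from .ecm import EcmAnnulus, subdomain_midpoints

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "max_stable_dt",
    "step_epithelial_cancer",
    "step_tcells",
    "apply_therapy_schedule",
    "run_simulation",
]

# phenotype codes used by the compiled state arrays
EPI, CANCER, TCELL = 0, 1, 2
_EV_NAMES = ("mutation", "division", "death", "kill")
_NMAX = 2048
_EVCAP = 40000


class SimulationConfig(BaseModel):
    """All model constants, therapy schedule and numerical controls.

    Defaults marked "calibrated, not from paper" are free constants of the
    model fixed by calibration of the default scenarios; the remainder are
    the published input values.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # numerics
    dt: float = 0.01                      # h
    t_end: float = 150.0                  # h
    seed: int = 0
    snapshot_every: float = 1.0           # h
    store_cells: bool = False
    max_det_step: float = 2.0             # μm; calibrated, not from paper

    # geometry
    domain_radius: float = 300.0          # μm; calibrated, not from paper
    cell_radius: float = 8.0              # R
    tcell_radius: float = 5.0             # R_t
    islet_inner_radius: float = 120.0     # R1
    islet_outer_radius: float = 200.0     # R2
    n_subdomains: int = 10

    # mechanics
    force: float = 30.0                   # F, kg·μm/h²
    substrate_modulus: float = 5.0        # E_s
    cell_modulus: float = 0.5             # E_c
    tcell_modulus: float = 250.0          # E_t
    mobility_coeff: float = 60.0          # β of the velocity parameter
    friction_coeff: float = 0.2           # μ
    eta: float = 2.0                      # η, μm/√h; calibrated, not from paper
    signal_threshold: float = 1e-9        # calibrated, not from paper

    # chemokine and T-cell migration
    chemokine_diffusivity: float = 5e3    # D_c
    secretion_rate: float = 5e6           # γ
    chemotactic_coeff: float = 0.4        # chemotactic constant β; calibrated
    chemotactic_mobility: float = 0.5     # μ_j; calibrated, not from paper

    # stromal annulus
    lambda1: float = 1.0                  # calibrated, not from paper
    lambda2_init: float = 10.0
    k_init: float = 0.3                   # 1/μm
    v0: float = 1.0                       # calibrated, not from paper
    ecm_decay_rate: float = 0.7           # L; calibrated, not from paper

    # fate rates
    mutation_trigger_rate: float = 100.0  # 1/h
    mutation_rate: float = 0.00465        # calibrated, not from paper
    division_rate: float = 0.018          # calibrated, not from paper
    death_rate: float = 0.001             # calibrated, not from paper
    kill_on_contact: bool = True
    kill_rate: float = 0.85               # calibrated, not from paper
    drug_sensitivity: float = 1.5         # A; calibrated, not from paper
    division_signal_min: float = -0.02    # calibrated, not from paper
    division_signal_max: float = 0.05     # calibrated, not from paper
    placement_slack: float = 1.25         # daughter overlap tolerance, in R

    # therapy
    scenario: Literal["none", "pegph20", "combo"] = "none"
    trigger_fraction: float = 0.35
    enzyme_duration: float = 1.0          # h
    drug_lag: float = 10.0                # h
    drug_duration: float = 1.0            # τ, h
    injection_rate_gamma0: float = 5e6
    enzyme_diffusivity: float = 3.6e4     # D_en, μm²/h (10 μm²/s)
    drug_diffusivity: float = 1e4         # D_drug
    enzyme_site_offset: float = 20.0      # radial offset beyond R2, μm
    #: equidistant from sensing points 5 and 6 (at angles 144° and 180°)
    injection_angle: float = 0.9 * math.pi

    # populations
    n_epithelial: int = 110               # calibrated, not from paper
    n_tcells: int = 30                    # calibrated, not from paper
    max_cells: int = 2048                 # hard capacity of the state arrays
    #: the stiff stromal ring encapsulates the islet: epithelial/cancer
    #: cells cannot penetrate R1 (T-lymphocytes can)
    confine_islet: bool = True
    #: explicit epithelial start positions (overrides the lattice layout)
    initial_positions: Optional[list] = None

    @model_validator(mode="after")
    def _check(self):
        if self.dt <= 0:
            raise ValueError("dt must be strictly positive")
        if self.t_end <= 0:
            raise ValueError("t_end must be strictly positive")
        if not 0 < self.trigger_fraction < 1:
            raise ValueError("trigger_fraction must lie in (0, 1)")
        if not 0 < self.islet_inner_radius < self.islet_outer_radius:
            raise ValueError("islet radii must satisfy 0 < R1 < R2")
        if self.islet_outer_radius >= self.domain_radius:
            raise ValueError("domain_radius must exceed R2")
        if self.snapshot_every < self.dt:
            raise ValueError("snapshot_every must be at least dt")
        return self

    # convenience views used across the package -------------------------
    def mechanics_params(self) -> MechanicsParams:
        return MechanicsParams(substrate_modulus=self.substrate_modulus,
                               cell_modulus=self.cell_modulus,
                               mobility_coeff=self.mobility_coeff,
                               friction_coeff=self.friction_coeff,
                               random_walk_scale=self.eta)

    def annulus(self) -> EcmAnnulus:
        return EcmAnnulus(inner_radius=self.islet_inner_radius,
                          outer_radius=self.islet_outer_radius,
                          n_subdomains=self.n_subdomains,
                          lambda1=self.lambda1,
                          lambda2_init=self.lambda2_init,
                          k_init=self.k_init, v0=self.v0,
                          decay_rate=self.ecm_decay_rate)

    def enzyme_site(self) -> np.ndarray:
        r = self.islet_outer_radius + self.enzyme_site_offset
        return np.array([r * math.cos(self.injection_angle),
                         r * math.sin(self.injection_angle)])

    def drug_site(self) -> np.ndarray:
        r = 0.5 * (self.islet_inner_radius + self.islet_outer_radius)
        return np.array([r * math.cos(self.injection_angle),
                         r * math.sin(self.injection_angle)])


@dataclass
class Trajectory:
    """Result of one simulation run."""

    timeseries: pd.DataFrame          # time_h, n_epithelial, n_cancer, n_tcell, f
    events: pd.DataFrame              # time_h, cell_id, event, x_um, y_um
    lambda2_history: pd.DataFrame     # per-snapshot λ2 of each subdomain
    k_history: pd.DataFrame
    summary: dict
    snapshots: Optional[pd.DataFrame] = None   # per-snapshot cell table
    final_cells: Optional[pd.DataFrame] = None


def max_stable_dt(radius: float, velocities, cap: float = np.inf) -> float:
    """Stability bound Δt ≤ R / (2·max‖v‖); the configured cap when idle."""
    v = np.atleast_2d(np.asarray(velocities, dtype=float))
    if v.size == 0:
        return cap
    vmax = float(np.max(np.linalg.norm(v, axis=-1)))
    if vmax == 0.0:
        return cap
    return min(radius / (2.0 * vmax), cap)


# ---------------------------------------------------------------------------
# compiled kernels
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _bin_of(x, y, half, bs, nb):
    bi = int((x + half) / bs)
    bj = int((y + half) / bs)
    if bi < 0:
        bi = 0
    elif bi >= nb:
        bi = nb - 1
    if bj < 0:
        bj = 0
    elif bj >= nb:
        bj = nb - 1
    return bi * nb + bj


@njit(cache=True)
def _build_grid(pos, alive, n, half, bs, nb, head, nxt):
    for b in range(nb * nb):
        head[b] = -1
    for i in range(n):
        if alive[i]:
            b = _bin_of(pos[i, 0], pos[i, 1], half, bs, nb)
            nxt[i] = head[b]
            head[b] = i


@njit(cache=True)
def _advance(seed, pos, phen, alive, birth, radius, n_init, par, lam2, kk,
             mids, ts, lam2_hist, k_hist, snap_cells, events, marks,
             store_cells):
    """Run the full simulation loop in place; see module docstring.

    par is the packed parameter vector (see _pack_params for the layout).
    """
    np.random.seed(seed)

    dt = par[0]
    t_end = par[1]
    R = par[2]
    Rt = par[3]
    R1 = par[4]
    R2 = par[5]
    dom = par[6]
    F = par[7]
    Es = par[8]
    Ec = par[9]
    Et = par[10]
    beta_m = par[11]
    mu = par[12]
    eta = par[13]
    thresh = par[14]
    cap = par[15]
    Dc = par[16]
    gam_c = par[17]
    beta_c = par[18]
    mu_j = par[19]
    lam1 = par[20]
    v0 = par[21]
    Lrate = par[22]
    trig_rate = par[23]
    mut_rate = par[24]
    div_rate = par[25]
    death_rate = par[26]
    kill_rate = par[27]
    A = par[28]
    mdiv_lo = par[29]
    mdiv_hi = par[30]
    gamma0 = par[31]
    Den = par[32]
    Ddrug = par[33]
    enz_x = par[34]
    enz_y = par[35]
    drug_x = par[36]
    drug_y = par[37]
    trig_frac = par[38]
    enz_dur = par[39]
    drug_lag = par[40]
    drug_dur = par[41]
    scenario = int(par[42])
    n_tcells = int(par[43])
    exclR = par[44]
    slack = par[45]
    snap_stride = int(par[46])
    tc_rmin = par[47]
    tc_rmax = par[48]
    kill_on = par[49] > 0.5
    confine = par[50] > 0.5

    nmax = pos.shape[0]
    nsub = lam2.shape[0]
    nsteps = int(round(t_end / dt))

    lam_att = Es / Ec                      # signal attenuation λ = E_s/E_c
    m0 = F * F / (2.0 * np.pi ** 2 * Es * R ** 4)
    alpha = beta_m * R ** 3 / (mu * F)
    sq_dt = math.sqrt(dt)

    # neighbour cutoff: contact range or the signal-sensing range
    cutoff = 2.0 * R + 2.0
    if thresh > 0.0 and thresh < m0:
        d_sense = R / lam_att * math.log(m0 / thresh)
        if d_sense + 1.0 > cutoff:
            cutoff = d_sense + 1.0
    else:
        cutoff = 4.0 * dom                 # effectively brute force
    half = dom + 4.0 * R
    bs = cutoff
    nb = int(2.0 * half / bs)
    if nb < 1:
        nb = 1
    if nb > 96:
        nb = 96
    bs = 2.0 * half / nb
    head = np.full(nb * nb, -1, dtype=np.int64)
    nxt = np.full(nmax, -1, dtype=np.int64)

    newx = np.zeros(nmax)
    newy = np.zeros(nmax)
    msens = np.zeros(nmax)
    cen = np.zeros(nsub)

    n_total = n_init
    n_epi = 0
    n_canc = 0
    n_tc = 0
    for i in range(n_init):
        if alive[i]:
            if phen[i] == 0:
                n_epi += 1
            elif phen[i] == 1:
                n_canc += 1
            else:
                n_tc += 1

    initiated = n_canc > 0
    triggered = False
    t0 = -1.0
    t1 = -1.0
    t2 = -1.0
    t3 = -1.0
    t_first = -1.0
    ev_n = 0
    snap_i = 0
    abort = 0.0

    f = 0.0
    if n_epi + n_canc > 0:
        f = n_canc / (n_epi + n_canc)
    ts[0, 0] = 0.0
    ts[0, 1] = n_epi
    ts[0, 2] = n_canc
    ts[0, 3] = n_tc
    ts[0, 4] = f
    for j in range(nsub):
        lam2_hist[0, j] = lam2[j]
        k_hist[0, j] = kk[j]
    if store_cells:
        for i in range(nmax):
            snap_cells[0, i, 0] = pos[i, 0]
            snap_cells[0, i, 1] = pos[i, 1]
            snap_cells[0, i, 2] = phen[i] if (i < n_total and alive[i]) else -1.0
    snap_i = 1

    for step in range(nsteps):
        t = step * dt
        t_next = t + dt

        # ---- fields: enzyme concentration at subdomain midpoints --------
        enz_on = triggered and scenario >= 1 and t > t0
        if enz_on:
            for j in range(nsub):
                dx = mids[j, 0] - enz_x
                dy = mids[j, 1] - enz_y
                rho = math.sqrt(dx * dx + dy * dy)
                cen[j] = _injected_concentration(rho, t, t0, t1, gamma0,
                                                 Den, exclR)
        else:
            for j in range(nsub):
                cen[j] = 0.0
        drug_on = triggered and scenario == 2 and t > t2

        # ---- stroma state update (forward Euler, clamped) ---------------
        for j in range(nsub):
            stepf = Lrate * cen[j] * dt
            if stepf > 1.0:
                stepf = 1.0
            lam2[j] += (lam1 - lam2[j]) * stepf
            kk[j] *= 1.0 - stepf

        # ---- neighbour grid ---------------------------------------------
        _build_grid(pos, alive, n_total, half, bs, nb, head, nxt)

        # ---- epithelial / cancer positions ------------------------------
        for i in range(n_total):
            if not alive[i] or phen[i] == 2:
                continue
            zx = 0.0
            zy = 0.0
            mtot = m0
            repx = 0.0
            repy = 0.0
            bi = int((pos[i, 0] + half) / bs)
            bj = int((pos[i, 1] + half) / bs)
            for dbi in range(-1, 2):
                ci = bi + dbi
                if ci < 0 or ci >= nb:
                    continue
                for dbj in range(-1, 2):
                    cj = bj + dbj
                    if cj < 0 or cj >= nb:
                        continue
                    jcell = head[ci * nb + cj]
                    while jcell >= 0:
                        if jcell != i:
                            dx = pos[i, 0] - pos[jcell, 0]
                            dy = pos[i, 1] - pos[jcell, 1]
                            d = math.sqrt(dx * dx + dy * dy)
                            if d < 1e-6:
                                # coincident: deterministic jitter direction
                                ang = 6.2831853 * abs(math.sin(
                                    i * 12.9898 + jcell * 78.233))
                                dx = 1e-3 * math.cos(ang)
                                dy = 1e-3 * math.sin(ang)
                                d = 1e-3
                            if phen[jcell] != 2:
                                sig = m0 * math.exp(-lam_att * d / R)
                                if sig >= thresh:
                                    zx += sig * dx / d
                                    zy += sig * dy / d
                                    mtot += sig
                            h = radius[i] + radius[jcell] - d
                            if h > 0.0:
                                em = Et if phen[jcell] == 2 else Ec
                                rm = 0.5 * (radius[i] + radius[jcell])
                                mij = (HERTZ_PREFACTOR * em / np.pi
                                       * (h / rm) ** 2.5)
                                mtot -= mij
                                repx += mij * dx / d
                                repy += mij * dy / d
                        jcell = nxt[jcell]
            msens[i] = mtot
            nz = math.sqrt(zx * zx + zy * zy)
            if nz > 1e-14:
                zx /= nz
                zy /= nz
            else:
                zx = 0.0
                zy = 0.0
            msig = mtot if mtot > 0.0 else 0.0
            vx = alpha * (msig * zx + repx)
            vy = alpha * (msig * zy + repy)
            ddx = vx * dt
            ddy = vy * dt
            dn = math.sqrt(ddx * ddx + ddy * ddy)
            if dn > cap:
                ddx *= cap / dn
                ddy *= cap / dn
            ddx += eta * sq_dt * np.random.normal()
            ddy += eta * sq_dt * np.random.normal()
            newx[i] = pos[i, 0] + ddx
            newy[i] = pos[i, 1] + ddy

        # ---- T-lymphocyte positions -------------------------------------
        pref = gam_c / (2.0 * np.pi * Dc)
        for i in range(n_total):
            if not alive[i] or phen[i] != 2:
                continue
            gx = 0.0
            gy = 0.0
            for jcell in range(n_total):
                if alive[jcell] and phen[jcell] == 1:
                    dx = pos[i, 0] - pos[jcell, 0]
                    dy = pos[i, 1] - pos[jcell, 1]
                    d2 = dx * dx + dy * dy
                    if d2 < exclR * exclR:
                        d2 = exclR * exclR
                    gx -= pref * dx / d2
                    gy -= pref * dy / d2
            nx = eta * sq_dt * np.random.normal()
            ny = eta * sq_dt * np.random.normal()
            corex = beta_c * gx * dt + nx
            corey = beta_c * gy * dt + ny
            r = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2)
            if R1 < r < R2:
                theta = math.atan2(pos[i, 1], pos[i, 0])
                if theta < 0.0:
                    theta += 2.0 * np.pi
                j = int(theta * nsub / (2.0 * np.pi))
                if j >= nsub:
                    j = nsub - 1
                s = R2 - r
                if s > R2 - R1:
                    s = R2 - R1
                w1x = pos[i, 0] / r
                w1y = pos[i, 1] / r
                ev_rad = v0 * math.exp(-kk[j] * s) * lam1
                ev_tan = v0 * lam2[j]
                crad = corex * w1x + corey * w1y
                ctan = -corex * w1y + corey * w1x
                corex = mu_j * (ev_rad * crad * w1x - ev_tan * ctan * w1y)
                corey = mu_j * (ev_rad * crad * w1y + ev_tan * ctan * w1x)
            # contact repulsion (no α for T-cells; they are stiff)
            repx = 0.0
            repy = 0.0
            bi = int((pos[i, 0] + half) / bs)
            bj = int((pos[i, 1] + half) / bs)
            for dbi in range(-1, 2):
                ci = bi + dbi
                if ci < 0 or ci >= nb:
                    continue
                for dbj in range(-1, 2):
                    cj = bj + dbj
                    if cj < 0 or cj >= nb:
                        continue
                    jcell = head[ci * nb + cj]
                    while jcell >= 0:
                        if jcell != i:
                            dx = pos[i, 0] - pos[jcell, 0]
                            dy = pos[i, 1] - pos[jcell, 1]
                            d = math.sqrt(dx * dx + dy * dy)
                            if d < 1e-6:
                                d = 1e-6
                            h = radius[i] + radius[jcell] - d
                            if h > 0.0:
                                rm = 0.5 * (radius[i] + radius[jcell])
                                mij = (HERTZ_PREFACTOR * Et / np.pi
                                       * (h / rm) ** 2.5)
                                repx += mij * dx / d
                                repy += mij * dy / d
                        jcell = nxt[jcell]
            ddx = corex + repx * dt
            ddy = corey + repy * dt
            dn = math.sqrt(ddx * ddx + ddy * ddy)
            if dn > cap + 3.0 * eta * sq_dt:
                sc = (cap + 3.0 * eta * sq_dt) / dn
                ddx *= sc
                ddy *= sc
            newx[i] = pos[i, 0] + ddx
            newy[i] = pos[i, 1] + ddy

        # ---- apply moves, reflect at the domain boundary ----------------
        for i in range(n_total):
            if not alive[i]:
                continue
            x = newx[i]
            y = newy[i]
            rr = math.sqrt(x * x + y * y)
            # the stiff stromal ring encapsulates the islet: epithelial and
            # cancer cells reflect at R1, everything reflects at the domain
            if confine and phen[i] != 2:
                rmaxi = R1 - radius[i]
            else:
                rmaxi = dom - radius[i]
            if rr > rmaxi and rr > 0.0:
                scale = (2.0 * rmaxi - rr) / rr
                if scale < 0.0:
                    scale = 0.0
                x *= scale
                y *= scale
            dispx = x - pos[i, 0]
            dispy = y - pos[i, 1]
            if dispx * dispx + dispy * dispy > (0.5 * R) ** 2:
                abort = 1.0
            pos[i, 0] = x
            pos[i, 1] = y
        if abort > 0.0:
            marks[5] = abort
            break

        # ---- fate events -------------------------------------------------
        _build_grid(pos, alive, n_total, half, bs, nb, head, nxt)
        born_start = n_total

        if not initiated:
            if np.random.random() <= -math.expm1(-trig_rate * dt):
                # choose a random live epithelial cell
                pick = int(np.random.random() * n_epi)
                cnt = 0
                for i in range(n_total):
                    if alive[i] and phen[i] == 0:
                        if cnt == pick:
                            phen[i] = 1
                            n_epi -= 1
                            n_canc += 1
                            initiated = True
                            t_first = t_next
                            if ev_n < events.shape[0]:
                                events[ev_n, 0] = t_next
                                events[ev_n, 1] = i
                                events[ev_n, 2] = 0.0
                                events[ev_n, 3] = pos[i, 0]
                                events[ev_n, 4] = pos[i, 1]
                                ev_n += 1
                            break
                        cnt += 1
                # immune response: seed T-lymphocytes outside the stroma
                if initiated:
                    for q in range(n_tcells):
                        if n_total >= nmax:
                            break
                        rr = math.sqrt(tc_rmin ** 2 + np.random.random()
                                       * (tc_rmax ** 2 - tc_rmin ** 2))
                        ang = 2.0 * np.pi * np.random.random()
                        i = n_total
                        pos[i, 0] = rr * math.cos(ang)
                        pos[i, 1] = rr * math.sin(ang)
                        phen[i] = 2
                        alive[i] = True
                        birth[i] = t_next
                        radius[i] = Rt
                        n_total += 1
                        n_tc += 1
        else:
            p_death = -math.expm1(-death_rate * dt)
            p_kill = -math.expm1(-kill_rate * dt)
            for i in range(n_total):
                if not alive[i]:
                    continue
                if phen[i] == 0:
                    lam = mut_rate
                    if drug_on and lam > 0.0:
                        dxs = pos[i, 0] - drug_x
                        dys = pos[i, 1] - drug_y
                        cd = _injected_concentration(
                            math.sqrt(dxs * dxs + dys * dys), t, t2, t3,
                            gamma0, Ddrug, exclR)
                        lam *= math.exp(-A * cd)
                    if lam > 0.0 and np.random.random() <= -math.expm1(-lam * dt):
                        phen[i] = 1
                        n_epi -= 1
                        n_canc += 1
                        if ev_n < events.shape[0]:
                            events[ev_n, 0] = t_next
                            events[ev_n, 1] = i
                            events[ev_n, 2] = 0.0
                            events[ev_n, 3] = pos[i, 0]
                            events[ev_n, 4] = pos[i, 1]
                            ev_n += 1
                elif phen[i] == 1 and i < born_start:
                    lam = div_rate
                    if drug_on:
                        dxs = pos[i, 0] - drug_x
                        dys = pos[i, 1] - drug_y
                        cd = _injected_concentration(
                            math.sqrt(dxs * dxs + dys * dys), t, t2, t3,
                            gamma0, Ddrug, exclR)
                        lam *= math.exp(-A * cd)
                    if np.random.random() <= -math.expm1(-lam * dt):
                        if mdiv_lo <= msens[i] <= mdiv_hi and n_total < nmax:
                            # tangent placement, up to 8 resamples
                            for _try in range(8):
                                ang = 2.0 * np.pi * np.random.random()
                                px = pos[i, 0] + 2.0 * radius[i] * math.cos(ang)
                                py = pos[i, 1] + 2.0 * radius[i] * math.sin(ang)
                                rlim = (R1 - radius[i]) if confine \
                                    else (dom - radius[i])
                                if px * px + py * py > rlim * rlim:
                                    continue
                                ok = True
                                cbi = int((px + half) / bs)
                                cbj = int((py + half) / bs)
                                for dbi in range(-1, 2):
                                    ci = cbi + dbi
                                    if ci < 0 or ci >= nb:
                                        continue
                                    for dbj in range(-1, 2):
                                        cj = cbj + dbj
                                        if cj < 0 or cj >= nb:
                                            continue
                                        jc = head[ci * nb + cj]
                                        while jc >= 0:
                                            if jc != i and alive[jc]:
                                                dx = px - pos[jc, 0]
                                                dy = py - pos[jc, 1]
                                                d = math.sqrt(dx * dx + dy * dy)
                                                if (radius[jc] + radius[i] - d
                                                        > slack * radius[i]):
                                                    ok = False
                                            jc = nxt[jc]
                                        if not ok:
                                            break
                                    if not ok:
                                        break
                                if ok:
                                    # check cells born earlier this step
                                    for jb in range(born_start, n_total):
                                        dx = px - pos[jb, 0]
                                        dy = py - pos[jb, 1]
                                        d = math.sqrt(dx * dx + dy * dy)
                                        if (radius[jb] + radius[i] - d
                                                > slack * radius[i]):
                                            ok = False
                                            break
                                if ok:
                                    inew = n_total
                                    pos[inew, 0] = px
                                    pos[inew, 1] = py
                                    phen[inew] = 1
                                    alive[inew] = True
                                    birth[inew] = t_next
                                    radius[inew] = radius[i]
                                    n_total += 1
                                    n_canc += 1
                                    if ev_n < events.shape[0]:
                                        events[ev_n, 0] = t_next
                                        events[ev_n, 1] = inew
                                        events[ev_n, 2] = 1.0
                                        events[ev_n, 3] = px
                                        events[ev_n, 4] = py
                                        ev_n += 1
                                    break
                    if alive[i] and np.random.random() <= p_death:
                        alive[i] = False
                        n_canc -= 1
                        if ev_n < events.shape[0]:
                            events[ev_n, 0] = t_next
                            events[ev_n, 1] = i
                            events[ev_n, 2] = 2.0
                            events[ev_n, 3] = pos[i, 0]
                            events[ev_n, 4] = pos[i, 1]
                            ev_n += 1
                elif phen[i] == 2 and kill_on:
                    # engulf one impinging cancer cell at the kill rate
                    bi = int((pos[i, 0] + half) / bs)
                    bj = int((pos[i, 1] + half) / bs)
                    done = False
                    for dbi in range(-1, 2):
                        if done:
                            break
                        ci = bi + dbi
                        if ci < 0 or ci >= nb:
                            continue
                        for dbj in range(-1, 2):
                            if done:
                                break
                            cj = bj + dbj
                            if cj < 0 or cj >= nb:
                                continue
                            jc = head[ci * nb + cj]
                            while jc >= 0 and not done:
                                if (jc != i and alive[jc] and phen[jc] == 1):
                                    dx = pos[i, 0] - pos[jc, 0]
                                    dy = pos[i, 1] - pos[jc, 1]
                                    d = math.sqrt(dx * dx + dy * dy)
                                    if d < radius[i] + radius[jc]:
                                        if np.random.random() <= p_kill:
                                            alive[jc] = False
                                            n_canc -= 1
                                            if ev_n < events.shape[0]:
                                                events[ev_n, 0] = t_next
                                                events[ev_n, 1] = jc
                                                events[ev_n, 2] = 3.0
                                                events[ev_n, 3] = pos[jc, 0]
                                                events[ev_n, 4] = pos[jc, 1]
                                                ev_n += 1
                                            done = True
                                jc = nxt[jc]

        # ---- therapy trigger --------------------------------------------
        f = 0.0
        if n_epi + n_canc > 0:
            f = n_canc / (n_epi + n_canc)
        if scenario >= 1 and not triggered and f > trig_frac:
            triggered = True
            t0 = t_next
            t1 = t0 + enz_dur
            if scenario == 2:
                t2 = t0 + drug_lag
                t3 = t2 + drug_dur

        # ---- record -------------------------------------------------------
        ts[step + 1, 0] = t_next
        ts[step + 1, 1] = n_epi
        ts[step + 1, 2] = n_canc
        ts[step + 1, 3] = n_tc
        ts[step + 1, 4] = f
        if (step + 1) % snap_stride == 0 and snap_i < lam2_hist.shape[0]:
            for j in range(nsub):
                lam2_hist[snap_i, j] = lam2[j]
                k_hist[snap_i, j] = kk[j]
            if store_cells:
                for i in range(nmax):
                    snap_cells[snap_i, i, 0] = pos[i, 0]
                    snap_cells[snap_i, i, 1] = pos[i, 1]
                    snap_cells[snap_i, i, 2] = (phen[i]
                                                if (i < n_total and alive[i])
                                                else -1.0)
            snap_i += 1

    marks[0] = t_first
    marks[1] = t0
    marks[2] = t1
    marks[3] = t2
    marks[4] = t3
    marks[6] = n_total
    marks[7] = ev_n
    marks[8] = snap_i


def _pack_params(cfg: SimulationConfig) -> np.ndarray:
    par = np.zeros(52)
    par[0] = cfg.dt
    par[1] = cfg.t_end
    par[2] = cfg.cell_radius
    par[3] = cfg.tcell_radius
    par[4] = cfg.islet_inner_radius
    par[5] = cfg.islet_outer_radius
    par[6] = cfg.domain_radius
    par[7] = cfg.force
    par[8] = cfg.substrate_modulus
    par[9] = cfg.cell_modulus
    par[10] = cfg.tcell_modulus
    par[11] = cfg.mobility_coeff
    par[12] = cfg.friction_coeff
    par[13] = cfg.eta
    par[14] = cfg.signal_threshold
    par[15] = cfg.max_det_step
    par[16] = cfg.chemokine_diffusivity
    par[17] = cfg.secretion_rate
    par[18] = cfg.chemotactic_coeff
    par[19] = cfg.chemotactic_mobility
    par[20] = cfg.lambda1
    par[21] = cfg.v0
    par[22] = cfg.ecm_decay_rate
    par[23] = cfg.mutation_trigger_rate
    par[24] = cfg.mutation_rate
    par[25] = cfg.division_rate
    par[26] = cfg.death_rate
    par[27] = cfg.kill_rate
    par[28] = cfg.drug_sensitivity
    par[29] = cfg.division_signal_min
    par[30] = cfg.division_signal_max
    par[31] = cfg.injection_rate_gamma0
    par[32] = cfg.enzyme_diffusivity
    par[33] = cfg.drug_diffusivity
    par[34], par[35] = cfg.enzyme_site()
    par[36], par[37] = cfg.drug_site()
    par[38] = cfg.trigger_fraction
    par[39] = cfg.enzyme_duration
    par[40] = cfg.drug_lag
    par[41] = cfg.drug_duration
    par[42] = {"none": 0, "pegph20": 1, "combo": 2}[cfg.scenario]
    par[43] = cfg.n_tcells
    par[44] = cfg.cell_radius          # exclusion radius for point sources
    par[45] = cfg.placement_slack
    par[46] = max(int(round(cfg.snapshot_every / cfg.dt)), 1)
    par[47] = cfg.islet_outer_radius + cfg.tcell_radius
    par[48] = cfg.domain_radius - 2.0 * cfg.tcell_radius
    par[49] = 1.0 if cfg.kill_on_contact else 0.0
    par[50] = 1.0 if cfg.confine_islet else 0.0
    return par


def initial_layout(cfg: SimulationConfig) -> np.ndarray:
    """Jittered hexagonal packing of the epithelium inside the islet.

    Builds a hexagonal lattice whose spacing fits ``n_epithelial`` cells
    into the disk of radius R1 − R, applies a small uniform jitter, and
    returns the ``n_epithelial`` positions closest to the centre.
    """
    if cfg.initial_positions is not None:
        return np.asarray(cfg.initial_positions, dtype=float).reshape(-1, 2)
    rng = np.random.default_rng((cfg.seed * 2654435761 + 97) % (2 ** 31))
    n = cfg.n_epithelial
    rmax = cfg.islet_inner_radius - cfg.cell_radius
    a = rmax * math.sqrt(2.0 * math.pi / (math.sqrt(3.0) * n))
    pts = []
    nrows = int(2 * rmax / (a * math.sqrt(3) / 2)) + 3
    for row in range(-nrows, nrows + 1):
        y = row * a * math.sqrt(3) / 2
        x0 = 0.5 * a if row % 2 else 0.0
        ncols = int(2 * rmax / a) + 3
        for col in range(-ncols, ncols + 1):
            x = x0 + col * a
            pts.append((x, y))
    pts = np.array(pts)
    pts += rng.uniform(-0.15 * a, 0.15 * a, size=pts.shape)
    r = np.linalg.norm(pts, axis=1)
    order = np.argsort(r)
    sel = pts[order[:n]]
    if np.any(np.linalg.norm(sel, axis=1) > rmax + 0.5 * a):
        raise RuntimeError("initial layout does not fit inside the islet")
    return sel


def run_simulation(cfg: SimulationConfig) -> Trajectory:
    """Run one simulation and return its trajectory.

    Deterministic: identical config (including seed) gives identical output.
    """
    nsteps = int(round(cfg.t_end / cfg.dt))
    nsub = cfg.n_subdomains
    nmax = cfg.max_cells

    pos = np.zeros((nmax, 2))
    phen = np.zeros(nmax, dtype=np.int64)
    alive = np.zeros(nmax, dtype=np.bool_)
    birth = np.zeros(nmax)
    radius = np.zeros(nmax)

    layout = initial_layout(cfg)
    n0 = layout.shape[0]
    pos[:n0] = layout
    alive[:n0] = True
    radius[:n0] = cfg.cell_radius

    par = _pack_params(cfg)
    lam2 = np.full(nsub, float(cfg.lambda2_init))
    kk = np.full(nsub, float(cfg.k_init))
    mids = subdomain_midpoints(cfg.islet_inner_radius,
                               cfg.islet_outer_radius, nsub)

    snap_stride = int(par[46])
    n_snaps = nsteps // snap_stride + 1
    ts = np.zeros((nsteps + 1, 5))
    lam2_hist = np.zeros((n_snaps, nsub))
    k_hist = np.zeros((n_snaps, nsub))
    if cfg.store_cells:
        snap_cells = np.zeros((n_snaps, nmax, 3))
    else:
        snap_cells = np.zeros((1, 1, 3))
    events = np.zeros((_EVCAP, 5))
    marks = np.zeros(9)

    _advance(cfg.seed % (2 ** 31), pos, phen, alive, birth, radius, n0, par,
             lam2, kk, mids, ts, lam2_hist, k_hist, snap_cells, events,
             marks, cfg.store_cells)

    if marks[5] > 0.0:
        raise RuntimeError(
            "simulation aborted: a cell moved more than one radius in a "
            "single step, violating the stability bound dt <= R/(2 max|v|)")

    n_total = int(marks[6])
    ev_n = int(marks[7])
    snap_n = int(marks[8])

    tsdf = pd.DataFrame(ts, columns=["time_h", "n_epithelial", "n_cancer",
                                     "n_tcell", "f"])
    evdf = pd.DataFrame(events[:ev_n],
                        columns=["time_h", "cell_id", "event", "x_um", "y_um"])
    evdf["cell_id"] = evdf["cell_id"].astype(int)
    evdf["event"] = [_EV_NAMES[int(c)] for c in evdf["event"]]

    snap_times = np.arange(snap_n) * snap_stride * cfg.dt
    lamdf = pd.DataFrame(lam2_hist[:snap_n],
                         columns=[f"lambda2_{j+1}" for j in range(nsub)])
    lamdf.insert(0, "time_h", snap_times)
    kdf = pd.DataFrame(k_hist[:snap_n],
                       columns=[f"k_{j+1}" for j in range(nsub)])
    kdf.insert(0, "time_h", snap_times)

    snapdf = None
    if cfg.store_cells:
        rows = []
        for si in range(snap_n):
            for i in range(n_total):
                p = snap_cells[si, i, 2]
                if p >= 0:
                    rows.append((snap_times[si], i,
                                 ("epithelial", "cancer", "tlymphocyte")[int(p)],
                                 snap_cells[si, i, 0], snap_cells[si, i, 1]))
        snapdf = pd.DataFrame(rows, columns=["time_h", "cell_id", "phenotype",
                                             "x_um", "y_um"])

    live = alive[:n_total]
    finaldf = pd.DataFrame({
        "cell_id": np.arange(n_total)[live],
        "phenotype": [("epithelial", "cancer", "tlymphocyte")[int(p)]
                      for p in phen[:n_total][live]],
        "x_um": pos[:n_total, 0][live],
        "y_um": pos[:n_total, 1][live],
        "birth_time_h": birth[:n_total][live],
    })

    n_e = int(ts[-1, 1])
    n_c = int(ts[-1, 2])
    summary = {
        "seed": cfg.seed,
        "scenario": cfg.scenario,
        "t_end_h": cfg.t_end,
        "n_epithelial_final": n_e,
        "n_cancer_final": n_c,
        "n_tcell_final": int(ts[-1, 3]),
        "f_c": float(ts[-1, 4]),
        "t_first_mutation_h": float(marks[0]),
        "t0_h": float(marks[1]),
        "t1_h": float(marks[2]),
        "t2_h": float(marks[3]),
        "t3_h": float(marks[4]),
        "lambda2_final": [float(v) for v in lam2],
        "k_final": [float(v) for v in kk],
        "config": cfg.model_dump(),
    }
    return Trajectory(timeseries=tsdf, events=evdf, lambda2_history=lamdf,
                      k_history=kdf, summary=summary, snapshots=snapdf,
                      final_cells=finaldf)


# ---------------------------------------------------------------------------
# single-step reference implementations (numpy, used for verification)
# ---------------------------------------------------------------------------

def step_epithelial_cancer(pos, radius, cfg: SimulationConfig, dt: float,
                           noise=None, tcell_mask=None):
    """One Euler–Maruyama step for epithelial/cancer cells (reference).

    ``pos`` is (n, 2); ``tcell_mask`` marks rows that are T-lymphocytes
    (obstacles only). ``noise`` is an (n, 2) array of standard-normal draws
    (zeros when omitted). Returns the new positions of the non-T rows.
    """
    pos = np.asarray(pos, dtype=float)
    radius = np.asarray(radius, dtype=float)
    n = pos.shape[0]
    if tcell_mask is None:
        tcell_mask = np.zeros(n, dtype=bool)
    if noise is None:
        noise = np.zeros((n, 2))
    lam = cfg.substrate_modulus / cfg.cell_modulus
    R = cfg.cell_radius
    m0 = cfg.force ** 2 / (2 * np.pi ** 2 * cfg.substrate_modulus * R ** 4)
    alpha = cfg.mobility_coeff * R ** 3 / (cfg.friction_coeff * cfg.force)
    out = pos.copy()
    for i in range(n):
        if tcell_mask[i]:
            continue
        z = np.zeros(2)
        mtot = m0
        rep = np.zeros(2)
        for j in range(n):
            if j == i:
                continue
            diff = pos[i] - pos[j]
            d = float(np.linalg.norm(diff))
            if d < 1e-6:
                d = 1e-6
            if not tcell_mask[j]:
                sig = m0 * math.exp(-lam * d / R)
                if sig >= cfg.signal_threshold:
                    z += sig * diff / d
                    mtot += sig
            h = radius[i] + radius[j] - d
            if h > 0:
                em = cfg.tcell_modulus if tcell_mask[j] else cfg.cell_modulus
                rm = 0.5 * (radius[i] + radius[j])
                mij = HERTZ_PREFACTOR * em / np.pi * (h / rm) ** 2.5
                mtot -= mij
                rep += mij * diff / d
        nz = float(np.linalg.norm(z))
        zhat = z / nz if nz > 1e-14 else np.zeros(2)
        msig = max(mtot, 0.0)
        disp = alpha * (msig * zhat + rep) * dt
        dn = float(np.linalg.norm(disp))
        if dn > cfg.max_det_step:
            disp *= cfg.max_det_step / dn
        out[i] = pos[i] + disp + cfg.eta * math.sqrt(dt) * noise[i]
    return out


def step_tcells(tpos, cancer_pos, obstacles, obstacle_radii,
                annulus: EcmAnnulus, cfg: SimulationConfig, dt: float,
                noise=None):
    """One displacement step for T-lymphocytes (reference implementation).

    Chemotactic drift up the chemokine gradient plus random walk; inside
    the stromal annulus the drift+noise is premultiplied by μ_j Ψ of the
    cell's subdomain; Hertz contact repulsion is added unweighted.
    """
    tpos = np.asarray(tpos, dtype=float)
    nT = tpos.shape[0]
    if noise is None:
        noise = np.zeros((nT, 2))
    fieldspec = ChemokineField(diffusivity=cfg.chemokine_diffusivity,
                               secretion_rate=cfg.secretion_rate,
                               source_positions=np.asarray(cancer_pos, float))
    out = tpos.copy()
    from .ecm import locate_subdomain, orientation_tensor
    for i in range(nT):
        g = chemokine_gradient(tpos[i], fieldspec,
                               exclusion_radius=cfg.cell_radius)
        core = (cfg.chemotactic_coeff * g * dt
                + cfg.eta * math.sqrt(dt) * noise[i])
        j = locate_subdomain(tpos[i], annulus)
        if j is not None:
            psi = orientation_tensor(tpos[i], annulus, j)
            core = cfg.chemotactic_mobility * (psi @ core)
        rep = np.zeros(2)
        for q in range(len(obstacles)):
            diff = tpos[i] - np.asarray(obstacles[q], float)
            d = float(np.linalg.norm(diff))
            if d < 1e-6:
                continue
            h = cfg.tcell_radius + obstacle_radii[q] - d
            if h > 0:
                rm = 0.5 * (cfg.tcell_radius + obstacle_radii[q])
                mij = (HERTZ_PREFACTOR * cfg.tcell_modulus / np.pi
                       * (h / rm) ** 2.5)
                rep += mij * diff / d
        out[i] = tpos[i] + core + rep * dt
    return out


def apply_therapy_schedule(times, fractions, cfg: SimulationConfig):
    """Injection events implied by the therapy schedule for an f(t) series.

    Returns ``(events, marks)``: the enzyme (and, for the combined scenario,
    drug) injection events created when f first exceeds the trigger
    fraction, and the realised time marks {t0, t1, t2, t3}.
    """
    times = np.asarray(times, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    events: list[InjectionEvent] = []
    marks = {"t0": None, "t1": None, "t2": None, "t3": None}
    if cfg.scenario == "none":
        return events, marks
    above = np.nonzero(fractions > cfg.trigger_fraction)[0]
    if above.size == 0:
        return events, marks
    t0 = float(times[above[0]])
    t1 = t0 + cfg.enzyme_duration
    marks["t0"], marks["t1"] = t0, t1
    events.append(InjectionEvent(species=Species.ENZYME,
                                 site=cfg.enzyme_site(), t_start=t0, t_end=t1,
                                 rate=cfg.injection_rate_gamma0,
                                 diffusivity=cfg.enzyme_diffusivity))
    if cfg.scenario == "combo":
        t2 = t0 + cfg.drug_lag
        t3 = t2 + cfg.drug_duration
        marks["t2"], marks["t3"] = t2, t3
        events.append(InjectionEvent(species=Species.DRUG,
                                     site=cfg.drug_site(), t_start=t2,
                                     t_end=t3,
                                     rate=cfg.injection_rate_gamma0,
                                     diffusivity=cfg.drug_diffusivity))
    return events, marks
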