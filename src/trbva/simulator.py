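"""Photon-by-photon simulation of diffusing, interconverting FRET particles.

The model follows the standard confocal smFRET picture, reduced to radial
symmetry. Particles perform Brownian motion in the radial coordinate inside
a sphere of radius R,

    r(t+dt) = r(t) + 2 D dt / r(t) + dr,   dr ~ Normal(0, 2 D dt),

are removed when they cross r = R, and are replenished every T_new by a
Poisson number of particles whose mean and entry-radius density follow from
the radial diffusion equation with c(R) = c0 (series solution, integrated
over the sphere volume). Each particle carries a conformational state from
the basis {donor-only, FRET states..., acceptor-only}; conformational
exchange follows the rate matrix K0, and photobleaching follows Kbl scaled
by the illumination profile I(r) = exp(-2 r^2 / w0^2): the acceptor
bleaches at ka*E_s*I(r) and the donor at kd*(1-E_s)*I(r) (excitation is
shared between the dyes in proportion to the transfer efficiency).

Photon emission is Poissonian per 1-us step with mean proportional to
I(r). Under donor excitation a FRET state with apparent efficiency E emits
donor-channel photons at lambda_tot*I*(1-E) and acceptor-channel photons at
lambda_tot*I*(gamma*E + beta*(1-E)) plus direct acceptor excitation at
alpha times the acceptor-excitation rate. During acceptor-excitation
half-periods, species with an active acceptor emit acceptor-channel
photons at lambda_tot*I/gamma_PIE. Background photons are homogeneous
Poisson processes per channel, with excitation labels assigned at equal
duty cycle. All printed defaults of the study conditions are the dataclass
defaults below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
from numba import njit

from .photon_model import PhotonStream

__all__ = [
    "DiffusionConfig",
    "KineticConfig",
    "DetectionConfig",
    "step_radial_position",
    "replenishment_mean",
    "entry_radius_table",
    "sample_entry_radius",
    "simulate_state_trajectory",
    "emit_photons",
    "run_simulation",
]

AVOGADRO = 6.02214076e23
# particles per um^3 per pM: 1e-12 mol/L * N_A / 1e15 um^3/L
_PM_TO_UM3 = 1e-12 * AVOGADRO / 1e15


@dataclass
class DiffusionConfig:
    """Brownian-dynamics parameters (um, us)."""

    d: float = 5e-5          # diffusion coefficient, um^2/us
    radius: float = 3.0      # simulation-sphere radius, um
    c0_pm: float = 50.0      # bulk concentration, pM
    dt: float = 1.0          # time step, us
    t_total_s: float = 10.0  # simulated duration, s
    t_new: float = 1000.0    # replenishment period, us
    w0: float = 0.4          # Gaussian spot waist, um

    def __post_init__(self):
        if self.d <= 0 or self.dt <= 0 or self.t_new <= 0:
            raise ValueError("D, dt and T_new must be positive")
        if self.radius <= self.w0:
            raise ValueError("sphere radius must exceed the spot waist")

    @property
    def c0_um3(self) -> float:
        return self.c0_pm * _PM_TO_UM3

    @property
    def n0(self) -> float:
        """Mean initial particle count (4/3) pi R^3 c0."""
        return 4.0 / 3.0 * math.pi * self.radius ** 3 * self.c0_um3


def _two_state_k0(k12: float, k21: float) -> np.ndarray:
    return np.array([[-k12, k21], [k12, -k21]], dtype=float)


@dataclass
class KineticConfig:
    """Conformational rate matrix, state efficiencies and bleaching rates.

    ``k0`` acts on the FRET states only (columns sum to zero, rates in
    1/us); the full simulation basis is {D-only, FRET states..., A-only}.
    ``state_e`` holds the *corrected* FRET efficiency per FRET state.
    ``p0`` is the initial-state distribution over the full basis; the
    default assigns 10% donor-only, 10% acceptor-only and splits the rest
    by the equilibrium of ``k0``.
    """

    k0: np.ndarray = field(default_factory=lambda: _two_state_k0(5e-4, 5e-4))
    state_e: np.ndarray = field(default_factory=lambda: np.array([0.1, 0.9]))
    ka: float = 5e-4         # acceptor bleaching rate at r=0, 1/us
    kd: float = 5e-4         # donor bleaching rate at r=0, 1/us
    frac_donor_only: float = 0.1
    frac_acceptor_only: float = 0.1
    p0: Optional[np.ndarray] = None

    def __post_init__(self):
        self.k0 = np.asarray(self.k0, dtype=float)
        self.state_e = np.asarray(self.state_e, dtype=float)
        n = self.state_e.size
        if self.k0.shape != (n, n):
            raise ValueError("k0 must be n_states x n_states")
        if not np.allclose(self.k0.sum(axis=0), 0.0, atol=1e-12):
            raise ValueError("columns of k0 must sum to zero")
        if np.any((self.state_e < 0) | (self.state_e > 1)):
            raise ValueError("state efficiencies must lie in [0, 1]")
        if self.ka < 0 or self.kd < 0:
            raise ValueError("bleaching rates must be >= 0")
        if self.p0 is not None:
            self.p0 = np.asarray(self.p0, dtype=float)
            if self.p0.size != n + 2 or not math.isclose(self.p0.sum(), 1.0,
                                                         rel_tol=1e-9):
                raise ValueError("p0 must sum to 1 over {D, states..., A}")

    @property
    def n_fret_states(self) -> int:
        return self.state_e.size

    @property
    def p_eq(self) -> np.ndarray:
        """Equilibrium of the conformational rate matrix."""
        ns = scipy.linalg.null_space(self.k0, rcond=1e-12)
        p = np.abs(ns[:, 0])
        return p / p.sum()

    def initial_probs(self) -> np.ndarray:
        """p0 over the full basis {D, FRET states..., A}."""
        if self.p0 is not None:
            return self.p0
        bulk = 1.0 - self.frac_donor_only - self.frac_acceptor_only
        return np.concatenate([[self.frac_donor_only],
                               bulk * self.p_eq,
                               [self.frac_acceptor_only]])

    @classmethod
    def two_state(cls, k12: float, k21: float,
                  e1: float = 0.1, e2: float = 0.9, **kw) -> "KineticConfig":
        """Two FRET states exchanging at k12 (1->2) and k21 (2->1), 1/us."""
        return cls(k0=_two_state_k0(k12, k21),
                   state_e=np.array([e1, e2]), **kw)

    @classmethod
    def three_state(cls, k12: float, k21: float, k23: float, k32: float,
                    e: Sequence[float] = (0.1, 0.5, 0.9), **kw) -> "KineticConfig":
        """Linear three-state chain 1 <-> 2 <-> 3 (rates in 1/us)."""
        k0 = np.array([
            [-k12, k21, 0.0],
            [k12, -(k21 + k23), k32],
            [0.0, k23, -k32],
        ])
        return cls(k0=k0, state_e=np.asarray(e, dtype=float), **kw)


@dataclass
class DetectionConfig:
    """Photon rates and channel imperfections (printed study defaults)."""

    lambda_tot: float = 0.4        # total rate at the spot centre, 1/us
    lambda_d: float = 5.6e-3       # donor-channel background, 1/us
    lambda_a: float = 3.0e-3       # acceptor-channel background, 1/us
    gamma: float = 1.16            # gamma = Qa eta_a / (Qd eta_d)
    leakage: float = 0.054         # beta: donor photons in acceptor channel
    direct_excitation: float = 0.048  # alpha, relative to n_AA
    gamma_pie: float = 2.0

    def __post_init__(self):
        if min(self.lambda_tot, self.lambda_d, self.lambda_a) < 0:
            raise ValueError("rates must be >= 0")
        if not (0 <= self.leakage <= 1 and 0 <= self.direct_excitation <= 1):
            raise ValueError("beta and alpha must lie in [0, 1]")
        if self.gamma <= 0 or self.gamma_pie <= 0:
            raise ValueError("gamma factors must be positive")


# ---------------------------------------------------------------------------
# elementary operations


def step_radial_position(r: float, d: float, dt: float, rng) -> float:
    """One Euler step of the radial Brownian dynamics; reflects at r = 0."""
    if r <= 0:
        raise ValueError("r must be positive")
    r_new = r + 2.0 * d * dt / r + rng.normal(0.0, math.sqrt(2.0 * d * dt))
    return abs(r_new)


def replenishment_mean(n0: float, d: float, radius: float,
                       t_new: float, rtol: float = 1e-12) -> float:
    """Mean number of particles entering the sphere per period T_new.

    Volume integral of the diffusion-equation series solution:
    n_new/n0 = 1 - (6/pi^2) sum_n n^-2 exp(-D n^2 pi^2 T_new / R^2).
    (The sum tends to pi^2/6 as T_new -> 0, so n_new -> 0.)
    """
    x = d * math.pi ** 2 * t_new / radius ** 2
    total = 0.0
    n = 1
    n_cap = 20000
    while True:
        term = math.exp(-x * n * n) / (n * n)
        total += term
        if term < rtol * max(total, 1e-300):
            break
        if n >= n_cap:
            # analytic tail for very small x, where the exponential decay
            # sets in beyond the cap:
            # sum_{n>N} n^-2 e^{-x n^2} ~ int_N^inf t^-2 e^{-x t^2} dt
            total += (math.exp(-x * n_cap ** 2) / n_cap
                      - math.sqrt(math.pi * x)
                      * math.erfc(math.sqrt(x) * n_cap))
            break
        n += 1
    return n0 * max(0.0, 1.0 - 6.0 / math.pi ** 2 * total)


def entry_radius_table(d: float, radius: float, t_new: float,
                       n_grid: int = 2048):
    """Tabulated CDF of the entry-radius density P_new(r) on (0, R).

    P_new(r) is proportional to 4 pi r^2 c_new(r) with c_new the series
    solution of the radial diffusion equation evaluated at T_new.
    """
    x = d * math.pi ** 2 * t_new / radius ** 2
    n_max = max(50, int(math.ceil(math.sqrt(40.0 / max(x, 1e-12)))))
    n_max = min(n_max, 20000)
    r = np.linspace(0.0, radius, n_grid + 1)[1:]
    n = np.arange(1, n_max + 1)
    decay = np.exp(-x * n ** 2)
    # c(r)/c0 = 1 + (2R/(pi r)) sum ((-1)^n / n) sin(n pi r / R) e^{-x n^2}
    sin_terms = np.sin(np.outer(n, math.pi * r / radius))
    series = ((-1.0) ** n / n * decay) @ sin_terms
    c_rel = 1.0 + (2.0 * radius / (math.pi * r)) * series
    dens = np.clip(4.0 * math.pi * r ** 2 * c_rel, 0.0, None)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1])
                                           * np.diff(r))])
    cdf /= cdf[-1]
    return r, dens, cdf


def sample_entry_radius(d: float, radius: float, t_new: float,
                        size: int, rng, table=None) -> np.ndarray:
    """Entry radii drawn from P_new by inverse-CDF interpolation."""
    if table is None:
        table = entry_radius_table(d, radius, t_new)
    r, _, cdf = table
    u = rng.random(size)
    return np.interp(u, cdf, r)


# ---------------------------------------------------------------------------
# state-machine tables shared by the trajectory simulator and the kernel


def _state_tables(kin: KineticConfig, dt: float):
    """Per-step transition tables over the full basis {D, states..., A}.

    Conformational switching uses the exact one-step matrix exp(K0 dt)
    (embedded in the full basis with absorbing D/A states); bleaching is a
    per-step Bernoulli hazard applied on top, scaled by I(r).
    """
    nf = kin.n_fret_states
    S = nf + 2
    k_full = np.zeros((S, S))
    k_full[1:1 + nf, 1:1 + nf] = kin.k0
    P1 = scipy.linalg.expm(k_full * dt)
    P1 = np.clip(P1, 0.0, None)
    P1 /= P1.sum(axis=0, keepdims=True)
    p_leave = 1.0 - np.diag(P1)
    dest_cum = np.zeros((S, S))
    for j in range(S):
        col = P1[:, j].copy()
        col[j] = 0.0
        tot = col.sum()
        dest_cum[:, j] = np.cumsum(col / tot) if tot > 0 else 1.0
    pa = np.zeros(S)
    pd = np.zeros(S)
    for i in range(nf):
        pa[1 + i] = 1.0 - math.exp(-kin.ka * kin.state_e[i] * dt)
        pd[1 + i] = 1.0 - math.exp(-kin.kd * (1.0 - kin.state_e[i]) * dt)
    return P1, p_leave, dest_cum, pa, pd


def _emission_tables(kin: KineticConfig, det: DetectionConfig):
    """Per-state emission rates at I = 1 for the three photon classes:
    (donor ch, Dex), (acceptor ch, Dex), (acceptor ch, Aex)."""
    nf = kin.n_fret_states
    S = nf + 2
    lam = det.lambda_tot
    lam_aex = lam / det.gamma_pie
    r_ddex = np.zeros(S)
    r_adex = np.zeros(S)
    r_aaex = np.zeros(S)
    # donor-only: pure donor fluorescence plus channel leakage
    r_ddex[0] = lam
    r_adex[0] = det.leakage * lam
    for i, e in enumerate(kin.state_e):
        s = 1 + i
        r_ddex[s] = lam * (1.0 - e)
        r_adex[s] = (lam * (det.gamma * e + det.leakage * (1.0 - e))
                     + det.direct_excitation * lam_aex)
        r_aaex[s] = lam_aex
    # acceptor-only: direct excitation under Dex, full response under Aex
    r_adex[S - 1] = det.direct_excitation * lam_aex
    r_aaex[S - 1] = lam_aex
    return r_ddex, r_adex, r_aaex


@njit(cache=True)
def _geometric_steps(p: float) -> np.int64:
    """Steps until the first per-step success (support >= 1)."""
    if p <= 0.0:
        return np.int64(1) << np.int64(62)
    if p >= 1.0:
        return np.int64(1)
    u = np.random.random()
    k = np.int64(math.ceil(math.log(u) / math.log(1.0 - p)))
    return k if k > 0 else np.int64(1)


@njit(cache=True)
def _pick_dest(s: int, v: float, dest_cum) -> int:
    for i in range(dest_cum.shape[0]):
        if v <= dest_cum[i, s] and i != s:
            return i
    return s


@njit(cache=True)
def _simulate_kernel(seed, n_steps, dt, d_coef, radius, r_cut, r_far,
                     far_factor, w0,
                     t0_steps, r0, s0,
                     p_leave, dest_cum, pk_diag, dest_cum_k,
                     pa, pd,
                     r_ddex, r_adex, r_aaex,
                     bl_t, bl_p, bl_k,
                     jp_t, jp_p, jp_from, jp_to,
                     record_jumps):
    """Fused particle loop. Truth buffers (bleach/jump events) are
    preallocated by the caller; the returned counters saturate at the
    buffer size so the caller can detect overflow and retry."""
    np.random.seed(seed)
    n_part = t0_steps.shape[0]
    S = p_leave.shape[0]
    state_d = 0
    state_a = S - 1
    sig1 = math.sqrt(2.0 * d_coef * dt)
    sig_k = math.sqrt(2.0 * d_coef * dt * far_factor)
    inv_w2 = 2.0 / (w0 * w0)
    lam_tot = np.empty(S)
    for s in range(S):
        lam_tot[s] = r_ddex[s] + r_adex[s] + r_aaex[s]

    cap = 1 << 16
    ph_t = np.empty(cap)
    ph_c = np.empty(cap, dtype=np.int8)
    nph = 0
    nbl = 0
    bcap = bl_t.shape[0]
    njp = 0
    jcap = jp_t.shape[0]
    exit_step = np.empty(n_part, dtype=np.int64)

    for p in range(n_part):
        step = t0_steps[p]
        r = r0[p]
        s = s0[p]
        in_near = False
        dwell = np.int64(0)
        while step < n_steps:
            if r > r_far:
                # coarse far-field step: no photons, no bleaching out here
                r = r + 2.0 * d_coef * (dt * far_factor) / r \
                    + sig_k * np.random.normal()
                if r < 0.0:
                    r = -r
                if r >= radius:
                    break
                if pk_diag[s] < 1.0:
                    u = np.random.random()
                    if u > pk_diag[s]:
                        v = (u - pk_diag[s]) / (1.0 - pk_diag[s])
                        s_new = _pick_dest(s, v, dest_cum_k)
                        if record_jumps and s_new != s and njp < jcap:
                            jp_t[njp] = (step + far_factor) * dt
                            jp_p[njp] = p
                            jp_from[njp] = s
                            jp_to[njp] = s_new
                            njp += 1
                        s = s_new
                in_near = False
                step += far_factor
            else:
                if not in_near:
                    dwell = _geometric_steps(p_leave[s])
                    in_near = True
                if r < 1e-9:
                    r = 1e-9
                r = r + 2.0 * d_coef * dt / r + sig1 * np.random.normal()
                if r < 0.0:
                    r = -r
                if r >= radius:
                    break
                dwell -= 1
                if dwell <= 0:
                    v = np.random.random()
                    s_new = _pick_dest(s, v, dest_cum)
                    if record_jumps and s_new != s and njp < jcap:
                        jp_t[njp] = (step + 1) * dt
                        jp_p[njp] = p
                        jp_from[njp] = s
                        jp_to[njp] = s_new
                        njp += 1
                    s = s_new
                    dwell = _geometric_steps(p_leave[s])
                if r < r_cut:
                    inten = math.exp(-inv_w2 * r * r)
                    if pa[s] > 0.0 or pd[s] > 0.0:
                        u = np.random.random()
                        if u < pa[s] * inten:
                            if nbl < bcap:
                                bl_t[nbl] = (step + 1) * dt
                                bl_p[nbl] = p
                                bl_k[nbl] = 0  # acceptor bleach -> D-only
                                nbl += 1
                            s = state_d
                            dwell = _geometric_steps(p_leave[s])
                        elif u < (pa[s] + pd[s]) * inten:
                            if nbl < bcap:
                                bl_t[nbl] = (step + 1) * dt
                                bl_p[nbl] = p
                                bl_k[nbl] = 1  # donor bleach -> A-only
                                nbl += 1
                            s = state_a
                            dwell = _geometric_steps(p_leave[s])
                    lam = lam_tot[s]
                    if lam > 0.0:
                        n_emit = np.random.poisson(lam * inten * dt)
                        for _ in range(n_emit):
                            u = np.random.random() * lam
                            if u < r_ddex[s]:
                                code = 0
                            elif u < r_ddex[s] + r_adex[s]:
                                code = 1
                            else:
                                code = 2
                            if nph >= cap:
                                cap2 = cap * 2
                                c1 = np.empty(cap2)
                                c1[:cap] = ph_t
                                ph_t = c1
                                c2 = np.empty(cap2, dtype=np.int8)
                                c2[:cap] = ph_c
                                ph_c = c2
                                cap = cap2
                            ph_t[nph] = (step + np.random.random()) * dt
                            ph_c[nph] = code
                            nph += 1
                step += 1
        exit_step[p] = step if step < n_steps else n_steps

    return ph_t[:nph].copy(), ph_c[:nph].copy(), nbl, njp, exit_step


@njit(cache=True)
def _state_traj_kernel(seed, r_traj, s_init, p_leave, dest_cum, pa, pd,
                       inv_w2):
    np.random.seed(seed)
    n = r_traj.shape[0]
    S = p_leave.shape[0]
    out = np.empty(n, dtype=np.int8)
    s = s_init
    dwell = _geometric_steps(p_leave[s])
    for i in range(n):
        dwell -= 1
        if dwell <= 0:
            v = np.random.random()
            s = _pick_dest(s, v, dest_cum)
            dwell = _geometric_steps(p_leave[s])
        if pa[s] > 0.0 or pd[s] > 0.0:
            inten = math.exp(-inv_w2 * r_traj[i] * r_traj[i])
            u = np.random.random()
            if u < pa[s] * inten:
                s = 0
                dwell = _geometric_steps(p_leave[s])
            elif u < (pa[s] + pd[s]) * inten:
                s = S - 1
                dwell = _geometric_steps(p_leave[s])
        out[i] = s
    return out


def simulate_state_trajectory(r_traj: np.ndarray, t0: int,
                              kin: KineticConfig, rng,
                              diff: Optional[DiffusionConfig] = None,
                              dt: float = 1.0, w0: float = 0.4,
                              s_init: Optional[int] = None) -> np.ndarray:
    """Markov state realization along a position trajectory.

    States are indices into {D-only=0, FRET states..., A-only=n+1}.
    Conformational switching uses the exact per-step matrix exp(K0 dt);
    bleaching hazards are scaled by I(r(t)).
    """
    if diff is not None:
        dt, w0 = diff.dt, diff.w0
    r_traj = np.asarray(r_traj, dtype=float)
    if r_traj.size == 0:
        raise ValueError("empty position trajectory")
    _, p_leave, dest_cum, pa, pd = _state_tables(kin, dt)
    if s_init is None:
        p0 = kin.initial_probs()
        s_init = int(rng.choice(p0.size, p=p0))
    seed = int(rng.integers(0, 2 ** 31 - 1))
    return _state_traj_kernel(seed, r_traj, s_init, p_leave, dest_cum,
                              pa, pd, 2.0 / w0 ** 2)


def emit_photons(r_traj: np.ndarray, state_traj: np.ndarray,
                 det: DetectionConfig, kin: KineticConfig, rng,
                 dt: float = 1.0, w0: float = 0.4,
                 t0: float = 0.0,
                 include_background: bool = False) -> PhotonStream:
    """Photon stream from aligned position and state trajectories.

    Vectorised counterpart of the in-kernel emission model; used for
    clamped-particle checks and small-scale simulations.
    """
    r_traj = np.asarray(r_traj, dtype=float)
    state_traj = np.asarray(state_traj)
    if r_traj.shape != state_traj.shape:
        raise ValueError("trajectories must be aligned")
    n = r_traj.size
    r_ddex, r_adex, r_aaex = _emission_tables(kin, det)
    inten = np.exp(-2.0 * r_traj ** 2 / w0 ** 2)
    lam_tot = (r_ddex + r_adex + r_aaex)[state_traj] * inten * dt
    counts = rng.poisson(lam_tot)
    idx = np.repeat(np.arange(n), counts)
    times = (idx + rng.random(idx.size)) * dt + t0
    s_ph = state_traj[idx]
    u = rng.random(idx.size) * (r_ddex + r_adex + r_aaex)[s_ph]
    code = np.where(u < r_ddex[s_ph], 0,
                    np.where(u < (r_ddex + r_adex)[s_ph], 1, 2))
    duration_s = n * dt * 1e-6
    if include_background:
        tb, cb = _background_photons(det, n * dt, rng)
        times = np.concatenate([times, tb + t0])
        code = np.concatenate([code, cb])
    order = np.argsort(times, kind="stable")
    times, code = times[order], code[order]
    channel = np.where((code == 1) | (code == 2), 1, 0).astype(np.int8)
    excitation = np.where(code >= 2, 1, 0).astype(np.int8)
    return PhotonStream(times, channel, excitation, duration_s + t0 * 1e-6,
                        metadata={"source": "emit_photons"})


def _background_photons(det: DetectionConfig, t_total_us: float, rng):
    """Homogeneous Poisson background per channel; excitation labels are
    assigned with equal duty cycle. Codes: 0 D/Dex, 1 A/Dex, 2 A/Aex,
    3 D/Aex."""
    nd = rng.poisson(det.lambda_d * t_total_us)
    na = rng.poisson(det.lambda_a * t_total_us)
    td = rng.random(nd) * t_total_us
    ta = rng.random(na) * t_total_us
    exd = rng.integers(0, 2, nd)
    exa = rng.integers(0, 2, na)
    codes_d = np.where(exd == 0, 0, 3).astype(np.int8)
    codes_a = np.where(exa == 0, 1, 2).astype(np.int8)
    return np.concatenate([td, ta]), np.concatenate([codes_d, codes_a])


def run_simulation(diff: DiffusionConfig, kin: KineticConfig,
                   det: DetectionConfig, seed: int = 0,
                   store_truth: bool = False,
                   far_field_factor: int = 16,
                   r_cut: Optional[float] = None) -> PhotonStream:
    """Full multi-particle simulation -> time-sorted photon stream.

    The initial particle count is Poisson with mean n0 = (4/3) pi R^3 c0;
    every T_new a Poisson number of new particles (mean from
    :func:`replenishment_mean`) enters at radii drawn from P_new; particles
    are removed on crossing r = R. Ground truth (bleaching events; particle
    entry/exit and conformational jump times when ``store_truth``) is kept
    in the stream metadata. Bit-reproducible for a given seed.
    """
    ss = np.random.SeedSequence(seed)
    rng_sched, = [np.random.default_rng(s) for s in ss.spawn(1)]
    kernel_seed = int(rng_sched.integers(0, 2 ** 31 - 1))
    bg_rng = np.random.default_rng(ss.spawn(1)[0])

    dt = diff.dt
    n_steps = int(round(diff.t_total_s * 1e6 / dt))
    # initial particles, uniform in the sphere
    n_init = rng_sched.poisson(diff.n0)
    r_init = diff.radius * rng_sched.random(n_init) ** (1.0 / 3.0)
    t0_init = np.zeros(n_init, dtype=np.int64)
    # replenishment schedule
    n_new = replenishment_mean(diff.n0, diff.d, diff.radius, diff.t_new)
    table = entry_radius_table(diff.d, diff.radius, diff.t_new)
    rep_steps = np.arange(diff.t_new, n_steps * dt, diff.t_new)
    counts = rng_sched.poisson(n_new, rep_steps.size)
    t0_rep = np.repeat((rep_steps / dt).astype(np.int64), counts)
    r_rep = sample_entry_radius(diff.d, diff.radius, diff.t_new,
                                t0_rep.size, rng_sched, table)
    t0_all = np.concatenate([t0_init, t0_rep])
    r_all = np.concatenate([r_init, r_rep])
    p0 = kin.initial_probs()
    s_all = rng_sched.choice(p0.size, size=t0_all.size, p=p0).astype(np.int8)

    P1, p_leave, dest_cum, pa, pd = _state_tables(kin, dt)
    far = max(1, int(far_field_factor))
    nf = kin.n_fret_states
    k_full = np.zeros((nf + 2, nf + 2))
    k_full[1:1 + nf, 1:1 + nf] = kin.k0
    PK = scipy.linalg.expm(k_full * dt * far)
    PK = np.clip(PK, 0.0, None)
    PK /= PK.sum(axis=0, keepdims=True)
    pk_diag = np.diag(PK).copy()
    dest_cum_k = np.zeros_like(PK)
    for j in range(PK.shape[0]):
        col = PK[:, j].copy()
        col[j] = 0.0
        tot = col.sum()
        dest_cum_k[:, j] = np.cumsum(col / tot) if tot > 0 else 1.0
    r_ddex, r_adex, r_aaex = _emission_tables(kin, det)
    if r_cut is None:
        # I(r_cut) = 1e-6: the neglected emission rate beyond r_cut is
        # ~4 orders of magnitude below the detector background
        r_cut = diff.w0 * math.sqrt(0.5 * math.log(1e6))
    # margin >> far-step displacement sqrt(2 D dt far) so a coarse step
    # cannot jump from the dark zone into the emitting zone
    r_far = min(r_cut + 0.3, 0.9 * diff.radius)

    bcap = 4096 + n_steps // 10000
    bl_t = np.empty(bcap)
    bl_p = np.empty(bcap, dtype=np.int64)
    bl_k = np.empty(bcap, dtype=np.int8)
    jcap = 1
    if store_truth:
        # bound: every particle-step could jump at the fastest printed rates
        jcap = int(min(2e7, 64 + 4.0 * n_steps * max(diff.n0, 1.0)
                       * min(1.0, -np.min(np.diag(kin.k0)) * dt)))
    jp_t = np.empty(jcap)
    jp_p = np.empty(jcap, dtype=np.int64)
    jp_from = np.empty(jcap, dtype=np.int8)
    jp_to = np.empty(jcap, dtype=np.int8)

    ph_t, ph_c, nbl, njp, exit_step = _simulate_kernel(
        kernel_seed, n_steps, dt, diff.d, diff.radius, r_cut, r_far,
        far, diff.w0,
        t0_all, r_all, s_all,
        p_leave, dest_cum, pk_diag, dest_cum_k, pa, pd,
        r_ddex, r_adex, r_aaex,
        bl_t, bl_p, bl_k, jp_t, jp_p, jp_from, jp_to,
        store_truth)
    bl_t, bl_p, bl_k = bl_t[:nbl], bl_p[:nbl], bl_k[:nbl]
    jp_t, jp_p = jp_t[:njp], jp_p[:njp]
    jp_from, jp_to = jp_from[:njp], jp_to[:njp]

    tb, cb = _background_photons(det, n_steps * dt, bg_rng)
    times = np.concatenate([ph_t, tb])
    codes = np.concatenate([ph_c, cb])
    order = np.argsort(times, kind="stable")
    times, codes = times[order], codes[order]
    channel = np.where((codes == 1) | (codes == 2), 1, 0).astype(np.int8)
    excitation = np.where(codes >= 2, 1, 0).astype(np.int8)

    metadata = {
        "simulation": {
            "diffusion": asdict(diff),
            "detection": asdict(det),
            "kinetics": {
                "k0_per_us": kin.k0.tolist(),
                "state_e": kin.state_e.tolist(),
                "ka": kin.ka, "kd": kin.kd,
                "p0": kin.initial_probs().tolist(),
            },
            "seed": seed,
            "n_particles": int(t0_all.size),
            "n_signal_photons": int(ph_t.size),
            "n_background_photons": int(tb.size),
            "n_new_per_period": n_new,
        },
        "truth": {
            "bleach_times_us": bl_t.tolist(),
            "bleach_particle": bl_p.tolist(),
            "bleach_kind": bl_k.tolist(),  # 0 acceptor, 1 donor
        },
    }
    if store_truth:
        metadata["truth"].update({
            "entry_step": t0_all.tolist(),
            "exit_step": exit_step.tolist(),
            "entry_radius": r_all.tolist(),
            "initial_state": s_all.tolist(),
            "jump_times_us": jp_t.tolist(),
            "jump_particle": jp_p.tolist(),
            "jump_from": jp_from.tolist(),
            "jump_to": jp_to.tolist(),
        })
    return PhotonStream(times, channel, excitation, diff.t_total_s, metadata)
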