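"""Jump-model geometry, exchange superoperator and stochastic-Liouville propagation.

The composite space is ordered **site-major**: the state vector concatenates
the row-major vectorized density operators of the sites,
``[vec(rho_a), vec(rho_b), ...]``, so the exchange superoperator is literally
``K (x) 1_{d^2}`` and the coherent part is block-diagonal.  The equation of
motion is

    d/dt |rho>> = Gamma(t) |rho>>,   Gamma(t) = blockdiag(-i L_s(t)) + K (x) 1

with ``L_s`` the commutation superoperator of site ``s``'s Hamiltonian.
``Gamma`` is periodic in the rotor period (or a small multiple of it for
phase-cycled sequences), so the propagator over one period is computed once
per crystallite — piecewise-constant steps, midpoint-sampled, exponentiated
with scaling-and-squaring — and reused for all later periods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .spinops import commutation_superop, sandwich_superop
from .tensors import (Rank2Tensor, RotorSpec, euler_compose,
                      mas_fourier_components, rotate_components,
                      spherical_components)

__all__ = [
    "JumpModel", "Trajectory", "CompositePropagator",
    "three_site_cone", "nine_site", "single_site",
    "exchange_superoperator", "build_composite_generator",
    "averaged_tensor_components", "averaged_delta",
    "Segment", "Pulse", "PeriodEngine",
    "propagate", "powder_trajectory",
    "monte_carlo_free_evolution",
]


# ---------------------------------------------------------------------------
# Jump models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JumpModel:
    """A set of site orientations with populations and exchange generator.

    ``site_eulers`` orient the interaction frame of each site in the
    crystallite (molecular) frame; ``rate_matrix`` is the kinetic generator
    ``K`` (s^-1) acting on site populations, ``dp/dt = K p``.
    """

    site_eulers: tuple
    populations: np.ndarray = field(repr=False)
    rate_matrix: np.ndarray = field(repr=False)
    label: str = ""

    def __post_init__(self):
        K = np.asarray(self.rate_matrix, dtype=float)
        p = np.asarray(self.populations, dtype=float)
        if K.shape != (self.n_sites, self.n_sites):
            raise ValueError("rate matrix shape does not match number of sites")
        if np.max(np.abs(K.sum(axis=0))) > 1e-9 * (1.0 + np.max(np.abs(K))):
            raise ValueError("columns of the exchange generator must sum to zero")
        if np.max(np.abs(K @ p)) > 1e-9 * (1.0 + np.max(np.abs(K))):
            raise ValueError("populations must be stationary under the exchange generator")

    @property
    def n_sites(self) -> int:
        return len(self.site_eulers)


def single_site() -> JumpModel:
    """Degenerate one-site model (no exchange); used for reference simulations."""
    return JumpModel(site_eulers=((0.0, 0.0, 0.0),), populations=np.array([1.0]),
                     rate_matrix=np.zeros((1, 1)), label="static")


def three_site_cone(theta_deg: float, k_ex: float) -> JumpModel:
    """Three-site jump on a cone: C3 rotation with opening angle ``theta``.

    The interaction symmetry axis is tilted by ``theta`` from the C3 axis at
    azimuths 0, 120 and 240 degrees; all pairs exchange at ``k_ex`` so the
    correlation time is ``1 / (3 k_ex)``.
    """
    if k_ex < 0:
        raise ValueError("exchange rate must be non-negative")
    th = math.radians(theta_deg)
    eulers = tuple((2.0 * math.pi * i / 3.0, th, 0.0) for i in range(3))
    K = k_ex * (np.ones((3, 3)) - 3.0 * np.eye(3))
    return JumpModel(site_eulers=eulers, populations=np.full(3, 1.0 / 3.0),
                     rate_matrix=K, label=f"three_site(theta={theta_deg},k={k_ex})")


def nine_site(theta1_deg: float, theta2_deg: float, k1: float, k2: float) -> JumpModel:
    """Nine-site model: two simultaneous three-site rotations about non-collinear C3 axes.

    The inner rotation (angle ``theta1``, rate ``k1``) exchanges the three
    sites within each subset; the outer rotation (angle ``theta2``, rate
    ``k2``) exchanges corresponding inner sites across subsets.  In the fast
    limit of both motions the averaged anisotropy is
    ``P2(cos theta1) P2(cos theta2) delta``.
    """
    if k1 < 0 or k2 < 0:
        raise ValueError("exchange rates must be non-negative")
    th1, th2 = math.radians(theta1_deg), math.radians(theta2_deg)
    eulers = []
    for o in range(3):          # outer azimuth
        outer = (2.0 * math.pi * o / 3.0, th2, 0.0)
        for i in range(3):      # inner azimuth
            inner = (2.0 * math.pi * i / 3.0, th1, 0.0)
            eulers.append(euler_compose(inner, outer))
    K = np.zeros((9, 9))
    for o in range(3):
        for i in range(3):
            a = 3 * o + i
            for i2 in range(3):
                if i2 != i:
                    K[3 * o + i2, a] += k1       # inner jumps within subset
            for o2 in range(3):
                if o2 != o:
                    K[3 * o2 + i, a] += k2       # outer jumps, matching inner index
    np.fill_diagonal(K, -K.sum(axis=0))
    return JumpModel(site_eulers=tuple(eulers), populations=np.full(9, 1.0 / 9.0),
                     rate_matrix=K,
                     label=f"nine_site(t1={theta1_deg},t2={theta2_deg},k1={k1},k2={k2})")


def averaged_tensor_components(tensor: Rank2Tensor, model: JumpModel) -> np.ndarray:
    """Population-weighted average of the site tensors (molecular-frame components)."""
    A = spherical_components(tensor.delta, tensor.eta)
    A = rotate_components(A, tensor.euler_pas_to_site)
    acc = np.zeros(5, dtype=complex)
    for p, e in zip(model.populations, model.site_eulers):
        acc += p * rotate_components(A, e)
    return acc


def averaged_delta(tensor: Rank2Tensor, model: JumpModel) -> float:
    """Anisotropy (rad/s, signed) of the fast-exchange averaged tensor.

    Valid for the shipped threefold-symmetric geometries, where the averaged
    tensor is axial about the (outermost) symmetry axis.
    """
    return averaged_tensor_components(tensor, model)[2].real / math.sqrt(1.5)


# ---------------------------------------------------------------------------
# Composite-space operators
# ---------------------------------------------------------------------------

def exchange_superoperator(model: JumpModel, hilbert_dim: int) -> np.ndarray:
    """Exchange superoperator ``K (x) 1_{d^2}`` in the site-major composite space."""
    return np.kron(model.rate_matrix, np.eye(hilbert_dim**2))


def build_composite_generator(site_hamiltonians, model: JumpModel) -> np.ndarray:
    """Composite stochastic-Liouville generator at one instant.

    ``Gamma = blockdiag(-i L_a, -i L_b, ...) + K (x) 1`` from the per-site
    Hamiltonian matrices.
    """
    if len(site_hamiltonians) != model.n_sites:
        raise ValueError(f"{len(site_hamiltonians)} Hamiltonians for "
                         f"{model.n_sites}-site model")
    d = site_hamiltonians[0].shape[0]
    D = model.n_sites * d * d
    G = np.zeros((D, D), dtype=complex)
    for s, H in enumerate(site_hamiltonians):
        L = commutation_superop(H)
        G[s * d * d:(s + 1) * d * d, s * d * d:(s + 1) * d * d] = -1j * L
    return G + exchange_superoperator(model, d)


# ---------------------------------------------------------------------------
# Piecewise-constant period engine
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """A constant-rf stretch of the sequence period, subdivided into equal steps."""

    duration: float
    rf: np.ndarray | None = None   # Hilbert-space rf Hamiltonian (d, d)
    n_step: int = 1


@dataclass
class Pulse:
    """An ideal (instantaneous) pulse: unitary ``U`` applied in every site block."""

    U: np.ndarray


def _batched_liouvillian(H: np.ndarray) -> np.ndarray:
    """Row-major commutation superoperator for a batch ``H[..., d, d]``."""
    d = H.shape[-1]
    eye = np.eye(d)
    left = np.einsum("...ij,kl->...ikjl", H, eye).reshape(*H.shape[:-2], d * d, d * d)
    right = np.einsum("ij,...lk->...ikjl", eye, H).reshape(*H.shape[:-2], d * d, d * d)
    return left - right


class PeriodEngine:
    """Propagators over one sequence period for a batch of crystallites.

    Parameters
    ----------
    omega_f : ndarray, shape (n_cryst, n_sites, 5)
        Rotor-frame Fourier coefficients of the spatial coefficient per
        crystallite and site (from :func:`~masjump.tensors.mas_fourier_components`).
    spin_T : ndarray, shape (d, d)
        Spin part multiplying ``omega(t)``.
    model : JumpModel
    rotor : RotorSpec
    schedule : list of Segment | Pulse
        One period of the sequence; segment durations must sum to a multiple
        of the rotor period (the generator's actual period).
    static_hams : ndarray or None
        Optional static Hamiltonian additions, shape ``(d, d)`` (shared),
        ``(n_sites, d, d)`` or ``(n_cryst, n_sites, d, d)``.
    sample_offsets : sequence of float
        Times within the period (must land on step boundaries) at which
        cumulative sub-period propagators are kept.
    """

    def __init__(self, omega_f, spin_T, model, rotor, schedule,
                 static_hams=None, sample_offsets=()):
        self.model = model
        self.rotor = rotor
        self.d = spin_T.shape[0]
        self.nc, self.ns = omega_f.shape[0], omega_f.shape[1]
        if self.ns != model.n_sites:
            raise ValueError("omega_f site count does not match jump model")
        self.D = self.ns * self.d**2
        self.period = sum(seg.duration for seg in schedule if isinstance(seg, Segment))
        n_rotor = self.period * rotor.nu_r
        if abs(n_rotor - round(n_rotor)) > 1e-6:
            raise ValueError("schedule must span an integer number of rotor periods")

        Kk = np.kron(model.rate_matrix, np.eye(self.d**2))
        m_idx = np.arange(-2, 3)

        # static part broadcast to (nc, ns, d, d)
        if static_hams is None:
            Hstat = np.zeros((1, 1, self.d, self.d), dtype=complex)
        else:
            Hstat = np.asarray(static_hams, dtype=complex)
            while Hstat.ndim < 4:
                Hstat = Hstat[None]

        want = sorted(set(float(x) for x in sample_offsets))
        self.sub_propagators: dict = {}
        P = np.tile(np.eye(self.D, dtype=complex), (self.nc, 1, 1))
        if any(abs(w) < 1e-15 for w in want):
            self.sub_propagators[0.0] = P.copy()

        t0 = 0.0
        max_drift = 0.0
        for item in schedule:
            if isinstance(item, Pulse):
                Up = sandwich_superop(item.U)
                Uc = np.kron(np.eye(self.ns), Up)
                P = Uc @ P
                continue
            dt = item.duration / item.n_step
            for k in range(item.n_step):
                tm = t0 + (k + 0.5) * dt
                phases = np.exp(1j * m_idx * self.rotor.omega_r * tm)
                om = (omega_f @ phases).real          # (nc, ns)
                H = om[..., None, None] * spin_T + Hstat
                if item.rf is not None:
                    H = H + item.rf
                G = -1j * _batched_liouvillian(H)      # (nc, ns, d^2, d^2)
                # assemble composite generator
                Gc = np.zeros((self.nc, self.D, self.D), dtype=complex)
                for s in range(self.ns):
                    sl = slice(s * self.d**2, (s + 1) * self.d**2)
                    Gc[:, sl, sl] = G[:, s]
                Gc += Kk
                step = expm(Gc * dt)
                P = step @ P
                t_end = t0 + (k + 1) * dt
                for w in want:
                    if abs(w - t_end) < 1e-6 * dt:
                        self.sub_propagators[w] = P.copy()
            t0 += item.duration
        self.period_propagator = P
        for w in want:
            if w not in self.sub_propagators and abs(w - self.period) > 1e-15:
                raise ValueError(f"sample offset {w} does not land on a step boundary")

    def composite_state(self, rho: np.ndarray) -> np.ndarray:
        """Population-weighted composite vector of a shared initial operator."""
        blocks = [p * rho.reshape(-1) for p in self.model.populations]
        v = np.concatenate(blocks)
        return np.tile(v, (self.nc, 1))

    def composite_detect(self, det: np.ndarray) -> np.ndarray:
        """Site-summed detection covector ``<det|`` (conjugated, ready to dot)."""
        v = np.tile(det.conj().reshape(-1), self.ns)
        return np.tile(v, (self.nc, 1))

    def crystallite_propagator(self, i: int) -> "CompositePropagator":
        """Single-crystallite view of the cached propagators."""
        return CompositePropagator(
            period_propagator=self.period_propagator[i],
            sub_period_propagators={w: p[i] for w, p in self.sub_propagators.items()},
            dims=(self.ns, self.d**2),
        )


@dataclass
class CompositePropagator:
    """Single-crystallite view of the stochastic-Liouville evolution operator."""

    period_propagator: np.ndarray
    sub_period_propagators: dict
    dims: tuple  # (n_sites, d^2)


def propagate(engine: PeriodEngine, rho0: np.ndarray, detect: np.ndarray,
              t_grid: np.ndarray) -> np.ndarray:
    """Per-crystallite signal ``s_c(t) = <det | rho_c(t)>`` on ``t_grid``.

    Each entry of ``t_grid`` must equal ``n * period + offset`` with
    ``offset`` one of the engine's cached sample offsets.  The state is kept
    anchored at full sequence periods so the period propagator is reused.
    Returns a complex array of shape ``(n_cryst, len(t_grid))`` normalized so
    that ``Tr(det^+ rho0) = 1`` at time zero (dephasing-type start value 1;
    transfer-type experiments start at 0 because ``rho0`` and ``detect`` live
    on different spins and the normalization then uses ``Tr(det^+ det)``).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    norm = np.trace(detect.conj().T @ rho0).real
    if abs(norm) < 1e-12:
        norm = np.trace(detect.conj().T @ detect).real
    rho = engine.composite_state(rho0)
    det = engine.composite_detect(detect)
    P = engine.period_propagator
    period = engine.period

    out = np.empty((engine.nc, len(t_grid)), dtype=complex)
    order = np.argsort(t_grid)
    n_now = 0
    for idx in order:
        t = t_grid[idx]
        n_full = int(math.floor(t / period + 1e-9))
        rem = t - n_full * period
        while n_now < n_full:
            rho = np.einsum("cij,cj->ci", P, rho)
            n_now += 1
        rho_t = rho
        if rem > 1e-12 * period:
            key = min(engine.sub_propagators, key=lambda w: abs(w - rem))
            if abs(key - rem) > 1e-6 * period:
                raise ValueError(f"no cached sub-period propagator at offset {rem:g}")
            rho_t = np.einsum("cij,cj->ci", engine.sub_propagators[key], rho)
        out[:, idx] = np.einsum("ci,ci->c", det, rho_t)
    return out / norm


def powder_trajectory(signals: np.ndarray, crystallites) -> np.ndarray:
    """Weight-summed powder average of per-crystallite signals ``(n_cryst, nt)``."""
    if len(crystallites) == 0:
        raise ValueError("empty crystallite list")
    w = np.array([c.weight for c in crystallites])
    return np.tensordot(w, signals, axes=(0, 0)) / w.sum()


@dataclass
class Trajectory:
    """Time grid plus (powder-averaged) signal of a simulated experiment."""

    t: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = {"t_seconds": self.t}
        if np.iscomplexobj(self.signal):
            cols["signal_real"] = self.signal.real
            cols["signal_imag"] = self.signal.imag
        else:
            cols["signal"] = self.signal
        pd.DataFrame(cols).to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json

        payload = {"meta": self.meta, "t_seconds": self.t.tolist()}
        if np.iscomplexobj(self.signal):
            payload["signal_real"] = self.signal.real.tolist()
            payload["signal_imag"] = self.signal.imag.tolist()
        else:
            payload["signal"] = self.signal.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def n_steps_for(max_omega: float, nu1_hz: float, rotor: RotorSpec,
                duration: float, base: int = 8) -> int:
    """Step count so that ``max|omega| dt < 0.1 rad`` and ``nu1 dt < 0.05`` cycles."""
    dt_max = np.inf
    if max_omega > 0:
        dt_max = min(dt_max, 0.1 / max_omega)
    if nu1_hz > 0:
        dt_max = min(dt_max, 0.05 / nu1_hz)
    n = max(base, int(math.ceil(duration / dt_max))) if np.isfinite(dt_max) else base
    return n


# ---------------------------------------------------------------------------
# Monte-Carlo jump-trajectory oracle
# ---------------------------------------------------------------------------

def monte_carlo_free_evolution(tensor: Rank2Tensor, model: JumpModel,
                               rotor: RotorSpec, crystallites, t_grid,
                               n_traj: int = 10000, seed: int = 1234,
                               n_step_per_rotor: int = 64):
    """Stochastic-trajectory reference for free dipolar dephasing under exchange.

    Independent of the stochastic-Liouville machinery: explicit Markov jump
    trajectories are simulated on a fine time grid (``n_step_per_rotor``
    slices per rotor period; per-step jump probabilities from the exact
    ``expm(K dt)``) and the accumulated phase
    ``Phi(t) = int a_{site(t')}(t') dt'`` gives the observable
    ``<cos(Phi/2)>`` — transverse I magnetization under the secular coupling
    ``a(t) Iz Sz`` with ``a(t) = (2/sqrt(6)) omega(t)`` (the same spin-part
    normalization the sequence simulations use).

    ``t_grid`` must consist of multiples of the slice duration.  Returns
    ``(mean, sem)`` over the powder and trajectory ensemble.
    """
    rng = np.random.default_rng(seed)
    t_grid = np.asarray(t_grid, dtype=float)
    dt = rotor.tau_r / n_step_per_rotor
    n_tot_steps = int(round(t_grid[-1] / dt))
    if np.max(np.abs(t_grid / dt - np.round(t_grid / dt))) > 1e-6:
        raise ValueError("t_grid must be multiples of the Monte-Carlo slice duration")
    grid_idx = np.round(t_grid / dt).astype(int)

    ns = model.n_sites
    Pj = expm(model.rate_matrix * dt)          # column-stochastic jump matrix
    cumP = np.cumsum(Pj, axis=0)               # (to, from)

    m_idx = np.arange(-2, 3)
    omr = rotor.omega_r
    acc = np.zeros(len(t_grid))
    acc2 = np.zeros(len(t_grid))
    for c in crystallites:
        wf = np.array([mas_fourier_components(tensor, e, c, rotor)
                       for e in model.site_eulers])   # (ns, 5)
        # omega at slice midpoints, one rotor period (periodic), per site
        tm = (np.arange(n_step_per_rotor) + 0.5) * dt
        om = (wf @ np.exp(1j * np.outer(m_idx, omr * tm))).real   # (ns, n_step)
        om *= 2.0 / math.sqrt(6.0)          # IzSz coefficient a(t)
        site = rng.choice(ns, size=n_traj, p=model.populations)
        phi = np.zeros(n_traj)
        sig = np.zeros((n_traj, len(t_grid)))
        pos = dict(zip(grid_idx.tolist(), range(len(grid_idx))))
        if 0 in pos:
            sig[:, pos[0]] = 1.0
        for k in range(n_tot_steps):
            phi += om[site, k % n_step_per_rotor] * dt
            r = rng.random(n_traj)
            site = (r[:, None] > cumP[:, site].T).sum(axis=1)
            if (k + 1) in pos:
                sig[:, pos[k + 1]] = np.cos(0.5 * phi)
        acc += c.weight * sig.mean(axis=0)
        acc2 += c.weight * (sig**2).mean(axis=0)
    wtot = sum(c.weight for c in crystallites)
    mean = acc / wtot
    var = np.maximum(acc2 / wtot - mean**2, 0.0)
    sem = np.sqrt(var / n_traj)
    return mean, sem
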