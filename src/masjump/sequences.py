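"""The recoupling and dephasing experiments as parameterized sequence generators.

Each generator assembles one period of its pulse schedule, hands it to the
stochastic-Liouville period engine and returns a powder-averaged
:class:`~masjump.exchange.Trajectory`.  Spin systems:

* dipolar experiments (CP, REDOR, wPARS, off-MAS): heteronuclear I-S
  spin-1/2 pair, secular coupling ``omega(t) * (2/sqrt(6)) Iz Sz`` so that a
  static crystallite at angle ``beta`` shows the splitting
  ``delta P2(cos beta)``;
* CSA recoupling: one spin-1/2, ``omega(t) * sqrt(2/3) Iz``;
* quadrupole: one spin-1, first order ``omega(t) * (3 Iz^2 - 2)/sqrt(6)``
  plus an optional static second-order secular correction.

Isotropic and anisotropic chemical shifts and J couplings are zero in the
dipolar recoupling experiments; the off-MAS echo adds the scalar coupling
``2 pi J Iz Sz``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .spinops import make_spin_operators, embed_two_spin, sandwich_superop
from .tensors import (QuadrupoleSpec, Rank2Tensor, RotorSpec,
                      mas_fourier_components, quad_delta, rotor_frame_components,
                      wigner_d2)
from .exchange import (JumpModel, PeriodEngine, Pulse, Segment, Trajectory,
                       n_steps_for, powder_trajectory, propagate, single_site)

__all__ = [
    "CPSpec", "REDORSpec", "RSequenceSpec", "OffMASSpec", "QuadSpec", "Spectrum",
    "cp_curve", "redor_curves", "wpars_curve", "r18_csa_curve",
    "offmas_echo", "closed_form_offmas", "quad_fid", "quad_spectrum",
]

_half = make_spin_operators(0.5)
_IX = embed_two_spin(_half.Ix, _half.identity)
_IY = embed_two_spin(_half.Iy, _half.identity)
_IZ = embed_two_spin(_half.Iz, _half.identity)
_SX = embed_two_spin(_half.identity, _half.Ix)
_SY = embed_two_spin(_half.identity, _half.Iy)
_SZ = embed_two_spin(_half.identity, _half.Iz)
_IZSZ = _IZ @ _SZ
_T_DIP = (2.0 / math.sqrt(6.0)) * _IZSZ
_T_CSA = math.sqrt(2.0 / 3.0) * _half.Iz


def _omega_f(tensor, model, crystallites, rotor):
    return np.array([[mas_fourier_components(tensor, e, c, rotor)
                      for e in model.site_eulers] for c in crystallites])


def _max_omega(omega_f):
    return float(np.abs(omega_f).sum(axis=-1).max()) if omega_f.size else 0.0


def _pi_pulse(op, phase_rad=0.0):
    """Ideal pi rotation about an axis in the transverse plane."""
    gen = math.cos(phase_rad) * op[0] + math.sin(phase_rad) * op[1]
    return expm(-1j * math.pi * gen)


# ---------------------------------------------------------------------------
# Cross polarization
# ---------------------------------------------------------------------------

@dataclass
class CPSpec:
    """Hartmann-Hahn cross polarization, optionally with a tilted I spin lock."""

    nu1_I: float = 93e3            # Hz
    nu1_S: float = 73e3
    tilt_deg: float = 90.0         # 90 deg = standard transverse CP
    contact_grid: np.ndarray | None = None
    match_order: int = 1

    def matching_offsets(self, rotor: RotorSpec):
        """Effective Hartmann-Hahn offsets ``nu1I +- nu1S - n nu_r`` (Hz)."""
        n = self.match_order
        return (self.nu1_I - self.nu1_S - n * rotor.nu_r,
                self.nu1_I + self.nu1_S - n * rotor.nu_r)


def cp_curve(spec: CPSpec, tensor: Rank2Tensor, model: JumpModel,
             rotor: RotorSpec, crystallites) -> Trajectory:
    """CP transfer curve: S-spin lock-axis signal vs. contact time.

    The initial state is I magnetization along the (possibly tilted) I lock
    axis; rf is applied continuously on both channels in every site block.
    The signal is normalized to the initial I polarization.
    """
    if spec.nu1_I <= 0 or spec.nu1_S <= 0:
        raise ValueError("CP requires non-zero rf amplitude on both channels")
    th = math.radians(spec.tilt_deg)
    axis_I = math.sin(th) * _IX + math.cos(th) * _IZ
    H_rf = 2 * math.pi * spec.nu1_I * axis_I + 2 * math.pi * spec.nu1_S * _SX
    omf = _omega_f(tensor, model, crystallites, rotor)
    n_step = n_steps_for(_max_omega(omf), max(spec.nu1_I, spec.nu1_S),
                         rotor, rotor.tau_r, base=16)
    n_step += n_step % 2             # half-period sampling needs an even count
    sched = [Segment(rotor.tau_r, rf=H_rf, n_step=n_step)]
    grid = spec.contact_grid
    if grid is None:
        grid = np.arange(0, 61) * rotor.tau_r / 2.0
    eng = PeriodEngine(omf, _T_DIP, model, rotor, sched,
                       sample_offsets=[rotor.tau_r / 2.0])
    sig = propagate(eng, axis_I, _SX, grid).real
    zq, dq = spec.matching_offsets(rotor)
    return Trajectory(t=np.asarray(grid, float), signal=powder_trajectory(sig, crystallites),
                      meta={"sequence": "cp", "nu1_I": spec.nu1_I, "nu1_S": spec.nu1_S,
                            "tilt_deg": spec.tilt_deg, "n_step": n_step,
                            "match_offset_zq_hz": zq, "match_offset_dq_hz": dq,
                            "n_crystallites": len(crystallites)})


# ---------------------------------------------------------------------------
# REDOR
# ---------------------------------------------------------------------------

@dataclass
class REDORSpec:
    """Rotor-synchronized pi-pulse dephasing with a pulse-position shift ``eps``."""

    pi_pulse_nu1: float = 100e3     # Hz; ignored when ideal_pulses
    ideal_pulses: bool = False
    shift_eps: float = 0.25         # classic REDOR
    n_rotor_max: int = 64           # dephasing durations: even counts up to this
    phase_scheme: str = "xy4"       # or "xx"


def _redor_rotor_schedule(spec: REDORSpec, rotor: RotorSpec, phases, max_om):
    """One rotor period with two I pi pulses centred at eps*tau_r and (eps+0.5)*tau_r."""
    tau_r = rotor.tau_r
    segs = []
    if spec.ideal_pulses:
        centers = [spec.shift_eps * tau_r, (spec.shift_eps + 0.5) * tau_r]
        t0 = 0.0
        for c, ph in zip(centers, phases):
            segs.append(Segment(c - t0, rf=None,
                                n_step=n_steps_for(max_om, 0.0, rotor, c - t0)))
            segs.append(Pulse(_pi_pulse((_IX, _IY), ph)))
            t0 = c
        segs.append(Segment(tau_r - t0, rf=None,
                            n_step=n_steps_for(max_om, 0.0, rotor, tau_r - t0)))
        return segs
    tp = 1.0 / (2.0 * spec.pi_pulse_nu1)
    edges = []
    for c in (spec.shift_eps * tau_r, (spec.shift_eps + 0.5) * tau_r):
        if c - tp / 2 < 0 or c + tp / 2 > tau_r:
            raise ValueError("finite pi pulses extend beyond the rotor period; "
                             "increase nu1 or adjust eps")
        edges.append((c - tp / 2, c + tp / 2))
    t0 = 0.0
    for (a, b), ph in zip(edges, phases):
        if a > t0:
            segs.append(Segment(a - t0, rf=None,
                                n_step=n_steps_for(max_om, 0.0, rotor, a - t0)))
        Hp = 2 * math.pi * spec.pi_pulse_nu1 * (math.cos(ph) * _IX + math.sin(ph) * _IY)
        segs.append(Segment(b - a, rf=Hp,
                            n_step=n_steps_for(max_om, spec.pi_pulse_nu1, rotor, b - a)))
        t0 = b
    segs.append(Segment(tau_r - t0, rf=None,
                        n_step=n_steps_for(max_om, 0.0, rotor, tau_r - t0)))
    return segs


def redor_curves(spec: REDORSpec, tensor: Rank2Tensor, model: JumpModel,
                 rotor: RotorSpec, crystallites):
    """REDOR dephasing: returns ``(S, S0, dS/S0)`` trajectories.

    The dephasing half before the echo center uses I pulses at
    ``(eps, eps + 0.5) tau_r``; the half after it is the time-mirrored train
    (``(0.5 - eps, 1 - eps) tau_r``), and the echo center carries ideal pi
    pulses on *both* channels.  The pi_I at the center is the toggling-frame
    defect that keeps the two halves adding instead of refocusing (at
    ``eps = 0.25`` this is the classic scheme in which the central pulse
    replaces one pulse of the continuous train); the mirrored second half
    yields the ``sin(2 pi eps)`` scaling of the shifted variant.  ``S0`` is
    the identical sequence without the I-channel pulses, so
    ``dS/S0 = (S0 - S)/S0`` is relaxation-compensated.  Dephasing durations
    are even numbers of rotor periods.
    """
    omf = _omega_f(tensor, model, crystallites, rotor)
    max_om = _max_omega(omf)
    if spec.phase_scheme == "xy4":
        # two pulses per rotor period, phases x, y: the XY-4 unit spans two
        # periods and every rotor period carries the same propagator
        phases = (0.0, math.pi / 2)
    elif spec.phase_scheme == "xx":
        phases = (0.0, 0.0)
    else:
        raise ValueError(f"unknown phase scheme {spec.phase_scheme!r}")

    eng = PeriodEngine(omf, _T_DIP, model, rotor,
                       _redor_rotor_schedule(spec, rotor, phases, max_om))
    mirror = REDORSpec(**{**spec.__dict__, "shift_eps": 0.5 - spec.shift_eps})
    eng_m = PeriodEngine(omf, _T_DIP, model, rotor,
                         _redor_rotor_schedule(mirror, rotor, phases[::-1], max_om))
    free = [Segment(rotor.tau_r, rf=None,
                    n_step=n_steps_for(max_om, 0.0, rotor, rotor.tau_r))]
    eng_0 = PeriodEngine(omf, _T_DIP, model, rotor, free)

    n_grid = np.arange(2, spec.n_rotor_max + 1, 2)
    t = n_grid * rotor.tau_r
    Pi_IS = np.kron(np.eye(model.n_sites),
                    sandwich_superop(_pi_pulse((_IX, _IY)) @ _pi_pulse((_SX, _SY))))
    Pi_S = np.kron(np.eye(model.n_sites), sandwich_superop(_pi_pulse((_SX, _SY))))
    s = _midpulse_signal(eng.period_propagator, eng_m.period_propagator, Pi_IS,
                         eng, _SX, _SX, n_grid)
    s0 = _midpulse_signal(eng_0.period_propagator, eng_0.period_propagator, Pi_S,
                          eng_0, _SX, _SX, n_grid)
    s_p = powder_trajectory(s, crystallites)
    s0_p = powder_trajectory(s0, crystallites)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(np.abs(s0_p) > 1e-6, (s0_p - s_p) / s0_p, np.nan)
    flagged = np.abs(s0_p) <= 1e-6
    meta = {"sequence": "redor", "eps": spec.shift_eps,
            "ideal_pulses": spec.ideal_pulses, "nu1": spec.pi_pulse_nu1,
            "n_crystallites": len(crystallites), "s0_zero_flagged": int(flagged.sum())}
    return (Trajectory(t, s_p, {**meta, "curve": "S"}),
            Trajectory(t, s0_p, {**meta, "curve": "S0"}),
            Trajectory(t, frac, {**meta, "curve": "dS_over_S0"}))


def _midpulse_signal(Ua, Ub, Pi, eng, rho0_op, det_op, n_grid):
    """Signals ``<det| Ub^m Pi Ua^m |rho0>`` for even rotor counts ``n = 2m``:
    an echo whose first half repeats the period propagator ``Ua``, whose
    center applies the ideal-pulse superoperator ``Pi`` and whose second half
    repeats ``Ub``.  Linear cost via state and covector iterates.
    """
    rho = eng.composite_state(rho0_op)
    det = eng.composite_detect(det_op)
    out = np.empty((eng.nc, len(n_grid)))
    m_max = int(n_grid.max() // 2)
    states = [rho]
    a = rho
    for _ in range(m_max):
        a = np.einsum("cij,cj->ci", Ua, a)
        states.append(a)
    covs = [det]
    cs = det
    for _ in range(m_max):
        cs = np.einsum("ci,cij->cj", cs, Ub)
        covs.append(cs)
    pos = {int(n): k for k, n in enumerate(n_grid)}
    for n in n_grid:
        m = int(n) // 2
        mid = np.einsum("ij,cj->ci", Pi, states[m])
        out[:, pos[int(n)]] = np.einsum("ci,ci->c", covs[m], mid).real
    norm = np.trace(det_op.conj().T @ rho0_op).real
    return out / norm


# ---------------------------------------------------------------------------
# Symmetry-based R sequences: wPARS (dipolar) and R18_1^7 (CSA)
# ---------------------------------------------------------------------------

@dataclass
class RSequenceSpec:
    """Phase-alternated RN_n^nu recoupling train.

    ``window_fraction w`` inserts an rf-free window in each R element; the
    pulse amplitude ``N nu_r / (2 n (1 - w))`` keeps every element a full pi
    rotation.  ``target`` selects the dipolar wPARS variant (R10_1^3 on the
    I channel, observing S, with pi pulses on S between blocks) or one-spin
    CSA recoupling (R18_1^7).
    """

    N: int = 10
    n: int = 1
    nu: int = 3
    window_fraction: float = 0.0
    window_placement: str = "split"  # "split" (window inside the pi rotation) | "trail"
    target: str = "dipolar"          # "dipolar" | "csa"
    s_channel_pi: bool = True
    n_block_max: int = 100           # number of supercycles sampled

    @property
    def phase(self) -> float:
        """R-element phase phi = pi nu / N (rad)."""
        return math.pi * self.nu / self.N

    def nu1(self, rotor: RotorSpec) -> float:
        """rf amplitude N nu_r / (2 n (1 - w)) in Hz."""
        if self.window_fraction >= 1.0:
            raise ValueError("window fraction must be < 1")
        return self.N * rotor.nu_r / (2.0 * self.n * (1.0 - self.window_fraction))


def _r_block_segments(spec: RSequenceSpec, rotor: RotorSpec, Iops, max_om,
                      phase_offset: float):
    """One RN_n^nu block: N R elements over n rotor periods.

    With a window fraction ``w > 0`` the default element splits the pi
    rotation around a central rf-free window (pi/2 - window - pi/2, the
    magnetization transverse during the window, which raises the effective
    recoupled coupling as the window grows); ``placement='trail'`` puts the
    whole pi pulse first instead.
    """
    el = spec.n * rotor.tau_r / spec.N
    w = spec.window_fraction
    tp = el * (1.0 - w)
    nu1 = spec.nu1(rotor)
    segs = []
    for k in range(spec.N):
        ph = (spec.phase if k % 2 == 0 else -spec.phase) + phase_offset
        Hp = 2 * math.pi * nu1 * (math.cos(ph) * Iops[0] + math.sin(ph) * Iops[1])

        def pulse(dur):
            return Segment(dur, rf=Hp, n_step=n_steps_for(max_om, nu1, rotor, dur))

        if w <= 0:
            segs.append(pulse(tp))
        elif spec.window_placement == "split":
            segs += [pulse(tp / 2),
                     Segment(el - tp, rf=None,
                             n_step=n_steps_for(max_om, 0.0, rotor, el - tp)),
                     pulse(tp / 2)]
        elif spec.window_placement == "trail":
            segs += [pulse(tp),
                     Segment(el - tp, rf=None,
                             n_step=n_steps_for(max_om, 0.0, rotor, el - tp))]
        else:
            raise ValueError(f"unknown window placement {spec.window_placement!r}")
    return segs


def wpars_curve(spec: RSequenceSpec, tensor: Rank2Tensor, model: JumpModel,
                rotor: RotorSpec, crystallites) -> Trajectory:
    """wPARS dipolar dephasing: alternating RN0 / RNpi blocks on I, observing S.

    S transverse magnetization dephases under the recoupled heteronuclear
    coupling; ideal pi pulses on S between blocks suppress I-spin CSA
    (inert here, retained as part of the sequence).
    """
    if spec.target != "dipolar":
        raise ValueError("wpars_curve expects target='dipolar'")
    omf = _omega_f(tensor, model, crystallites, rotor)
    max_om = _max_omega(omf)
    sched = list(_r_block_segments(spec, rotor, (_IX, _IY), max_om, 0.0))
    if spec.s_channel_pi:
        sched.append(Pulse(_pi_pulse((_SX, _SY))))
    sched += _r_block_segments(spec, rotor, (_IX, _IY), max_om, math.pi)
    if spec.s_channel_pi:
        sched.append(Pulse(_pi_pulse((_SX, _SY))))
    period = 2 * spec.n * rotor.tau_r
    eng = PeriodEngine(omf, _T_DIP, model, rotor, sched)
    grid = period * np.arange(0, spec.n_block_max + 1)
    sig = propagate(eng, _SX, _SX, grid).real
    return Trajectory(grid, powder_trajectory(sig, crystallites),
                      meta={"sequence": "wpars", "N": spec.N, "n": spec.n,
                            "nu": spec.nu, "phase_deg": math.degrees(spec.phase),
                            "w": spec.window_fraction, "nu1_hz": spec.nu1(rotor),
                            "n_crystallites": len(crystallites)})


def r18_csa_curve(spec: RSequenceSpec, tensor: Rank2Tensor, model: JumpModel,
                  rotor: RotorSpec, crystallites) -> Trajectory:
    """CSA recoupling of a one-spin system by an R18_1^7 pi-pulse train.

    Transverse magnetization evolves under the recoupled CSA; the rf
    amplitude is ``N nu_r / 2n`` (9 nu_r for R18_1^7), so the pi pulses are
    contiguous at zero window fraction.
    """
    if spec.target != "csa":
        raise ValueError("r18_csa_curve expects target='csa'")
    omf = _omega_f(tensor, model, crystallites, rotor)
    max_om = _max_omega(omf)
    ops = (_half.Ix, _half.Iy)
    sched = list(_r_block_segments(spec, rotor, ops, max_om, 0.0))
    period = spec.n * rotor.tau_r
    eng = PeriodEngine(omf, _T_CSA, model, rotor, sched)
    grid = period * np.arange(0, spec.n_block_max + 1)
    sig = propagate(eng, _half.Ix, _half.Ix, grid).real
    return Trajectory(grid, powder_trajectory(sig, crystallites),
                      meta={"sequence": "r18_csa", "N": spec.N, "n": spec.n,
                            "nu": spec.nu, "phase_deg": math.degrees(spec.phase),
                            "nu1_hz": spec.nu1(rotor),
                            "n_crystallites": len(crystallites)})


# ---------------------------------------------------------------------------
# Off-magic-angle spinning echo
# ---------------------------------------------------------------------------

@dataclass
class OffMASSpec:
    """Heteronuclear J-modulated spin echo under slightly off-magic-angle spinning."""

    J: float = -90.0                # Hz
    offset_deg: float = 0.05        # Delta
    window: float = 0.080           # s
    tau_step_periods: int = 2       # echo times in multiples of this many tau_r


def offmas_echo(spec: OffMASSpec, tensor: Rank2Tensor, model: JumpModel,
                rotor: RotorSpec, crystallites) -> Trajectory:
    """Echo modulation of I transverse magnetization under J + residual dipolar coupling.

    The rotor spins at ``theta_m + Delta``; simultaneous ideal pi pulses on
    both spins at tau/2 refocus shifts but not the J or residual dipolar
    modulation.  Echo times are multiples of two rotor periods.
    """
    if abs(spec.offset_deg) > 5.0:
        warnings.warn("offset angle outside the small-offset regime (|Delta| > 5 deg)")
    rotor = RotorSpec(nu_r=rotor.nu_r, offset_deg=spec.offset_deg)
    omf = _omega_f(tensor, model, crystallites, rotor)
    max_om = _max_omega(omf)
    HJ = 2 * math.pi * spec.J * _IZSZ
    free = [Segment(rotor.tau_r, rf=None,
                    n_step=n_steps_for(max_om, 0.0, rotor, rotor.tau_r))]
    eng = PeriodEngine(omf, _T_DIP, model, rotor, free, static_hams=HJ)
    step = spec.tau_step_periods
    if step % 2:
        raise ValueError("tau_step_periods must be even so tau/2 is rotor-synchronized")
    n_max = int(spec.window / (step * rotor.tau_r))
    n_grid = step * np.arange(1, n_max + 1)
    Pi = np.kron(np.eye(model.n_sites),
                 sandwich_superop(_pi_pulse((_IX, _IY)) @ _pi_pulse((_SX, _SY))))
    P = eng.period_propagator
    sig = _midpulse_signal(P, P, Pi, eng, _IX, _IX, n_grid)
    t = n_grid * rotor.tau_r
    return Trajectory(t, powder_trajectory(sig, crystallites),
                      meta={"sequence": "offmas_echo", "J_hz": spec.J,
                            "offset_deg": spec.offset_deg,
                            "n_crystallites": len(crystallites)})


def closed_form_offmas(spec: OffMASSpec, delta_IS: float,
                       tau: np.ndarray | None = None,
                       rotor: RotorSpec | None = None,
                       n_beta: int = 400) -> Trajectory:
    """Small-offset closed form of the off-MAS echo for a rigid spin pair.

    ``S(tau) = 1/2 int_0^pi cos[pi J tau - (Delta delta_IS / sqrt(2))
    P2(cos beta_PR) tau] sin(beta_PR) d beta_PR`` with ``Delta`` in radians
    and ``beta_PR`` the angle between internuclear vector and rotor axis
    (Gauss-Legendre quadrature in ``cos beta_PR``).
    """
    if tau is None:
        if rotor is None:
            raise ValueError("provide either tau or rotor to build the default grid")
        step = spec.tau_step_periods * rotor.tau_r
        tau = step * np.arange(1, int(spec.window / step) + 1)
    tau = np.asarray(tau, dtype=float)
    x, w = np.polynomial.legendre.leggauss(n_beta)   # x = cos(beta), weights sum 2
    p2 = 0.5 * (3 * x**2 - 1)
    d_rad = math.radians(spec.offset_deg)
    phase = (math.pi * spec.J * tau[:, None]
             - (d_rad * delta_IS / math.sqrt(2.0)) * p2[None, :] * tau[:, None])
    sig = 0.5 * (np.cos(phase) @ w)
    return Trajectory(tau, sig, meta={"sequence": "offmas_closed_form",
                                      "J_hz": spec.J, "offset_deg": spec.offset_deg,
                                      "delta_IS_hz": delta_IS / (2 * math.pi)})


# ---------------------------------------------------------------------------
# Deuterium sideband spectra
# ---------------------------------------------------------------------------

@dataclass
class QuadSpec:
    """Acquisition of a 2H one-pulse FID under MAS."""

    quad: QuadrupoleSpec = field(default_factory=lambda: QuadrupoleSpec(Cqcc=160e3))
    window: float = 0.150           # s
    samples_per_period: int = 20    # dwell = tau_r / this
    display_lb: float = 10.0        # Hz, spectrum display broadening


@dataclass
class Spectrum:
    freq: np.ndarray      # Hz
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)


_spin1 = make_spin_operators(1.0)
_T_QUAD = (3.0 * _spin1.Iz @ _spin1.Iz - 2.0 * _spin1.identity) / math.sqrt(6.0)
# spherical spin tensors of the quadrupole for the second-order correction
_T2 = {
    0: _T_QUAD,
    1: -0.5 * (_spin1.Iz @ _spin1.Ip + _spin1.Ip @ _spin1.Iz),
    -1: 0.5 * (_spin1.Iz @ _spin1.Im + _spin1.Im @ _spin1.Iz),
    2: 0.5 * _spin1.Ip @ _spin1.Ip,
    -2: 0.5 * _spin1.Im @ _spin1.Im,
}


def _second_order_shifts(AR, rotor: RotorSpec, larmor: float) -> np.ndarray:
    """Static secular second-order level shifts per (crystallite, site).

    Second-order perturbation theory over the Zeeman ladder (``H0 = omega0
    Iz``), using the rotor-period averages ``<|A_2mu(t)|^2> = sum_m
    d2[mu, m](theta_rot)^2 |A^R_m|^2`` of the lab-frame non-secular
    components (cross terms oscillate and drop).  ``AR`` are rotor-frame
    components of shape ``(nc, ns, 5)``; returns ``(nc, ns, 3)`` diagonal
    level corrections in rad/s, states ordered m = +1, 0, -1.
    """
    d2 = wigner_d2(rotor.theta_rot)
    AR2 = np.abs(AR)**2
    m_states = np.array([1.0, 0.0, -1.0])
    out = np.zeros((*AR.shape[:2], 3))
    for mu in (1, -1, 2, -2):
        avg = AR2 @ d2[mu + 2, :]**2            # <|A_2mu|^2>
        T = _T2[mu]
        for a in range(3):
            for b in range(3):
                if a == b or abs(T[b, a]) == 0.0:
                    continue
                out[..., a] += avg * abs(T[b, a])**2 / (larmor * (m_states[a] - m_states[b]))
    return out


def quad_fid(spec: QuadSpec, model: JumpModel, rotor: RotorSpec,
             crystallites) -> Trajectory:
    """Complex one-pulse 2H FID under MAS with exchange.

    The first-order quadrupolar Hamiltonian is diagonal in the Zeeman basis
    for every site, so each single-quantum coherence evolves in an
    ``n_sites``-dimensional block; the two coherences are propagated with
    cached rotor-period propagators and sampled within each period.
    """
    tensor = quad_delta(spec.quad)
    omf = _omega_f(tensor, model, crystallites, rotor)
    AR = np.array([[rotor_frame_components(tensor, e, c)
                    for e in model.site_eulers] for c in crystallites])
    nc, ns = omf.shape[:2]
    ndw = spec.samples_per_period
    dwell = rotor.tau_r / ndw
    max_tr = math.sqrt(1.5) * _max_omega(omf) / (2 * math.pi)
    if 1.0 / dwell < 2.2 * max_tr:
        raise ValueError(f"dwell too coarse: need spectral width >= {2.2 * max_tr:.0f} Hz, "
                         f"have {1.0 / dwell:.0f} Hz")
    # transition frequencies: coherence (m=1,0): +sqrt(3/2) omega ; (0,-1): -sqrt(3/2) omega
    coeff = np.array([math.sqrt(1.5), -math.sqrt(1.5)])
    shift2 = (_second_order_shifts(AR, rotor, spec.quad.larmor)
              if spec.quad.second_order else np.zeros((nc, ns, 3)))
    d2nd = np.stack([shift2[..., 0] - shift2[..., 1],
                     shift2[..., 1] - shift2[..., 2]], axis=-1)  # (nc, ns, 2)

    n_per = max(1, int(round(spec.window / rotor.tau_r)))
    m_idx = np.arange(-2, 3)
    n_step = max(ndw, n_steps_for(math.sqrt(1.5) * _max_omega(omf), 0.0,
                                  rotor, rotor.tau_r))
    n_step = int(math.ceil(n_step / ndw) * ndw)      # dwell points on step grid
    dt = rotor.tau_r / n_step
    K = model.rate_matrix

    # step propagators (nc, 2, n_step, ns, ns), built per step to bound memory
    P = np.tile(np.eye(ns, dtype=complex), (nc, 2, 1, 1))
    subs = np.empty((ndw, nc, 2, ns, ns), dtype=complex)
    for k in range(n_step):
        tm = (k + 0.5) * dt
        ph = np.exp(1j * m_idx * rotor.omega_r * tm)
        om = (omf @ ph).real                       # (nc, ns)
        freq = coeff[None, :, None] * om[:, None, :] + d2nd.transpose(0, 2, 1)
        G = np.zeros((nc, 2, ns, ns), dtype=complex)
        G[..., np.arange(ns), np.arange(ns)] = -1j * freq
        G += K
        P = expm(G * dt) @ P
        if (k + 1) % (n_step // ndw) == 0:
            subs[(k + 1) // (n_step // ndw) - 1] = P
    # initial coherence vector: Ix elements 1/sqrt(2) in each SQ coordinate,
    # detection Tr(I- rho) = sqrt(2) (rho_01 + rho_12); normalized to s(0) = 1
    r0 = np.tile(model.populations.astype(complex), (nc, 2, 1))
    w = np.array([c.weight for c in crystallites])
    fid = np.empty(n_per * ndw + 1, dtype=complex)
    fid[0] = 1.0
    r = r0
    wsum = w.sum()
    for n in range(n_per):
        prop = np.einsum("kcqij,cqj->kcqi", subs, r)     # (ndw, nc, 2, ns)
        fid[1 + n * ndw:1 + (n + 1) * ndw] = \
            np.einsum("kcq,c->k", prop.sum(axis=3), w) / (2.0 * wsum)
        r = prop[-1]
    t = dwell * np.arange(n_per * ndw + 1)
    return Trajectory(t, fid, meta={"sequence": "quad_fid",
                                    "Cqcc_hz": spec.quad.Cqcc,
                                    "second_order": spec.quad.second_order,
                                    "dwell_s": dwell, "n_step": n_step,
                                    "n_crystallites": nc})


def offmas_reference(spec: OffMASSpec, delta_values: np.ndarray,
                     rotor: RotorSpec, crystallites,
                     tau: np.ndarray) -> np.ndarray:
    """Exchange-free off-MAS echo trajectories for a grid of trial anisotropies.

    Exact for rotor-synchronized echo times: the diagonal Hamiltonian
    commutes with itself, so only the ``m = 0`` Fourier coefficient of the
    spatial part survives integer rotor periods and
    ``s(tau) = <cos(pi J tau + omega_bar (2/sqrt(6)) tau / 2)>_powder``.
    Returns shape ``(n_delta, n_tau)``.
    """
    rotor = RotorSpec(nu_r=rotor.nu_r, offset_deg=spec.offset_deg)
    unit = Rank2Tensor(delta=1.0)
    wbar = np.array([mas_fourier_components(unit, (0.0, 0.0, 0.0), c, rotor)[2].real
                     for c in crystallites])
    w = np.array([c.weight for c in crystallites])
    w = w / w.sum()
    delta_rad = 2 * math.pi * np.asarray(delta_values, dtype=float)   # Hz -> rad/s
    # phase per crystallite and delta: (pi J + omega_bar * delta / sqrt(6)) tau
    rate = (math.pi * spec.J
            + delta_rad[:, None] * wbar[None, :] / math.sqrt(6.0))    # (nd, nc)
    return np.einsum("c,dct->dt", w, np.cos(rate[:, :, None] * tau[None, None, :]))


def quad_reference(spec: QuadSpec, delta_values: np.ndarray,
                   rotor: RotorSpec, crystallites,
                   t: np.ndarray) -> np.ndarray:
    """Exchange-free 2H FIDs for a grid of trial anisotropies (analytic phases).

    The rigid FID is a sum over the two single-quantum transitions with
    phases ``+-sqrt(3/2) Phi_c(t)`` obtained by integrating the Fourier
    series of the spatial coefficient exactly; the second-order level
    shifts scale with ``delta^2``.  Returns shape ``(n_delta, n_t)``
    (complex) on the target FID's time grid.
    """
    tensor = quad_delta(spec.quad)
    base_delta = tensor.delta
    AR = np.array([rotor_frame_components(tensor, (0.0, 0.0, 0.0), c)
                   for c in crystallites])                    # (nc, 5)
    d0 = wigner_d2(rotor.theta_rot)[2, :]
    wf = (d0 * AR)[:, ::-1]                                   # omega Fourier coeffs
    m = np.arange(-2, 3)
    omr = rotor.omega_r
    # Phi_c(t) = w0 t + sum_{m!=0} w_m (e^{i m omr t} - 1)/(i m omr)
    phi = wf[:, 2].real[:, None] * t[None, :]
    for j, mm in enumerate(m):
        if mm == 0:
            continue
        phi = phi + (wf[:, j][:, None]
                     * (np.exp(1j * mm * omr * t[None, :]) - 1.0)
                     / (1j * mm * omr)).real
    shift2 = _second_order_shifts(AR[:, None, :], rotor, spec.quad.larmor)[:, 0, :]
    d2nd = np.stack([shift2[:, 0] - shift2[:, 1],
                     shift2[:, 1] - shift2[:, 2]], axis=-1)   # (nc, 2)
    if not spec.quad.second_order:
        d2nd = np.zeros_like(d2nd)
    w = np.array([c.weight for c in crystallites])
    w = w / w.sum()
    scale = np.asarray(delta_values, dtype=float) * 2 * math.pi / base_delta
    coeff = np.array([math.sqrt(1.5), -math.sqrt(1.5)])
    out = np.zeros((len(scale), len(t)), dtype=complex)
    for di, sc in enumerate(scale):      # one delta at a time to bound memory
        for qi in range(2):
            ph = coeff[qi] * sc * phi + sc**2 * d2nd[:, qi][:, None] * t[None, :]
            out[di] += 0.5 * (w @ np.exp(-1j * ph))
    return out


def quad_spectrum(fid: Trajectory, display_lb: float = 10.0) -> Spectrum:
    """Sideband spectrum: Fourier transform of the FID after display broadening."""
    dwell = fid.t[1] - fid.t[0]
    s = fid.signal * np.exp(-math.pi * display_lb * fid.t)
    s = s.copy()
    s[0] *= 0.5
    spec = np.fft.fftshift(np.fft.fft(s))
    freq = np.fft.fftshift(np.fft.fftfreq(len(s), dwell))
    return Spectrum(freq=freq, intensity=spec.real,
                    meta={**fid.meta, "display_lb_hz": display_lb})
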