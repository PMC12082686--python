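"""Second-rank interaction tensors, frame transformations and powder schemes.

Conventions (fixed once, pinned by the test suite):

* Tensor anisotropies ``delta`` are stored as angular frequencies (rad/s);
  user-facing values are ``delta / (2 pi)`` in Hz.
* Irreducible spherical components in the principal-axis system (PAS):
  ``A20 = sqrt(3/2) * delta``, ``A2+-1 = 0``, ``A2+-2 = -delta * eta / 2``.
* Euler angles ``(alpha, beta, gamma)`` are active ZYZ rotations,
  ``R = Rz(alpha) Ry(beta) Rz(gamma)``.  Spherical components transform as
  ``A'_m = sum_mp D2[m, mp] A_mp`` with
  ``D2[m, mp] = exp(-i m alpha) d2[m, mp](beta) exp(-i mp gamma)``
  (the matrix of ``U T_m U^+ = sum_mp T_mp D2[mp, m]`` acting on component
  vectors).  Worked example: an axial tensor rotated by ``(alpha, beta, 0)``
  acquires ``A'_m = exp(-i m alpha) d2[m, 0](beta) A20``, so
  ``A'_20 = P2(cos beta) A20`` and the azimuth alpha phases the m != 0
  components.
* The frame chain is PAS -> jump site -> crystallite -> rotor, followed by
  the time-dependent rotor -> lab rotation at the angle
  ``theta_rot = theta_m + Delta`` between rotor axis and static field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MU0", "HBAR", "GAMMA", "THETA_MAGIC",
    "Rank2Tensor", "DipolarGeometry", "QuadrupoleSpec", "RotorSpec", "Crystallite",
    "order_parameter", "dipolar_delta", "quad_delta",
    "spherical_components", "wigner_d2", "wigner_D2", "rotate_components",
    "euler_compose", "rotor_frame_components", "mas_fourier_components", "mas_frequency",
    "zcw_orientations", "crystallites_to_csv",
]

# CODATA 2018
MU0 = 1.25663706212e-6      # vacuum permeability, N A^-2
HBAR = 1.054571817e-34      # reduced Planck constant, J s

#: Gyromagnetic ratios in rad s^-1 T^-1 (sign included).
GAMMA = {
    "1H": 2.6752218744e8,
    "2H": 4.10662791e7,
    "13C": 6.728284e7,
    "15N": -2.7116e7,
    "19F": 2.518148e8,
    "31P": 1.08394e8,
}

THETA_MAGIC = math.acos(1.0 / math.sqrt(3.0))  # magic angle, rad


def order_parameter(theta_deg: float) -> float:
    """Order parameter ``S = P2(cos theta)`` of rotation on a cone of half-angle ``theta``."""
    theta_deg = float(theta_deg)
    if not 0.0 <= theta_deg <= 180.0:
        raise ValueError(f"opening angle must be in [0, 180] degrees, got {theta_deg}")
    c = math.cos(math.radians(theta_deg))
    return 0.5 * (3.0 * c * c - 1.0)


@dataclass(frozen=True)
class Rank2Tensor:
    """An anisotropic second-rank interaction in its principal-axis frame.

    ``delta`` is the anisotropy in rad/s; ``eta`` the asymmetry (0 for every
    shipped experiment, the attribute is accepted for completeness);
    ``euler_pas_to_site`` orients the PAS in the first jump-site frame.
    """

    delta: float
    eta: float = 0.0
    euler_pas_to_site: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"asymmetry eta must be in [0, 1], got {self.eta}")

    @property
    def delta_hz(self) -> float:
        return self.delta / (2.0 * math.pi)

    @classmethod
    def from_hz(cls, delta_hz: float, eta: float = 0.0,
                euler_pas_to_site: tuple = (0.0, 0.0, 0.0)) -> "Rank2Tensor":
        return cls(delta=2.0 * math.pi * delta_hz, eta=eta,
                   euler_pas_to_site=euler_pas_to_site)


@dataclass(frozen=True)
class DipolarGeometry:
    """Geometry of a heteronuclear dipolar coupling: gyromagnetic ratios and distance."""

    gamma_I: float  # rad s^-1 T^-1
    gamma_S: float
    r_IS: float     # m

    def __post_init__(self):
        if self.r_IS <= 0:
            raise ValueError(f"internuclear distance must be positive, got {self.r_IS}")

    @classmethod
    def from_isotopes(cls, iso_I: str, iso_S: str, r_angstrom: float) -> "DipolarGeometry":
        return cls(gamma_I=GAMMA[iso_I], gamma_S=GAMMA[iso_S], r_IS=r_angstrom * 1e-10)


def dipolar_delta(geom: DipolarGeometry) -> Rank2Tensor:
    """Dipolar-coupling tensor anisotropy ``delta_IS = -2 (mu0/4pi) hbar gI gS / r^3``."""
    delta = -2.0 * (MU0 / (4.0 * math.pi)) * HBAR * geom.gamma_I * geom.gamma_S / geom.r_IS**3
    return Rank2Tensor(delta=delta, eta=0.0)


@dataclass(frozen=True)
class QuadrupoleSpec:
    """Quadrupolar interaction of a spin ``I >= 1`` nucleus at field ``B0``."""

    Cqcc: float                 # quadrupolar coupling constant, Hz
    spin: float = 1.0
    B0: float = 18.7            # T
    isotope: str = "2H"
    second_order: bool = True

    def __post_init__(self):
        if self.spin < 1.0:
            raise ValueError("quadrupolar coupling requires spin I >= 1")

    @property
    def larmor(self) -> float:
        """Larmor frequency ``gamma B0`` in rad/s (magnitude)."""
        return abs(GAMMA[self.isotope]) * self.B0


def quad_delta(spec: QuadrupoleSpec) -> Rank2Tensor:
    """Quadrupolar tensor anisotropy ``delta_Q = 2 pi Cqcc / (2I(2I-1))``."""
    I = spec.spin
    return Rank2Tensor(delta=2.0 * math.pi * spec.Cqcc / (2.0 * I * (2.0 * I - 1.0)))


@dataclass(frozen=True)
class RotorSpec:
    """Sample-rotation parameters: spinning frequency and magic-angle offset."""

    nu_r: float             # Hz
    offset_deg: float = 0.0  # Delta, signed deviation from the magic angle

    @property
    def omega_r(self) -> float:
        return 2.0 * math.pi * self.nu_r

    @property
    def tau_r(self) -> float:
        return 1.0 / self.nu_r

    @property
    def theta_rot(self) -> float:
        """Angle between rotation axis and static field, rad."""
        return THETA_MAGIC + math.radians(self.offset_deg)


@dataclass(frozen=True)
class Crystallite:
    """One powder orientation (Euler angles in radians) with its normalized weight."""

    alpha: float
    beta: float
    gamma: float
    weight: float


# ---------------------------------------------------------------------------
# Spherical-tensor components and Wigner rotations
# ---------------------------------------------------------------------------

def spherical_components(delta: float, eta: float = 0.0) -> np.ndarray:
    """PAS components ``[A2-2, A2-1, A20, A21, A22]`` of a traceless rank-2 tensor."""
    A = np.zeros(5, dtype=complex)
    A[2] = math.sqrt(1.5) * delta
    A[0] = A[4] = -0.5 * delta * eta
    return A


def wigner_d2(beta: float) -> np.ndarray:
    """Reduced Wigner matrix ``d2[m', m](beta)``, indices ordered m = -2..2."""
    c = math.cos(beta)
    s = math.sin(beta)
    d = np.empty((5, 5))
    # top row: m' = +2 (array index 4); fill from standard closed forms, then
    # complete by the symmetries d[m',m] = (-1)^(m'-m) d[m,m'] = d[-m,-m'].
    d22 = ((1 + c) / 2) ** 2
    d21 = -0.5 * (1 + c) * s
    d20 = math.sqrt(6.0) / 4.0 * s * s
    d2m1 = -0.5 * (1 - c) * s
    d2m2 = ((1 - c) / 2) ** 2
    d11 = 0.5 * (1 + c) * (2 * c - 1)
    d10 = -math.sqrt(1.5) * s * c
    d1m1 = 0.5 * (1 - c) * (2 * c + 1)
    d00 = 0.5 * (3 * c * c - 1)

    def put(mp, m, val):
        d[mp + 2, m + 2] = val

    put(2, 2, d22); put(2, 1, d21); put(2, 0, d20); put(2, -1, d2m1); put(2, -2, d2m2)
    put(1, 1, d11); put(1, 0, d10); put(1, -1, d1m1)
    put(0, 0, d00)
    # complete via d[m',m] = (-1)^(m'-m) d[m,m'] = d[-m,-m']
    filled = {(2, 2), (2, 1), (2, 0), (2, -1), (2, -2), (1, 1), (1, 0), (1, -1), (0, 0)}
    for mp in range(-2, 3):
        for m in range(-2, 3):
            if (mp, m) in filled:
                continue
            if (m, mp) in filled:
                put(mp, m, (-1) ** (mp - m) * d[m + 2, mp + 2])
            elif (-m, -mp) in filled:
                put(mp, m, d[-m + 2, -mp + 2])
            else:
                put(mp, m, (-1) ** (mp - m) * d[-mp + 2, -m + 2])
    return d


def wigner_D2(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Full Wigner rotation matrix ``D2[m', m] = e^{-i m' alpha} d2[m', m] e^{-i m gamma}``."""
    m = np.arange(-2, 3)
    return np.exp(-1j * m[:, None] * alpha) * wigner_d2(beta) * np.exp(-1j * m[None, :] * gamma)


def rotate_components(A2m: np.ndarray, euler: tuple) -> np.ndarray:
    """Actively rotate spherical components: ``A'_m = sum_mp D2[m, mp](euler) A_mp``."""
    D = wigner_D2(*euler)
    return D @ np.asarray(A2m, dtype=complex)


def euler_compose(e1: tuple, e2: tuple) -> tuple:
    """Euler angles of the composed rotation *e2 after e1* (``R = R(e2) R(e1)``).

    ``rotate_components(rotate_components(A, e1), e2)`` equals
    ``rotate_components(A, euler_compose(e1, e2))``.
    """
    from scipy.spatial.transform import Rotation

    r = Rotation.from_euler("ZYZ", e2) * Rotation.from_euler("ZYZ", e1)
    a, b, g = r.as_euler("ZYZ")
    return (float(a), float(b), float(g))


# ---------------------------------------------------------------------------
# MAS time dependence
# ---------------------------------------------------------------------------

def rotor_frame_components(tensor: Rank2Tensor, site_euler: tuple,
                           crystallite: Crystallite) -> np.ndarray:
    """Spherical components in the rotor frame after the PAS -> site ->
    crystallite -> rotor chain (no time dependence yet)."""
    A = spherical_components(tensor.delta, tensor.eta)
    A = rotate_components(A, tensor.euler_pas_to_site)
    A = rotate_components(A, site_euler)
    return rotate_components(A, (crystallite.alpha, crystallite.beta, crystallite.gamma))


def mas_fourier_components(tensor: Rank2Tensor, site_euler: tuple,
                           crystallite: Crystallite, rotor: RotorSpec) -> np.ndarray:
    """Rotor-frame Fourier coefficients of the lab-frame spatial coefficient.

    Returns ``w[m]``, m = -2..2, such that
    ``omega(t) = sum_m w[m] exp(i m omega_r t)`` (real-valued).  The lab-frame
    ``m' = 0`` spherical component under spinning is
    ``sum_m d2[0, m](theta_rot) exp(-i m omega_r t) A2m(rotor frame)``, so
    ``w[m] = d2[0, -m](theta_rot) A2,-m``; the ``m = 0`` coefficient carries
    ``P2(cos theta_rot)`` and vanishes at the magic angle.
    """
    A = rotor_frame_components(tensor, site_euler, crystallite)
    d0 = wigner_d2(rotor.theta_rot)[2, :]  # d2[0, m](theta_rot)
    return (d0 * A)[::-1]


def mas_frequency(tensor: Rank2Tensor, site_euler: tuple, crystallite: Crystallite,
                  rotor: RotorSpec, t: np.ndarray) -> np.ndarray:
    """Instantaneous spatial coefficient ``omega(t)`` in rad/s under (off-)MAS."""
    w = mas_fourier_components(tensor, site_euler, crystallite, rotor)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    m = np.arange(-2, 3)
    phases = np.exp(1j * np.outer(t, m) * rotor.omega_r)
    out = (phases @ w).real
    return out if out.size > 1 else out[0]


# ---------------------------------------------------------------------------
# ZCW powder scheme
# ---------------------------------------------------------------------------

def _fibonacci_upto(n: int):
    fibs = [1, 2]
    while fibs[-1] < n:
        fibs.append(fibs[-1] + fibs[-2])
    return fibs


def zcw_orientations(n_target: int, three_angle: bool = False) -> list:
    """Deterministic ZCW-style powder orientations with equal weights.

    Uses the Fibonacci-number ZCW recursion; when ``n_target`` is not a ZCW
    set size the nearest set with at least ``n_target`` orientations is
    returned (the actual count is ``len(result)``).  With ``three_angle`` the
    gamma angle is distributed as a third quasi-uniform ZCW coordinate;
    otherwise gamma is 0.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if n_target == 1:
        return [Crystallite(0.0, THETA_MAGIC, 0.0, 1.0)]
    fibs = _fibonacci_upto(max(n_target, 5))
    k = next(i for i, f in enumerate(fibs) if f >= n_target)
    k = max(k, 3)
    N, g1 = fibs[k], fibs[k - 2]
    # the second increment must avoid resonances with g1 (g1 + F[k-3] = F[k-1]
    # would anti-correlate alpha and gamma); F[k-4] decorrelates the lattice
    g2 = fibs[k - 4] if k >= 4 else 1
    j = np.arange(N)
    alpha = 2.0 * math.pi * np.mod(j * g1 / N, 1.0)
    cosbeta = 2.0 * np.mod((j + 0.5) / N, 1.0) - 1.0
    beta = np.arccos(np.clip(cosbeta, -1.0, 1.0))
    gamma = 2.0 * math.pi * np.mod(j * g2 / N, 1.0) if three_angle else np.zeros(N)
    w = 1.0 / N
    return [Crystallite(float(a), float(b), float(c), w)
            for a, b, c in zip(alpha, beta, gamma)]


def crystallites_to_csv(crystallites, path) -> None:
    """Write a powder scheme as CSV columns (alpha, beta, gamma, weight)."""
    import pandas as pd

    pd.DataFrame(
        [(c.alpha, c.beta, c.gamma, c.weight) for c in crystallites],
        columns=["alpha", "beta", "gamma", "weight"],
    ).to_csv(path, index=False)
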