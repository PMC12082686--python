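"""Spin operator algebra in Hilbert space and its lift to Liouville space.

Angular-momentum operators are built for arbitrary spin quantum number
(``hbar = 1``; all interaction strengths elsewhere in the package are angular
frequencies in rad/s).  Density operators are vectorized in **row-major
(C) order**, i.e. ``vec(rho) = rho.reshape(-1)``.  Under this convention the
commutation superoperator of a Hamiltonian ``H`` is

    L = H (x) 1  -  1 (x) H^T

so that ``L @ vec(rho) == vec(H @ rho - rho @ H)``, and a unitary sandwich
``rho -> U rho U^+`` lifts to ``U (x) conj(U)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpinOperatorSet",
    "make_spin_operators",
    "embed_two_spin",
    "commutation_superop",
    "sandwich_superop",
    "vec",
    "unvec",
]


@dataclass(frozen=True)
class SpinOperatorSet:
    """Angular-momentum matrices for a single spin.

    Attributes
    ----------
    s : float
        Spin quantum number (1/2, 1, 3/2, ...).
    Ix, Iy, Iz, Ip, Im, identity : ndarray
        Complex ``(2s+1, 2s+1)`` matrices; ``Ip``/``Im`` are the raising and
        lowering operators.
    """

    s: float
    Ix: np.ndarray = field(repr=False)
    Iy: np.ndarray = field(repr=False)
    Iz: np.ndarray = field(repr=False)
    Ip: np.ndarray = field(repr=False)
    Im: np.ndarray = field(repr=False)
    identity: np.ndarray = field(repr=False)

    @property
    def dim(self) -> int:
        return self.Iz.shape[0]


def make_spin_operators(s: float) -> SpinOperatorSet:
    """Construct the standard angular-momentum matrices for spin ``s``.

    Raises
    ------
    ValueError
        If ``2 s`` is not a positive integer.
    """
    two_s = 2 * s
    if abs(two_s - round(two_s)) > 1e-12 or round(two_s) < 1:
        raise ValueError(f"non-physical spin quantum number s={s!r}; 2s must be a positive integer")
    s = round(two_s) / 2.0
    dim = int(round(two_s)) + 1
    m = s - np.arange(dim)  # s, s-1, ..., -s
    Iz = np.diag(m).astype(complex)
    # <m+1| I+ |m> = sqrt(s(s+1) - m(m+1))
    cp = np.sqrt(s * (s + 1) - m[1:] * (m[1:] + 1))
    Ip = np.zeros((dim, dim), dtype=complex)
    Ip[np.arange(dim - 1), np.arange(1, dim)] = cp
    Im = Ip.conj().T
    Ix = 0.5 * (Ip + Im)
    Iy = -0.5j * (Ip - Im)
    return SpinOperatorSet(s=s, Ix=Ix, Iy=Iy, Iz=Iz, Ip=Ip, Im=Im,
                           identity=np.eye(dim, dtype=complex))


def embed_two_spin(opI: np.ndarray, opS: np.ndarray) -> np.ndarray:
    """Embed single-spin operators into the I (x) S product space.

    Both arguments must be 2x2 (the heteronuclear two-spin systems handled
    here are spin-1/2 pairs); spin I is the left tensor factor.
    """
    opI = np.asarray(opI)
    opS = np.asarray(opS)
    if opI.shape != (2, 2) or opS.shape != (2, 2):
        raise ValueError(f"expected 2x2 operators, got {opI.shape} and {opS.shape}")
    return np.kron(opI, opS)


def vec(rho: np.ndarray) -> np.ndarray:
    """Row-major vectorization of an operator."""
    return np.asarray(rho).reshape(-1)


def unvec(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vec`."""
    v = np.asarray(v)
    d = int(round(np.sqrt(v.size)))
    return v.reshape(d, d)


def commutation_superop(H: np.ndarray) -> np.ndarray:
    """Commutation superoperator of ``H`` acting on row-major vectorized operators.

    ``commutation_superop(H) @ vec(rho)`` equals ``vec(H @ rho - rho @ H)``.
    For Hermitian ``H`` the eigenvalues are the transition frequencies
    ``E_a - E_b`` (real), so ``-1j * L`` generates coherent evolution.
    """
    H = np.asarray(H, dtype=complex)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError(f"Hamiltonian must be square, got shape {H.shape}")
    d = H.shape[0]
    eye = np.eye(d, dtype=complex)
    return np.kron(H, eye) - np.kron(eye, H.T)


def sandwich_superop(U: np.ndarray) -> np.ndarray:
    """Superoperator of the unitary sandwich ``rho -> U rho U^+``."""
    U = np.asarray(U, dtype=complex)
    return np.kron(U, U.conj())
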