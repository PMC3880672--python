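"""Finite-deformation kinematics at a material point.

Deformation measures (C, B, J), the classical isotropic invariants, the
structural quasi-invariants of a fibre/sheet/sheet-normal triad, and the
residual-stress invariants ``I6 = tr(tau C)``, ``I7 = tr(tau C^2)``,
``I8 = tr(tau^2 C)``, ``I9 = tr(tau^2 C^2)``.

All tensors live in a fixed global Cartesian basis; fibre frames are stored
per material point.  Every function broadcasts over leading axes, so a
transmural profile of deformation states is one stacked call, not a loop.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

#: Relative tolerance for incompressibility and symmetry checks.
REL_TOL = 1e-8

_EYE = np.eye(3)


def _sym_check(t: np.ndarray, name: str, scale: float | None = None) -> None:
    t = np.asarray(t, dtype=float)
    if t.shape[-2:] != (3, 3):
        raise InvalidInputError(f"{name} must be a 3x3 tensor (got shape {t.shape})")
    if not np.all(np.isfinite(t)):
        raise InvalidInputError(f"{name} contains non-finite entries")
    s = scale if scale is not None else max(float(np.max(np.abs(t))), 1.0)
    if np.max(np.abs(t - np.swapaxes(t, -1, -2))) > REL_TOL * s:
        raise InvalidInputError(f"{name} is not symmetric within tolerance")


@dataclass(frozen=True)
class DeformationState:
    """Deformation gradient ``F`` with derived measures.

    Attributes
    ----------
    F : ndarray, shape (..., 3, 3)
        Deformation gradient (dimensionless).
    C : ndarray
        Right Cauchy-Green tensor ``F^T F``.
    B : ndarray
        Left Cauchy-Green tensor ``F F^T``.
    J : ndarray or float
        ``det F``; the material model assumes ``J = 1`` (incompressibility),
        and `isochoric` records whether that holds within `REL_TOL`.
    """

    F: np.ndarray
    C: np.ndarray = field(repr=False)
    B: np.ndarray = field(repr=False)
    J: np.ndarray
    isochoric: bool


def make_deformation(F) -> DeformationState:
    """Build a `DeformationState` from a deformation gradient.

    Raises
    ------
    InvalidInputError
        If ``F`` is non-finite or ``det F <= 0``.  A ``J != 1`` state is
        allowed (it is flagged, not rejected): the strain-route residual
        stress estimator legitimately consumes non-isochoric strain data.
    """
    F = np.asarray(F, dtype=float)
    if F.shape[-2:] != (3, 3):
        raise InvalidInputError(f"F must be a 3x3 tensor (got shape {F.shape})")
    if not np.all(np.isfinite(F)):
        raise InvalidInputError("F contains non-finite entries")
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise InvalidInputError("det F must be positive (orientation-preserving)")
    Ft = np.swapaxes(F, -1, -2)
    C = Ft @ F
    B = F @ Ft
    isochoric = bool(np.max(np.abs(J - 1.0)) <= REL_TOL)
    return DeformationState(F=F, C=C, B=B, J=J, isochoric=isochoric)


def _unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != 3:
        raise InvalidInputError(f"{name} must be a 3-vector")
    n = np.linalg.norm(v, axis=-1)
    if np.any(np.abs(n - 1.0) > 1e-6):
        raise InvalidInputError(f"{name} must be a unit vector")
    return v


@dataclass(frozen=True)
class FibreFrame:
    """Orthonormal material triad: fibre ``f0``, sheet ``s0``, sheet-normal ``n0``.

    ``n0 = f0 x s0`` holds by construction when built with `from_fs`.
    """

    f0: np.ndarray
    s0: np.ndarray
    n0: np.ndarray

    @classmethod
    def from_fs(cls, f0, s0) -> "FibreFrame":
        """Build a frame from fibre and sheet directions; ``n0 = f0 x s0``."""
        f0 = _unit(f0, "f0")
        s0 = _unit(s0, "s0")
        dot = np.sum(f0 * s0, axis=-1)
        if np.any(np.abs(dot) > 1e-6):
            raise InvalidInputError("f0 and s0 must be orthogonal")
        return cls(f0=f0, s0=s0, n0=np.cross(f0, s0))

    @classmethod
    def canonical(cls) -> "FibreFrame":
        """The frame aligned with the global axes (f0=e1, s0=e2, n0=e3)."""
        return cls.from_fs(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))

    def as_matrix(self) -> np.ndarray:
        """Rows are (f0, s0, n0): the rotation taking global to frame components."""
        return np.stack([self.f0, self.s0, self.n0], axis=-2)

    def validate(self) -> None:
        """Check unit norms, pairwise orthogonality, and n0 = f0 x s0."""
        for v, nm in ((self.f0, "f0"), (self.s0, "s0"), (self.n0, "n0")):
            _unit(v, nm)
        if np.max(np.abs(np.sum(self.f0 * self.s0, axis=-1))) > 1e-6:
            raise InvalidInputError("f0 and s0 are not orthogonal")
        if np.max(np.abs(self.n0 - np.cross(self.f0, self.s0))) > 1e-6:
            raise InvalidInputError("n0 is not f0 x s0")


@dataclass(frozen=True)
class InvariantSet:
    """Scalar invariants of a deformation state, frame, and residual stress.

    ``I1, I2, I4*, I5*`` are dimensionless; ``I6, I7`` carry kPa and
    ``I8, I9`` kPa^2 when the residual stress is in kPa.  The residual
    invariants are ``None`` unless a residual stress tensor was supplied.

    ``I2`` is computed for completeness only: no energy in this package
    uses it.
    """

    I1: np.ndarray
    I2: np.ndarray
    I4f: np.ndarray
    I4s: np.ndarray
    I4fs: np.ndarray
    I4n: np.ndarray
    I5f: np.ndarray
    I5s: np.ndarray
    I5n: np.ndarray
    I6: np.ndarray | None = None
    I7: np.ndarray | None = None
    I8: np.ndarray | None = None
    I9: np.ndarray | None = None


def _dot(v, M, w):
    # v . (M w) with broadcasting over leading axes
    return np.einsum("...i,...ij,...j->...", v, M, w)


def structural_invariants(state: DeformationState, frame: FibreFrame) -> InvariantSet:
    """Isotropic and structural quasi-invariants of ``C`` in the given frame.

    Returns I1, I2, I4f, I4s, I4fs, I4n, I5f, I5s, I5n.  For an orthonormal
    triad the identity ``I1 = I4f + I4s + I4n`` holds exactly (up to
    round-off), because the I4s are the diagonal of ``C`` in the frame.
    """
    C = state.C
    C2 = C @ C
    trC = np.trace(C, axis1=-2, axis2=-1)
    I1 = trC
    I2 = 0.5 * (trC**2 - np.trace(C2, axis1=-2, axis2=-1))
    f0, s0, n0 = frame.f0, frame.s0, frame.n0
    return InvariantSet(
        I1=I1,
        I2=I2,
        I4f=_dot(f0, C, f0),
        I4s=_dot(s0, C, s0),
        I4fs=_dot(f0, C, s0),
        I4n=_dot(n0, C, n0),
        I5f=_dot(f0, C2, f0),
        I5s=_dot(s0, C2, s0),
        I5n=_dot(n0, C2, n0),
    )


def residual_invariants(state: DeformationState, tau) -> tuple:
    """Residual-stress invariants ``(I6, I7, I8, I9)``.

    ``I6 = tr(tau C)``, ``I7 = tr(tau C^2)``, ``I8 = tr(tau^2 C)``,
    ``I9 = tr(tau^2 C^2)``.  At ``F = I`` these reduce to
    ``I6 = I7 = tr(tau)`` and ``I8 = I9 = tr(tau^2)``.

    ``tau`` may be a bare symmetric 3x3 array or anything with a ``.tau``
    attribute holding one.
    """
    t = np.asarray(getattr(tau, "tau", tau), dtype=float)
    _sym_check(t, "tau")
    C = state.C
    C2 = C @ C
    t2 = t @ t
    tr = lambda M: np.trace(M, axis1=-2, axis2=-1)  # noqa: E731
    return tr(t @ C), tr(t @ C2), tr(t2 @ C), tr(t2 @ C2)


def invariants(state: DeformationState, frame: FibreFrame, tau=None) -> InvariantSet:
    """All invariants at once; residual ones filled only when ``tau`` is given."""
    inv = structural_invariants(state, frame)
    if tau is None:
        return inv
    I6, I7, I8, I9 = residual_invariants(state, tau)
    return InvariantSet(
        I1=inv.I1, I2=inv.I2, I4f=inv.I4f, I4s=inv.I4s, I4fs=inv.I4fs,
        I4n=inv.I4n, I5f=inv.I5f, I5s=inv.I5s, I5n=inv.I5n,
        I6=I6, I7=I7, I8=I8, I9=I9,
    )
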