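"""Transmural fibre architecture for the cylindrical ventricle surrogate.

The myocyte (fibre) direction rotates helically through the wall and the
laminar sheet planes tilt with it.  On a cylinder with local orthonormal
basis (e_r, e_theta, e_z) the frame at wall-depth fraction ``xi`` (0 at the
endocardium, 1 at the epicardium) is

    f0 = cos(phi) e_theta + sin(phi) e_z
    s0 = e_r rotated about f0 by the sheet angle beta
    n0 = f0 x s0

with ``phi`` and ``beta`` varying linearly in ``xi``.  Defaults: fibre
angle +60 deg (endo) to -60 deg (epi), sheet angle -45 deg to +45 deg.
Tensors are expressed pointwise in the cylindrical basis treated as a
Cartesian triad (axisymmetry makes this exact): index 0 = radial,
1 = circumferential, 2 = axial.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .kinematics import FibreFrame

E_R = np.array([1.0, 0.0, 0.0])
E_TH = np.array([0.0, 1.0, 0.0])
E_Z = np.array([0.0, 0.0, 1.0])


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle) -> np.ndarray:
    """Rotate vector(s) v about unit axis by angle (radians), broadcasting."""
    angle = np.asarray(angle, dtype=float)[..., None]
    c, s = np.cos(angle), np.sin(angle)
    k = axis / np.linalg.norm(axis, axis=-1, keepdims=True)
    return (v * c + np.cross(k, v) * s
            + k * np.sum(k * v, axis=-1, keepdims=True) * (1.0 - c))


@dataclass(frozen=True)
class FibreRule:
    """Linear transmural rule for fibre angle phi and sheet angle beta (degrees)."""

    phi_endo_deg: float = 60.0
    phi_epi_deg: float = -60.0
    beta_endo_deg: float = -45.0
    beta_epi_deg: float = 45.0

    def angles(self, xi):
        """(phi, beta) in radians at wall-depth fraction xi in [0, 1]."""
        xi = np.asarray(xi, dtype=float)
        if np.any(xi < -1e-12) or np.any(xi > 1 + 1e-12):
            raise InvalidInputError("wall-depth fraction xi must lie in [0, 1]")
        phi = np.deg2rad(self.phi_endo_deg + (self.phi_epi_deg - self.phi_endo_deg) * xi)
        beta = np.deg2rad(self.beta_endo_deg + (self.beta_epi_deg - self.beta_endo_deg) * xi)
        return phi, beta

    def frame_at(self, xi) -> FibreFrame:
        """Orthonormal (f0, s0, n0) in cylindrical components at xi (broadcasts)."""
        phi, beta = self.angles(xi)
        cphi, sphi = np.cos(phi), np.sin(phi)
        f0 = np.stack([np.zeros_like(cphi), cphi, sphi], axis=-1)
        s0 = _rodrigues(np.broadcast_to(E_R, f0.shape), f0, beta)
        n0 = np.cross(f0, s0)
        return FibreFrame(f0=f0, s0=s0, n0=n0)


def circumferential_rule() -> FibreRule:
    """All fibres circumferential, sheets radial: f0=e_theta, s0=e_r, n0=-e_z...

    Used for axis-aligned checks: at phi=0, beta=0 the triad is
    (e_theta, e_r, -e_z), so tau_ff = tau_thth and tau_ss = tau_rr.
    """
    return FibreRule(phi_endo_deg=0.0, phi_epi_deg=0.0,
                     beta_endo_deg=0.0, beta_epi_deg=0.0)
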