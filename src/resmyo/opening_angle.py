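"""Residual stress of a closed tube from an opened stress-free sector.

A radially cut ventricular ring springs open into a sector of opening
angle ``alpha``; the opening-angle method takes that opened sector as the
stress-free configuration and computes the stress locked into the closed,
unloaded tube.  With sector radii ``R_i <= R <= R_o``, circumferential
span ``2 pi - alpha``, and axial stretch ``lambda_z``, the (isochoric)
sector-to-tube map is

    r(R) = sqrt((R^2 - R_i^2) / (kappa lambda_z) + r_i^2),
    kappa = 2 pi / (2 pi - alpha),

with principal stretches ``lambda_r = R / (r kappa lambda_z)``,
``lambda_th = kappa r / R``, so ``lambda_r lambda_th lambda_z = 1``
identically.  The closed inner radius ``r_i`` is not free: it is fixed by
requiring the radial residual stress, obtained by integrating the only
non-trivial equilibrium equation

    d tau_rr / dr + (tau_rr - tau_thth) / r = 0,

from ``tau_rr(r_i) = 0``, to vanish at the outer surface as well.  The
Lagrange pressure is closed by the same radial integration; the
circumferential and axial stresses follow from the constitutive response
(ground-matrix part by default, full orthotropic law as an option).
Rotating the cylindrical-axis field into the fibre frame gives the
residual stress tensor the constitutive model consumes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_simpson, simpson
from scipy.optimize import brentq

from .constitutive import MaterialParams, ResidualStressTensor, _sigma_hat
from .errors import InvalidInputError, SolverError
from .fibres import FibreRule
from .kinematics import make_deformation

#: Default tolerances of the r_i root solve (cm) and the stress quadrature (kPa).
ROOT_XTOL = 1e-10
QUAD_ATOL = 1e-8


@dataclass(frozen=True)
class CylinderGeometry:
    """Opened-sector geometry: radii in cm, opening angle stored in radians.

    ``kappa = 2 pi / (2 pi - alpha) >= 1`` measures the opening;
    ``kappa = 1`` iff ``alpha = 0`` (no cut opening, stress-free tube).
    """

    R_i: float
    R_o: float
    alpha: float = 0.0
    lambda_z: float = 1.0
    L: float = 1.0

    def __post_init__(self):
        if not (0 < self.R_i < self.R_o):
            raise InvalidInputError("need 0 < R_i < R_o")
        if not (0 <= self.alpha < 2 * np.pi):
            raise InvalidInputError("opening angle must lie in [0, 2 pi)")
        if self.lambda_z <= 0 or self.L <= 0:
            raise InvalidInputError("lambda_z and L must be positive")

    @classmethod
    def from_degrees(cls, R_i, R_o, alpha_deg, lambda_z=1.0, L=1.0):
        return cls(R_i=R_i, R_o=R_o, alpha=np.deg2rad(alpha_deg),
                   lambda_z=lambda_z, L=L)

    @property
    def kappa(self) -> float:
        return 2 * np.pi / (2 * np.pi - self.alpha)


def close_sector(geom: CylinderGeometry, r_i: float, R=None):
    """Sector-to-tube map: radii ``r(R)`` and stretches for closed inner radius r_i.

    Returns ``(r, lambda_r, lambda_th)`` evaluated at ``R`` (defaults to
    the sector radii span).  The map is monotone in R and pointwise
    isochoric: ``lambda_r * lambda_th * lambda_z = 1``.
    """
    if r_i <= 0:
        raise InvalidInputError("closed inner radius r_i must be positive")
    if R is None:
        R = np.array([geom.R_i, geom.R_o])
    R = np.asarray(R, dtype=float)
    k, lz = geom.kappa, geom.lambda_z
    r = np.sqrt((R**2 - geom.R_i**2) / (k * lz) + r_i**2)
    lam_r = R / (r * k * lz)
    lam_th = k * r / R
    return r, lam_r, lam_th


@dataclass(frozen=True)
class ResidualStressProfileCyl:
    """Residual stress of the closed tube on a radial grid (cylindrical axes).

    ``tau_cyl`` has shape ``(n, 3, 3)`` with index order (r, theta, z);
    ``tau_rr``, ``tau_thth``, ``tau_zz`` are views of its diagonal.
    ``tau_rr`` vanishes at both wall surfaces within solver tolerance.
    """

    r: np.ndarray
    tau_cyl: np.ndarray
    geometry: CylinderGeometry
    r_i: float
    r_o: float

    @property
    def tau_rr(self):
        return self.tau_cyl[:, 0, 0]

    @property
    def tau_thth(self):
        return self.tau_cyl[:, 1, 1]

    @property
    def tau_zz(self):
        return self.tau_cyl[:, 2, 2]

    @property
    def xi(self):
        return (self.r - self.r_i) / (self.r_o - self.r_i)

    def equilibrium_residual(self) -> np.ndarray:
        """|d tau_rr/dr + (tau_rr - tau_thth)/r| on the grid (kPa/cm)."""
        d = np.gradient(self.tau_rr, self.r)
        return np.abs(d + (self.tau_rr - self.tau_thth) / self.r)

    def self_equilibrium_integral(self) -> float:
        """integral of (tau_thth - tau_rr)/r over the wall; zero when balanced."""
        return float(simpson((self.tau_thth - self.tau_rr) / self.r, x=self.r))


def _sector_sigma_hat(geom, params, energy_mode, fibre_rule, r_i, R):
    """Constitutive stress (pressure excluded) of the sector-to-tube map at R."""
    r, lam_r, lam_th = close_sector(geom, r_i, R)
    n = r.shape[0]
    F = np.zeros((n, 3, 3))
    F[:, 0, 0] = lam_r
    F[:, 1, 1] = lam_th
    F[:, 2, 2] = geom.lambda_z
    state = make_deformation(F)
    if energy_mode == "isotropic":
        p = params.isotropic_part()
        rule = fibre_rule or FibreRule()
    elif energy_mode == "orthotropic":
        p = params
        rule = fibre_rule or FibreRule()
    else:
        raise InvalidInputError(f"unknown energy_mode {energy_mode!r}")
    # xi needs the final r_i, r_o of this trial map
    r_o = r[-1] if R[-1] == geom.R_o else close_sector(geom, r_i)[0][-1]
    xi = np.clip((r - r_i) / (r_o - r_i), 0.0, 1.0)
    frame = rule.frame_at(xi)
    sigma_hat, _ = _sigma_hat("baseline", p, state, frame, None)
    return r, sigma_hat


def solve_residual_field(geom: CylinderGeometry, params: MaterialParams | None = None,
                         energy_mode: str = "isotropic",
                         fibre_rule: FibreRule | None = None,
                         n_radial: int = 201,
                         bracket: tuple = (0.2, 2.0),
                         root_xtol: float = ROOT_XTOL) -> ResidualStressProfileCyl:
    """Solve the opening-angle boundary-value problem for the closed tube.

    Finds the closed inner radius ``r_i`` (bracketed between
    ``bracket[0]*R_i`` and ``bracket[1]*R_i``) such that the integrated
    radial stress is traction-free at both surfaces, then assembles the
    full residual stress profile on an ``n_radial``-point grid.

    With ``alpha = 0`` the map is the identity and the field is zero.
    """
    params = params or MaterialParams.default()
    if n_radial < 5:
        raise InvalidInputError("n_radial must be >= 5")
    # internal fine grid for the quadrature; results restricted to n_radial
    n_fine = max(4 * (n_radial - 1), 800) + 1
    R = np.linspace(geom.R_i, geom.R_o, n_fine)

    def tau_rr_outer(r_i):
        r, sig = _sector_sigma_hat(geom, params, energy_mode, fibre_rule, r_i, R)
        integrand = (sig[:, 1, 1] - sig[:, 0, 0]) / r
        return simpson(integrand, x=r)

    if geom.alpha == 0 and geom.lambda_z == 1.0:
        r_i_closed = geom.R_i
    else:
        lo, hi = bracket[0] * geom.R_i, bracket[1] * geom.R_i
        flo, fhi = tau_rr_outer(lo), tau_rr_outer(hi)
        if flo * fhi > 0:
            raise SolverError(
                f"no admissible r_i in bracket [{lo:.4g}, {hi:.4g}] cm: "
                f"residual tau_rr(r_o) = {flo:.4g} and {fhi:.4g} kPa")
        r_i_closed = brentq(tau_rr_outer, lo, hi, xtol=root_xtol)

    r_fine, sig = _sector_sigma_hat(geom, params, energy_mode, fibre_rule,
                                    r_i_closed, R)
    integrand = (sig[:, 1, 1] - sig[:, 0, 0]) / r_fine
    tau_rr = cumulative_simpson(integrand, x=r_fine, initial=0.0)
    p = sig[:, 0, 0] - tau_rr
    tau_fine = sig - p[:, None, None] * np.eye(3)

    idx = np.linspace(0, n_fine - 1, n_radial).round().astype(int)
    return ResidualStressProfileCyl(
        r=r_fine[idx], tau_cyl=tau_fine[idx], geometry=geom,
        r_i=float(r_fine[0]), r_o=float(r_fine[-1]))


def rotate_to_fibre_frame(profile: ResidualStressProfileCyl,
                          fibre_rule: FibreRule | None = None,
                          keep_shear: bool = False) -> ResidualStressTensor:
    """Express the cylindrical-axis residual stress in the fibre frame.

    Components are ``tau_ab = a . tau_cyl b`` for a, b in (f0, s0, n0);
    the rotation preserves trace and eigenvalues.  Fibre-frame shear
    components are small but non-zero for a helical fibre rule; they are
    zeroed by default (negligible-shear rule) unless ``keep_shear``.
    """
    rule = fibre_rule or FibreRule()
    frame = rule.frame_at(profile.xi)
    frame.validate()
    Q = frame.as_matrix()             # rows f0, s0, n0 in cylindrical components
    tau_fib = Q @ profile.tau_cyl @ np.swapaxes(Q, -1, -2)
    if keep_shear:
        return ResidualStressTensor(tau=tau_fib)
    d = np.einsum("...ii->...i", tau_fib).copy()
    tau_diag = np.zeros_like(tau_fib)
    np.einsum("...ii->...i", tau_diag)[...] = d
    return ResidualStressTensor(tau=tau_diag, principal=True,
                                tau_ff=d[..., 0], tau_ss=d[..., 1], tau_nn=d[..., 2])
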