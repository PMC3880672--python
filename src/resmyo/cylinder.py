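"""Diastolic inflation of a residually stressed thick-walled cylinder.

A desk-scale surrogate of the passive left ventricle: the wall is an
incompressible, fibre-reinforced thick-walled tube (the same tube the
opening-angle method closes), loaded by an endocardial pressure P of
0-8 mmHg at fixed axial stretch.  The axisymmetric plane deformation

    r(R) = sqrt(r_i_def^2 + (R^2 - R_i^2) / lambda_z)

is exactly isochoric; the deformed inner radius is found by shooting on
the radial equilibrium equation

    d sigma_rr / dr + (sigma_rr - sigma_thth) / r = 0,
    sigma_rr(r_i_def) = -P,   sigma_rr(r_o_def) = 0,

whose integrated form also closes the Lagrange pressure p pointwise.
The total Cauchy stress includes the residual-stress contribution of the
chosen model (``simple``: Sigma = F tau F^T; ``extended``:
Sigma/2 + (Sigma B + B Sigma)/4), with tau the residual field of the
unloaded wall supplied by either estimation route.

Units: radii cm, stresses kPa, pressures mmHg at the interface
(1 mmHg = 0.133322 kPa internally).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_simpson, simpson
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .constitutive import MaterialParams, _sigma_hat
from .errors import InvalidInputError, SolverError
from .fibres import FibreRule
from .kinematics import make_deformation
from .opening_angle import ResidualStressProfileCyl
from .residual_strain import ResidualStrainProfile, estimate_profile

MMHG_TO_KPA = 0.133322

MODELS_WITH_TAU = ("simple", "extended")


@dataclass(frozen=True)
class TubeGeometry:
    """Unloaded (residually stressed) tube: inner/outer radii in cm."""

    r_i: float
    r_o: float
    lambda_z: float = 1.0

    def __post_init__(self):
        if not (0 < self.r_i < self.r_o):
            raise InvalidInputError("need 0 < r_i < r_o")
        if self.lambda_z <= 0:
            raise InvalidInputError("lambda_z must be positive")


class TauField:
    """Residual stress across the unloaded wall, as a function of depth xi.

    Stores cylindrical-axis components on a xi grid and interpolates
    componentwise with monotone (PCHIP) cubics, so sampling any radial
    grid introduces no overshoot.
    """

    def __init__(self, xi: np.ndarray, tau_cyl: np.ndarray):
        xi = np.asarray(xi, dtype=float)
        tau_cyl = np.asarray(tau_cyl, dtype=float)
        if xi.ndim != 1 or tau_cyl.shape != (xi.size, 3, 3):
            raise InvalidInputError("xi must be 1-D and tau_cyl shaped (n, 3, 3)")
        if np.any(np.diff(xi) <= 0):
            raise InvalidInputError("xi must be strictly increasing")
        self.xi = xi
        self.tau_cyl = tau_cyl
        self._interp = PchipInterpolator(xi, tau_cyl, axis=0, extrapolate=False)

    def at(self, xi) -> np.ndarray:
        """tau (cylindrical components) at wall-depth fraction xi, shape (..., 3, 3)."""
        xi = np.clip(np.asarray(xi, dtype=float), self.xi[0], self.xi[-1])
        return self._interp(xi)

    def scaled(self, factor: float) -> "TauField":
        """A copy with tau multiplied by ``factor`` (sensitivity studies)."""
        return TauField(self.xi, factor * self.tau_cyl)

    @classmethod
    def from_opening_angle(cls, profile: ResidualStressProfileCyl) -> "TauField":
        return cls(profile.xi, profile.tau_cyl)

    @classmethod
    def from_strain_profile(cls, profile: ResidualStrainProfile,
                            params: MaterialParams,
                            fibre_rule: FibreRule | None = None,
                            variant: str = "isotropic") -> "TauField":
        """Estimate tau from measured strains and rotate it to cylindrical axes.

        The strain components are given in the fibre frame; the fibre rule
        supplies the frame at each depth, so
        ``tau_cyl = Q^T tau_fib Q`` with Q rows the frame vectors.
        """
        rule = fibre_rule or FibreRule()
        tau_fib = estimate_profile(profile, params, variant=variant).tau
        Q = rule.frame_at(profile.xi).as_matrix()
        tau_cyl = np.swapaxes(Q, -1, -2) @ tau_fib @ Q
        return cls(profile.xi, tau_cyl)


@dataclass(frozen=True)
class InflationSolution:
    """Transmural stress state of the inflated tube.

    ``sigma_cyl`` holds (r, theta, z) components on the deformed radial
    grid ``r``; ``sigma_ff/ss/nn`` are normal stresses along the deformed
    (push-forward, normalised) fibre, sheet, and sheet-normal directions.
    ``cavity_area`` is the deformed cavity cross-section pi r_i_def^2
    (cm^2), i.e. cavity volume per unit axial length.
    """

    P_mmHg: float
    P_kPa: float
    geometry: TubeGeometry
    r: np.ndarray
    xi: np.ndarray
    sigma_cyl: np.ndarray
    sigma_ff: np.ndarray
    sigma_ss: np.ndarray
    sigma_nn: np.ndarray
    p: np.ndarray
    r_i_def: float
    r_o_def: float
    model: str
    cavity_area: float

    @property
    def sigma_rr(self):
        return self.sigma_cyl[:, 0, 0]

    @property
    def sigma_thth(self):
        return self.sigma_cyl[:, 1, 1]

    @property
    def sigma_zz(self):
        return self.sigma_cyl[:, 2, 2]

    def equilibrium_residual(self) -> np.ndarray:
        d = np.gradient(self.sigma_rr, self.r)
        return np.abs(d + (self.sigma_rr - self.sigma_thth) / self.r)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r_cm": self.r, "xi": self.xi,
            "sigma_rr_kPa": self.sigma_rr, "sigma_thth_kPa": self.sigma_thth,
            "sigma_zz_kPa": self.sigma_zz, "sigma_ff_kPa": self.sigma_ff,
            "sigma_ss_kPa": self.sigma_ss, "sigma_nn_kPa": self.sigma_nn,
            "p_kPa": self.p,
        })


def _deformed_sigma_hat(geom, params, model, tau_field, fibre_rule, r_i_def, R):
    """Stress (pressure excluded) of the inflation map at unloaded radii R."""
    r = np.sqrt(r_i_def**2 + (R**2 - geom.r_i**2) / geom.lambda_z)
    lam_th = r / R
    lam_r = R / (r * geom.lambda_z)
    n = R.shape[0]
    F = np.zeros((n, 3, 3))
    F[:, 0, 0] = lam_r
    F[:, 1, 1] = lam_th
    F[:, 2, 2] = geom.lambda_z
    state = make_deformation(F)
    xi = np.clip((R - geom.r_i) / (geom.r_o - geom.r_i), 0.0, 1.0)
    frame = fibre_rule.frame_at(xi)
    tau = None if tau_field is None else tau_field.at(xi)
    sigma_hat, _ = _sigma_hat(model, params, state, frame, tau)
    return r, lam_r, state, frame, sigma_hat


def inflate(geom: TubeGeometry, params: MaterialParams | None = None,
            model: str = "baseline", tau_field: TauField | None = None,
            P_mmHg: float = 0.0, fibre_rule: FibreRule | None = None,
            n_radial: int = 200, root_xtol: float = 1e-10) -> InflationSolution:
    """Inflate the unloaded tube to endocardial pressure ``P_mmHg``.

    ``model='baseline'`` requires ``tau_field=None``; the residual models
    require one.  Shooting brackets the deformed inner radius around the
    unloaded value and enforces ``sigma_rr = -P`` inside, ``0`` outside.
    """
    params = params or MaterialParams.default()
    fibre_rule = fibre_rule or FibreRule()
    if P_mmHg < 0:
        raise InvalidInputError("inflation pressure must be non-negative")
    if model in MODELS_WITH_TAU and tau_field is None:
        raise InvalidInputError(f"model {model!r} requires a residual stress field")
    if model == "baseline" and tau_field is not None:
        raise InvalidInputError("baseline model cannot accept a residual stress field")
    P_kPa = P_mmHg * MMHG_TO_KPA

    n_fine = max(4 * (n_radial - 1), 800) + 1
    R = np.linspace(geom.r_i, geom.r_o, n_fine)

    def outer_traction(r_i_def):
        r, lam_r, _, _, sig = _deformed_sigma_hat(
            geom, params, model, tau_field, fibre_rule, r_i_def, R)
        integrand = (sig[:, 1, 1] - sig[:, 0, 0]) / r * lam_r  # dr = lam_r dR
        return -P_kPa + simpson(integrand, x=R)

    lo, hi = 0.5 * geom.r_i, 3.0 * geom.r_i
    flo, fhi = outer_traction(lo), outer_traction(hi)
    if flo * fhi > 0:
        raise SolverError(
            f"shooting failed to bracket r_i_def in [{lo:.4g}, {hi:.4g}] cm "
            f"at P = {P_mmHg} mmHg (residuals {flo:.4g}, {fhi:.4g} kPa)")
    r_i_def = brentq(outer_traction, lo, hi, xtol=root_xtol)

    r, lam_r, state, frame, sig = _deformed_sigma_hat(
        geom, params, model, tau_field, fibre_rule, r_i_def, R)
    integrand = (sig[:, 1, 1] - sig[:, 0, 0]) / r * lam_r
    sigma_rr = -P_kPa + cumulative_simpson(integrand, x=R, initial=0.0)
    p = sig[:, 0, 0] - sigma_rr
    sigma = sig - p[:, None, None] * np.eye(3)

    def normal_stress(v0):
        v = np.einsum("nij,nj->ni", state.F, v0)
        v = v / np.linalg.norm(v, axis=-1, keepdims=True)
        return np.einsum("ni,nij,nj->n", v, sigma, v)

    idx = np.linspace(0, n_fine - 1, n_radial).round().astype(int)
    xi = (R - geom.r_i) / (geom.r_o - geom.r_i)
    return InflationSolution(
        P_mmHg=float(P_mmHg), P_kPa=float(P_kPa), geometry=geom,
        r=r[idx], xi=xi[idx], sigma_cyl=sigma[idx],
        sigma_ff=normal_stress(frame.f0)[idx],
        sigma_ss=normal_stress(frame.s0)[idx],
        sigma_nn=normal_stress(frame.n0)[idx],
        p=p[idx], r_i_def=float(r[0]), r_o_def=float(r[-1]),
        model=model, cavity_area=float(np.pi * r[0] ** 2))


def pv_curve(geom: TubeGeometry, params: MaterialParams | None = None,
             model: str = "baseline", tau_field: TauField | None = None,
             P_mmHg_grid=None, fibre_rule: FibreRule | None = None,
             n_radial: int = 200) -> pd.DataFrame:
    """Pressure-volume relation over a diastolic pressure grid.

    Volume is the deformed cavity volume per unit unloaded length,
    ``V = pi r_i_def^2 lambda_z`` (cm^3/cm); ``V_norm`` rescales it to
    [0, 1] over the grid for shape (Klotz-style) comparison between runs.
    """
    if P_mmHg_grid is None:
        P_mmHg_grid = np.linspace(0.0, 8.0, 9)
    P_mmHg_grid = np.asarray(P_mmHg_grid, dtype=float)
    if P_mmHg_grid[0] < 0 or np.any(np.diff(P_mmHg_grid) <= 0):
        raise InvalidInputError("pressure grid must be increasing from >= 0")
    vols = []
    for P in P_mmHg_grid:
        sol = inflate(geom, params, model, tau_field, P, fibre_rule, n_radial)
        vols.append(sol.cavity_area * geom.lambda_z)
    vols = np.asarray(vols)
    span = vols[-1] - vols[0]
    vnorm = (vols - vols[0]) / span if span > 0 else np.zeros_like(vols)
    return pd.DataFrame({"P_mmHg": P_mmHg_grid, "V_cm3_per_cm": vols,
                         "V_norm": vnorm})


def compare_models(sol_a: InflationSolution, sol_b: InflationSolution,
                   threshold: float = 0.05) -> dict:
    """Per-component maximum relative difference between two solutions.

    For each of sigma_ff, sigma_ss, sigma_nn the difference is scaled by
    the larger of the two profiles' maximum magnitudes (floored to avoid
    dividing by a vanishing component).  ``within_threshold`` flags the
    "almost identical" regime (default 5%).
    """
    if sol_a.r.shape != sol_b.r.shape or np.max(np.abs(sol_a.xi - sol_b.xi)) > 1e-12:
        raise InvalidInputError("solutions must share the same radial grid")
    out = {}
    for comp in ("sigma_ff", "sigma_ss", "sigma_nn"):
        a, b = getattr(sol_a, comp), getattr(sol_b, comp)
        scale = max(np.max(np.abs(a)), np.max(np.abs(b)), 1e-12)
        out[comp] = float(np.max(np.abs(a - b)) / scale)
    out["within_threshold"] = all(out[c] <= threshold
                                  for c in ("sigma_ff", "sigma_ss", "sigma_nn"))
    return out


def surface_summary(sol: InflationSolution, band: float = 0.1) -> pd.DataFrame:
    """Mean and standard deviation of the fibre-frame normal stresses
    over the sub-endocardial and sub-epicardial bands (innermost and
    outermost ``band`` fraction of the wall grid)."""
    rows = []
    for surface, mask in (("endocardial", sol.xi <= band),
                          ("epicardial", sol.xi >= 1.0 - band)):
        for comp in ("sigma_ff", "sigma_ss", "sigma_nn"):
            v = getattr(sol, comp)[mask]
            rows.append({"surface": surface, "component": comp,
                         "mean_kPa": float(np.mean(v)), "sd_kPa": float(np.std(v))})
    return pd.DataFrame(rows)
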