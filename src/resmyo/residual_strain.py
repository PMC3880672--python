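"""Residual stress estimated from measured transmural residual strains.

Bead-displacement experiments give the Euler-Almansi strain ``e0`` of the
unloaded-but-residually-stressed wall relative to the (fictitious)
stress-free state, sampled across the wall and expressed in the local
fibre frame.  The left Cauchy-Green tensor of that pre-deformation is

    B_r = F0 F0^T = (I - 2 e0)^{-1},

and the residual Cauchy stress follows from the constitutive law with the
Lagrange pressure fixed by the unloaded-configuration condition
``p_r = 2 W1 = a``:

* isotropic route (default) - fibres are assumed relaxed (wavy) in the
  unloaded state, so only the ground-matrix energy acts:

      tau = a exp[b (I1_r - 3)] B_r - a I,   I1_r = tr(B_r);

* orthotropic route (opt-in) - the full eight-parameter energy acts, with
  the tension-only switch, via ``tau = F0 dW/dF0 - a I`` and the
  symmetric square root ``F0 = B_r^{1/2}``.

The estimated field is pointwise and generally does not satisfy radial
equilibrium exactly; `divergence_diagnostic` reports (never enforces) the
discrete residual of d tau_rr/dr + (tau_rr - tau_thth)/r = 0.
"""
from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd

from .constitutive import MaterialParams, ResidualStressTensor, _sigma_hat
from .errors import ConfigurationError, InvalidInputError
from .kinematics import FibreFrame, make_deformation

#: Fibre-frame shear strains below this are treated as negligible (zeroed
#: under the shear-neglect rule); larger shears raise instead of being
#: silently dropped.
SHEAR_TOL = 0.02

_TABLE_COLUMNS = ["xi", "e_ff", "e_ss", "e_nn", "e_fs", "e_fn", "e_sn"]


def _e0_matrix(e_ff, e_ss, e_nn, e_fs, e_fn, e_sn) -> np.ndarray:
    comps = [np.asarray(c, dtype=float) for c in (e_ff, e_ss, e_nn, e_fs, e_fn, e_sn)]
    e_ff, e_ss, e_nn, e_fs, e_fn, e_sn = np.broadcast_arrays(*comps)
    e0 = np.zeros(e_ff.shape + (3, 3))
    e0[..., 0, 0] = e_ff
    e0[..., 1, 1] = e_ss
    e0[..., 2, 2] = e_nn
    e0[..., 0, 1] = e0[..., 1, 0] = e_fs
    e0[..., 0, 2] = e0[..., 2, 0] = e_fn
    e0[..., 1, 2] = e0[..., 2, 1] = e_sn
    return e0


@dataclass(frozen=True)
class ResidualStrainProfile:
    """Transmural Euler-Almansi residual strain in the fibre frame.

    ``xi`` is the wall-depth fraction (0 = endocardium, 1 = epicardium),
    strictly increasing; ``e0`` has shape ``(n, 3, 3)`` with index order
    (f, s, n).  ``I - 2 e0`` must be positive definite at every station.
    """

    xi: np.ndarray
    e0: np.ndarray

    def __post_init__(self):
        xi = np.asarray(self.xi, dtype=float)
        e0 = np.asarray(self.e0, dtype=float)
        if xi.ndim != 1 or e0.shape != (xi.size, 3, 3):
            raise InvalidInputError("xi must be 1-D and e0 shaped (n, 3, 3)")
        if np.any(xi < 0) or np.any(xi > 1) or np.any(np.diff(xi) <= 0):
            raise InvalidInputError("xi must be strictly increasing within [0, 1]")
        if np.max(np.abs(e0 - np.swapaxes(e0, -1, -2))) > 1e-12:
            raise InvalidInputError("e0 must be symmetric")
        admissible(e0, xi)  # raises naming the offending xi
        object.__setattr__(self, "xi", xi)
        object.__setattr__(self, "e0", e0)

    @classmethod
    def from_components(cls, xi, e_ff, e_ss, e_nn, e_fs=0.0, e_fn=0.0, e_sn=0.0):
        xi = np.asarray(xi, dtype=float)
        comps = [np.broadcast_to(np.asarray(c, dtype=float), xi.shape)
                 for c in (e_ff, e_ss, e_nn, e_fs, e_fn, e_sn)]
        return cls(xi=xi, e0=_e0_matrix(*comps))

    @classmethod
    def from_table(cls, path_or_buffer) -> "ResidualStrainProfile":
        """Read the comma-separated columnar format (header row required)."""
        df = pd.read_csv(path_or_buffer)
        missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidInputError(f"strain table is missing columns {missing}")
        return cls.from_components(*(df[c].to_numpy() for c in _TABLE_COLUMNS))

    def to_table(self, path=None) -> str | None:
        """Write the canonical comma-separated table (deterministic formatting)."""
        df = pd.DataFrame({
            "xi": self.xi,
            "e_ff": self.e0[:, 0, 0], "e_ss": self.e0[:, 1, 1],
            "e_nn": self.e0[:, 2, 2], "e_fs": self.e0[:, 0, 1],
            "e_fn": self.e0[:, 0, 2], "e_sn": self.e0[:, 1, 2],
        })
        if path is None:
            buf = StringIO()
            df.to_csv(buf, index=False, float_format="%.8f")
            return buf.getvalue()
        df.to_csv(path, index=False, float_format="%.8f")
        return None

    def shear_magnitude(self) -> np.ndarray:
        off = self.e0[:, [0, 0, 1], [1, 2, 2]]
        return np.max(np.abs(off), axis=-1)

    def drop_shears(self, shear_tol: float = SHEAR_TOL) -> "ResidualStrainProfile":
        """Zero the fibre-frame shear strains (principal-direction reduction).

        Raises if any shear exceeds ``shear_tol``: the negligible-shear
        assumption must hold before it is applied.
        """
        bad = self.shear_magnitude() > shear_tol
        if np.any(bad):
            i = int(np.argmax(bad))
            raise InvalidInputError(
                f"shear strain exceeds shear_tol={shear_tol} at xi={self.xi[i]:.4f}")
        e0 = self.e0.copy()
        e0[:, [0, 0, 1, 1, 2, 2], [1, 2, 0, 2, 0, 1]] = 0.0
        return ResidualStrainProfile(xi=self.xi, e0=e0)


def admissible(e0: np.ndarray, xi=None) -> None:
    """Raise unless ``I - 2 e0`` is positive definite everywhere."""
    e0 = np.asarray(e0, dtype=float)
    A = np.eye(3) - 2.0 * e0
    ev = np.linalg.eigvalsh(A)
    bad = np.min(ev, axis=-1) <= 1e-12
    if np.any(bad):
        if xi is not None and np.ndim(bad) == 1:
            i = int(np.argmax(bad))
            raise InvalidInputError(
                f"I - 2 e0 is singular or indefinite at xi={np.asarray(xi)[i]:.4f}")
        raise InvalidInputError("I - 2 e0 is singular or indefinite")


def strain_to_B(e0) -> np.ndarray:
    """Pre-deformation left Cauchy-Green tensor ``B_r = (I - 2 e0)^{-1}``."""
    e0 = np.asarray(e0, dtype=float)
    admissible(e0)
    return np.linalg.inv(np.eye(3) - 2.0 * e0)


def _sqrtm_spd(B: np.ndarray) -> np.ndarray:
    """Symmetric square root of a (batched) SPD tensor via eigendecomposition."""
    w, V = np.linalg.eigh(B)
    return np.einsum("...ik,...k,...jk->...ij", V, np.sqrt(w), V)


def estimate_tau_isotropic(e0, params: MaterialParams) -> ResidualStressTensor:
    """Residual stress from strain via the ground-matrix energy only.

    ``tau = a exp[b (I1_r - 3)] B_r - a I``; exactly zero at zero strain.
    """
    B_r = strain_to_B(e0)
    I1_r = np.trace(B_r, axis1=-2, axis2=-1)
    coef = params.a * np.exp(params.b * (I1_r - 3.0))
    tau = coef[..., None, None] * B_r - params.a * np.eye(3)
    return ResidualStressTensor(tau=tau)


def estimate_tau_orthotropic(e0, params: MaterialParams,
                             frame: FibreFrame | None = None) -> ResidualStressTensor:
    """Residual stress from strain via the full orthotropic energy.

    The pre-deformation gradient is taken as the rotation-free square root
    ``F0 = B_r^{1/2}``; the fibre terms switch on only where the fibre
    family is extended in the unloaded state (``I4f_r > 1``), so with
    compressed fibres this reduces exactly to the isotropic estimate.
    ``frame`` defaults to the canonical triad, matching strain components
    already expressed in the fibre frame.
    """
    if frame is None:
        frame = FibreFrame.canonical()
    B_r = strain_to_B(e0)
    F0 = _sqrtm_spd(B_r)
    state = make_deformation(F0)
    sigma_hat, _ = _sigma_hat("baseline", params, state, frame, None)
    return ResidualStressTensor(tau=sigma_hat - params.a * np.eye(3))


def estimate_profile(profile: ResidualStrainProfile, params: MaterialParams,
                     variant: str = "isotropic") -> ResidualStressTensor:
    """Per-station residual stress for a whole transmural profile.

    Returns a `ResidualStressTensor` whose ``tau`` is stacked ``(n, 3, 3)``
    in the fibre frame.
    """
    if variant == "isotropic":
        return estimate_tau_isotropic(profile.e0, params)
    if variant == "orthotropic":
        return estimate_tau_orthotropic(profile.e0, params)
    raise ConfigurationError(f"unknown estimator variant {variant!r}")


def divergence_diagnostic(r, tau_rr, tau_thth) -> np.ndarray:
    """Discrete radial-equilibrium residual ``|d tau_rr/dr + (tau_rr - tau_thth)/r|``.

    Units kPa/cm.  Purely diagnostic: strain-measurement-based fields are
    generally not self-equilibrated, and that is reported, not rejected.
    """
    r = np.asarray(r, dtype=float)
    tau_rr = np.asarray(tau_rr, dtype=float)
    tau_thth = np.asarray(tau_thth, dtype=float)
    if r.ndim != 1 or r.size < 3:
        raise InvalidInputError("need at least 3 radial samples for the diagnostic")
    if np.any(np.diff(r) <= 0) or np.any(r <= 0):
        raise InvalidInputError("r must be positive and strictly increasing")
    d = np.gradient(tau_rr, r)
    return np.abs(d + (tau_rr - tau_thth) / r)


@dataclass(frozen=True)
class StrainFixtureConfig:
    """Parameters of the synthetic transmural strain profile.

    Defaults emulate the qualitative structure of canine mid-wall
    measurements: smooth low-order profiles, compressive fibre strain at
    the endocardium and tensile at the epicardium, small cross-fibre
    strains of the opposite trend, and negligible shears.  Endpoint values
    are dimensionless Euler-Almansi components.
    """

    e_ff_endo: float = -0.04
    e_ff_epi: float = 0.06
    e_ss_endo: float = 0.02
    e_ss_epi: float = -0.02
    e_nn_endo: float = 0.01
    e_nn_epi: float = -0.03
    shear_amp: float = 0.005
    curvature: float = 0.02   # amplitude scale of the seeded quadratic bump
    n_points: int = 21
    max_abs: float = 0.1      # admissibility bound on any component

    def __post_init__(self):
        ends = (self.e_ff_endo, self.e_ff_epi, self.e_ss_endo, self.e_ss_epi,
                self.e_nn_endo, self.e_nn_epi)
        if any(abs(v) > self.max_abs for v in ends):
            raise ConfigurationError(
                f"endpoint strain amplitudes must satisfy |e| <= {self.max_abs}")
        if not (0 <= self.shear_amp <= SHEAR_TOL):
            raise ConfigurationError(f"shear_amp must lie in [0, {SHEAR_TOL}]")
        if self.n_points < 3:
            raise ConfigurationError("n_points must be >= 3")


def generate_strain_fixture(config: StrainFixtureConfig | None = None,
                            seed: int = 0) -> ResidualStrainProfile:
    """Deterministic synthetic strain profile (see `StrainFixtureConfig`).

    Each normal component is linear between its endo/epi endpoints plus a
    seeded quadratic bump ``c xi (1 - xi)`` that vanishes at the surfaces,
    so the endpoint signs are exact by construction.  Shears are smooth
    seeded sinusoids bounded by ``shear_amp``.
    """
    cfg = config or StrainFixtureConfig()
    rng = np.random.default_rng(seed)
    xi = np.linspace(0.0, 1.0, cfg.n_points)
    bump = xi * (1.0 - xi)

    def normal(endo, epi):
        c = cfg.curvature * rng.uniform(-1.0, 1.0)
        e = endo + (epi - endo) * xi + c * bump
        return np.clip(e, -cfg.max_abs, cfg.max_abs)

    e_ff = normal(cfg.e_ff_endo, cfg.e_ff_epi)
    e_ss = normal(cfg.e_ss_endo, cfg.e_ss_epi)
    e_nn = normal(cfg.e_nn_endo, cfg.e_nn_epi)

    def shear():
        amp = cfg.shear_amp * rng.uniform(0.3, 1.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        return amp * np.sin(np.pi * xi + phase) * bump * 4.0

    if cfg.shear_amp > 0:
        e_fs, e_fn, e_sn = shear(), shear(), shear()
    else:
        e_fs = e_fn = e_sn = np.zeros_like(xi)
    return ResidualStrainProfile.from_components(xi, e_ff, e_ss, e_nn, e_fs, e_fn, e_sn)
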