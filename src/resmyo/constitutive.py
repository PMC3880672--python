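"""Strain-energy functions and Cauchy stress for passive myocardium.

The baseline material is the eight-parameter orthotropic Holzapfel-Ogden
law,

    W = a/(2b) exp[b(I1 - 3)]
      + sum_{i=f,s} a_i/(2 b_i) {exp[b_i (I4i - 1)^2] - 1}
      + a_fs/(2 b_fs) {exp[b_fs I4fs^2] - 1},

with the fibre and sheet terms active only in tension (I4i > 1), since
myocytes and collagen fibres buckle rather than support compression.

Residual stress enters through the invariants I6 = tr(tau C) and
I7 = tr(tau C^2) without any new material parameter:

* ``simple`` model:   W += 1/2 I6          -> stress term  Sigma
* ``extended`` model: W += 1/4 I6 + 1/8 I7 -> stress term  1/2 Sigma
                                              + 1/4 (Sigma B + B Sigma)

where Sigma = F tau F^T.  The constant derivative coefficients are fixed
by requiring that in the unloaded configuration (F = I, p = a) the Cauchy
stress reduce exactly to tau:

    2 W1 = p_r = a,   2 (W6 + 2 W7) = 1,   W8 + 2 W9 = 0.

The material is incompressible; the Lagrange pressure p is statically
indeterminate pointwise and is fixed by the caller through a traction
condition (see `solve_pressure`), never by the material law itself.

All stress quantities are in kPa.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .errors import ConfigurationError, InvalidInputError
from .kinematics import (
    DeformationState,
    FibreFrame,
    InvariantSet,
    invariants,
    make_deformation,
    residual_invariants,
)

MODELS = ("baseline", "simple", "extended")

_PARAM_KEYS = ("a", "b", "a_f", "b_f", "a_s", "b_s", "a_fs", "b_fs")


@dataclass(frozen=True)
class MaterialParams:
    """The eight Holzapfel-Ogden constants.

    ``a, a_f, a_s, a_fs`` are stress-like moduli in kPa; ``b, b_f, b_s,
    b_fs`` are dimensionless exponents.  All eight must be non-negative.
    """

    a: float
    b: float
    a_f: float
    b_f: float
    a_s: float
    b_s: float
    a_fs: float
    b_fs: float

    def __post_init__(self):
        for k in _PARAM_KEYS:
            v = getattr(self, k)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"material parameter {k} must be >= 0 (got {v})")

    @classmethod
    def from_mapping(cls, mapping) -> "MaterialParams":
        """Strict parse: exactly the eight known keys, nothing else."""
        unknown = set(mapping) - set(_PARAM_KEYS)
        if unknown:
            raise ConfigurationError(f"unknown material parameter keys: {sorted(unknown)}")
        missing = set(_PARAM_KEYS) - set(mapping)
        if missing:
            raise ConfigurationError(f"missing material parameter keys: {sorted(missing)}")
        return cls(**{k: float(mapping[k]) for k in _PARAM_KEYS})

    @classmethod
    def from_file(cls, path) -> "MaterialParams":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigurationError(f"material parameter file {path} is not a flat mapping")
        return cls.from_mapping(data)

    @classmethod
    def default(cls) -> "MaterialParams":
        """Packaged defaults: an orthotropic fit to canine simple-shear data."""
        text = resources.files("resmyo").joinpath("data/material_default.yaml").read_text()
        return cls.from_mapping(yaml.safe_load(text))

    def isotropic_part(self) -> "MaterialParams":
        """Ground-matrix-only copy: the anisotropic moduli set to zero."""
        return MaterialParams(a=self.a, b=self.b, a_f=0.0, b_f=self.b_f,
                              a_s=0.0, b_s=self.b_s, a_fs=0.0, b_fs=self.b_fs)


@dataclass(frozen=True)
class ResidualStressTensor:
    """Symmetric residual Cauchy stress ``tau`` (kPa) at a material point.

    ``principal`` marks a tensor that is diagonal in the fibre frame, in
    which case ``(tau_ff, tau_ss, tau_nn)`` are its principal components.
    """

    tau: np.ndarray
    principal: bool = False
    tau_ff: np.ndarray | None = None
    tau_ss: np.ndarray | None = None
    tau_nn: np.ndarray | None = None

    @classmethod
    def from_matrix(cls, tau) -> "ResidualStressTensor":
        tau = np.asarray(tau, dtype=float)
        _check_tau(tau)
        return cls(tau=tau)

    @classmethod
    def from_principal(cls, tau_ff, tau_ss, tau_nn, frame: FibreFrame) -> "ResidualStressTensor":
        """Assemble ``tau = tau_ff f0xf0 + tau_ss s0xs0 + tau_nn n0xn0``."""
        tau_ff, tau_ss, tau_nn = (np.asarray(t, dtype=float) for t in (tau_ff, tau_ss, tau_nn))
        outer = lambda v: np.einsum("...i,...j->...ij", v, v)  # noqa: E731
        tau = (tau_ff[..., None, None] * outer(frame.f0)
               + tau_ss[..., None, None] * outer(frame.s0)
               + tau_nn[..., None, None] * outer(frame.n0))
        return cls(tau=tau, principal=True, tau_ff=tau_ff, tau_ss=tau_ss, tau_nn=tau_nn)

    @classmethod
    def zero(cls) -> "ResidualStressTensor":
        return cls(tau=np.zeros((3, 3)), principal=True,
                   tau_ff=np.float64(0), tau_ss=np.float64(0), tau_nn=np.float64(0))


def _check_tau(tau: np.ndarray) -> None:
    if tau.shape[-2:] != (3, 3):
        raise InvalidInputError(f"tau must be 3x3 (got shape {tau.shape})")
    if not np.all(np.isfinite(tau)):
        raise InvalidInputError("tau contains non-finite entries")
    scale = max(float(np.max(np.abs(tau))), 1e-30)
    if np.max(np.abs(tau - np.swapaxes(tau, -1, -2))) > 1e-8 * scale:
        raise InvalidInputError("tau must be symmetric")


@dataclass(frozen=True)
class StressResult:
    """Cauchy stress ``sigma = sigma_hat - p I`` with its term breakdown.

    ``parts`` maps term names (``isotropic``, ``fibre``, ``sheet``,
    ``fibre_sheet``, ``residual``) to their contributions to ``sigma_hat``,
    all in kPa.
    """

    sigma: np.ndarray
    p: np.ndarray
    sigma_hat: np.ndarray
    parts: dict


def _as_tau_array(tau):
    if tau is None:
        return None
    t = np.asarray(getattr(tau, "tau", tau), dtype=float)
    _check_tau(t)
    return t


def energy(model: str, params: MaterialParams, inv: InvariantSet):
    """Strain-energy density (kPa) for the requested model.

    The fibre and sheet exponential terms contribute only where
    ``I4i > 1`` (tension-only rule); the prefactor structure makes the
    energy C^1-continuous across ``I4i = 1``.  ``simple`` adds ``I6/2``,
    ``extended`` adds ``I6/4 + I7/8``; both require the residual
    invariants to be present in ``inv``.
    """
    if model not in MODELS:
        raise ConfigurationError(f"unknown model {model!r}; expected one of {MODELS}")
    p = params
    W = p.a / (2 * p.b) * np.exp(p.b * (inv.I1 - 3.0))
    for ai, bi, I4 in ((p.a_f, p.b_f, inv.I4f), (p.a_s, p.b_s, inv.I4s)):
        if ai > 0:
            term = ai / (2 * bi) * np.expm1(bi * (I4 - 1.0) ** 2)
            W = W + np.where(I4 > 1.0, term, 0.0)
    if p.a_fs > 0:
        W = W + p.a_fs / (2 * p.b_fs) * np.expm1(p.b_fs * inv.I4fs**2)
    if model == "baseline":
        return W
    if inv.I6 is None or (model == "extended" and inv.I7 is None):
        raise ConfigurationError(f"model {model!r} needs residual invariants (supply tau)")
    if model == "simple":
        return W + 0.5 * inv.I6
    return W + 0.25 * inv.I6 + 0.125 * inv.I7


def _sigma_hat(model, params, state, frame, tau):
    """F dW/dF, split into named parts (pressure term excluded)."""
    p = params
    F, B = state.F, state.B
    inv = invariants(state, frame, tau)
    f = np.einsum("...ij,...j->...i", F, frame.f0)
    s = np.einsum("...ij,...j->...i", F, frame.s0)
    outer = lambda u, v: np.einsum("...i,...j->...ij", u, v)  # noqa: E731

    parts = {}
    parts["isotropic"] = (p.a * np.exp(p.b * (inv.I1 - 3.0)))[..., None, None] * B
    for name, ai, bi, I4, v in (("fibre", p.a_f, p.b_f, inv.I4f, f),
                                ("sheet", p.a_s, p.b_s, inv.I4s, s)):
        if ai > 0:
            coef = 2 * ai * (I4 - 1.0) * np.exp(bi * (I4 - 1.0) ** 2)
            coef = np.where(I4 > 1.0, coef, 0.0)
            parts[name] = coef[..., None, None] * outer(v, v)
        else:
            parts[name] = np.zeros_like(B)
    if p.a_fs > 0:
        coef = p.a_fs * inv.I4fs * np.exp(p.b_fs * inv.I4fs**2)
        parts["fibre_sheet"] = coef[..., None, None] * (outer(f, s) + outer(s, f))
    else:
        parts["fibre_sheet"] = np.zeros_like(B)

    if model == "baseline":
        parts["residual"] = np.zeros_like(B)
    else:
        Sigma = F @ tau @ np.swapaxes(F, -1, -2)
        if model == "simple":
            parts["residual"] = Sigma
        else:
            parts["residual"] = 0.5 * Sigma + 0.25 * (Sigma @ B + B @ Sigma)
    sigma_hat = sum(parts.values())
    return sigma_hat, parts


def cauchy_stress(model: str, params: MaterialParams, state: DeformationState,
                  frame: FibreFrame, tau=None, *, p=None,
                  traction: tuple | None = None) -> StressResult:
    """Cauchy stress ``sigma = F dW/dF - p I`` for the requested model.

    Parameters
    ----------
    tau
        Residual stress (required for ``simple``/``extended``; must be
        absent or zero for ``baseline``).
    p
        Lagrange pressure (kPa).  If ``None`` and no ``traction`` is given,
        ``p = 0`` and ``sigma`` equals ``sigma_hat``: the caller owns the
        pressure.
    traction
        Alternative to ``p``: a pair ``(n, t)`` prescribing the normal
        stress ``n . sigma n = t`` along unit direction ``n``; ``p`` is
        solved from it.
    """
    if model not in MODELS:
        raise ConfigurationError(f"unknown model {model!r}; expected one of {MODELS}")
    t = _as_tau_array(tau)
    if model != "baseline" and t is None:
        raise ConfigurationError(f"model {model!r} requires a residual stress tau")
    if model == "baseline":
        t = None
    sigma_hat, parts = _sigma_hat(model, params, state, frame, t)
    if p is not None and traction is not None:
        raise ConfigurationError("give either p or a traction condition, not both")
    if traction is not None:
        n, tval = traction
        p = solve_pressure(sigma_hat, n, tval)
    elif p is None:
        p = np.zeros(sigma_hat.shape[:-2])
    p = np.asarray(p, dtype=float)
    sigma = sigma_hat - p[..., None, None] * np.eye(3)
    return StressResult(sigma=sigma, p=p, sigma_hat=sigma_hat, parts=parts)


def solve_pressure(sigma_hat, n, normal_stress):
    """Pressure that realises ``n . sigma n = normal_stress``: ``p = n.sigma_hat.n - t``."""
    n = np.asarray(n, dtype=float)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    return np.einsum("...i,...ij,...j->...", n, sigma_hat, n) - np.asarray(normal_stress)


def cauchy_stress_full(params: MaterialParams, state: DeformationState,
                       frame: FibreFrame, tau, *, W6: float, W7: float,
                       W8: float = 0.0, W9: float = 0.0, p=None) -> StressResult:
    """Research-mode stress with user-supplied constant W6, W7, W8, W9.

    The general residual contribution is

        2 W6 Sigma + 2 W7 (Sigma B + B Sigma) + 2 W8 Sigma B^-1 Sigma
        + 2 W9 (Sigma B^-1 Sigma B + B Sigma B^-1 Sigma),

    and the coefficients must satisfy the unloaded-configuration
    consistency conditions ``2(W6 + 2 W7) = 1`` and ``W8 + 2 W9 = 0``.
    Disabled by default because the quadratic-in-tau terms are negligible
    for physiological residual stress magnitudes.
    """
    if abs(2 * (W6 + 2 * W7) - 1.0) > 1e-12 or abs(W8 + 2 * W9) > 1e-12:
        raise ConfigurationError(
            "W coefficients must satisfy 2(W6+2W7)=1 and W8+2W9=0")
    t = _as_tau_array(tau)
    if t is None:
        raise ConfigurationError("full-invariant model requires tau")
    base_hat, parts = _sigma_hat("baseline", params, state, frame, None)
    F, B = state.F, state.B
    Sigma = F @ t @ np.swapaxes(F, -1, -2)
    Binv = np.linalg.inv(B)
    SBS = Sigma @ Binv @ Sigma
    res = (2 * W6 * Sigma + 2 * W7 * (Sigma @ B + B @ Sigma)
           + 2 * W8 * SBS + 2 * W9 * (SBS @ B + B @ SBS))
    parts = dict(parts)
    parts["residual"] = res
    sigma_hat = base_hat + res
    if p is None:
        p = np.zeros(sigma_hat.shape[:-2])
    p = np.asarray(p, dtype=float)
    return StressResult(sigma=sigma_hat - p[..., None, None] * np.eye(3),
                        p=p, sigma_hat=sigma_hat, parts=parts)


def consistency_constants(model: str, params: MaterialParams | None = None) -> dict:
    """Derivative coefficients at the unloaded configuration and their checks.

    Returns ``W1 = a/2`` (so that ``2 W1 = p_r = a``) together with the
    hard-coded ``W6, W7, W8, W9`` of the model, and verifies the three
    consistency conditions ``2 W1 = a``, ``2 (W6 + 2 W7) = 1`` (residual
    models only), ``W8 + 2 W9 = 0``.
    """
    if model not in MODELS:
        raise ConfigurationError(f"unknown model {model!r}; expected one of {MODELS}")
    a = (params or MaterialParams.default()).a
    W6, W7 = {"baseline": (0.0, 0.0), "simple": (0.5, 0.0),
              "extended": (0.25, 0.125)}[model]
    out = {"W1": a / 2.0, "W6": W6, "W7": W7, "W8": 0.0, "W9": 0.0, "p_r": a}
    assert out["p_r"] == 2 * out["W1"]
    if model != "baseline":
        assert 2 * (W6 + 2 * W7) == 1.0
    assert out["W8"] + 2 * out["W9"] == 0.0
    return out


def reduced_I6(tau_ff, tau_ss, tau_nn, inv: InvariantSet):
    """I6 from principal fibre-frame components of tau:

    ``I6 = tau_nn I1 + (tau_ff - tau_nn) I4f + (tau_ss - tau_nn) I4s``,

    valid because ``I1 = I4f + I4s + I4n`` for an orthonormal triad.
    """
    return (tau_nn * inv.I1 + (tau_ff - tau_nn) * inv.I4f
            + (tau_ss - tau_nn) * inv.I4s)


def reduced_I6_from_tensor(tau: ResidualStressTensor, inv: InvariantSet):
    """`reduced_I6` taking a `ResidualStressTensor` declared principal."""
    if not tau.principal:
        raise InvalidInputError("reduced I6 form requires tau principal in the fibre frame")
    return reduced_I6(tau.tau_ff, tau.tau_ss, tau.tau_nn, inv)


def reduced_I7(tau_ff, tau_ss, tau_nn, inv: InvariantSet):
    """I7 from principal components: ``tau_ff I5f + tau_ss I5s + tau_nn I5n``."""
    return tau_ff * inv.I5f + tau_ss * inv.I5s + tau_nn * inv.I5n


def numerical_energy_gradient(model, params, F, frame, tau=None, h=1e-6):
    """Central finite difference of W with respect to F: the stress oracle.

    Returns the 3x3 tensor ``F dW/dF`` evaluated by perturbing each entry
    of F.  Independent of the analytic stress path; used to verify it.
    """
    F = np.asarray(F, dtype=float)
    t = _as_tau_array(tau)

    def W_of(Fm):
        st = make_deformation(Fm)
        return float(energy(model, params, invariants(st, frame, t)))

    dWdF = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp, Fm_ = F.copy(), F.copy()
            Fp[i, j] += h
            Fm_[i, j] -= h
            dWdF[i, j] = (W_of(Fp) - W_of(Fm_)) / (2 * h)
    return F @ dWdF.T
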