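"""Inverse recovery of the unloaded configuration at cylinder scale.

In vivo imaging gives the ventricle in a loaded state even at diastole,
so the unloaded (residually stressed) reference geometry must be found by
inverse analysis.  The backward-displacement fixed-point iteration takes
the measured loaded geometry ``x_m`` at known pressure P and updates the
unloaded estimate by subtracting the computed load-induced displacement:

    x_{k+1} = x_m - (inflate(x_k, P) - x_k).

At cylinder scale the geometry reduces to the two wall radii, so the map
acts on ``(r_i, r_o)`` rather than nodal displacement fields.  On
convergence, inflating the recovered tube to P reproduces the measured
radii within tolerance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constitutive import MaterialParams
from .cylinder import TauField, TubeGeometry, inflate
from .errors import ConvergenceError, InvalidInputError
from .fibres import FibreRule

#: Convergence requires BOTH radius and relative cavity-area agreement.
TOL_RADII_CM = 1e-4
TOL_AREA_REL = 0.005
MAX_ITER = 50


@dataclass(frozen=True)
class UnloadResult:
    """Recovered unloaded tube plus the convergence history.

    ``history`` has one row per iteration with the radius mismatch (cm)
    and the relative cavity-area mismatch between the inflated iterate
    and the measured geometry.
    """

    geometry: TubeGeometry
    iterations: int
    converged: bool
    history: pd.DataFrame


def recover_unloaded(measured: TubeGeometry, P_mmHg: float,
                     params: MaterialParams | None = None,
                     model: str = "baseline",
                     tau_builder=None,
                     fibre_rule: FibreRule | None = None,
                     tol_radii_cm: float = TOL_RADII_CM,
                     tol_area_rel: float = TOL_AREA_REL,
                     max_iter: int = MAX_ITER,
                     freeze_tau: bool = False,
                     n_radial: int = 200) -> UnloadResult:
    """Backward-displacement iteration for the unloaded radii.

    Parameters
    ----------
    tau_builder
        Optional callable ``TubeGeometry -> TauField`` re-attaching the
        residual stress field to each new unloaded estimate (the residual
        field is a property of the unloaded wall, so by default it is
        regenerated per iterate).  With ``freeze_tau`` the field built on
        the first iterate is reused unchanged thereafter.
    P_mmHg
        Measured-state pressure; at P = 0 the measured geometry is already
        unloaded and is returned after one verification pass.

    Raises
    ------
    ConvergenceError
        If the mismatch grows well beyond its initial value or ``max_iter``
        is exhausted; the history travels with the exception.
    """
    if P_mmHg < 0:
        raise InvalidInputError("pressure must be non-negative")
    params = params or MaterialParams.default()
    x_m = np.array([measured.r_i, measured.r_o])
    x = x_m.copy()
    rows = []
    frozen_field = None
    area_m = np.pi * measured.r_i**2

    for k in range(1, max_iter + 1):
        geom_k = TubeGeometry(r_i=float(x[0]), r_o=float(x[1]),
                              lambda_z=measured.lambda_z)
        if tau_builder is None:
            field = None
        elif freeze_tau and frozen_field is not None:
            field = frozen_field
        else:
            field = tau_builder(geom_k)
            if freeze_tau:
                frozen_field = field
        sol = inflate(geom_k, params, model, field, P_mmHg,
                      fibre_rule, n_radial=n_radial)
        computed = np.array([sol.r_i_def, sol.r_o_def])
        mismatch = float(np.max(np.abs(computed - x_m)))
        area_mismatch = float(abs(np.pi * sol.r_i_def**2 - area_m) / area_m)
        rows.append({"iteration": k, "r_i_cm": geom_k.r_i, "r_o_cm": geom_k.r_o,
                     "radius_mismatch_cm": mismatch,
                     "cavity_area_mismatch_rel": area_mismatch})
        if mismatch <= tol_radii_cm and area_mismatch <= tol_area_rel:
            return UnloadResult(geometry=geom_k, iterations=k, converged=True,
                                history=pd.DataFrame(rows))
        if k > 1 and mismatch > 5.0 * rows[0]["radius_mismatch_cm"] + tol_radii_cm:
            raise ConvergenceError(
                f"backward-displacement iteration diverging at step {k} "
                f"(mismatch {mismatch:.3g} cm)", history=pd.DataFrame(rows))
        x = x_m - (computed - x)
        if not (0 < x[0] < x[1]):
            raise ConvergenceError(
                f"iterate {k + 1} produced inadmissible radii {x}",
                history=pd.DataFrame(rows))

    raise ConvergenceError(
        f"no convergence within {max_iter} iterations "
        f"(last mismatch {rows[-1]['radius_mismatch_cm']:.3g} cm)",
        history=pd.DataFrame(rows))
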