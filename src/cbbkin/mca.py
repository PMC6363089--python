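"""Metabolic control analysis for stable parameterized steady states.

Scaled concentration and flux control coefficients are obtained by linear
analysis at the steady state:

    C_X = -D_X0^-1 . L . J'^-1 . S' . D_v0
    C_J =  I + D_v0^-1 . dv/dX|X0 . D_X0 . C_X

with ``D_X0`` / ``D_v0`` diagonal matrices of steady-state concentrations
and fluxes, ``J' = S' dv/dX L`` the reduced Jacobian.  The coefficients are
dimensionless; per metabolite the concentration control coefficients over
all reactions sum to 0 and per target flux the flux control coefficients
sum to 1 (summation theorems), which is asserted for every computed set.

An independent finite-difference oracle perturbs one reaction's Vmax,
re-equilibrates the full nonlinear system and measures d ln J / d ln Vmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .kinetics import ParameterEnsemble, ParameterSet, normalized_rates, \
    rates_and_elasticities
from .model import NetworkModel
from .stability import StabilityResult, classify_ensemble

CONDITION_LIMIT = 1e12
SUMMATION_TOL = 1e-6


class SingularJacobianError(RuntimeError):
    """Reduced Jacobian is singular or too ill-conditioned for control analysis."""


@dataclass
class ControlCoefficients:
    """Scaled control coefficient matrices for one stable parameter set."""

    C_X: np.ndarray  # balanced metabolites x reactions
    C_J: np.ndarray  # target reactions x effector reactions
    fmcs_index: int | None = None
    set_index: int | None = None

    def check_summation(self, tol: float = SUMMATION_TOL) -> None:
        cx = np.abs(self.C_X.sum(axis=1)).max() if self.C_X.size else 0.0
        cj = np.abs(self.C_J.sum(axis=1) - 1.0).max() if self.C_J.size else 0.0
        if cx > tol or cj > tol:
            raise AssertionError(
                f"summation theorems violated: max|sum C_X|={cx:.2e}, "
                f"max|sum C_J - 1|={cj:.2e}"
            )


def _balanced_concentrations(model: NetworkModel, x0: np.ndarray) -> np.ndarray:
    return np.asarray(x0, float)[[model.met_index(m) for m in model.balanced_ids]]


def concentration_control(
    model: NetworkModel,
    stability: StabilityResult,
    x0: np.ndarray,
    v0: np.ndarray,
) -> np.ndarray:
    """Scaled concentration control coefficients ``C_X``.

    Requires a stable (hence invertible) reduced Jacobian; raises
    :class:`SingularJacobianError` for near-singular systems.
    """
    J = stability.reduced_jacobian
    if not np.all(np.isfinite(J)) or (
        J.size and np.linalg.cond(J) > CONDITION_LIMIT
    ):
        raise SingularJacobianError(
            "reduced Jacobian singular or condition number above 1e12"
        )
    xb = _balanced_concentrations(model, x0)
    v0 = np.asarray(v0, float)
    Z = np.linalg.solve(J, model.Sred * v0[None, :])  # J'^-1 S' D_v0
    return -(model.L @ Z) / xb[:, None]


def flux_control(
    model: NetworkModel,
    C_X: np.ndarray,
    elasticities: np.ndarray,
    x0: np.ndarray,
    v0: np.ndarray,
) -> np.ndarray:
    """Scaled flux control coefficients ``C_J`` from ``C_X``."""
    xb = _balanced_concentrations(model, x0)
    v0 = np.asarray(v0, float)
    E = np.asarray(elasticities, float)
    if C_X.shape != (len(xb), model.n_reactions):
        raise ValueError("C_X has wrong shape")
    return np.eye(model.n_reactions) + (E * xb[None, :]) @ C_X / v0[:, None]


def control_coefficients(
    model: NetworkModel,
    stability: StabilityResult,
    x0: np.ndarray,
    v0: np.ndarray,
    *,
    check: bool = True,
) -> ControlCoefficients:
    """C_X and C_J for one stable set, with summation theorems asserted."""
    C_X = concentration_control(model, stability, x0, v0)
    C_J = flux_control(model, C_X, stability.elasticity_matrix, x0, v0)
    cc = ControlCoefficients(C_X, C_J)
    if check:
        cc.check_summation()
    return cc


def control_ensemble(
    model: NetworkModel,
    ens: ParameterEnsemble,
    x0: np.ndarray,
    classification: dict | None = None,
    *,
    check: bool = True,
) -> dict:
    """Control coefficients for every stable set of a calibrated ensemble.

    Returns ``set_indices`` (rows of the ensemble that were stable and
    well-conditioned), tensors ``C_X`` (n, mets, rxns) and ``C_J``
    (n, targets, effectors), and the count of sets dropped for
    near-singular Jacobians.
    """
    cls = classification or classify_ensemble(model, ens, x0)
    xb = _balanced_concentrations(model, x0)
    kept, CX_list, CJ_list = [], [], []
    dropped = 0
    for i in np.flatnonzero(cls["stable"]):
        J = cls["jacobians"][i]
        if np.linalg.cond(J) > CONDITION_LIMIT:
            dropped += 1
            continue
        v = cls["rates"][i]
        Z = np.linalg.solve(J, model.Sred * v[None, :])
        C_X = -(model.L @ Z) / xb[:, None]
        E = cls["elasticities"][i]
        C_J = np.eye(model.n_reactions) + (E * xb[None, :]) @ C_X / v[:, None]
        if check:
            ControlCoefficients(C_X, C_J).check_summation()
        kept.append(int(i))
        CX_list.append(C_X)
        CJ_list.append(C_J)
    return {
        "set_indices": np.array(kept, dtype=int),
        "C_X": np.array(CX_list) if CX_list else np.empty((0, len(xb), model.n_reactions)),
        "C_J": np.array(CJ_list) if CJ_list else np.empty((0, model.n_reactions, model.n_reactions)),
        "n_dropped_singular": dropped,
    }


# ---------------------------------------------------------------------------
# finite-difference re-equilibration oracle
# ---------------------------------------------------------------------------

def _steady_state(
    model: NetworkModel,
    K: np.ndarray,
    vmax: np.ndarray,
    x0: np.ndarray,
    *,
    relax_time: float = 50.0,
) -> np.ndarray:
    """Re-solve the steady state in reduced coordinates.

    Stiff ODE relaxation from ``x0`` (analytic Jacobian) followed by a
    derivative-free root polish; dependent metabolites follow the
    conservation relations via ``X = X0 + L (y - y0)``.
    """
    bal = [model.met_index(m) for m in model.balanced_ids]
    ind = model.independent_rows
    xb0 = np.asarray(x0, float)[bal]
    y0 = xb0[ind]
    if len(ind) == 0:  # no dynamic state: every x is a steady state
        return np.asarray(x0, float).copy()

    def assemble(y):
        x = np.asarray(x0, float).copy()
        x[bal] = xb0 + model.L @ (y - y0)
        return x

    def reduced_rhs(_t, y):
        v = vmax * normalized_rates(model, K, assemble(y))
        return model.Sred @ v[0]

    def reduced_jac(_t, y):
        _, E = rates_and_elasticities(model, K, vmax, assemble(y))
        return model.Sred @ E[0] @ model.L

    y = y0
    resid = np.inf
    for horizon in (relax_time, 4 * relax_time, 16 * relax_time):
        sol = solve_ivp(
            reduced_rhs, (0.0, horizon), y, method="LSODA", jac=reduced_jac,
            rtol=1e-9, atol=1e-11 * np.maximum(np.abs(y0), 1e-6),
        )
        if sol.success:
            y = sol.y[:, -1]
        polish = root(
            lambda yy: reduced_rhs(0.0, yy), y, method="hybr", tol=1e-13
        )
        if polish.success:
            y = polish.x
        resid = np.abs(reduced_rhs(0.0, y)).max()
        if resid < 1e-8:
            return assemble(y)
    raise RuntimeError(f"re-equilibration failed, residual {resid:.2e}")


def fcc_finite_difference_oracle(
    model: NetworkModel,
    params: ParameterSet,
    x0: np.ndarray,
    effector_reaction: str,
    delta: float = 1e-3,
) -> np.ndarray:
    """FCC column d ln v_j / d ln Vmax_e by explicit re-equilibration.

    Scales the effector's Vmax by ``(1 +/- delta)``, relaxes the full
    nonlinear system to its new steady state (stiff integration plus
    root polish) and returns the central difference quotient for every
    target flux.  Raises RuntimeError when re-equilibration fails
    (oracle inconclusive for that set).
    """
    ens = params.ensemble
    row = slice(params.row, params.row + 1)
    K = ens.K[row]
    vmax0 = ens.vmax[row].copy()
    e = model.rxn_index(effector_reaction)

    def fluxes(scale: float) -> np.ndarray:
        vmax = vmax0.copy()
        vmax[0, e] *= scale
        x = _steady_state(model, K, vmax, x0)
        v = vmax * normalized_rates(model, K, x)
        return v[0]

    v_up = fluxes(1.0 + delta)
    v_dn = fluxes(1.0 - delta)
    if np.any(v_up <= 0) or np.any(v_dn <= 0):
        raise RuntimeError("flux changed sign during re-equilibration")
    return (np.log(v_up) - np.log(v_dn)) / (np.log1p(delta) - np.log1p(-delta))
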