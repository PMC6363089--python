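"""Synthetic inputs: steady-state flux vectors, ranges, and toy models.

The original analysis took its steady-state flux distribution from
genome-scale flux balance analysis.  Here a small linear program on the
29-reaction stoichiometry itself produces an equivalent strictly positive
steady-state vector: downstream mathematics depends only on ``S v0 = 0``
and the reaction directions, not on the absolute flux scale.  A flux table
in TSV form (columns reaction, v0) can be supplied instead and is validated
against the same invariants.

Toy models with closed-form steady states, spectra and control
coefficients serve as independent oracles for the stability and control
modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model import NetworkModel, build_network
from .sampling import ConcentrationRangeTable, MetabolomeSample

STEADY_STATE_TOL = 1e-10


@dataclass
class FluxVector:
    """Steady-state input fluxes v0 per reaction, strictly positive."""

    reactions: list[str]
    values: np.ndarray
    provenance: str = "lp-generated"  # or "table-file"

    def series(self) -> pd.Series:
        return pd.Series(self.values, index=self.reactions, name="v0")

    def to_tsv(self, path: str | Path) -> None:
        df = self.series().rename_axis("reaction").reset_index()
        df.to_csv(path, sep="\t", index=False)


class FluxValidationError(ValueError):
    pass


def validate_flux_vector(
    model: NetworkModel, values: np.ndarray, tol: float = STEADY_STATE_TOL
) -> None:
    """Check steady state (``S v = 0``) and positive directionality."""
    values = np.asarray(values, dtype=float)
    resid = model.S @ values
    scale = max(1.0, float(np.abs(values).max()))
    bad = np.flatnonzero(np.abs(resid) > tol * scale)
    if bad.size:
        mets = [model.balanced_ids[i] for i in bad]
        raise FluxValidationError(
            f"flux vector is not at steady state; unbalanced metabolites: {mets}"
        )
    nonpos = np.flatnonzero(values <= 0)
    if nonpos.size:
        rxns = [model.reaction_ids[i] for i in nonpos]
        raise FluxValidationError(
            f"fluxes must be positive in the defined direction: {rxns}"
        )


def apply_flux(model: NetworkModel, flux: FluxVector) -> None:
    """Attach v0 values to the model's reactions."""
    for rid, v in zip(flux.reactions, flux.values):
        model.reaction(rid).v0 = float(v)


def generate_flux_vector(
    model: NetworkModel,
    objective_weights: dict[str, float] | None = None,
    seed: int = 0,
    *,
    upper_bound: float = 10.0,
    min_flux_fraction: float = 1e-3,
) -> FluxVector:
    """Solve a small LP for a strictly positive steady-state flux vector.

    Maximizes the weighted sum of sink fluxes (default weight 1 on every
    reaction in group ``sink``, deterministically jittered from ``seed`` to
    break degeneracy) subject to ``S v = 0`` and
    ``min_flux_fraction * upper_bound <= v <= upper_bound``, so every
    reaction carries flux in its defined direction.
    """
    n = model.n_reactions
    lb = min_flux_fraction * upper_bound
    c = np.zeros(n)
    if objective_weights is None:
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 4)))
        for j, rxn in enumerate(model.reactions):
            if rxn.group == "sink":
                c[j] = -(1.0 + 0.01 * rng.random())
        if not np.any(c):
            c[:] = -1.0  # toy networks without sinks: maximize everything
    else:
        for rid, w in objective_weights.items():
            c[model.rxn_index(rid)] = -float(w)
    res = linprog(
        c,
        A_eq=model.S,
        b_eq=np.zeros(model.S.shape[0]),
        bounds=[(lb, upper_bound)] * n,
        method="highs",
    )
    if not res.success:
        conflict = _diagnose_infeasibility(model, lb, upper_bound)
        raise FluxValidationError(
            "steady-state LP infeasible (conflicting reaction directions); "
            f"metabolites that cannot be balanced: {conflict}"
        )
    v = np.asarray(res.x, dtype=float)
    # polish the equality residual to machine precision (minimum-norm
    # correction; the LP solution is already feasible to solver tolerance)
    v = v - np.linalg.lstsq(model.S, model.S @ v, rcond=None)[0]
    validate_flux_vector(model, v)
    return FluxVector(model.reaction_ids, v, "lp-generated")


def _diagnose_infeasibility(
    model: NetworkModel, lb: float, ub: float
) -> list[str]:
    """Metabolites needing nonzero slack when the balance is relaxed."""
    m, n = model.S.shape
    # minimize sum of elastic slacks s+ + s- with S v + s+ - s- = 0
    c = np.concatenate([np.zeros(n), np.ones(2 * m)])
    A_eq = np.hstack([model.S, np.eye(m), -np.eye(m)])
    bounds = [(lb, ub)] * n + [(0, None)] * (2 * m)
    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(m), bounds=bounds, method="highs")
    if not res.success:
        return list(model.balanced_ids)
    slack = res.x[n : n + m] + res.x[n + m :]
    return [model.balanced_ids[i] for i in np.flatnonzero(slack > 1e-9)]


def load_flux_tsv(model: NetworkModel, path: str | Path) -> FluxVector:
    """Read and validate a flux table (columns reaction, v0)."""
    df = pd.read_csv(path, sep="\t")
    by_id = dict(zip(df["reaction"].astype(str), df["v0"].astype(float)))
    missing = [r for r in model.reaction_ids if r not in by_id]
    if missing:
        raise FluxValidationError(f"flux file lacks reactions {missing}")
    v = np.array([by_id[r] for r in model.reaction_ids])
    validate_flux_vector(model, v)
    return FluxVector(model.reaction_ids, v, "table-file")


def default_ranges(model: NetworkModel) -> ConcentrationRangeTable:
    """The shipped per-metabolite sampling ranges for this model."""
    return ConcentrationRangeTable.from_model(model)


# ---------------------------------------------------------------------------
# toy models with closed-form reference quantities
# ---------------------------------------------------------------------------

@dataclass
class ToyModel:
    """A small network plus closed-form reference quantities.

    ``reference_fcc`` is the flux control coefficient matrix
    (targets x effectors); ``x0`` the steady-state concentrations (full
    vector, mM) and ``v0`` the steady-state fluxes.  The references are
    verified against a brute-force perturbation computation at build time.
    """

    model: NetworkModel
    x0: np.ndarray
    v0: np.ndarray
    reference_fcc: np.ndarray
    description: str = ""
    fmcs: MetabolomeSample = None

    def parameter_ensemble(self, n_sets: int = 1, seed: int = 0):
        from .kinetics import calibrate_vmax_ensemble, sample_parameter_ensemble

        ens = sample_parameter_ensemble(self.model, self.fmcs, n_sets, seed)
        return calibrate_vmax_ensemble(self.model, ens, self.x0, self.v0)


def _make_fmcs(model: NetworkModel, conc: dict[str, float]) -> MetabolomeSample:
    ids = model.sampled_ids
    return MetabolomeSample(
        concentrations=pd.Series({m: conc[m] for m in ids}, dtype=float),
        ppool_multiple=1.0,
        dG=pd.Series(dtype=float),
        feasible=True,
        index=0,
    )


def toy_linear_chain(
    n_steps: int,
    saturation_regime: str = "zero-order-first",
    *,
    verify: bool = True,
) -> ToyModel:
    """Open reaction chain with known control structure.

    ``zero-order-first``: irreversible Michaelis-Menten steps from a clamped
    pathway substrate; the first step is substrate-saturated and rate
    determines the chain flux, so its flux control coefficient is exactly 1
    over every step and all other coefficients vanish.

    ``first-order``: the same chain with every step far below saturation;
    the first step still sets the flux (its substrate is clamped), so the
    closed form is identical — the regime only moves the internal
    concentrations' sensitivity.

    ``resistor``: symmetric mass-action steps between clamped end
    metabolites, ``v_i = k_i (X_{i-1} - X_i)``; the classic series-resistance
    result gives ``C_i = (1/k_i) / sum_j (1/k_j)`` for the chain flux.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if saturation_regime not in ("zero-order-first", "first-order", "resistor"):
        raise ValueError(f"unknown saturation regime {saturation_regime!r}")

    if saturation_regime == "resistor":
        # clamped ends A (high) and Z (low); internal M1..M_{n-1}
        x_levels = np.linspace(2.0, 1.0, n_steps + 1)
        mets = [
            {"id": "A", "role": "boundary-unbalanced", "conc_fixed_mM": x_levels[0]}
        ]
        internal = [f"M{i}" for i in range(1, n_steps)]
        for i, mid in enumerate(internal, start=1):
            mets.append(
                {"id": mid, "role": "balanced", "conc_range_mM": [1e-6, 1e3]}
            )
        mets.append(
            {"id": "Z", "role": "boundary-unbalanced", "conc_fixed_mM": x_levels[-1]}
        )
        chain = ["A"] + internal + ["Z"]
        rxns = [
            {
                "id": f"R{i}",
                "stoichiometry": {chain[i - 1]: -1, chain[i]: 1},
                "rate_law": "mass-action-symmetric",
            }
            for i in range(1, n_steps + 1)
        ]
        model = build_network(
            {"name": f"resistor-chain-{n_steps}", "metabolites": mets,
             "reactions": rxns}
        )
        conc = {mid: float(x_levels[i + 1]) for i, mid in enumerate(internal)}
        fmcs = _make_fmcs(model, conc)
        from .sampling import full_concentration_vector

        x0 = full_concentration_vector(model, fmcs)
        v0 = np.ones(n_steps)
        # calibrated k_i = v0 / (X_{i-1} - X_i); here all gaps equal
        k = 1.0 / np.diff(-x_levels)
        inv = 1.0 / k
        ref = np.tile(inv / inv.sum(), (n_steps, 1))
        toy = ToyModel(model, x0, v0, ref, "resistor chain", fmcs)
    else:
        sat_first = saturation_regime == "zero-order-first"
        mets = [{"id": "A", "role": "boundary-unbalanced", "conc_fixed_mM": 10.0}]
        internal = [f"M{i}" for i in range(1, n_steps)]
        for mid in internal:
            mets.append(
                {"id": mid, "role": "balanced", "conc_range_mM": [1e-6, 1e3]}
            )
        mets.append({"id": "SINK", "role": "sink-pool", "conc_fixed_mM": 1.0})
        chain = ["A"] + internal + ["SINK"]
        rxns = [
            {
                "id": f"R{i}",
                "stoichiometry": {chain[i - 1]: -1, chain[i]: 1},
                "rate_law": "irreversible-MM",
            }
            for i in range(1, n_steps + 1)
        ]
        model = build_network(
            {"name": f"mm-chain-{n_steps}", "metabolites": mets, "reactions": rxns}
        )
        conc = {mid: 1.0 for mid in internal}
        fmcs = _make_fmcs(model, conc)
        from .sampling import full_concentration_vector

        x0 = full_concentration_vector(model, fmcs)
        v0 = np.ones(n_steps)
        ref = np.zeros((n_steps, n_steps))
        ref[:, 0] = 1.0  # clamped-substrate first step sets the chain flux
        toy = ToyModel(
            model, x0, v0, ref,
            f"irreversible MM chain ({saturation_regime})", fmcs,
        )
        # pin the saturation regime by overriding the sampled K draw
        toy._k_override = {}
        for p in model.sampled_parameters:
            c = x0[model.met_index(p.metabolite)]
            if p.reaction == "R1" and sat_first:
                toy._k_override[p.symbol] = 0.01 * c  # saturated, zero order
            else:
                toy._k_override[p.symbol] = 100.0 * c  # first-order regime

    if verify:
        bf = brute_force_fcc(toy)
        if not np.allclose(bf, toy.reference_fcc, rtol=5e-3, atol=5e-3):
            raise AssertionError(
                "toy reference FCCs disagree with brute-force perturbation:\n"
                f"{bf}\nvs\n{toy.reference_fcc}"
            )
    return toy


def toy_parameter_ensemble(toy: ToyModel, seed: int = 0):
    """One calibrated parameter set honoring the toy's saturation regime."""
    from .kinetics import calibrate_vmax_ensemble, sample_parameter_ensemble

    ens = sample_parameter_ensemble(toy.model, toy.fmcs, 1, seed)
    override = getattr(toy, "_k_override", None)
    if override:
        for j, p in enumerate(toy.model.sampled_parameters):
            ens.K[0, j] = override[p.symbol]
    return calibrate_vmax_ensemble(toy.model, ens, toy.x0, toy.v0)


def brute_force_fcc(
    toy: ToyModel, delta: float = 1e-4, seed: int = 0
) -> np.ndarray:
    """Flux control coefficients by explicit perturbation and re-solving.

    Scales each reaction's activity by ``(1 +/- delta)``, re-solves the
    steady state with a derivative-free nonlinear solve on the balanced
    concentrations, and returns the central log-log difference quotients.
    Independent of the linear-algebra control-coefficient path.
    """
    from scipy.optimize import root

    from .kinetics import normalized_rates

    model = toy.model
    ens = toy_parameter_ensemble(toy, seed)
    n = model.n_reactions
    bal = [model.met_index(m) for m in model.balanced_ids]
    x_base = toy.x0.copy()

    def fluxes(vmax_scale: np.ndarray) -> np.ndarray:
        vmax = ens.vmax * vmax_scale

        def residual(xb):
            x = x_base.copy()
            x[bal] = xb
            v = vmax * normalized_rates(model, ens.K, x)
            return model.S @ v[0]

        if bal:
            sol = root(residual, x_base[bal], method="hybr", tol=1e-12)
            if not sol.success:
                raise RuntimeError("brute-force steady-state solve failed")
            x = x_base.copy()
            x[bal] = sol.x
        else:
            x = x_base
        return (vmax * normalized_rates(model, ens.K, x))[0]

    C = np.zeros((n, n))
    for e in range(n):
        up = np.ones(n)
        up[e] = 1 + delta
        dn = np.ones(n)
        dn[e] = 1 - delta
        v_up = fluxes(up)
        v_dn = fluxes(dn)
        C[:, e] = (np.log(v_up) - np.log(v_dn)) / (
            np.log(1 + delta) - np.log(1 - delta)
        )
    return C


def toy_supply_drain() -> ToyModel:
    """Zero-order supply feeding a strictly first-order drain.

    The classic two-step motif: ``v1 = const`` (lumped supply) and
    ``v2 = k X`` (symmetric mass action into an empty pool), for which the
    concentration control coefficients are exactly +1 (supply) and -1
    (drain), and the flux control coefficients are 1 for the supply over
    both fluxes and 0 for the drain.
    """
    mets = [
        {"id": "X", "role": "balanced", "conc_range_mM": [1e-6, 1e3]},
        {"id": "W", "role": "sink-pool", "conc_fixed_mM": 0.0},
    ]
    rxns = [
        {"id": "supply", "stoichiometry": {"X": 1}, "rate_law": "lumped-supply"},
        {
            "id": "drain",
            "stoichiometry": {"X": -1, "W": 1},
            "rate_law": "mass-action-symmetric",
        },
    ]
    model = build_network(
        {"name": "supply-drain", "metabolites": mets, "reactions": rxns}
    )
    fmcs = _make_fmcs(model, {"X": 1.0})
    from .sampling import full_concentration_vector

    x0 = full_concentration_vector(model, fmcs)
    v0 = np.ones(2)
    ref = np.array([[1.0, 0.0], [1.0, 0.0]])
    return ToyModel(model, x0, v0, ref, "zero-order supply, first-order drain", fmcs)
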