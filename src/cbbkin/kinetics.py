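"""Rate laws, kinetic-constant sampling and Vmax calibration.

The generic reversible Michaelis-Menten-like law for a reaction with
substrates :math:`S_i` (stoichiometry :math:`n_i`), products :math:`P_j`
(:math:`m_j`), competitive inhibitors :math:`I_c` and allosteric modifiers
is the convenience-kinetics generalization of the textbook 1:1 scheme

.. math::

    v = V_{max} \\cdot \\prod_a \\frac{a}{K_a + a}
              \\cdot \\prod_i \\frac{K_i}{K_i + i}
              \\cdot \\frac{\\prod_i (S_i/K_{S_i})^{n_i}
                           \\,(1 - Q/K_{eq})}{D}

with the mass-action ratio :math:`Q` taken in the defined flux direction
(molar units, so :math:`v = 0` exactly at equilibrium) and

.. math::

    D = \\prod_i \\sum_{k=0}^{n_i} (S_i/K_{S_i})^k
      + \\prod_j \\sum_{k=0}^{m_j} (P_j/K_{P_j})^k - 1
      + \\sum_c I_c/K_{I_c}.

For a 1:1 conversion this reduces exactly to
``v = Vmax (A/K_A)(1 - B/(A Keq)) / (1 + A/K_A + B/K_B)``.  Irreversible
laws drop the thermodynamic factor and the product pool; the phosphate
supply follows symmetric mass action ``v = k (PPool - Pi)``; lumped supply
steps are zero order (``v = Vmax``).

Kinetic constants are sampled log-uniformly from 0.01x to 100x the
concentration of the associated metabolite in the current metabolome, which
corresponds to enzyme saturation between 99% and 1%.  Vmax is then
calibrated per reaction so the rate at the reference state equals the input
steady-state flux exactly (``Vmax = v0 / f``).

Everything is vectorized over parameter sets: concentrations are scalars
per metabolome while the sampled constants carry the set dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import NetworkModel, ReactionSpec
from .rng import STAGE_PARAMS, stream as rng_stream
from .sampling import MetabolomeSample, full_concentration_vector

K_FACTOR_RANGE = (0.01, 100.0)  # sampling window around the concentration


class CalibrationError(RuntimeError):
    """Normalized rate non-positive at the reference state.

    For thermodynamically filtered metabolomes every reaction satisfies
    ``Q < Keq`` in its flux direction, so this signals an internal
    inconsistency between the feasibility filter and the rate laws.
    """


def saturation_fraction(concentration, K):
    """Fraction of enzyme occupied, ``[S] / ([S] + K)``."""
    concentration = np.asarray(concentration, dtype=float)
    K = np.asarray(K, dtype=float)
    if np.any(concentration <= 0) or np.any(K <= 0):
        raise ValueError("concentration and K must be positive")
    return concentration / (concentration + K)


# ---------------------------------------------------------------------------
# compiled kinetic structure
# ---------------------------------------------------------------------------

@dataclass
class _Term:
    species: int  # index into the full concentration vector
    coeff: int  # stoichiometric multiplicity (positive)
    col: int  # column in the sampled-constant matrix
    balanced: int  # column in the balanced state, or -1 if clamped


@dataclass
class CompiledReaction:
    rid: str
    kind: str
    substrates: list[_Term] = field(default_factory=list)
    products: list[_Term] = field(default_factory=list)
    competitive: list[_Term] = field(default_factory=list)
    activators: list[_Term] = field(default_factory=list)
    inhibitors: list[_Term] = field(default_factory=list)  # allosteric
    keq: float | None = None
    q_species: list[tuple[int, float, int]] = field(default_factory=list)
    # (species index, signed coeff, balanced column or -1) entering Q
    ma_a: int = -1  # mass action: v = k (x[ma_a] - x[ma_b])
    ma_b: int = -1
    ma_a_bal: int = -1
    ma_b_bal: int = -1


def compile_kinetics(model: NetworkModel) -> list[CompiledReaction]:
    """Index the rate-law structure of every reaction (cached on the model)."""
    cached = getattr(model, "_compiled_kinetics", None)
    if cached is not None:
        return cached
    sym_col = {p.symbol: i for i, p in enumerate(model.sampled_parameters)}
    bal_col = {m: i for i, m in enumerate(model.balanced_ids)}

    def term(rxn_id: str, mid: str, coeff: float, symbol: str) -> _Term:
        return _Term(
            species=model.met_index(mid),
            coeff=int(round(coeff)),
            col=sym_col[symbol],
            balanced=bal_col.get(mid, -1),
        )

    out: list[CompiledReaction] = []
    for rxn in model.reactions:
        cr = CompiledReaction(rid=rxn.id, kind=rxn.rate_law, keq=rxn.keq)
        if rxn.rate_law in ("reversible-MM", "irreversible-MM"):
            for mid, coeff in rxn.substrates():
                if model.metabolite(mid).kinetics_excluded:
                    continue
                cr.substrates.append(
                    term(rxn.id, mid, coeff, f"KM__{rxn.id}__{mid}")
                )
            if rxn.rate_law == "reversible-MM":
                for mid, coeff in rxn.products():
                    if model.metabolite(mid).kinetics_excluded:
                        continue
                    cr.products.append(
                        term(rxn.id, mid, coeff, f"KM__{rxn.id}__{mid}")
                    )
                for mid, coeff in rxn.stoichiometry.items():
                    if model.metabolite(mid).kinetics_excluded:
                        continue
                    cr.q_species.append(
                        (model.met_index(mid), float(coeff), bal_col.get(mid, -1))
                    )
            for reg in rxn.regulators:
                t = term(rxn.id, reg.metabolite, 1, reg.symbol)
                if reg.mode == "competitive-inhibitor":
                    cr.competitive.append(t)
                elif reg.mode == "allosteric-activator":
                    cr.activators.append(t)
                else:
                    cr.inhibitors.append(t)
        elif rxn.rate_law == "mass-action-symmetric":
            (a, _), = rxn.substrates()
            (b, _), = rxn.products()
            cr.ma_a = model.met_index(a)
            cr.ma_b = model.met_index(b)
            cr.ma_a_bal = bal_col.get(a, -1)
            cr.ma_b_bal = bal_col.get(b, -1)
        out.append(cr)
    model._compiled_kinetics = out
    return out


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class ParameterEnsemble:
    """Sampled constants (and calibrated Vmax) for many sets of one fMCS."""

    model: NetworkModel
    K: np.ndarray  # (n_sets, n_sampled_constants), mM
    vmax: np.ndarray | None = None  # (n_sets, n_reactions), flux units
    fmcs_index: int | None = None
    seed: int | None = None

    @property
    def n_sets(self) -> int:
        return self.K.shape[0]

    @property
    def symbols(self) -> list[str]:
        return [p.symbol for p in self.model.sampled_parameters]

    def constants_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.K, columns=self.symbols)

    def __getitem__(self, i: int) -> "ParameterSet":
        return ParameterSet(self, int(i))


class ParameterSet:
    """A single sampled parameter set (view into an ensemble row).

    Exposes the constants as per-reaction K_M / K_i / K_a maps plus Vmax and
    the inherited equilibrium constants.
    """

    def __init__(self, ensemble: ParameterEnsemble, row: int):
        self.ensemble = ensemble
        self.row = row
        self.model = ensemble.model
        self._by_symbol = dict(zip(ensemble.symbols, ensemble.K[row]))

    @property
    def fmcs_index(self):
        return self.ensemble.fmcs_index

    @property
    def seed(self):
        return self.ensemble.seed

    def constant(self, symbol: str) -> float:
        return float(self._by_symbol[symbol])

    def km(self, reaction: str) -> dict[str, float]:
        return self._map(reaction, "K_M")

    def ki(self, reaction: str) -> dict[str, float]:
        return self._map(reaction, "K_i")

    def ka(self, reaction: str) -> dict[str, float]:
        return self._map(reaction, "K_a")

    def _map(self, reaction: str, kind: str) -> dict[str, float]:
        out = {}
        for p in self.model.sampled_parameters:
            if p.kind == kind and p.reaction == reaction:
                out[p.metabolite] = self._by_symbol[p.symbol]
        if kind in ("K_i", "K_a"):
            # include referenced (promiscuity-shared) constants
            rxn = self.model.reaction(reaction)
            want = (
                {"competitive-inhibitor", "allosteric-inhibitor"}
                if kind == "K_i"
                else {"allosteric-activator"}
            )
            for reg in rxn.regulators:
                if reg.mode in want and reg.metabolite not in out:
                    out[reg.metabolite] = self._by_symbol[reg.symbol]
        return out

    def vmax(self, reaction: str) -> float:
        if self.ensemble.vmax is None:
            raise ValueError("Vmax not calibrated yet")
        return float(
            self.ensemble.vmax[self.row, self.model.rxn_index(reaction)]
        )

    def keq(self, reaction: str) -> float | None:
        return self.model.reaction(reaction).keq


def sample_parameter_ensemble(
    model: NetworkModel,
    fmcs: MetabolomeSample,
    n_sets: int,
    seed: int,
) -> ParameterEnsemble:
    """Draw kinetic constants for ``n_sets`` parameter sets around an fMCS.

    Every sampled constant (K_M, K_i, K_a) is drawn log-uniformly from
    ``[0.01, 100] x`` the concentration of its metabolite in this
    metabolome; promiscuity-shared constants are drawn once.
    """
    if not fmcs.feasible:
        raise ValueError("parameter sampling requires a feasible metabolome")
    x = full_concentration_vector(model, fmcs)
    ref = np.empty(model.n_sampled_constants)
    for j, p in enumerate(model.sampled_parameters):
        c = x[model.met_index(p.metabolite)]
        if not np.isfinite(c) or c <= 0:
            raise ValueError(
                f"regulator/participant {p.metabolite!r} has no positive "
                "concentration in this metabolome"
            )
        ref[j] = c
    rng = rng_stream(
        seed, STAGE_PARAMS, 0 if fmcs.index is None else fmcs.index
    )
    lo, hi = np.log10(K_FACTOR_RANGE[0]), np.log10(K_FACTOR_RANGE[1])
    factors = 10.0 ** (lo + rng.random((n_sets, ref.size)) * (hi - lo))
    return ParameterEnsemble(
        model=model, K=factors * ref, fmcs_index=fmcs.index, seed=seed
    )


def sample_parameter_set(
    model: NetworkModel, fmcs: MetabolomeSample, seed: int
) -> ParameterSet:
    """Draw a single parameter set (Vmax not yet calibrated)."""
    return sample_parameter_ensemble(model, fmcs, 1, seed)[0]


# ---------------------------------------------------------------------------
# rate evaluation
# ---------------------------------------------------------------------------

def _poly(y: np.ndarray, n: int) -> np.ndarray:
    """sum_{k=0..n} y^k"""
    out = np.ones_like(y)
    p = np.ones_like(y)
    for _ in range(n):
        p = p * y
        out = out + p
    return out


def _poly_prime(y: np.ndarray, n: int) -> np.ndarray:
    """d/dy sum_{k=0..n} y^k"""
    out = np.zeros_like(y)
    p = np.ones_like(y)
    for k in range(1, n + 1):
        out = out + k * p
        p = p * y
    return out


def _gamma(cr: CompiledReaction, x: np.ndarray) -> float:
    """Q / Keq in molar units (thermodynamic displacement from equilibrium)."""
    ln_q = 0.0
    for sp, coeff, _ in cr.q_species:
        ln_q += coeff * np.log(x[sp] / 1000.0)
    return float(np.exp(ln_q) / cr.keq)


def normalized_rates(
    model: NetworkModel, K: np.ndarray, x: np.ndarray
) -> np.ndarray:
    """Rates at Vmax = 1 (the function ``f``) for all reactions and sets.

    ``K`` is (n_sets, n_sampled); ``x`` the full concentration vector (mM).
    Mass-action reactions return ``x_A - x_B`` (rate at k = 1); lumped
    supply returns 1.
    """
    compiled = compile_kinetics(model)
    n_sets = K.shape[0]
    f = np.empty((n_sets, len(compiled)))
    for j, cr in enumerate(compiled):
        f[:, j] = _eval_reaction(cr, K, x)[0]
    return f


def _eval_reaction(
    cr: CompiledReaction,
    K: np.ndarray,
    x: np.ndarray,
    with_elasticities: bool = False,
):
    """Evaluate one reaction's normalized rate f (and optionally d f/dx).

    Returns ``(f, contribs)`` with ``f`` shaped (n_sets,) and ``contribs`` a
    list of ``(balanced_column, df_dx)`` pairs (only balanced metabolites).
    """
    n_sets = K.shape[0]
    contribs: list[tuple[int, np.ndarray]] = []

    if cr.kind == "lumped-supply":
        return np.ones(n_sets), contribs
    if cr.kind == "mass-action-symmetric":
        f = np.full(n_sets, x[cr.ma_a] - x[cr.ma_b])
        if with_elasticities:
            one = np.ones(n_sets)
            if cr.ma_a_bal >= 0:
                contribs.append((cr.ma_a_bal, one))
            if cr.ma_b_bal >= 0:
                contribs.append((cr.ma_b_bal, -one))
        return f, contribs

    # Michaelis-Menten family
    T = np.ones(n_sets)
    Ds = np.ones(n_sets)
    sub_polys = []
    for t in cr.substrates:
        y = x[t.species] / K[:, t.col]
        T = T * y**t.coeff
        p = _poly(y, t.coeff)
        sub_polys.append((t, y, p))
        Ds = Ds * p
    if cr.kind == "reversible-MM":
        Dp = np.ones(n_sets)
        prod_polys = []
        for t in cr.products:
            y = x[t.species] / K[:, t.col]
            p = _poly(y, t.coeff)
            prod_polys.append((t, y, p))
            Dp = Dp * p
        D = Ds + Dp - 1.0
        gamma = _gamma(cr, x)
        thermo = 1.0 - gamma
    else:
        D = Ds
        gamma = 0.0
        thermo = 1.0
    for t in cr.competitive:
        D = D + x[t.species] / K[:, t.col]

    A = np.ones(n_sets)
    for t in cr.activators:
        A = A * x[t.species] / (K[:, t.col] + x[t.species])
    for t in cr.inhibitors:
        A = A * K[:, t.col] / (K[:, t.col] + x[t.species])

    W = A * T / D
    f = W * thermo

    if with_elasticities:
        dD: dict[int, np.ndarray] = {}

        def add_dD(t: _Term, val: np.ndarray) -> None:
            if t.balanced < 0:
                return
            dD[t.balanced] = dD.get(t.balanced, 0.0) + val

        for t, y, p in sub_polys:
            add_dD(t, _poly_prime(y, t.coeff) / K[:, t.col] * Ds / p)
        if cr.kind == "reversible-MM":
            for t, y, p in prod_polys:
                add_dD(t, _poly_prime(y, t.coeff) / K[:, t.col] * Dp / p)
        for t in cr.competitive:
            add_dD(t, 1.0 / K[:, t.col])

        per_bal: dict[int, np.ndarray] = {}

        def add(bal: int, val: np.ndarray) -> None:
            if bal < 0:
                return
            per_bal[bal] = per_bal.get(bal, 0.0) + val

        for t, y, p in sub_polys:
            add(t.balanced, W * t.coeff / x[t.species])
        if cr.kind == "reversible-MM":
            # Q may involve clamped species; derivative only for balanced
            for sp, coeff, bal in cr.q_species:
                if coeff > 0:
                    add(bal, -W * gamma * coeff / x[sp])
                # negative (substrate) Q-coefficients combine with the
                # substrate product term: d/dx [T (1-gamma)] =
                # (n/x) T (1-gamma) + T gamma n/x = (n/x) T  -> already the
                # W * n/x term added above
        for bal, val in dD.items():
            per_bal[bal] = per_bal.get(bal, 0.0) - f * val / D
        for t in cr.activators:
            add(
                t.balanced,
                f * K[:, t.col] / (x[t.species] * (K[:, t.col] + x[t.species])),
            )
        for t in cr.inhibitors:
            add(t.balanced, -f / (K[:, t.col] + x[t.species]))
        contribs = sorted(per_bal.items())
    return f, contribs


def rates_and_elasticities(
    model: NetworkModel,
    K: np.ndarray,
    vmax: np.ndarray,
    x: np.ndarray,
):
    """Rates v and elasticity matrices dv/dX at concentrations ``x``.

    Returns ``(v, E)`` with ``v`` shaped (n_sets, n_reactions) and ``E``
    shaped (n_sets, n_reactions, n_balanced).  Clamped species contribute
    no columns; fixed boundary species therefore have zero elasticity.
    """
    compiled = compile_kinetics(model)
    n_sets = K.shape[0]
    n_bal = len(model.balanced_ids)
    v = np.empty((n_sets, len(compiled)))
    E = np.zeros((n_sets, len(compiled), n_bal))
    for j, cr in enumerate(compiled):
        f, contribs = _eval_reaction(cr, K, x, with_elasticities=True)
        v[:, j] = vmax[:, j] * f
        for bal, df in contribs:
            E[:, j, bal] = vmax[:, j] * df
    return v, E


def rates(model: NetworkModel, ens: ParameterEnsemble, x: np.ndarray) -> np.ndarray:
    """Reaction rates (n_sets, n_reactions) at concentrations ``x`` (mM)."""
    if ens.vmax is None:
        raise ValueError("Vmax not calibrated")
    return ens.vmax * normalized_rates(model, ens.K, x)


def rate(
    reaction: ReactionSpec,
    params: ParameterSet,
    concentrations,
    model: NetworkModel | None = None,
) -> float:
    """Rate of a single reaction for one parameter set.

    ``concentrations`` is either a mapping metabolite -> mM or a full
    concentration vector in declaration order.
    """
    model = model or params.model
    j = model.rxn_index(reaction.id)
    if isinstance(concentrations, np.ndarray):
        x = concentrations
    else:
        x = model.fixed_concentration_vector()
        for mid, c in dict(concentrations).items():
            x[model.met_index(mid)] = c
    needed = [model.met_index(m) for m in reaction.stoichiometry]
    if np.any(~np.isfinite(x[needed])) or np.any(x[needed] <= 0):
        if not (reaction.rate_law == "mass-action-symmetric"):
            raise ValueError("non-positive or missing concentration")
    cr = compile_kinetics(model)[j]
    K = params.ensemble.K[params.row : params.row + 1]
    f = _eval_reaction(cr, K, x)[0][0]
    return float(params.vmax(reaction.id) * f)


# ---------------------------------------------------------------------------
# Vmax calibration
# ---------------------------------------------------------------------------

def calibrate_vmax_ensemble(
    model: NetworkModel,
    ens: ParameterEnsemble,
    x: np.ndarray,
    v0: np.ndarray,
) -> ParameterEnsemble:
    """Set Vmax (or the mass-action k) so each rate equals the input flux.

    ``Vmax = v0 / f`` with ``f`` the normalized rate at the reference state.
    Raises :class:`CalibrationError` if any f is non-positive, which cannot
    happen for thermodynamically feasible metabolomes.
    """
    f = normalized_rates(model, ens.K, x)
    if np.any(f <= 0):
        sets_idx, rxn_idx = np.nonzero(f <= 0)
        rid = model.reaction_ids[rxn_idx[0]]
        raise CalibrationError(
            f"normalized rate <= 0 for reaction {rid!r} (set {sets_idx[0]}); "
            "thermodynamics/direction conflict"
        )
    ens.vmax = np.asarray(v0, dtype=float) / f
    return ens


def calibrate_vmax(
    reaction: ReactionSpec,
    params: ParameterSet,
    concentrations,
    v0: float | None = None,
) -> float:
    """Calibrated Vmax for one reaction, ``Vmax = v0 / f``."""
    model = params.model
    if v0 is None:
        v0 = reaction.v0
    if v0 is None:
        raise ValueError(f"reaction {reaction.id!r} has no input flux v0")
    if isinstance(concentrations, np.ndarray):
        x = concentrations
    else:
        x = model.fixed_concentration_vector()
        for mid, c in dict(concentrations).items():
            x[model.met_index(mid)] = c
    cr = compile_kinetics(model)[model.rxn_index(reaction.id)]
    K = params.ensemble.K[params.row : params.row + 1]
    f = float(_eval_reaction(cr, K, x)[0][0])
    if f <= 0:
        raise CalibrationError(
            f"normalized rate f = {f} <= 0 for reaction {reaction.id!r}"
        )
    return v0 / f


def write_parameter_tsv(
    ens: ParameterEnsemble, path, *, mode: str = "w"
) -> None:
    """Append-friendly tidy serialization of a calibrated ensemble.

    Columns: fmcs_index, set_index, reaction, constant, value.  Writing is
    streamed set-by-set so memory stays bounded at ensemble scale; pass
    ``mode='a'`` to append further metabolomes to the same file.
    """
    model = ens.model
    header = mode == "w"
    with open(path, mode) as fh:
        if header:
            fh.write("fmcs_index\tset_index\treaction\tconstant\tvalue\n")
        fmcs = ens.fmcs_index if ens.fmcs_index is not None else 0
        for i in range(ens.n_sets):
            for j, p in enumerate(model.sampled_parameters):
                fh.write(
                    f"{fmcs}\t{i}\t{p.reaction}\t{p.symbol}\t"
                    f"{ens.K[i, j]:.12g}\n"
                )
            if ens.vmax is not None:
                for r, rid in enumerate(model.reaction_ids):
                    fh.write(
                        f"{fmcs}\t{i}\t{rid}\tVmax__{rid}\t"
                        f"{ens.vmax[i, r]:.12g}\n"
                    )


def saturation_profile(
    model: NetworkModel, ens: ParameterEnsemble, x: np.ndarray
) -> pd.DataFrame:
    """Saturation fractions [S]/([S]+K) for every K_M (tidy frame).

    Columns: set_index, reaction, metabolite, saturation, s_over_km.
    """
    rows = []
    for j, p in enumerate(model.sampled_parameters):
        if p.kind != "K_M":
            continue
        c = x[model.met_index(p.metabolite)]
        sat = c / (c + ens.K[:, j])
        rows.append(
            pd.DataFrame(
                {
                    "set_index": np.arange(ens.n_sets),
                    "reaction": p.reaction,
                    "metabolite": p.metabolite,
                    "saturation": sat,
                    "s_over_km": c / ens.K[:, j],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
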