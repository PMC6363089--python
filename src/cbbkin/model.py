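"""Network data model for ensemble kinetic analysis.

A :class:`NetworkModel` holds the metabolites, reactions, regulators and
promiscuity links of a kinetic metabolic model, the stoichiometric matrix
``S`` over balanced metabolites, and its conservation structure
``S = L @ Sred`` (link matrix / reduced full-rank stoichiometry).  The
conservation analysis is carried out with exact rational arithmetic so the
factorization is deterministic.

The shipped definition ``data/cbb_synechocystis.model`` encodes the
Calvin-Benson-Bassham cycle of *Synechocystis* sp. PCC 6803 embedded in
central carbon metabolism: 29 reactions, 36 metabolites and 149 kinetic
parameters (100 sampled binding/regulation constants, 29 Vmax or rate
constants, 20 equilibrium constants fixed from standard transformed Gibbs
energies).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import sympy
import yaml

R_GAS = 8.314e-3  # kJ mol^-1 K^-1
DEFAULT_TEMPERATURE = 298.15  # K

ROLES = {"balanced", "boundary-unbalanced", "sink-pool", "phosphate-pool"}
RATE_LAWS = {
    "reversible-MM",
    "irreversible-MM",
    "mass-action-symmetric",
    "lumped-supply",
}
REGULATOR_MODES = {
    "competitive-inhibitor",
    "allosteric-inhibitor",
    "allosteric-activator",
}


class ModelDefinitionError(ValueError):
    """Raised when a model definition violates the schema or its invariants."""


@dataclass
class MetaboliteSpec:
    id: str
    name: str = ""
    role: str = "balanced"
    conc_range: tuple[float, float] | None = None  # mM, for sampled species
    conc_fixed: float | None = None  # mM, for clamped species
    kinetics_excluded: bool = False  # e.g. water: activity 1 everywhere

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ModelDefinitionError(
                f"metabolite {self.id!r}: unknown role {self.role!r}"
            )
        if self.conc_range is not None:
            lo, hi = self.conc_range
            if not (0 < lo <= hi):
                raise ModelDefinitionError(
                    f"metabolite {self.id!r}: concentration range must satisfy "
                    f"0 < min <= max, got ({lo}, {hi})"
                )
        if self.conc_fixed is not None and self.conc_fixed < 0:
            raise ModelDefinitionError(
                f"metabolite {self.id!r}: fixed concentration must be >= 0"
            )

    @property
    def sampled(self) -> bool:
        return self.conc_range is not None


@dataclass
class RegulatorSpec:
    metabolite: str
    mode: str  # one of REGULATOR_MODES
    symbol: str  # parameter symbol of the K_i / K_a this regulator uses
    ref: bool = False  # True if `symbol` references an existing constant
    shared_group: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in REGULATOR_MODES:
            raise ModelDefinitionError(f"unknown regulator mode {self.mode!r}")


@dataclass
class ReactionSpec:
    id: str
    stoichiometry: dict[str, float]
    rate_law: str
    group: str = ""
    dG0_prime: float | None = None  # kJ/mol in the defined direction
    keq: float | None = None  # derived, 1 M reference state
    regulators: list[RegulatorSpec] = field(default_factory=list)
    promiscuity_partner: str | None = None
    v0: float | None = None  # steady-state input flux (model flux units)

    def __post_init__(self) -> None:
        if self.rate_law not in RATE_LAWS:
            raise ModelDefinitionError(
                f"reaction {self.id!r}: unknown or missing rate law "
                f"{self.rate_law!r}"
            )

    def substrates(self) -> list[tuple[str, float]]:
        return [(m, -c) for m, c in self.stoichiometry.items() if c < 0]

    def products(self) -> list[tuple[str, float]]:
        return [(m, c) for m, c in self.stoichiometry.items() if c > 0]


@dataclass
class ParameterDef:
    symbol: str
    kind: str  # 'K_M' | 'K_i' | 'K_a' | 'Vmax' | 'k' | 'Keq'
    reaction: str
    metabolite: str | None = None
    shared_group: str | None = None

    @property
    def sampled(self) -> bool:
        return self.kind in ("K_M", "K_i", "K_a")


@dataclass
class NetworkModel:
    name: str
    metabolites: list[MetaboliteSpec]
    reactions: list[ReactionSpec]
    temperature: float
    S: np.ndarray  # balanced metabolites x reactions
    Sred: np.ndarray  # full-rank reduced stoichiometric matrix
    L: np.ndarray  # link matrix, S = L @ Sred
    conservation_relations: np.ndarray  # left-nullspace basis, rows gamma
    independent_rows: list[int]  # rows of S kept in Sred
    parameters: list[ParameterDef]
    sampling_config: dict = field(default_factory=dict)
    source: dict = field(default_factory=dict)

    # -- index helpers ----------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def balanced_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.role == "balanced"]

    @property
    def sampled_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.sampled]

    def metabolite(self, mid: str) -> MetaboliteSpec:
        return self._met_map[mid]

    def reaction(self, rid: str) -> ReactionSpec:
        return self._rxn_map[rid]

    def met_index(self, mid: str) -> int:
        return self._met_idx[mid]

    def rxn_index(self, rid: str) -> int:
        return self._rxn_idx[rid]

    def __post_init__(self) -> None:
        self._met_map = {m.id: m for m in self.metabolites}
        self._rxn_map = {r.id: r for r in self.reactions}
        self._met_idx = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_idx = {r.id: i for i, r in enumerate(self.reactions)}
        self._par_idx = {p.symbol: i for i, p in enumerate(self.parameters)}

    # -- counts ------------------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def sampled_parameters(self) -> list[ParameterDef]:
        return [p for p in self.parameters if p.sampled]

    @property
    def n_sampled_constants(self) -> int:
        return len(self.sampled_parameters)

    @property
    def n_kinetic_parameters(self) -> int:
        """Distinct kinetic symbols: sampled constants + Vmax/k + Keq."""
        return len(self.parameters)

    def summary(self) -> dict:
        kinds: dict[str, int] = {}
        for p in self.parameters:
            kinds[p.kind] = kinds.get(p.kind, 0) + 1
        return {
            "name": self.name,
            "n_reactions": self.n_reactions,
            "n_metabolites": self.n_metabolites,
            "n_balanced": len(self.balanced_ids),
            "rank": self.Sred.shape[0],
            "n_conservation_relations": self.conservation_relations.shape[0],
            "n_kinetic_parameters": self.n_kinetic_parameters,
            "n_sampled_constants": self.n_sampled_constants,
            "parameter_kinds": kinds,
        }

    # -- concentration state helpers ---------------------------------------
    def fixed_concentration_vector(self) -> np.ndarray:
        """Full-length concentration vector with fixed species filled in.

        Sampled species are NaN; the phosphate pool is NaN (set per sample).
        """
        x = np.full(self.n_metabolites, np.nan)
        for i, m in enumerate(self.metabolites):
            if m.conc_fixed is not None and not m.sampled:
                x[i] = m.conc_fixed
        return x

    def thermo_checked_reactions(self) -> list[ReactionSpec]:
        """Reactions subject to the Gibbs-energy feasibility filter."""
        return [r for r in self.reactions if r.dG0_prime is not None]


# ---------------------------------------------------------------------------
# conservation structure
# ---------------------------------------------------------------------------

def compute_conservation(
    S: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    """Factor ``S = L @ Sred`` and find the conservation relations.

    Uses exact rational row reduction, so the choice of independent rows
    (the first maximal independent subset in declaration order) and the link
    matrix are deterministic.

    Returns ``(Sred, L, conservation_relations, independent_rows)`` where the
    rows of ``conservation_relations`` span the left nullspace of ``S``
    (each row ``gamma`` satisfies ``gamma @ S == 0``).
    """
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    M = sympy.Matrix(
        [[sympy.nsimplify(v, rational=True) for v in row] for row in S.tolist()]
    )
    # pivot columns of rref(S^T) index a maximal independent row subset of S
    _, pivots = M.T.rref()
    ind = [int(p) for p in pivots]
    if not ind:
        Sred = np.zeros((0, n))
        L = np.zeros((m, 0))
        relations = np.eye(m)
        return Sred, L, relations, ind
    Ms = M[ind, :]
    # L solves L @ Sred = S; rows of Sred are independent, so the normal
    # equations are exact: L = S Sred^T (Sred Sred^T)^-1
    G = Ms * Ms.T
    Lsym = (M * Ms.T) * G.inv()
    assert Lsym * Ms == M
    L = np.array(Lsym.tolist(), dtype=float)
    Sred = np.array(Ms.tolist(), dtype=float)
    null = M.T.nullspace()
    if null:
        rel_rows = []
        for v in null:
            v = sympy.nsimplify(1) * v
            denoms = [sympy.fraction(x)[1] for x in v]
            scale = sympy.lcm([d for d in denoms]) if denoms else 1
            rel_rows.append([float(x * scale) for x in v])
        relations = np.array(rel_rows, dtype=float)
    else:
        relations = np.zeros((0, m))
    return Sred, L, relations, ind


# ---------------------------------------------------------------------------
# building a model from a structured definition
# ---------------------------------------------------------------------------

def _parse_metabolite(entry: Mapping) -> MetaboliteSpec:
    rng = entry.get("conc_range_mM")
    return MetaboliteSpec(
        id=str(entry["id"]),
        name=str(entry.get("name", "")),
        role=entry.get("role", "balanced"),
        conc_range=tuple(float(v) for v in rng) if rng is not None else None,
        conc_fixed=(
            float(entry["conc_fixed_mM"]) if "conc_fixed_mM" in entry else None
        ),
        kinetics_excluded=bool(entry.get("kinetics_excluded", False)),
    )


def build_network(
    source: str | Path | Mapping,
    *,
    share_promiscuity_constants: bool = True,
) -> NetworkModel:
    """Build and validate a :class:`NetworkModel` from a definition.

    ``source`` may be a path to a YAML model file or an already-parsed
    mapping with sections ``metabolites`` / ``reactions`` / ``promiscuity``.

    With ``share_promiscuity_constants=False`` every promiscuity-derived
    cross inhibitor and every ``shared:`` regulator receives an independent
    constant instead of referencing the partner's, which changes the
    parameter count (used as a structural guard).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            defn = yaml.safe_load(fh)
    else:
        defn = dict(source)

    temperature = float(defn.get("temperature_K", DEFAULT_TEMPERATURE))

    mets = [_parse_metabolite(e) for e in defn.get("metabolites", [])]
    met_ids = [m.id for m in mets]
    if len(set(met_ids)) != len(met_ids):
        dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
        raise ModelDefinitionError(f"duplicated metabolite ids: {dupes}")
    met_map = {m.id: m for m in mets}
    n_ppool = sum(1 for m in mets if m.role == "phosphate-pool")
    if n_ppool > 1:
        raise ModelDefinitionError("more than one phosphate-pool metabolite")

    rxns: list[ReactionSpec] = []
    seen_rxn: set[str] = set()
    for e in defn.get("reactions", []):
        rid = str(e["id"])
        if rid in seen_rxn:
            raise ModelDefinitionError(f"duplicated reaction id: {rid!r}")
        seen_rxn.add(rid)
        if "rate_law" not in e:
            raise ModelDefinitionError(f"reaction {rid!r} has no rate law")
        stoich = {str(k): float(v) for k, v in e["stoichiometry"].items()}
        for mid in stoich:
            if mid not in met_map:
                raise ModelDefinitionError(
                    f"reaction {rid!r}: unknown metabolite {mid!r} in "
                    f"stoichiometry"
                )
        dg0 = e.get("dG0_prime_kJ_mol")
        rxn = ReactionSpec(
            id=rid,
            group=str(e.get("group", "")),
            stoichiometry=stoich,
            rate_law=e["rate_law"],
            dG0_prime=float(dg0) if dg0 is not None else None,
            v0=float(e["v0"]) if e.get("v0") is not None else None,
        )
        if rxn.dG0_prime is not None:
            rxn.keq = float(np.exp(-rxn.dG0_prime / (R_GAS * temperature)))
        if rxn.rate_law == "reversible-MM" and rxn.keq is None:
            raise ModelDefinitionError(
                f"reaction {rid!r}: reversible-MM requires dG0_prime_kJ_mol"
            )
        for reg in e.get("regulators", []) or []:
            mid = str(reg["metabolite"])
            if mid not in met_map:
                raise ModelDefinitionError(
                    f"reaction {rid!r}: regulator references unknown "
                    f"metabolite {mid!r}"
                )
            mode = reg.get("mode", "")
            shared = reg.get("shared")
            if not share_promiscuity_constants:
                shared = None
            scope = shared if shared is not None else rid
            prefix = {
                "competitive-inhibitor": "Ki",
                "allosteric-inhibitor": "Kai",
                "allosteric-activator": "Kaa",
            }.get(mode)
            if prefix is None:
                raise ModelDefinitionError(
                    f"reaction {rid!r}: unknown regulator mode {mode!r}"
                )
            rxn.regulators.append(
                RegulatorSpec(
                    metabolite=mid,
                    mode=mode,
                    symbol=f"{prefix}__{scope}__{mid}",
                    shared_group=shared,
                )
            )
        rxns.append(rxn)
    rxn_map = {r.id: r for r in rxns}

    # promiscuity links: partner annotation + derived cross inhibition
    pairs = [tuple(p) for p in defn.get("promiscuity", []) or []]
    for pair in pairs:
        if len(pair) != 2:
            raise ModelDefinitionError(f"promiscuity entry must be a pair: {pair}")
        a, b = (str(x) for x in pair)
        for x in (a, b):
            if x not in rxn_map:
                raise ModelDefinitionError(
                    f"promiscuity partner {x!r} not found among reactions"
                )
        rxn_map[a].promiscuity_partner = b
        rxn_map[b].promiscuity_partner = a

    # enumerate the parameter catalog (declaration order everywhere)
    params: list[ParameterDef] = []
    seen_sym: set[str] = set()

    def _add(p: ParameterDef) -> None:
        if p.symbol in seen_sym:
            return
        seen_sym.add(p.symbol)
        params.append(p)

    def _km_symbol(rid: str, mid: str) -> str:
        return f"KM__{rid}__{mid}"

    def _km_metabolites(rxn: ReactionSpec) -> list[str]:
        out = [m for m, _ in rxn.substrates() if not met_map[m].kinetics_excluded]
        if rxn.rate_law == "reversible-MM":
            out += [m for m, _ in rxn.products() if not met_map[m].kinetics_excluded]
        return out

    for rxn in rxns:
        if rxn.rate_law in ("reversible-MM", "irreversible-MM"):
            for mid in _km_metabolites(rxn):
                _add(ParameterDef(_km_symbol(rxn.id, mid), "K_M", rxn.id, mid))
        for reg in rxn.regulators:
            kind = "K_a" if reg.mode == "allosteric-activator" else "K_i"
            _add(
                ParameterDef(
                    reg.symbol, kind, rxn.id, reg.metabolite, reg.shared_group
                )
            )

    # cross-competitive inhibition from promiscuity: partner metabolites that
    # carry a K_M in the partner reaction and do not participate here
    for rxn in rxns:
        partner_id = rxn.promiscuity_partner
        if partner_id is None:
            continue
        partner = rxn_map[partner_id]
        own_mets = set(rxn.stoichiometry)
        for mid in _km_metabolites(partner):
            if mid in own_mets:
                continue
            if share_promiscuity_constants:
                rxn.regulators.append(
                    RegulatorSpec(
                        metabolite=mid,
                        mode="competitive-inhibitor",
                        symbol=_km_symbol(partner_id, mid),
                        ref=True,
                        shared_group=f"{rxn.id}.{partner_id}",
                    )
                )
            else:
                sym = f"Ki__{rxn.id}__{mid}"
                rxn.regulators.append(
                    RegulatorSpec(metabolite=mid, mode="competitive-inhibitor",
                                  symbol=sym)
                )
                _add(ParameterDef(sym, "K_i", rxn.id, mid))

    for rxn in rxns:
        if rxn.rate_law == "mass-action-symmetric":
            _add(ParameterDef(f"k__{rxn.id}", "k", rxn.id))
        else:
            _add(ParameterDef(f"Vmax__{rxn.id}", "Vmax", rxn.id))
    for rxn in rxns:
        if rxn.rate_law == "reversible-MM":
            _add(ParameterDef(f"Keq__{rxn.id}", "Keq", rxn.id))

    # stoichiometric matrix over balanced metabolites
    balanced = [m.id for m in mets if m.role == "balanced"]
    bal_idx = {m: i for i, m in enumerate(balanced)}
    S = np.zeros((len(balanced), len(rxns)))
    for j, rxn in enumerate(rxns):
        for mid, coeff in rxn.stoichiometry.items():
            i = bal_idx.get(mid)
            if i is not None:
                S[i, j] = coeff

    Sred, L, relations, ind = compute_conservation(S)

    return NetworkModel(
        name=str(defn.get("name", "model")),
        metabolites=mets,
        reactions=rxns,
        temperature=temperature,
        S=S,
        Sred=Sred,
        L=L,
        conservation_relations=relations,
        independent_rows=ind,
        parameters=params,
        sampling_config=dict(defn.get("sampling", {}) or {}),
        source=defn,
    )


def save_model(model: NetworkModel, path: str | Path) -> None:
    """Write the model definition back to a YAML file (round-trip safe)."""
    with open(path, "w") as fh:
        yaml.safe_dump(model.source, fh, sort_keys=False)


def builtin_model_path() -> Path:
    """Path of the shipped CBB model definition."""
    return Path(
        importlib.resources.files("cbbkin").joinpath(
            "data/cbb_synechocystis.model"
        )
    )


def load_cbb_model(**kwargs) -> NetworkModel:
    """Build the shipped Calvin-cycle model of *Synechocystis*."""
    return build_network(builtin_model_path(), **kwargs)
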