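"""Generation of feasible metabolite concentration sets (fMCSs).

Candidate metabolomes are drawn log-uniformly within per-metabolite
concentration ranges and kept only if they satisfy all four physiological
constraints:

1. every reaction with thermodynamic data has a negative Gibbs-energy change
   in its defined flux direction (``dG = dG0' + RT ln Q < 0``),
2. the summed concentration of the balanced (sampled) metabolites does not
   exceed a total cap (default 100 mM),
3. cofactor pair ratios (ATP/ADP, NADPH/NADP, NADH/NAD) lie within bounds,
4. the phosphate pool is a sampled multiple (default 1.1-5x) of free Pi.

Sampling is plain rejection sampling, vectorized over fixed-size blocks of
rounds.  Each block derives its own counter-based random stream from
``(seed, block_index)``, so results are bit-identical regardless of how the
rounds are chunked or parallelized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import R_GAS, NetworkModel, ReactionSpec
from .rng import STAGE_FMCS, stream as rng_stream

DEFAULT_BLOCK_SIZE = 1 << 16

GIBBS = "gibbs"
TOTAL_CAP = "total_concentration"
COFACTOR_RATIO = "cofactor_ratio"
PPOOL = "ppool_multiplier"
CONSTRAINTS = (GIBBS, TOTAL_CAP, COFACTOR_RATIO, PPOOL)


class InfeasibleConfiguration(RuntimeError):
    """No feasible metabolome found within the round budget."""

    def __init__(self, message: str, rejection_tally: dict):
        super().__init__(message)
        self.rejection_tally = rejection_tally


@dataclass
class ConcentrationRangeTable:
    """Per-metabolite sampling ranges plus the physiological constraints."""

    metabolites: list[str]
    min_mM: np.ndarray
    max_mM: np.ndarray
    cofactor_ratio_bounds: dict[str, tuple[float, float]] = field(
        default_factory=dict
    )  # e.g. {"ATP/ADP": (1, 10)}
    ppool_multiplier_range: tuple[float, float] = (1.1, 5.0)
    total_cap_mM: float = 100.0

    def __post_init__(self) -> None:
        self.min_mM = np.asarray(self.min_mM, dtype=float)
        self.max_mM = np.asarray(self.max_mM, dtype=float)
        if np.any(self.min_mM <= 0) or np.any(self.max_mM <= 0):
            raise ValueError("concentration bounds must be positive")
        if np.any(self.min_mM > self.max_mM):
            bad = [
                m
                for m, lo, hi in zip(self.metabolites, self.min_mM, self.max_mM)
                if lo > hi
            ]
            raise ValueError(f"min > max for metabolites {bad}")
        if self.ppool_multiplier_range[0] <= 1.0:
            raise ValueError("PPool multiplier range must start above 1")

    def index(self, mid: str) -> int:
        return self.metabolites.index(mid)

    @classmethod
    def from_model(cls, model: NetworkModel) -> "ConcentrationRangeTable":
        """Build the table from the ranges shipped in the model definition."""
        ids = model.sampled_ids
        lo = np.array([model.metabolite(m).conc_range[0] for m in ids])
        hi = np.array([model.metabolite(m).conc_range[1] for m in ids])
        cfg = model.sampling_config
        ratio = {
            str(k): (float(v[0]), float(v[1]))
            for k, v in (cfg.get("cofactor_ratio_bounds") or {}).items()
        }
        ppool = tuple(cfg.get("ppool_multiplier_range", (1.1, 5.0)))
        cap = float(cfg.get("total_concentration_cap_mM", 100.0))
        return cls(ids, lo, hi, ratio, (ppool[0], ppool[1]), cap)

    @classmethod
    def from_tsv(
        cls, path: str | Path, model: NetworkModel
    ) -> "ConcentrationRangeTable":
        """Read a ranges table (columns metabolite, min_mM, max_mM).

        Constraint settings (ratio bounds, cap, PPool multiplier) are taken
        from the model definition; the TSV overrides the ranges only.
        """
        df = pd.read_csv(path, sep="\t", dtype={"metabolite": str})
        table = cls.from_model(model)
        by_id = dict(zip(df["metabolite"], zip(df["min_mM"], df["max_mM"])))
        missing = [m for m in table.metabolites if m not in by_id]
        if missing:
            raise ValueError(f"ranges file lacks sampled metabolites {missing}")
        lo = np.array([by_id[m][0] for m in table.metabolites], dtype=float)
        hi = np.array([by_id[m][1] for m in table.metabolites], dtype=float)
        return cls(
            table.metabolites,
            lo,
            hi,
            table.cofactor_ratio_bounds,
            table.ppool_multiplier_range,
            table.total_cap_mM,
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "metabolite": self.metabolites,
                "min_mM": self.min_mM,
                "max_mM": self.max_mM,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class MetabolomeSample:
    """One candidate metabolome with its feasibility verdict."""

    concentrations: pd.Series  # mM over sampled metabolites
    ppool_multiple: float
    dG: pd.Series  # kJ/mol over thermodynamically checked reactions
    feasible: bool
    rejection_reasons: list[str] = field(default_factory=list)
    index: int | None = None  # position in the feasible ensemble

    @property
    def ppool_mM(self) -> float:
        return float(self.ppool_multiple * self.concentrations["Pi"])


@dataclass
class FmcsResult:
    """Feasible samples plus acceptance bookkeeping for one sampling run."""

    samples: list[MetabolomeSample]
    rounds: int
    accepted: int
    seed: int
    rejection_tally: dict

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.rounds if self.rounds else 0.0

    def concentration_frame(self) -> pd.DataFrame:
        """fMCS x metabolite matrix (mM), with the PPool column appended."""
        rows = [s.concentrations for s in self.samples]
        df = pd.DataFrame(rows).reset_index(drop=True)
        df["PPool"] = [s.ppool_mM for s in self.samples]
        df.index.name = "fmcs_index"
        return df


def _rng_for_block(seed: int, block: int) -> np.random.Generator:
    return rng_stream(seed, STAGE_FMCS, block)


def sample_log_uniform(
    ranges: ConcentrationRangeTable,
    n: int,
    seed: int,
    *,
    block: int = 0,
) -> np.ndarray:
    """Draw ``n`` concentration vectors, each coordinate log10-uniform.

    Returns an ``(n, n_metabolites)`` array in mM.  Degenerate ranges
    (min == max) yield that constant.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng_for_block(seed, block)
    lo = np.log10(ranges.min_mM)
    hi = np.log10(ranges.max_mM)
    u = rng.random((n, lo.size))
    return 10.0 ** (lo + u * (hi - lo))


def gibbs_energy(
    reaction: ReactionSpec,
    concentrations: Mapping[str, float],
    temperature: float = 298.15,
    *,
    excluded: Sequence[str] = ("H2O",),
) -> float:
    """Gibbs-energy change (kJ/mol) of a reaction at given concentrations.

    ``dG = dG0' + RT ln Q`` with the mass-action ratio ``Q`` taken in the
    reaction's defined direction and concentrations (mM) converted to molar.
    Water is treated at unit activity.
    """
    if reaction.dG0_prime is None:
        raise ValueError(
            f"reaction {reaction.id!r} has no dG0_prime; sink and supply "
            "reactions are not thermodynamically checkable"
        )
    rt = R_GAS * temperature
    ln_q = 0.0
    for mid, coeff in reaction.stoichiometry.items():
        if mid in excluded:
            continue
        c = float(concentrations[mid])
        if c <= 0:
            raise ValueError(f"non-positive concentration for {mid!r}")
        ln_q += coeff * np.log(c / 1000.0)
    return reaction.dG0_prime + rt * ln_q


def _thermo_matrices(
    model: NetworkModel, ranges: ConcentrationRangeTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Stoichiometry of checked reactions over (sampled | fixed) species.

    Returns ``(N_sampled, fixed_logq, dG0, reaction_ids)`` where for block
    concentration matrix C (rows = rounds, mM):
    ``dG = dG0 + RT * (log(C/1000) @ N_sampled.T + fixed_logq)``.
    """
    checked = model.thermo_checked_reactions()
    ids = [r.id for r in checked]
    n_s = len(ranges.metabolites)
    pos = {m: i for i, m in enumerate(ranges.metabolites)}
    N = np.zeros((len(checked), n_s))
    fixed_logq = np.zeros(len(checked))
    for j, rxn in enumerate(checked):
        for mid, coeff in rxn.stoichiometry.items():
            spec = model.metabolite(mid)
            if spec.kinetics_excluded:
                continue
            if mid in pos:
                N[j, pos[mid]] = coeff
            elif spec.conc_fixed is not None:
                fixed_logq[j] += coeff * np.log(spec.conc_fixed / 1000.0)
            else:
                raise ValueError(
                    f"reaction {rxn.id!r}: metabolite {mid!r} is neither "
                    "sampled nor fixed"
                )
    dG0 = np.array([r.dG0_prime for r in checked])
    return N, fixed_logq, dG0, ids


def _ratio_indices(
    ranges: ConcentrationRangeTable,
) -> list[tuple[str, int, int, float, float]]:
    out = []
    for key, (lo, hi) in ranges.cofactor_ratio_bounds.items():
        num, den = key.split("/")
        out.append((key, ranges.index(num), ranges.index(den), lo, hi))
    return out


def generate_fmcs(
    model: NetworkModel,
    ranges: ConcentrationRangeTable | None = None,
    max_rounds: int = 10_000_000,
    target: int = 100,
    seed: int = 0,
    *,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> FmcsResult:
    """Rejection-sample feasible metabolite concentration sets.

    Stops when ``target`` feasible sets are collected or ``max_rounds``
    candidate rounds are exhausted.  Raises
    :class:`InfeasibleConfiguration` with a per-constraint rejection tally
    if no candidate passes.
    """
    if ranges is None:
        ranges = ConcentrationRangeTable.from_model(model)
    missing = [m for m in model.sampled_ids if m not in ranges.metabolites]
    if missing:
        raise ValueError(f"ranges table lacks sampled metabolites {missing}")

    N, fixed_logq, dG0, checked_ids = _thermo_matrices(model, ranges)
    rt = R_GAS * model.temperature
    balanced_cols = [
        ranges.index(m) for m in model.balanced_ids if m in ranges.metabolites
    ]
    ratios = _ratio_indices(ranges)
    pi_col = ranges.index("Pi") if "Pi" in ranges.metabolites else None
    has_ppool = any(m.role == "phosphate-pool" for m in model.metabolites)
    mult_lo, mult_hi = ranges.ppool_multiplier_range

    tally = {c: 0 for c in CONSTRAINTS}
    tally["gibbs_by_reaction"] = {r: 0 for r in checked_ids}

    samples: list[MetabolomeSample] = []
    rounds = accepted = 0
    block = 0
    while rounds < max_rounds and accepted < target:
        n = min(block_size, max_rounds - rounds)
        conc = sample_log_uniform(ranges, n, seed, block=block)
        rng = _rng_for_block(seed, block)
        rng.random((n, len(ranges.metabolites)))  # skip the draws used above
        if has_ppool and pi_col is not None:
            lm = np.log10(mult_lo)
            hm = np.log10(mult_hi)
            mult = 10.0 ** (lm + rng.random(n) * (hm - lm))
        else:
            mult = np.ones(n)

        dG = dG0 + rt * (np.log(conc / 1000.0) @ N.T + fixed_logq)
        ok_g = dG < 0
        ok_gibbs = ok_g.all(axis=1)
        total = conc[:, balanced_cols].sum(axis=1)
        ok_cap = total <= ranges.total_cap_mM
        ok_ratio = np.ones(n, dtype=bool)
        for _, i_num, i_den, lo, hi in ratios:
            r = conc[:, i_num] / conc[:, i_den]
            ok_ratio &= (r >= lo) & (r <= hi)
        ok_mult = (mult >= mult_lo) & (mult <= mult_hi)

        feasible = ok_gibbs & ok_cap & ok_ratio & ok_mult
        tally[GIBBS] += int((~ok_gibbs).sum())
        tally[TOTAL_CAP] += int((~ok_cap).sum())
        tally[COFACTOR_RATIO] += int((~ok_ratio).sum())
        tally[PPOOL] += int((~ok_mult).sum())
        bad_per_rxn = (~ok_g).sum(axis=0)
        for rid, cnt in zip(checked_ids, bad_per_rxn):
            tally["gibbs_by_reaction"][rid] += int(cnt)

        for i in np.flatnonzero(feasible):
            if accepted >= target:
                break
            samples.append(
                MetabolomeSample(
                    concentrations=pd.Series(
                        conc[i], index=ranges.metabolites, dtype=float
                    ),
                    ppool_multiple=float(mult[i]),
                    dG=pd.Series(dG[i], index=checked_ids, dtype=float),
                    feasible=True,
                    index=accepted,
                )
            )
            accepted += 1
        rounds += n
        block += 1

    if accepted == 0:
        raise InfeasibleConfiguration(
            f"no feasible metabolome in {rounds} rounds; rejection tally: "
            + ", ".join(f"{k}={tally[k]}" for k in CONSTRAINTS),
            tally,
        )
    return FmcsResult(samples, rounds, accepted, seed, tally)


def full_concentration_vector(
    model: NetworkModel, sample: MetabolomeSample
) -> np.ndarray:
    """Assemble the complete concentration vector (mM, declaration order)."""
    x = model.fixed_concentration_vector()
    for mid, c in sample.concentrations.items():
        x[model.met_index(mid)] = c
    for i, m in enumerate(model.metabolites):
        if m.role == "phosphate-pool":
            x[i] = sample.ppool_mM
    if np.isnan(x).any():
        bad = [model.metabolite_ids[i] for i in np.flatnonzero(np.isnan(x))]
        raise ValueError(f"no concentration available for {bad}")
    return x


def verify_fmcs(
    model: NetworkModel,
    ranges: ConcentrationRangeTable,
    sample: MetabolomeSample,
) -> list[str]:
    """Re-check all four feasibility constraints; returns violated ones."""
    reasons = []
    conc = dict(sample.concentrations)
    conc.update(
        {
            m.id: m.conc_fixed
            for m in model.metabolites
            if m.conc_fixed is not None and m.id not in conc
        }
    )
    for rxn in model.thermo_checked_reactions():
        if gibbs_energy(rxn, conc, model.temperature) >= 0:
            reasons.append(f"{GIBBS}:{rxn.id}")
    total = sum(sample.concentrations[m] for m in model.balanced_ids)
    if total > ranges.total_cap_mM:
        reasons.append(TOTAL_CAP)
    for key, (lo, hi) in ranges.cofactor_ratio_bounds.items():
        num, den = key.split("/")
        r = sample.concentrations[num] / sample.concentrations[den]
        if not (lo <= r <= hi):
            reasons.append(f"{COFACTOR_RATIO}:{key}")
    lo, hi = ranges.ppool_multiplier_range
    if not (lo <= sample.ppool_multiple <= hi):
        reasons.append(PPOOL)
    return reasons
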