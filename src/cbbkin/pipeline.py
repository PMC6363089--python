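"""Checkpointed orchestration of the full ensemble analysis.

Stages: fixtures (steady-state flux) -> metabolome sampling -> kinetic
parameter sampling -> stability classification -> control analysis ->
ensemble post-processing.  Every stage writes its outputs (TSV + JSON
sidecar with seed and counts) into the run directory and is skipped on
rerun when its outputs already exist, so deleting only downstream
artifacts and rerunning reproduces them identically.  All stochastic
stages derive their streams from ``(master seed, stage, block index)``;
a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fixtures import (
    FluxVector,
    apply_flux,
    default_ranges,
    generate_flux_vector,
    load_flux_tsv,
)
from .kinetics import calibrate_vmax_ensemble, sample_parameter_ensemble
from .mca import control_ensemble
from .model import NetworkModel, build_network, load_cbb_model
from .postprocess import (
    EnsembleSummary,
    aggregate_fcc,
    cluster_control_patterns,
    decile_location_test,
    stability_decile_density,
)
from .sampling import (
    ConcentrationRangeTable,
    FmcsResult,
    MetabolomeSample,
    full_concentration_vector,
    generate_fmcs,
)
from .stability import classify_ensemble

FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Configuration of one ensemble run (all counts must be >= 1)."""

    model: str = "builtin"  # path to a model file, or "builtin"
    ranges: str = "default"  # path to a ranges TSV, or "default"
    flux: str = "generate"  # path to a flux TSV, or "generate"
    max_rounds: int = 10_000_000
    target_fmcs: int = 100
    sets_per_fmcs: int = 1000
    seed: int = 0
    outdir: str = "cbbkin_run"
    subsample_fraction: float = 0.1
    n_bootstrap: int = 1000
    make_plots: bool = False

    def __post_init__(self) -> None:
        for name in ("max_rounds", "target_fmcs", "sets_per_fmcs", "n_bootstrap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sidecar(path: Path, payload: dict) -> None:
    payload = {"cbbkin_version": __version__, **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_model_for(cfg: RunConfig) -> NetworkModel:
    if cfg.model == "builtin":
        return load_cbb_model()
    return build_network(cfg.model)


def ranges_for(cfg: RunConfig, model: NetworkModel) -> ConcentrationRangeTable:
    if cfg.ranges == "default":
        return default_ranges(model)
    return ConcentrationRangeTable.from_tsv(cfg.ranges, model)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_flux(cfg: RunConfig, model: NetworkModel) -> FluxVector:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "flux.tsv"
    if path.exists():
        flux = load_flux_tsv(model, path)
    elif cfg.flux == "generate":
        flux = generate_flux_vector(model, seed=cfg.seed)
        flux.to_tsv(path)
        _sidecar(out / "flux.json", {"seed": cfg.seed, "provenance": flux.provenance})
    else:
        flux = load_flux_tsv(model, cfg.flux)
        flux.to_tsv(path)
        _sidecar(out / "flux.json", {"seed": cfg.seed, "provenance": flux.provenance})
    apply_flux(model, flux)
    return flux


def stage_states(cfg: RunConfig, model: NetworkModel) -> pd.DataFrame:
    """Feasible metabolome table (fmcs_index x metabolite, plus PPool)."""
    out = Path(cfg.outdir)
    path = out / "fmcs.tsv"
    if path.exists():
        return pd.read_csv(path, sep="\t", index_col="fmcs_index")
    ranges = ranges_for(cfg, model)
    res: FmcsResult = generate_fmcs(
        model, ranges, max_rounds=cfg.max_rounds, target=cfg.target_fmcs,
        seed=cfg.seed,
    )
    df = res.concentration_frame()
    df["ppool_multiple"] = [s.ppool_multiple for s in res.samples]
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    # downstream stages must see exactly what a resumed run would read,
    # so hand back the serialized (12-significant-digit) table
    df = pd.read_csv(path, sep="\t", index_col="fmcs_index")
    _sidecar(
        out / "fmcs.json",
        {
            "seed": cfg.seed,
            "rounds": res.rounds,
            "accepted": res.accepted,
            "acceptance_rate": res.acceptance_rate,
            "rejection_tally": res.rejection_tally,
        },
    )
    return df


def _samples_from_frame(
    model: NetworkModel, fmcs_frame: pd.DataFrame
) -> list[MetabolomeSample]:
    sampled = model.sampled_ids
    out = []
    for idx, row in fmcs_frame.iterrows():
        out.append(
            MetabolomeSample(
                concentrations=row[sampled].astype(float),
                ppool_multiple=float(row["ppool_multiple"]),
                dG=pd.Series(dtype=float),
                feasible=True,
                index=int(idx),
            )
        )
    return out


def stage_params(
    cfg: RunConfig, model: NetworkModel, fmcs_frame: pd.DataFrame
) -> dict:
    """Sample and calibrate parameter ensembles for every fMCS (cached)."""
    out = Path(cfg.outdir)
    path = out / "params_cache.npz"
    if path.exists():
        data = np.load(path)
        return {"K": data["K"], "vmax": data["vmax"]}
    samples = _samples_from_frame(model, fmcs_frame)
    v0 = np.array([model.reaction(r).v0 for r in model.reaction_ids])
    K_all, vmax_all = [], []
    for s in samples:
        x0 = full_concentration_vector(model, s)
        ens = sample_parameter_ensemble(model, s, cfg.sets_per_fmcs, cfg.seed)
        calibrate_vmax_ensemble(model, ens, x0, v0)
        K_all.append(ens.K)
        vmax_all.append(ens.vmax)
    K = np.stack(K_all)
    vmax = np.stack(vmax_all)
    np.savez_compressed(path, K=K, vmax=vmax)
    _sidecar(
        out / "params.json",
        {
            "seed": cfg.seed,
            "n_fmcs": len(samples),
            "sets_per_fmcs": cfg.sets_per_fmcs,
            "n_sampled_constants": model.n_sampled_constants,
        },
    )
    return {"K": K, "vmax": vmax}


def stage_stability(
    cfg: RunConfig,
    model: NetworkModel,
    fmcs_frame: pd.DataFrame,
    params: dict,
) -> pd.DataFrame:
    """Per-set stability verdicts plus the per-fMCS summary table."""
    out = Path(cfg.outdir)
    path = out / "stability.tsv"
    if path.exists():
        return pd.read_csv(path, sep="\t")
    samples = _samples_from_frame(model, fmcs_frame)
    rows = []
    for i, s in enumerate(samples):
        x0 = full_concentration_vector(model, s)
        from .kinetics import ParameterEnsemble

        ens = ParameterEnsemble(
            model,
            params["K"][i].astype(float),
            params["vmax"][i].astype(float),
            fmcs_index=s.index,
            seed=cfg.seed,
        )
        cls = classify_ensemble(model, ens, x0)
        rows.append(
            pd.DataFrame(
                {
                    "fmcs_index": s.index,
                    "set_index": np.arange(ens.n_sets),
                    "stable": cls["stable"].astype(int),
                    "marginal": cls["marginal"].astype(int),
                    "failed": cls["failed"].astype(int),
                    "max_real_part": cls["max_real_part"],
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    summary = (
        df.groupby("fmcs_index")
        .agg(
            n_sets=("stable", "size"),
            n_stable=("stable", "sum"),
            n_marginal=("marginal", "sum"),
            n_failed=("failed", "sum"),
        )
        .assign(fraction=lambda t: t["n_stable"] / t["n_sets"])
    )
    summary.to_csv(out / "stability_summary.tsv", sep="\t", float_format=FLOAT_FMT)
    _sidecar(
        out / "stability.json",
        {
            "seed": cfg.seed,
            "n_sets_total": int(len(df)),
            "n_stable_total": int(df["stable"].sum()),
            "median_stable_percent": float(
                100.0 * summary["fraction"].median()
            ),
        },
    )
    return df


def stage_mca(
    cfg: RunConfig,
    model: NetworkModel,
    fmcs_frame: pd.DataFrame,
    params: dict,
) -> dict:
    """Flux control coefficients for all stable sets (cached tensor)."""
    out = Path(cfg.outdir)
    path = out / "fcc_cache.npz"
    if path.exists():
        data = np.load(path)
        fcc = data["C_J"].astype(float)
        meta = {
            "fmcs_index": data["fmcs_index"],
            "set_index": data["set_index"],
            "n_dropped_singular": int(data["n_dropped"]),
        }
    else:
        samples = _samples_from_frame(model, fmcs_frame)
        from .kinetics import ParameterEnsemble

        tensors, fmcs_ids, set_ids = [], [], []
        dropped = 0
        for i, s in enumerate(samples):
            x0 = full_concentration_vector(model, s)
            ens = ParameterEnsemble(
                model,
                params["K"][i].astype(float),
                params["vmax"][i].astype(float),
                fmcs_index=s.index,
                seed=cfg.seed,
            )
            cc = control_ensemble(model, ens, x0)
            dropped += cc["n_dropped_singular"]
            if cc["C_J"].size:
                tensors.append(cc["C_J"].astype(np.float32))
                fmcs_ids.append(np.full(len(cc["set_indices"]), s.index))
                set_ids.append(cc["set_indices"])
        fcc = (
            np.concatenate(tensors)
            if tensors
            else np.empty((0, model.n_reactions, model.n_reactions), np.float32)
        )
        fmcs_idx = np.concatenate(fmcs_ids) if fmcs_ids else np.empty(0, int)
        set_idx = np.concatenate(set_ids) if set_ids else np.empty(0, int)
        np.savez_compressed(
            path, C_J=fcc, fmcs_index=fmcs_idx, set_index=set_idx,
            n_dropped=dropped,
        )
        fcc = fcc.astype(float)
        meta = {
            "fmcs_index": fmcs_idx,
            "set_index": set_idx,
            "n_dropped_singular": dropped,
        }
        _sidecar(
            out / "mca.json",
            {
                "seed": cfg.seed,
                "n_stable_sets": int(fcc.shape[0]),
                "n_dropped_singular": dropped,
            },
        )
    if fcc.shape[0]:
        med, mad = aggregate_fcc(fcc, model.reaction_ids)
        med.to_csv(out / "fcc_median.tsv", sep="\t", float_format=FLOAT_FMT)
        mad.to_csv(out / "fcc_mad.tsv", sep="\t", float_format=FLOAT_FMT)
    return {"C_J": fcc, **meta}


def stage_postprocess(
    cfg: RunConfig,
    model: NetworkModel,
    fmcs_frame: pd.DataFrame,
    stability_df: pd.DataFrame,
    mca_out: dict,
) -> EnsembleSummary:
    out = Path(cfg.outdir)
    frac = (
        stability_df.groupby("fmcs_index")["stable"].mean().rename("fraction")
    )
    conc = fmcs_frame.drop(columns=["ppool_multiple"])
    summary = EnsembleSummary(
        stable_fraction=frac, n_sets_per_fmcs=cfg.sets_per_fmcs
    )
    fcc = mca_out["C_J"]
    if fcc.shape[0]:
        summary.fcc_median, summary.fcc_mad = aggregate_fcc(
            fcc, model.reaction_ids
        )
    if len(frac) >= 20:
        dens = stability_decile_density(conc, frac)
        rows = []
        for met, d in dens.items():
            rows.append(
                pd.DataFrame(
                    {
                        "metabolite": met,
                        "log10_mM": d["grid"],
                        "density_top": d["top"],
                        "density_bottom": d["bottom"],
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(
            out / "decile_densities.tsv", sep="\t", index=False,
            float_format=FLOAT_FMT,
        )
        summary.decile_densities = dens
        if "RuBP" in conc.columns:
            summary.rubp_test = decile_location_test(conc, frac, "RuBP")
            _sidecar(out / "rubp_test.json", summary.rubp_test)
    if fcc.shape[0] >= 10:
        for axis in ("effector", "target"):
            res = cluster_control_patterns(
                fcc,
                model.reaction_ids,
                axis=axis,
                subsample_fraction=cfg.subsample_fraction,
                n_bootstrap=cfg.n_bootstrap,
                seed=cfg.seed,
            )
            (out / f"clusters_{axis}.nwk").write_text(res.newick + "\n")
            sup = pd.DataFrame(
                {
                    "members": [
                        ";".join(sorted(res.labels[i] for i in s))
                        for s in res.support
                    ],
                    "support": list(res.support.values()),
                }
            )
            sup.to_csv(
                out / f"cluster_support_{axis}.tsv", sep="\t", index=False,
                float_format=FLOAT_FMT,
            )
            setattr(summary, f"{axis}_clusters", res)
    summary.counts = {
        "n_fmcs": int(len(frac)),
        "n_sets_per_fmcs": cfg.sets_per_fmcs,
        "n_stable_sets": int(fcc.shape[0]),
        "n_dropped_singular": int(mca_out.get("n_dropped_singular", 0)),
    }
    _sidecar(
        out / "summary.json",
        {
            "seed": cfg.seed,
            **summary.counts,
            "stable_percent": summary.stable_percent_stats(),
        },
    )
    if cfg.make_plots:
        _make_plots(out, summary)
    return summary


def _make_plots(out: Path, summary: EnsembleSummary) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(100 * summary.stable_fraction, bins=20, color="#5e4b8b")
    ax.set_xlabel("stable parameter sets per fMCS (%)")
    ax.set_ylabel("fMCS count")
    fig.tight_layout()
    fig.savefig(out / "stable_fraction_hist.png", dpi=150)
    plt.close(fig)

    if summary.fcc_median is not None:
        fig, ax = plt.subplots(figsize=(7.5, 6.5))
        m = summary.fcc_median
        im = ax.imshow(m.to_numpy(), cmap="RdBu", vmin=-1, vmax=1)
        ax.set_xticks(range(len(m.columns)), m.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(m.index)), m.index, fontsize=6)
        ax.set_xlabel("effector reaction")
        ax.set_ylabel("target reaction")
        fig.colorbar(im, label="median FCC")
        fig.tight_layout()
        fig.savefig(out / "fcc_median_heatmap.png", dpi=150)
        plt.close(fig)


def run_pipeline(cfg: RunConfig) -> EnsembleSummary:
    """Execute all stages in order with checkpointing."""
    model = load_model_for(cfg)
    stage_flux(cfg, model)
    fmcs_frame = stage_states(cfg, model)
    params = stage_params(cfg, model, fmcs_frame)
    stability_df = stage_stability(cfg, model, fmcs_frame, params)
    mca_out = stage_mca(cfg, model, fmcs_frame, params)
    return stage_postprocess(cfg, model, fmcs_frame, stability_df, mca_out)
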