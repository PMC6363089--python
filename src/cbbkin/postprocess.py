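"""Ensemble-level statistics: stability deciles, FCC aggregation, clustering.

These operations condense the sampled ensemble into the headline analyses:
which metabolite concentrations associate with stability (density contrast
between the most- and least-stable deciles of metabolomes), how saturation
levels split between stable and unstable states, the median/MAD flux
control coefficient matrices, and hierarchical clustering of control
patterns after an asinh/PCA reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import gaussian_kde, mannwhitneyu
from sklearn.decomposition import PCA

from .rng import STAGE_CLUSTER, stream as rng_stream

FCC_ROUND_EPS = 1e-6  # values below this magnitude are exact zeros
MIN_FMCS_FOR_DECILES = 20


# ---------------------------------------------------------------------------
# stability-concentration deciles
# ---------------------------------------------------------------------------

def decile_indices(stable_fraction: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Top and bottom deciles of fMCSs ranked by stable fraction.

    Ties are broken deterministically by fMCS index, so the split is
    invariant under permutation of the input order.
    """
    if len(stable_fraction) < MIN_FMCS_FOR_DECILES:
        raise ValueError(
            f"deciles need >= {MIN_FMCS_FOR_DECILES} fMCSs, got "
            f"{len(stable_fraction)}"
        )
    df = stable_fraction.rename("frac").rename_axis("fmcs_index").reset_index()
    df = df.sort_values(["frac", "fmcs_index"], kind="mergesort")
    k = len(df) // 10
    bottom = df["fmcs_index"].to_numpy()[:k]
    top = df["fmcs_index"].to_numpy()[-k:]
    return np.sort(top), np.sort(bottom)


def log_density(values: np.ndarray, grid: np.ndarray | None = None):
    """Gaussian kernel density (Silverman bandwidth) of log10 values."""
    logs = np.log10(np.asarray(values, dtype=float))
    if grid is None:
        lo, hi = logs.min(), logs.max()
        pad = 0.25 * max(hi - lo, 0.5)
        grid = np.linspace(lo - pad, hi + pad, 256)
    if np.ptp(logs) == 0:  # degenerate: all mass at one point
        dens = np.zeros_like(grid)
        dens[np.argmin(np.abs(grid - logs[0]))] = 1.0
        return grid, dens
    kde = gaussian_kde(logs)  # Silverman is scipy's default rule
    return grid, kde(grid)


def stability_decile_density(
    concentrations: pd.DataFrame, stable_fraction: pd.Series
) -> dict[str, dict[str, np.ndarray]]:
    """Per-metabolite log10-concentration densities, top vs bottom decile.

    ``concentrations`` is the fMCS x metabolite matrix (mM);
    ``stable_fraction`` the per-fMCS fraction of stable parameter sets.
    """
    top, bottom = decile_indices(stable_fraction)
    out: dict[str, dict[str, np.ndarray]] = {}
    for met in concentrations.columns:
        both = np.log10(
            concentrations.loc[np.concatenate([top, bottom]), met].to_numpy()
        )
        lo, hi = both.min(), both.max()
        pad = 0.25 * max(hi - lo, 0.5)
        grid = np.linspace(lo - pad, hi + pad, 256)
        _, d_top = log_density(concentrations.loc[top, met].to_numpy(), grid)
        _, d_bot = log_density(concentrations.loc[bottom, met].to_numpy(), grid)
        out[met] = {"grid": grid, "top": d_top, "bottom": d_bot}
    return out


def decile_location_test(
    concentrations: pd.DataFrame,
    stable_fraction: pd.Series,
    metabolite: str,
    alternative: str = "less",
) -> dict:
    """One-sided Mann-Whitney test of top- vs bottom-decile concentrations.

    ``alternative='less'`` asks whether the most-stable decile has *lower*
    concentrations of the metabolite than the least-stable decile.
    """
    top, bottom = decile_indices(stable_fraction)
    a = concentrations.loc[top, metabolite].to_numpy()
    b = concentrations.loc[bottom, metabolite].to_numpy()
    stat, p = mannwhitneyu(a, b, alternative=alternative)
    return {
        "metabolite": metabolite,
        "statistic": float(stat),
        "p_value": float(p),
        "mean_log10_top": float(np.log10(a).mean()),
        "mean_log10_bottom": float(np.log10(b).mean()),
    }


# ---------------------------------------------------------------------------
# saturation vs stability
# ---------------------------------------------------------------------------

def saturation_split(
    saturation: pd.DataFrame, stable: np.ndarray
) -> pd.DataFrame:
    """Attach the stability verdict to a tidy saturation table.

    ``saturation`` comes from :func:`cbbkin.kinetics.saturation_profile`
    (columns set_index, reaction, metabolite, saturation, s_over_km);
    ``stable`` is the per-set boolean vector.  The paper-style axis is
    log10([S]/K_M).
    """
    df = saturation.copy()
    df["stable"] = np.asarray(stable)[df["set_index"].to_numpy()]
    df["log10_s_over_km"] = np.log10(df["s_over_km"])
    return df


# ---------------------------------------------------------------------------
# FCC aggregation
# ---------------------------------------------------------------------------

def aggregate_fcc(
    fcc: np.ndarray, reaction_ids: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Element-wise median and MAD over all stable sets.

    ``fcc`` is an (n_sets, n_targets, n_effectors) tensor; returns
    (median, MAD) DataFrames with target rows and effector columns.
    """
    fcc = np.asarray(fcc, dtype=float)
    if fcc.ndim != 3 or fcc.shape[0] == 0:
        raise ValueError("need a non-empty (sets x targets x effectors) tensor")
    med = np.median(fcc, axis=0)
    mad = np.median(np.abs(fcc - med[None]), axis=0)
    idx = pd.Index(reaction_ids, name="target")
    cols = pd.Index(reaction_ids, name="effector")
    return (
        pd.DataFrame(med, index=idx, columns=cols),
        pd.DataFrame(mad, index=idx, columns=cols),
    )


def fcc_tidy_frame(
    fcc: np.ndarray,
    reaction_ids: list[str],
    fmcs_index: np.ndarray,
    set_index: np.ndarray,
) -> pd.DataFrame:
    """Tidy records (fmcs_index, set_index, effector, target, value)."""
    fcc = np.asarray(fcc, dtype=float)
    n, n_t, n_e = fcc.shape
    tgt, eff = np.meshgrid(np.arange(n_t), np.arange(n_e), indexing="ij")
    ids = np.asarray(reaction_ids)
    return pd.DataFrame(
        {
            "fmcs_index": np.repeat(np.asarray(fmcs_index), n_t * n_e),
            "set_index": np.repeat(np.asarray(set_index), n_t * n_e),
            "effector": np.tile(ids[eff.ravel()], n),
            "target": np.tile(ids[tgt.ravel()], n),
            "value": fcc.reshape(n, -1).ravel(),
        }
    )


# ---------------------------------------------------------------------------
# clustering of control patterns
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    labels: list[str]
    linkage: np.ndarray
    features: np.ndarray  # reactions x retained PC scores
    support: dict[frozenset, float] = field(default_factory=dict)
    newick: str = ""
    dropped_columns: int = 0


def _cluster_sets(Z: np.ndarray, n_leaves: int) -> list[frozenset]:
    """Leaf sets of all internal nodes of a linkage tree."""
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n_leaves)}
    out = []
    for k, (a, b, _, _) in enumerate(Z):
        node = members[int(a)] | members[int(b)]
        members[n_leaves + k] = node
        out.append(node)
    return out


def _correlation_linkage(F: np.ndarray) -> np.ndarray:
    d = pdist(F, metric="correlation")
    d = np.clip(d, 0.0, None)  # tiny negatives from rounding
    if not np.all(np.isfinite(d)):
        raise ValueError("correlation distance undefined (constant pattern)")
    return linkage(d, method="average")


def cluster_control_patterns(
    fcc: np.ndarray,
    reaction_ids: list[str],
    axis: str = "effector",
    subsample_fraction: float = 0.1,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Hierarchical clustering of control-exertion or control-experience.

    Pipeline: FCC values with magnitude below 1e-6 are rounded to exact
    zero, asinh-transformed, and arranged as one row per reaction with one
    column per (parameter set, partner reaction) pattern entry.  A random
    subsample of the columns (default a tenth) is standardized, reduced by
    PCA across the 29 reaction observations, and the PC scores are
    clustered with correlation distance and average linkage.  Ordinary
    bootstrap over the score dimensions yields cluster support values.
    """
    if axis not in ("effector", "target"):
        raise ValueError("axis must be 'effector' or 'target'")
    X = np.asarray(fcc, dtype=float)
    n_sets, n_t, n_e = X.shape
    # subsample the (set, partner-reaction) pattern columns up front so the
    # full flattened pattern matrix is never materialized
    n_cols = n_sets * (n_t if axis == "effector" else n_e)
    rng = rng_stream(seed, STAGE_CLUSTER, 0 if axis == "effector" else 1)
    k = max(2, int(round(subsample_fraction * n_cols)))
    cols = np.sort(rng.choice(n_cols, size=min(k, n_cols), replace=False))
    set_idx, partner_idx = np.divmod(cols, n_t if axis == "effector" else n_e)
    if axis == "effector":
        M = X[set_idx, partner_idx, :].T  # rows: effector reactions
    else:
        M = X[set_idx, :, partner_idx].T  # rows: target reactions
    M = np.where(np.abs(M) < FCC_ROUND_EPS, 0.0, M)
    M = np.arcsinh(M)

    sd = M.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = int((~keep).sum())
    M = (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep]
    if M.shape[1] < 2:
        raise ValueError("fewer than two informative pattern columns")

    def _scores(data: np.ndarray) -> np.ndarray:
        pca = PCA(n_components=min(data.shape), svd_solver="full")
        F = pca.fit_transform(data)  # rotate observations onto the PCs
        return F[:, np.all(np.isfinite(F), axis=0)]

    F = _scores(M)
    Z = _correlation_linkage(F)
    n = len(reaction_ids)
    counts = {s: 0 for s in _cluster_sets(Z, n)}
    # ordinary bootstrap over the pattern columns feeding the PCA
    for b in range(n_bootstrap):
        brng = rng_stream(
            seed, STAGE_CLUSTER,
            100 + b * 2 + (0 if axis == "effector" else 1),
        )
        cols_b = brng.integers(0, M.shape[1], size=M.shape[1])
        try:
            Zb = _correlation_linkage(_scores(M[:, cols_b]))
        except ValueError:
            continue
        for s in _cluster_sets(Zb, n):
            if s in counts:
                counts[s] += 1
    support = {s: c / n_bootstrap for s, c in counts.items()}
    newick = _linkage_to_newick(Z, reaction_ids)
    return ClusterResult(list(reaction_ids), Z, F, support, newick, dropped)


def cut_clusters(result: ClusterResult, n_clusters: int) -> dict[str, int]:
    """Flat cluster assignment by cutting the dendrogram."""
    assign = fcluster(result.linkage, t=n_clusters, criterion="maxclust")
    return dict(zip(result.labels, (int(a) for a in assign)))


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a newick tree string."""
    import io

    from skbio import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, id_list=list(labels))
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# ensemble summary container
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSummary:
    """Aggregated outputs of one full ensemble analysis run."""

    stable_fraction: pd.Series  # per fMCS
    n_sets_per_fmcs: int
    fcc_median: pd.DataFrame | None = None
    fcc_mad: pd.DataFrame | None = None
    decile_densities: dict | None = None
    rubp_test: dict | None = None
    effector_clusters: ClusterResult | None = None
    target_clusters: ClusterResult | None = None
    counts: dict = field(default_factory=dict)

    def stable_percent_stats(self) -> dict:
        pct = 100.0 * self.stable_fraction
        return {
            "median": float(pct.median()),
            "min": float(pct.min()),
            "max": float(pct.max()),
            "n_fmcs": int(len(pct)),
        }
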