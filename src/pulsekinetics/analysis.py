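"""Post-estimation analytics over kinetic parameter tables.

Covers: parameter-wise z-scoring and pairwise correlation of the
(4- or 12-dimensional) kinetic landscape; kinetic gene clustering on a
k-nearest-neighbor graph with Louvain community detection; gene-gene
expression covariation over chase time under one fixed hierarchical
gene ordering; the nucleocytoplasmic (nuclear || cytoplasmic)
concatenated expression matrix; and rank-based comparison of kinetic
parameters between gene groups (e.g. m6A-modified vs unmodified
transcripts).
"""

from __future__ import annotations

import random as _py_random
import warnings

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.neighbors import NearestNeighbors

from .datamodel import CompartmentMatrix

__all__ = [
    "zscore_parameters",
    "pairwise_parameter_correlation",
    "cluster_kinetics",
    "covariation_over_time",
    "build_nucleocytoplasmic_matrix",
    "compare_gene_groups",
    "pivot_phase_parameters",
]

_PARAMS = ("alpha", "beta", "lam", "gamma")


def pivot_phase_parameters(estimates: pd.DataFrame, qc_only: bool = True) -> pd.DataFrame:
    """Genes x parameters table from a long estimate table.

    With phase-resolved estimates this yields up to 12 columns
    (``alpha_G1`` ... ``gamma_G2/M``); 'all'-phase rows yield the plain
    4.  Only genes passing QC in *every* phase they appear in are kept
    when ``qc_only``.
    """
    df = estimates.copy()
    phases = [p for p in df["phase"].unique() if p != "all"]
    use = df[df["phase"] != "all"] if phases else df[df["phase"] == "all"]
    if qc_only:
        ok = use.groupby("gene")["qc_pass"].all()
        use = use[use["gene"].isin(ok.index[ok])]
    if phases:
        wide = use.pivot(index="gene", columns="phase", values=list(_PARAMS))
        wide.columns = [f"{p}_{ph}" for p, ph in wide.columns]
    else:
        wide = use.set_index("gene")[list(_PARAMS)]
    return wide.dropna()


def zscore_parameters(pm: pd.DataFrame) -> pd.DataFrame:
    """Column-standardized copy (mean 0, sample sd 1) of the table.

    Rows with any missing value are excluded first (and logged via a
    warning); zero-variance columns raise.
    """
    complete = pm.dropna()
    dropped = len(pm) - len(complete)
    if dropped:
        warnings.warn(f"dropping {dropped} gene(s) with missing parameters", stacklevel=2)
    sd = complete.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"zero-variance parameter(s): {list(sd.index[sd == 0])}")
    return (complete - complete.mean()) / sd


def pairwise_parameter_correlation(pm: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between every pair of kinetic parameters."""
    complete = pm.dropna()
    if len(complete) < 3:
        raise ValueError("need at least 3 complete gene rows")
    sd = complete.std(ddof=1)
    if (sd == 0).any():
        warnings.warn(
            f"zero-variance parameter(s) {list(sd.index[sd == 0])}: correlations undefined",
            stacklevel=2,
        )
    corr = complete.corr(method="pearson")
    np.fill_diagonal(corr.values, np.where(sd > 0, 1.0, np.nan))
    return corr


def cluster_kinetics(
    pm: pd.DataFrame,
    k_neighbors: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
    zscore: bool = True,
) -> pd.Series:
    """Louvain communities on the kNN graph of (z-scored) parameters.

    Builds an undirected k-nearest-neighbor graph (Euclidean) over the
    gene rows and runs Louvain multilevel community detection at the
    given resolution.  Deterministic for a fixed seed.  Disconnected
    singleton genes keep their own community, with a warning.
    """
    z = zscore_parameters(pm) if zscore else pm.dropna()
    if len(z) <= k_neighbors:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_genes={len(z)}")
    # genes with identical parameter vectors must share a label: cluster
    # the unique vectors, then broadcast
    uniq, inverse = np.unique(z.values, axis=0, return_inverse=True)
    n = len(uniq)
    if n == 1:
        return pd.Series(0, index=z.index, name="cluster")
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(uniq)
    _, idx = nn.kneighbors(uniq)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    if any(d == 0 for d in g.degree()):
        warnings.warn("disconnected singleton gene(s) form their own cluster", stacklevel=2)
    _py_random.seed(seed)  # igraph draws randomness from Python's random module
    membership = np.asarray(g.community_multilevel(resolution=resolution).membership)
    return pd.Series(membership[inverse], index=z.index, name="cluster")


def covariation_over_time(
    expr_by_timepoint: dict[float, pd.DataFrame],
    combine_timepoints: tuple[float, ...] | None = None,
) -> tuple[pd.DataFrame, dict[float, pd.DataFrame]]:
    """Gene-gene Pearson correlation, combined and per timepoint.

    The combined matrix pools all cells of ``combine_timepoints``
    (default: all provided).  Average-linkage hierarchical clustering
    on correlation distance (1 - r) fixes one gene ordering, which all
    per-timepoint matrices reuse so they are directly comparable.
    Zero-variance genes get NaN rows/columns (warned) and sort last.
    """
    if combine_timepoints is None:
        combine_timepoints = tuple(sorted(expr_by_timepoint))
    blocks = [expr_by_timepoint[t] for t in combine_timepoints]
    genes = blocks[0].index
    for b in blocks:
        if not b.index.equals(genes):
            raise ValueError("all timepoint matrices must share one gene index")
        if b.shape[1] < 3:
            raise ValueError("need >= 3 cells per timepoint")
    combined_cells = pd.concat(blocks, axis=1)
    sd = combined_cells.std(axis=1, ddof=1)
    flat = list(sd.index[sd == 0])
    if flat:
        warnings.warn(f"zero-variance gene(s) excluded from ordering: {flat}", stacklevel=2)
    live = [g for g in genes if g not in set(flat)]
    corr = combined_cells.T.corr(method="pearson")

    sub = corr.loc[live, live]
    dist = squareform(np.clip(1.0 - sub.values, 0.0, None), checks=False)
    order = hierarchy.leaves_list(hierarchy.linkage(dist, method="average"))
    ordered = [live[i] for i in order] + flat
    combined = corr.reindex(index=ordered, columns=ordered)
    per_tp = {
        t: expr_by_timepoint[t].T.corr(method="pearson").reindex(index=ordered, columns=ordered)
        for t in sorted(expr_by_timepoint)
    }
    return combined, per_tp


def build_nucleocytoplasmic_matrix(cm: CompartmentMatrix) -> pd.DataFrame:
    """Cells x 2G matrix: nuclear counts beside cytoplasmic counts.

    Columns are ``<gene>_nuc`` then ``<gene>_cyto``; each row sums to
    the cell's total reads.  This doubled feature space separates cells
    by subcellular state, not just expression level.
    """
    nuc = np.asarray(cm.counts["nucleus"].todense()).T
    cyt = np.asarray(cm.cytoplasm.todense()).T
    cols = [f"{g}_nuc" for g in cm.genes] + [f"{g}_cyto" for g in cm.genes]
    return pd.DataFrame(np.hstack([nuc, cyt]), index=cm.cells.index, columns=cols)


def compare_gene_groups(
    estimates: pd.DataFrame,
    labels: dict[str, str],
    parameter: str,
    group_a: str = "m6a",
    group_b: str = "non_m6a",
    phase: str = "all",
    qc_only: bool = True,
) -> dict:
    """Two-sided rank-sum comparison of a parameter between gene groups.

    Exact null distribution when the smaller group has <= 10 genes,
    normal approximation with tie correction otherwise.  Returns the
    test statistic, p-value, group medians and sizes.
    """
    df = estimates[estimates["phase"] == phase]
    if qc_only:
        df = df[df["qc_pass"]]
    df = df[np.isfinite(df[parameter])]
    a = df.loc[df["gene"].map(labels) == group_a, parameter].to_numpy()
    b = df.loc[df["gene"].map(labels) == group_b, parameter].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"empty group after filtering: {group_a}: {len(a)}, {group_b}: {len(b)}")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "parameter": parameter,
        "phase": phase,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "method": method,
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_a": int(len(a)),
        "n_b": int(len(b)),
        "group_a": group_a,
        "group_b": group_b,
    }
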