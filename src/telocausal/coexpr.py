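"""Weighted co-expression networks: soft connectivity, topological-overlap
module detection with module-eigengene/trait correlation, an RTL-ordered
sliding-window connectivity analysis, and over-representation enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "soft_connectivity",
    "tom_similarity",
    "detect_modules",
    "module_trait",
    "sliding_connectivity",
    "cluster_tracks",
    "set_enrichment",
    "NetworkModules",
    "ConnectivityTrack",
]


def _adjacency(expr: np.ndarray, power: float) -> np.ndarray:
    """|Pearson correlation|^power between gene rows, zero diagonal."""
    A = np.abs(np.corrcoef(expr)) ** power
    np.fill_diagonal(A, 0.0)
    return A


def soft_connectivity(expr: pd.DataFrame, power: float = 9.0) -> pd.Series:
    """Per-gene soft connectivity ``k_i = sum_j |cor(x_i, x_j)|^power``.

    ``expr`` is genes x samples; zero-variance genes are excluded with a
    note in the returned series' attrs.
    """
    X = expr.to_numpy(dtype=float)
    if X.shape[0] < 3 or X.shape[1] < 4:
        raise ValueError("need >= 3 genes and >= 4 samples")
    ok = X.std(axis=1) > 0
    A = _adjacency(X[ok], power)
    k = pd.Series(A.sum(axis=1), index=expr.index[ok], name="connectivity")
    k.attrs["excluded"] = list(expr.index[~ok])
    return k


def tom_similarity(A: np.ndarray) -> np.ndarray:
    """Topological overlap of an adjacency matrix with zero diagonal.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``TOM_ii = 1`` by convention; for adjacency in [0, 1] the result lies in
    [0, 1].
    """
    k = A.sum(axis=1)
    num = A @ A + A
    den = np.minimum.outer(k, k) + 1.0 - A
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


@dataclass
class NetworkModules:
    labels: pd.Series  # gene -> module label ("unassigned" allowed)
    eigengenes: pd.DataFrame  # samples x modules
    power: float
    trait_table: pd.DataFrame | None = None


def _eigengene(expr_block: np.ndarray) -> np.ndarray:
    """First PC of a module's standardized expression, sign-anchored to the
    module mean profile."""
    sd = expr_block.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (expr_block - expr_block.mean(axis=1, keepdims=True)) / sd
    if Z.shape[0] == 1:
        return Z[0]
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    me = vt[0]
    if np.corrcoef(me, Z.mean(axis=0))[0, 1] < 0:
        me = -me
    return me


def detect_modules(
    expr: pd.DataFrame,
    power: float = 9.0,
    min_module_size: int = 30,
    cut_height_quantile: float = 0.99,
) -> NetworkModules:
    """Average-linkage clustering of the TOM dissimilarity into modules.

    The tree is cut at the given quantile of its merge heights; clusters
    smaller than ``min_module_size`` are relabelled ``unassigned``. Each
    surviving module gets an eigengene (first PC of its standardized
    expression).
    """
    X = expr.to_numpy(dtype=float)
    genes = expr.index
    if X.shape[0] < min_module_size:
        labels = pd.Series("unassigned", index=genes)
        return NetworkModules(labels, pd.DataFrame(index=expr.columns), power)

    A = _adjacency(X, power)
    dissim = 1.0 - tom_similarity(A)
    np.fill_diagonal(dissim, 0.0)
    link = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    height = np.quantile(link[:, 2], cut_height_quantile)
    raw = hierarchy.fcluster(link, t=height, criterion="distance")

    labels = np.full(len(genes), "unassigned", dtype=object)
    counts = pd.Series(raw).value_counts()
    next_id = 0
    for cl in counts.index:
        if counts[cl] >= min_module_size:
            labels[raw == cl] = f"module{next_id}"
            next_id += 1
    labels = pd.Series(labels, index=genes, name="module")

    mes = {}
    for mod in sorted(set(labels) - {"unassigned"}):
        mes[mod] = _eigengene(X[labels.to_numpy() == mod])
    eig = pd.DataFrame(mes, index=expr.columns)
    return NetworkModules(labels, eig, power)


def module_trait(modules: NetworkModules, trait: pd.Series) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with a trait, BH-adjusted.

    Missing trait values are handled pairwise-complete; the per-module n is
    reported.
    """
    rows = []
    for mod in modules.eigengenes.columns:
        me = modules.eigengenes[mod]
        t = trait.reindex(me.index)
        ok = ~t.isna()
        n = int(ok.sum())
        r, p = stats.pearsonr(me[ok], t[ok])
        rows.append({"module": mod, "r": r, "p": p, "n": n})
    df = pd.DataFrame(rows)
    if not df.empty:
        _, q, _, _ = multipletests(df["p"], method="fdr_bh")
        df["q"] = q
    modules.trait_table = df
    return df


@dataclass
class ConnectivityTrack:
    tracks: pd.DataFrame  # genes x windows, z-standardized per gene
    windows: list[list[str]]  # sample ids per window, RTL-descending order
    raw: pd.DataFrame | None = None


def sliding_connectivity(
    expr: pd.DataFrame,
    rtl: pd.Series,
    top_var_fraction: float = 0.30,
    window_fraction: float = 0.25,
    power: float = 9.0,
) -> ConnectivityTrack:
    """Soft connectivity along an RTL-ordered sliding window of samples.

    Genes are restricted to the top ``top_var_fraction`` by log-expression
    variance; samples are sorted by RTL descending (ties by sample id, so
    the order is deterministic) and window *t* holds ranks ``t..t+m-1`` with
    ``m = round(window_fraction * n)`` — each step drops the longest-RTL
    sample and adds the next shorter one. Tracks are z-scored per gene
    across windows.
    """
    n = expr.shape[1]
    m = int(round(window_fraction * n))
    if m < 10:
        raise ValueError("window too small; need round(window_fraction * n) >= 10")

    logx = np.log2(expr.to_numpy(dtype=float) + 1.0)
    var = logx.var(axis=1)
    n_keep = max(int(round(top_var_fraction * expr.shape[0])), 3)
    keep = np.argsort(-var, kind="mergesort")[:n_keep]
    genes = expr.index[keep]

    order = sorted(expr.columns, key=lambda s: (-rtl[s], s))
    col_idx = {s: j for j, s in enumerate(expr.columns)}
    X = logx[keep]

    windows = [order[t : t + m] for t in range(n - m + 1)]
    tracks = np.empty((len(genes), len(windows)))
    for t, win in enumerate(windows):
        cols = [col_idx[s] for s in win]
        sub = X[:, cols]
        sd = sub.std(axis=1)
        safe = sub.copy()
        safe[sd == 0] += 1e-12 * np.random.default_rng(0).standard_normal(
            safe[sd == 0].shape
        )
        A = _adjacency(safe, power)
        tracks[:, t] = np.nan_to_num(A).sum(axis=1)

    raw = pd.DataFrame(tracks, index=genes,
                       columns=[f"window{t:03d}" for t in range(len(windows))])
    sd = tracks.std(axis=1, keepdims=True)
    z = (tracks - tracks.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)
    zdf = pd.DataFrame(z, index=genes, columns=raw.columns)
    return ConnectivityTrack(tracks=zdf, windows=windows, raw=raw)


def cluster_tracks(
    track: ConnectivityTrack, k_max: int = 10, seed: int = 0
) -> tuple[pd.Series, int]:
    """K-means clustering of connectivity tracks with elbow model selection.

    Runs k-means (k-means++ init, 10 restarts, fixed seed) for k = 1..k_max
    and picks k at the largest second difference of the within-cluster SSE
    curve. Degenerate all-equal tracks collapse to k = 1.
    """
    X = track.tracks.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        return pd.Series(0, index=track.tracks.index, name="cluster"), 1
    if X.shape[0] < k_max * 5:
        raise ValueError("need at least 5 * k_max genes for stable clustering")

    sse = []
    fits = {}
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        km.fit(X)
        sse.append(km.inertia_)
        fits[k] = km
    sse = np.array(sse)
    if len(sse) >= 3:
        second_diff = sse[:-2] - 2 * sse[1:-1] + sse[2:]
        k_best = int(np.argmax(second_diff)) + 2
    else:
        k_best = 1
    labels = pd.Series(fits[k_best].labels_, index=track.tracks.index, name="cluster")
    return labels, k_best


def set_enrichment(
    selected: set[str], universe: set[str], gene_sets: dict[str, set[str]]
) -> pd.DataFrame:
    """Hypergeometric over-representation of selected genes in each set.

    Sets are intersected with the universe; the upper-tail p is
    ``P(overlap >= observed)``. BH q across sets.
    """
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    N = len(universe)
    n = len(selected)
    rows = []
    for name, s in gene_sets.items():
        s = s & universe
        K = len(s)
        k = len(s & selected)
        p = 1.0 if n == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "set_size": K, "overlap": k, "p": p})
    df = pd.DataFrame(rows)
    if not df.empty:
        _, q, _, _ = multipletests(df["p"], method="fdr_bh")
        df["q"] = q
    return df
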