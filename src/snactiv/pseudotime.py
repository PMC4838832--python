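"""Supervised pseudotemporal ordering of nuclei along an activation continuum.

Genes differentially expressed between the stain groups are z-scored and
reduced to two independent components (PCA whitening + fixed-point ICA); a
minimum spanning tree over the component coordinates is built and its
diameter path taken as the main trajectory. Pseudotime is the normalized
cumulative distance from the root (the diameter endpoint with the lower
activation-marker expression); samples off the main path attach at their
nearest tree node on it. MST edge removal yields clusters, and FOS-stained
samples sitting in majority-negative clusters are flagged pseudo-positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import FastICA

from .core import ExpressionMatrix, SampleMetadata, Stain, ValidationError, log2p1
from .diffexp import bh_adjust

DEFAULT_PADJ = 0.01
DEFAULT_K = 5


@dataclass
class PseudotimeResult:
    samples: pd.DataFrame        # ic1, ic2, pseudotime, on_main_path, cluster, pseudo_positive
    tree: nx.Graph               # the MST over component coordinates
    main_path: list[str]         # diameter path from root to tip


@dataclass
class OrderingRobustness:
    rho: pd.Series               # per left-out sample: |Spearman rho| on shared samples

    @property
    def min(self) -> float:
        return float(self.rho.min())

    @property
    def mean(self) -> float:
        return float(self.rho.mean())


def supervised_gene_filter(de: pd.DataFrame, padj_threshold: float = DEFAULT_PADJ) -> list[str]:
    """Genes with BH-adjusted p strictly below the threshold, order preserved."""
    genes = [g for g, q in zip(de["gene_id"], de["q_value"]) if q < padj_threshold]
    if not genes:
        raise ValidationError(
            f"no gene passes adjusted p < {padj_threshold}; relax the threshold"
        )
    return genes


def _zscore_genes(log_expr: pd.DataFrame) -> np.ndarray:
    x = log_expr.to_numpy()
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def reduce_ica(
    log_expr: pd.DataFrame,
    stain: pd.Series,
    n_components: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Two independent components over samples from z-scored log expression.

    The data are PCA-whitened and rotated by fixed-point ICA; the rotation is
    then applied to the data-scale principal-component scores rather than to
    the whitened unit-variance sources. The embedding therefore keeps the
    Euclidean geometry of the two-dimensional principal subspace — a strong
    expression program spans more of the plane than residual noise — while
    the axes are the ICA directions. (On the whitened unit scale, heavy-
    tailed noise components are as wide as the trajectory and dominate the
    downstream spanning tree.) Components are ordered by the F statistic of
    their association with the stain label (descending) and oriented so the
    FOS_POS group mean is positive, making the output deterministic up to
    the seed.
    """
    n_samples = log_expr.shape[1]
    if n_samples < n_components + 1:
        raise ValidationError("need more samples than components")
    z = _zscore_genes(log_expr).T  # samples x genes
    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        random_state=seed,
        max_iter=1000,
        tol=1e-4,
    )
    sources = ica.fit_transform(z)
    # data-scale PC scores and the orthogonal rotation whitened -> sources
    zc = z - z.mean(axis=0, keepdims=True)
    u, sv, _ = np.linalg.svd(zc, full_matrices=False)
    u, sv = u[:, :n_components], sv[:n_components]
    m = u.T @ sources
    ru, _, rvt = np.linalg.svd(m)       # orthogonal Procrustes alignment
    rotation = ru @ rvt
    coords = (u * sv) @ rotation

    stain = stain.loc[log_expr.columns]
    labels = stain.to_numpy()
    f_stats = []
    for j in range(n_components):
        groups = [coords[labels == g, j] for g in np.unique(labels)]
        if len(groups) > 1 and all(len(g) > 1 for g in groups):
            f, _ = sps.f_oneway(*groups)
            f_stats.append(float(f) if np.isfinite(f) else 0.0)
        else:
            f_stats.append(0.0)
    order = np.argsort(f_stats)[::-1]
    coords = coords[:, order]
    pos = labels == Stain.FOS_POS.value
    if pos.any():
        for j in range(n_components):
            if coords[pos, j].mean() < 0:
                coords[:, j] = -coords[:, j]
    return pd.DataFrame(
        coords,
        index=log_expr.columns,
        columns=[f"ic{j + 1}" for j in range(n_components)],
    )


def _mst(coords: pd.DataFrame) -> nx.Graph:
    """Kruskal MST on the complete Euclidean graph, ties broken by the
    lexicographic (sample_id, sample_id) pair for determinism."""
    ids = list(coords.index)
    x = coords.to_numpy()
    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = sorted((ids[i], ids[j]))
            edges.append((float(np.linalg.norm(x[i] - x[j])), a, b))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))
    parent = {s: s for s in ids}

    def find(s: str) -> str:
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    tree = nx.Graph()
    tree.add_nodes_from(ids)
    for w, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            tree.add_edge(a, b, weight=w)
            if tree.number_of_edges() == len(ids) - 1:
                break
    return tree


def build_mst_order(
    coords: pd.DataFrame, root_marker_expr: pd.Series
) -> tuple[pd.DataFrame, nx.Graph, list[str]]:
    """Pseudotime from the MST diameter path.

    The main trajectory is the maximum-weight leaf-to-leaf path of the MST;
    the root is the endpoint with the lower mean activation-marker
    expression, so pseudotime increases with activation. Off-path samples
    inherit the pseudotime of the path node their tree branch attaches to.
    Returns (per-sample frame, tree, path node list).
    """
    if len(coords) < 3:
        raise ValidationError("need >= 3 samples")
    if np.allclose(coords.to_numpy().var(axis=0), 0.0):
        raise ValidationError("all samples have identical coordinates")
    tree = _mst(coords)
    ids = sorted(coords.index)

    dist = dict(nx.all_pairs_dijkstra_path_length(tree, weight="weight"))
    best = (-1.0, None, None)
    for a in ids:
        for b in ids:
            if a < b and dist[a][b] > best[0]:
                best = (dist[a][b], a, b)
    diameter, end1, end2 = best
    if diameter <= 0:
        raise ValidationError("zero-length diameter; coordinates degenerate")

    marker = root_marker_expr.loc[coords.index]
    root, tip = (end1, end2) if marker[end1] <= marker[end2] else (end2, end1)
    path = nx.shortest_path(tree, root, tip, weight="weight")
    path_set = set(path)

    # cumulative distance along the path, normalized to [0, 1]
    cum = {path[0]: 0.0}
    for u, v in zip(path, path[1:]):
        cum[v] = cum[u] + tree[u][v]["weight"]
    total = cum[path[-1]]

    pt, on_path = {}, {}
    for s in coords.index:
        if s in path_set:
            pt[s] = cum[s] / total
            on_path[s] = True
        else:
            walk = nx.shortest_path(tree, s, root)
            attach = next(node for node in walk if node in path_set)
            pt[s] = cum[attach] / total
            on_path[s] = False
    frame = pd.DataFrame(
        {
            "ic1": coords.iloc[:, 0],
            "ic2": coords.iloc[:, 1] if coords.shape[1] > 1 else 0.0,
            "pseudotime": pd.Series(pt),
            "on_main_path": pd.Series(on_path),
        },
        index=coords.index,
    )
    return frame, tree, path


def assign_clusters(tree: nx.Graph, pseudotime: pd.Series, k: int = DEFAULT_K) -> pd.Series:
    """Cut the k-1 longest MST edges; components become clusters labelled
    0..k-1 by ascending mean pseudotime."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > tree.number_of_nodes():
        raise ValidationError("k exceeds the number of samples")
    pruned = tree.copy()
    edges = sorted(
        tree.edges(data="weight"),
        key=lambda e: (-e[2], tuple(sorted((e[0], e[1])))),
    )
    for u, v, _ in edges[: k - 1]:
        pruned.remove_edge(u, v)
    comps = [sorted(c) for c in nx.connected_components(pruned)]
    comps.sort(key=lambda c: pseudotime[c].mean())
    labels = {}
    for lab, comp in enumerate(comps):
        for s in comp:
            labels[s] = lab
    return pd.Series(labels, name="cluster").loc[pseudotime.index]


def flag_pseudo_positive(clusters: pd.Series, stain: pd.Series) -> pd.Series:
    """FOS_POS samples sitting in clusters whose members are majority FOS_NEG."""
    stain = stain.loc[clusters.index]
    flags = pd.Series(False, index=clusters.index, name="pseudo_positive")
    for lab in clusters.unique():
        members = clusters.index[clusters == lab]
        neg_frac = (stain[members] == Stain.FOS_NEG.value).mean()
        if neg_frac > 0.5:
            flags[members] = stain[members] == Stain.FOS_POS.value
    return flags


def stain_association(values: pd.Series, stain: pd.Series) -> tuple[float, float]:
    """One-way ANOVA F-test of a per-sample scalar against the stain label."""
    stain = stain.loc[values.index]
    groups = [values[stain == g].to_numpy() for g in sorted(stain.unique())]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 groups with >= 2 members each")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def _slope_f_test(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized simple linear regression of each row of y on x: slope and
    F-test p for the slope (equivalent to the squared-t test)."""
    n = len(x)
    xc = x - x.mean()
    sxx = float((xc**2).sum())
    yc = y - y.mean(axis=1, keepdims=True)
    slope = (yc * xc).sum(axis=1) / sxx
    ss_tot = (yc**2).sum(axis=1)
    ss_reg = slope**2 * sxx
    ss_res = np.maximum(ss_tot - ss_reg, 0.0)
    df_res = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ss_res > 0, ss_reg * df_res / ss_res, np.inf)
    p = sps.f.sf(f, 1, df_res)
    constant = ss_tot == 0
    p = np.where(constant, 1.0, p)
    f = np.where(constant, 0.0, f)
    return slope, np.asarray(p)


def gene_pseudotime_regression(
    log_expr: pd.DataFrame, result: PseudotimeResult, on_path_only: bool = True
) -> pd.DataFrame:
    """Per-gene linear regression of log2(TPM+1) on pseudotime.

    Restricted to main-path samples by default to dampen outlier clusters;
    the slope's F-test p is BH-adjusted across genes.
    """
    frame = result.samples
    samples = frame.index[frame["on_main_path"]] if on_path_only else frame.index
    if len(samples) < 3:
        raise ValidationError("need >= 3 samples for regression")
    y = log_expr.loc[:, samples].to_numpy()
    x = frame.loc[samples, "pseudotime"].to_numpy()
    slope, p = _slope_f_test(y, x)
    return pd.DataFrame(
        {"gene_id": log_expr.index, "slope": slope, "p_value": p, "q_value": bh_adjust(p)}
    ).set_index("gene_id", drop=False)


def cluster_vs_rest_regression(
    log_expr: pd.DataFrame, clusters: pd.Series, target: int
) -> pd.DataFrame:
    """Per-gene comparison of one cluster against all remaining samples via
    the linear-model F-test on the cluster indicator (equals the pooled
    two-sample t-test squared)."""
    clusters = clusters.loc[log_expr.columns]
    indicator = (clusters == target).to_numpy().astype(float)
    n_in = int(indicator.sum())
    if n_in == 0 or n_in == len(indicator):
        raise ValidationError("target cluster must be a proper non-empty subset")
    slope, p = _slope_f_test(log_expr.to_numpy(), indicator)
    return pd.DataFrame(
        {"gene_id": log_expr.index, "slope": slope, "p_value": p, "q_value": bh_adjust(p)}
    ).set_index("gene_id", drop=False)


def order_nuclei(
    expr: ExpressionMatrix,
    de: pd.DataFrame,
    meta: list[SampleMetadata],
    padj_threshold: float = DEFAULT_PADJ,
    k: int = DEFAULT_K,
    root_markers: list[str] | None = None,
    seed: int = 0,
) -> PseudotimeResult:
    """Full supervised ordering: DE filter -> ICA -> MST diameter pseudotime
    -> clusters -> pseudo-positive flags.

    ``root_markers`` is the activation marker panel used to orient the
    trajectory (IEGs in real data); by default the DE genes higher in the
    FOS_POS group serve as the panel.
    """
    genes = supervised_gene_filter(de, padj_threshold)
    log_expr = log2p1(expr).loc[genes]
    stain = pd.Series(
        {m.sample_id: m.stain.value for m in meta}, name="stain"
    ).loc[expr.sample_ids]
    if root_markers is None:
        up = de.loc[de["gene_id"].isin(genes)]
        root_markers = list(up.loc[up["direction"] == Stain.FOS_POS.value, "gene_id"])
        if not root_markers:
            root_markers = genes
    coords = reduce_ica(log_expr, stain, seed=seed)
    marker_expr = log2p1(expr).loc[root_markers].mean(axis=0)
    frame, tree, path = build_mst_order(coords, marker_expr)
    frame["cluster"] = assign_clusters(tree, frame["pseudotime"], k=k)
    frame["pseudo_positive"] = flag_pseudo_positive(frame["cluster"], stain)
    frame["stain"] = stain
    return PseudotimeResult(samples=frame, tree=tree, main_path=path)


def loo_robustness(
    expr: ExpressionMatrix,
    de: pd.DataFrame,
    meta: list[SampleMetadata],
    padj_threshold: float = DEFAULT_PADJ,
    root_markers: list[str] | None = None,
    seed: int = 0,
) -> OrderingRobustness:
    """Leave-one-out stability of the ordering.

    Each sample is excluded in turn, the ICA + MST ordering recomputed on the
    remaining nuclei, and the absolute Spearman correlation with the full
    ordering taken over the shared samples (the absolute value absorbs
    orientation flips).
    """
    if len(expr.sample_ids) < 4:
        raise ValidationError("need >= 4 samples")
    full = order_nuclei(
        expr, de, meta, padj_threshold=padj_threshold, root_markers=root_markers, seed=seed
    )
    full_pt = full.samples["pseudotime"]
    rhos = {}
    for left_out in expr.sample_ids:
        keep = [s for s in expr.sample_ids if s != left_out]
        sub_meta = [m for m in meta if m.sample_id != left_out]
        res = order_nuclei(
            expr.subset_samples(keep),
            de,
            sub_meta,
            padj_threshold=padj_threshold,
            root_markers=root_markers,
            seed=seed,
        )
        rho, _ = sps.spearmanr(full_pt.loc[keep], res.samples["pseudotime"].loc[keep])
        rhos[left_out] = abs(float(rho))
    return OrderingRobustness(rho=pd.Series(rhos, name="spearman_abs"))
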