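"""WGCNA-style co-expression modules: filter, soft threshold, TOM, tree cut.

The pipeline is: count filter (an edgeR filterByExpr-style rule), unsigned
adjacency |cor|^beta with beta chosen for approximate scale-free topology,
topological overlap similarity, and average-linkage clustering of the 1-TOM
dissimilarity with a static quantile cut plus a minimum module size.  The
static cut stands in for the dynamic hybrid tree cut; the deep-split level d
maps to cutting at the (0.95 - 0.05 d) quantile of merge heights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .netprop import ModulePartition


@dataclass(frozen=True)
class SoftThreshold:
    power: int
    scale_free_r2: float
    mean_connectivity: float


def filter_low_expression(
    counts: pd.DataFrame,
    groups: dict[str, str],
    min_count: float = 10.0,
    min_total_count: float = 15.0,
) -> pd.DataFrame:
    """Low-expression filter on a genes x samples count matrix.

    A gene is kept when its CPM reaches ``min_count`` (rescaled by the median
    library size) in at least as many samples as the smallest group — shrunk
    to 10 + (size-10)*0.7 when that group exceeds 10 samples — and its total
    count reaches ``min_total_count``.
    """
    if not groups:
        raise ValueError("groups mapping is empty")
    missing = [s for s in counts.columns if s not in groups]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    lib = counts.sum(axis=0).to_numpy(float)
    if (lib == 0).any():
        raise ValueError("zero library size sample")
    sizes = pd.Series([groups[s] for s in counts.columns]).value_counts()
    n = float(sizes.min())
    if n > 10:
        n = 10.0 + (n - 10.0) * 0.7
    cutoff = min_count / np.median(lib) * 1e6
    cpm = counts.to_numpy(float) / lib * 1e6
    keep = ((cpm >= cutoff).sum(axis=1) >= n) & (
        counts.sum(axis=1).to_numpy(float) >= min_total_count
    )
    return counts.loc[keep]


def adjacency_matrix(expr: pd.DataFrame, power: int) -> pd.DataFrame:
    """Unsigned weighted adjacency |cor|^beta with zero diagonal.

    Pearson correlation across samples; constant rows are dropped with a
    warning before correlating.
    """
    x = expr.to_numpy(float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"dropping {int((sd == 0).sum())} constant expression rows", stacklevel=2)
        expr = expr.loc[sd > 0]
        x = expr.to_numpy(float)
    cor = np.corrcoef(x)
    a = np.abs(cor) ** power
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 frequency vs log10 connectivity over equal-width bins."""
    k = k[k > 0]
    if k.size < 3 or np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    centers, freqs = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size:
            centers.append(members.mean())
            freqs.append(members.size)
    if len(centers) < 3:
        return 0.0
    lx, ly = np.log10(centers), np.log10(freqs)
    if np.allclose(lx, lx[0]) or np.allclose(ly, ly[0]):
        return 0.0
    r = np.corrcoef(lx, ly)[0, 1]
    return float(r**2)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: range = range(1, 21),
    r2_target: float = 0.8,
) -> SoftThreshold:
    """Smallest power reaching the scale-free fit target, else the argmax.

    For each candidate beta the connectivity k_i = sum_j |cor_ij|^beta is
    binned and the linearity of log-frequency vs log-connectivity scored.
    """
    if expr.shape[0] < 10:
        raise ValueError("need >= 10 genes to assess scale-free topology")
    best: SoftThreshold | None = None
    for beta in powers:
        a = adjacency_matrix(expr, beta).to_numpy()
        k = a.sum(axis=1)
        r2 = _scale_free_r2(k)
        st = SoftThreshold(power=int(beta), scale_free_r2=r2, mean_connectivity=float(k.mean()))
        if r2 >= r2_target:
            return st
        if best is None or r2 > best.scale_free_r2:
            best = st
    warnings.warn(
        f"no power reached scale-free R2 >= {r2_target}; "
        f"best beta={best.power} with R2={best.scale_free_r2:.3f}",
        stacklevel=2,
    )
    return best


def tom_from_adjacency(a: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Topological overlap TOM_ij = (sum_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1-a_ij).

    Requires a symmetric adjacency with zero diagonal and entries in [0,1];
    the diagonal of the result is 1 by definition.
    """
    index = a.index if isinstance(a, pd.DataFrame) else None
    m = np.asarray(a, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(m, m.T):
        raise ValueError("adjacency must be symmetric")
    if (m < 0).any() or (m > 1).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(m), 0.0):
        raise ValueError("adjacency diagonal must be zero")
    k = m.sum(axis=1)
    shared = m @ m
    denom = np.minimum.outer(k, k) + 1.0 - m
    tom = (shared + m) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if index is not None:
        return pd.DataFrame(tom, index=index, columns=index)
    return pd.DataFrame(tom)


def _trim_loose_members(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Detach cluster members that sit far from their cluster's core.

    A member whose mean dissimilarity to the rest of its cluster exceeds the
    cluster median by more than 3 median absolute deviations is moved to a
    fresh singleton label (which the min-size rule then sends to module 0).
    """
    labels = labels.copy()
    next_label = labels.max() + 1
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < 3:
            continue
        sub = d[np.ix_(idx, idx)]
        mean_d = sub.sum(axis=1) / (idx.size - 1)
        med = np.median(mean_d)
        mad = np.median(np.abs(mean_d - med))
        if mad <= 0:
            continue
        loose = mean_d > med + 3.0 * mad
        for i in idx[loose]:
            labels[i] = next_label
            next_label += 1
    return labels


def cut_modules(
    dissim: pd.DataFrame,
    min_size: int = 30,
    deep_split: int = 2,
) -> ModulePartition:
    """Average-linkage clustering of a dissimilarity with a static cut.

    The tree is cut at the fraction (0.95 - 0.05 * deep_split) of the merge
    height range; each resulting cluster is then trimmed of loosely attached
    members (mean within-cluster dissimilarity beyond 3 MADs of the cluster
    median — a deterministic stand-in for the dynamic hybrid cut's core
    step); clusters smaller than ``min_size`` are relabelled module 0.
    Surviving modules are numbered 1..k by decreasing size (ties by
    smallest member label).
    """
    genes = list(dissim.index)
    d = np.asarray(dissim, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity must be square and symmetric")
    if len(genes) < min_size:
        warnings.warn("fewer genes than min_size: everything unassigned", stacklevel=2)
        return ModulePartition(assignments={g: 0 for g in genes}, modularity=0.0)
    condensed = squareform(np.round((d + d.T) / 2.0, 12), checks=False)
    link = hierarchy.average(condensed)
    heights = link[:, 2]
    if np.allclose(heights, heights[0] if heights.size else 0.0):
        # degenerate all-equal dissimilarity: a single module
        return ModulePartition(assignments={g: 1 for g in genes}, modularity=0.0)
    q = 0.95 - 0.05 * deep_split
    cut = float(heights.min() + q * (heights.max() - heights.min()))
    labels = hierarchy.fcluster(link, t=cut, criterion="distance")
    labels = _trim_loose_members(d, labels)
    assignments: dict[str, int] = {}
    sizes = pd.Series(labels).value_counts()
    keep = sorted(
        (lab for lab in sizes.index if sizes[lab] >= min_size),
        key=lambda lab: (-sizes[lab], min(g for g, l in zip(genes, labels) if l == lab)),
    )
    remap = {lab: i + 1 for i, lab in enumerate(keep)}
    for g, lab in zip(genes, labels):
        assignments[g] = remap.get(lab, 0)
    return ModulePartition(assignments=assignments, modularity=float("nan"))


def detect_coexpr_modules(
    counts: pd.DataFrame,
    groups: dict[str, str],
    min_size: int = 30,
    deep_split: int = 2,
    power: int | None = None,
    log_transform: bool = True,
) -> tuple[ModulePartition, SoftThreshold]:
    """Full stage: filter counts, pick beta, TOM, cut modules."""
    filtered = filter_low_expression(counts, groups)
    expr = np.log2(filtered + 1.0) if log_transform else filtered
    if power is None:
        st = pick_soft_threshold(expr)
    else:
        a0 = adjacency_matrix(expr, power)
        k = a0.to_numpy().sum(axis=1)
        st = SoftThreshold(power=power, scale_free_r2=_scale_free_r2(k), mean_connectivity=float(k.mean()))
    a = adjacency_matrix(expr, st.power)
    tom = tom_from_adjacency(a)
    partition = cut_modules(1.0 - tom, min_size=min_size, deep_split=deep_split)
    return partition, st
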