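"""Single-sample GSEA: weighted running-sum enrichment with leading edge.

For a profile ranked by score (descending) and a gene set S, the in-set
cumulative weight uses |score|^alpha over set members while the out-of-set
cumulative fraction is unweighted; their running difference yields both the
integral enrichment statistic (the single-sample convention) and the
maximum-deviation statistic (the classic KS-style GSEA statistic, which
defines the leading edge).  Significance comes from a gene-label
permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneSet


@dataclass
class SsgseaResult:
    es_integral: float
    es_max_dev: float
    alpha: float
    leading_edge: GeneSet
    nes: float | None = None
    perm_p: float | None = None
    n_perm: int = 0


def rank_genes(scores: pd.Series) -> pd.Series:
    """Deterministic descending ranking: ties broken by gene symbol ascending."""
    df = pd.DataFrame({"gene": scores.index.astype(str), "score": scores.to_numpy(float)})
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene symbols in ranked profile")
    return pd.Series(df["score"].to_numpy(), index=df["gene"].to_numpy())


def _running_difference(scores: np.ndarray, in_set: np.ndarray, alpha: float):
    n = scores.size
    k = int(in_set.sum())
    if k == 0:
        raise ValueError("gene set absent from ranking")
    w = np.abs(scores) ** alpha if alpha > 0 else np.ones(n)
    w_in = np.where(in_set, w, 0.0)
    denom_in = w_in.sum()
    if denom_in == 0:
        # all member scores are exactly zero at alpha>0: fall back to uniform
        w_in = in_set.astype(float)
        denom_in = w_in.sum()
    p_in = np.cumsum(w_in) / denom_in
    if n == k:
        p_out = np.ones(n)
    else:
        p_out = np.cumsum(~in_set) / (n - k)
    return p_in - p_out


def enrichment_score(
    ranked: pd.Series, gene_set: GeneSet, alpha: float = 0.75
) -> SsgseaResult:
    """Enrichment of ``gene_set`` in an already-ranked profile.

    ``ranked`` must be ordered descending (use :func:`rank_genes`).  Returns
    the integral statistic (sum of the running difference), the maximum
    absolute deviation with its sign, and the leading-edge members: set
    genes at or before the extremum when it is positive, after it when
    negative.
    """
    scores = ranked.to_numpy(dtype=float)
    genes = np.asarray(ranked.index, dtype=object)
    members = gene_set.as_set()
    in_set = np.array([g in members for g in genes])
    diff = _running_difference(scores, in_set, alpha)
    es_integral = float(diff.sum())
    # extremum of the running difference; an exact positive/negative
    # magnitude tie resolves to the positive deviation
    pos_idx, neg_idx = int(np.argmax(diff)), int(np.argmin(diff))
    if diff[pos_idx] >= -diff[neg_idx] - 1e-12:
        pos, es_max_dev = pos_idx, float(diff[pos_idx])
    else:
        pos, es_max_dev = neg_idx, float(diff[neg_idx])
    if es_max_dev >= 0:
        le = [g for g, m in zip(genes[: pos + 1], in_set[: pos + 1]) if m]
    else:
        le = [g for g, m in zip(genes[pos + 1 :], in_set[pos + 1 :]) if m]
    leading = GeneSet(name=f"{gene_set.name}_leading_edge", genes=tuple(le))
    return SsgseaResult(
        es_integral=es_integral, es_max_dev=es_max_dev, alpha=alpha, leading_edge=leading
    )


def ssgsea_significance(
    ranked: pd.Series,
    gene_set: GeneSet,
    alpha: float = 0.75,
    n_perm: int = 1000,
    seed: int = 0,
) -> SsgseaResult:
    """Gene-label permutation test of the integral enrichment statistic.

    The null places a same-size set at random rank positions.  NES is the
    observed statistic divided by the mean |null| of matching sign; the
    p-value is two-sided empirical with the +1 correction.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100 for stable p-values")
    res = enrichment_score(ranked, gene_set, alpha=alpha)
    scores = ranked.to_numpy(dtype=float)
    genes = np.asarray(ranked.index, dtype=object)
    members = gene_set.as_set()
    in_set = np.array([g in members for g in genes])
    k = int(in_set.sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n = scores.size
    for i in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=k, replace=False)] = True
        null[i] = _running_difference(scores, perm, alpha).sum()
    same_sign = null[np.sign(null) == np.sign(res.es_integral)] if res.es_integral != 0 else null
    denom = np.abs(same_sign).mean() if same_sign.size else np.abs(null).mean()
    nes = res.es_integral / denom if denom > 0 else 0.0
    p = (1.0 + np.sum(np.abs(null) >= abs(res.es_integral))) / (n_perm + 1.0)
    res.nes = float(nes)
    res.perm_p = float(min(1.0, p))
    res.n_perm = n_perm
    return res


def run_stiffness_ssgsea(
    de: pd.DataFrame,
    stiffness_set: GeneSet,
    contrasts: list[str] | None = None,
    timepoints: list[str] | None = None,
    alpha: float = 0.75,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, SsgseaResult]:
    """Per-condition enrichment of the cartilage-stiffness set in log2FC ranks."""
    results: dict[str, SsgseaResult] = {}
    conditions = de[["contrast", "timepoint"]].drop_duplicates()
    for _, (contrast, tp) in conditions.iterrows():
        if contrasts is not None and contrast not in contrasts:
            continue
        if timepoints is not None and tp not in timepoints:
            continue
        sub = de[(de["contrast"] == contrast) & (de["timepoint"] == tp)]
        ranked = rank_genes(pd.Series(sub["log2fc"].to_numpy(), index=sub["gene"]))
        if not stiffness_set.as_set() & set(ranked.index):
            raise ValueError(f"stiffness genes absent from {contrast}:{tp} profile")
        results[f"{contrast}:{tp}"] = ssgsea_significance(
            ranked, stiffness_set, alpha=alpha, n_perm=n_perm, seed=seed
        )
    if not results:
        raise ValueError("no conditions matched the requested contrasts/timepoints")
    return results


def load_stiffness_set() -> GeneSet:
    """The shipped 11-gene cartilage-stiffness fixture."""
    from importlib.resources import files

    from .io import read_gmt

    path = files("oanet.data").joinpath("cartilage_stiffness.gmt")
    return read_gmt(str(path))[0]
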