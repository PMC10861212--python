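"""Age-specific trauma-response gene selection and trajectory summaries.

The core operation is set algebra over significance calls from a time-course
DE table: a gene belongs to the age-specific response if it is significantly
regulated in the stated direction at every required timepoint in the aged
contrast and at no (or, optionally, not every) required timepoint in the
young contrast.  A small PCA utility summarises log2FC trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSet


@dataclass(frozen=True)
class SelectionRule:
    """Thresholds defining a significant directional response.

    ``exclusion="any"`` removes genes significant at *any* required timepoint
    in the exclusion contrast (the default, matching an "uniquely in aged"
    reading over a four-list Venn); ``"all"`` removes only genes significant
    at every required timepoint there.
    """

    fdr_threshold: float = 0.05
    direction: str = "up"
    required_timepoints: tuple[str, ...] = ("W1", "W2")
    exclusion_contrast: str = "young"
    exclusion: str = "any"

    def __post_init__(self) -> None:
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if not self.required_timepoints:
            raise ValueError("required_timepoints must be nonempty")
        if self.exclusion not in ("any", "all"):
            raise ValueError("exclusion must be 'any' or 'all'")


def _check_coverage(de: pd.DataFrame, contrasts, timepoints) -> None:
    have = set(zip(de["contrast"], de["timepoint"]))
    missing = [(c, t) for c in contrasts for t in timepoints if (c, t) not in have]
    if missing:
        raise ValueError(f"DE table missing contrast/timepoint combinations: {missing}")


def significant_genes(
    de: pd.DataFrame, contrast: str, timepoint: str, rule: SelectionRule
) -> set[str]:
    """Genes significant in ``direction`` at one contrast x timepoint."""
    sub = de[(de["contrast"] == contrast) & (de["timepoint"] == timepoint)]
    sig = sub["fdr"] < rule.fdr_threshold
    direc = sub["log2fc"] > 0 if rule.direction == "up" else sub["log2fc"] < 0
    return set(sub.loc[sig & direc, "gene"])


def select_stress_response(
    de: pd.DataFrame, rule: SelectionRule = SelectionRule(), target_contrast: str = "aged"
) -> GeneSet:
    """Genes responding at every required timepoint in the target contrast only.

    Returns the intersection over required timepoints of the target-contrast
    significant sets, minus the union (exclusion="any") or intersection
    (exclusion="all") of the exclusion-contrast sets.
    """
    _check_coverage(de, [target_contrast, rule.exclusion_contrast], rule.required_timepoints)
    target_sets = [
        significant_genes(de, target_contrast, t, rule) for t in rule.required_timepoints
    ]
    excl_sets = [
        significant_genes(de, rule.exclusion_contrast, t, rule)
        for t in rule.required_timepoints
    ]
    selected = set.intersection(*target_sets)
    excluded = set.union(*excl_sets) if rule.exclusion == "any" else set.intersection(*excl_sets)
    genes = sorted(selected - excluded)
    return GeneSet(
        name=f"{target_contrast}_{rule.direction}_{'_'.join(rule.required_timepoints)}",
        description=f"{rule.direction} at {rule.required_timepoints} in {target_contrast} only",
        genes=tuple(genes),
    )


def select_shared_response(de: pd.DataFrame, rule: SelectionRule = SelectionRule()) -> GeneSet:
    """Genes responding at every required timepoint in *both* contrasts."""
    present = set(de["contrast"])
    contrasts = ["young", "aged"] if {"young", "aged"} <= present else sorted(present)
    _check_coverage(de, contrasts, rule.required_timepoints)
    sets = [
        significant_genes(de, c, t, rule)
        for c in contrasts
        for t in rule.required_timepoints
    ]
    genes = sorted(set.intersection(*sets))
    return GeneSet(
        name=f"shared_{rule.direction}_{'_'.join(rule.required_timepoints)}",
        description=f"{rule.direction} at {rule.required_timepoints} in all contrasts",
        genes=tuple(genes),
    )


def fc_trajectory_matrix(de: pd.DataFrame, genes: GeneSet) -> pd.DataFrame:
    """Conditions x genes log2FC matrix (rows labelled contrast:timepoint)."""
    sub = de[de["gene"].isin(genes.as_set())]
    mat = sub.pivot_table(
        index=["contrast", "timepoint"], columns="gene", values="log2fc"
    )
    mat.index = [f"{c}:{t}" for c, t in mat.index]
    return mat


def fc_trajectory_pca(de: pd.DataFrame, genes: GeneSet, n_components: int = 2):
    """PCA of log2FC trajectories: centred (not scaled) SVD projection.

    Component signs follow the convention that each loading vector's
    largest-magnitude entry is positive.  Returns (scores DataFrame,
    variance-explained fractions, loadings DataFrame).
    """
    mat = fc_trajectory_matrix(de, genes)
    if mat.shape[1] < 2 or mat.shape[0] < 2:
        raise ValueError("need >= 2 genes and >= 2 condition rows")
    x = mat.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    if np.allclose(x, 0.0):
        raise ValueError("zero variance: constant log2FC matrix")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, s.size)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u[:, :k] * s[:k]
    var = s**2
    var_frac = var / var.sum()
    cols = [f"PC{j + 1}" for j in range(k)]
    return (
        pd.DataFrame(scores, index=mat.index, columns=cols),
        var_frac[:k],
        pd.DataFrame(vt[:k].T, index=mat.columns, columns=cols),
    )


def filter_top_regulated(
    de: pd.DataFrame,
    contrast: str,
    timepoint: str | None = None,
    mean_expr_min: float = 10.0,
    log2fc_min: float = 2.5,
) -> GeneSet:
    """Strongly induced genes: mean expression and log2FC above thresholds."""
    sub = de[de["contrast"] == contrast]
    if timepoint is not None:
        sub = sub[sub["timepoint"] == timepoint]
    if sub.empty:
        raise ValueError(f"no records for contrast {contrast!r}")
    keep = (sub["mean_expr"] > mean_expr_min) & (sub["log2fc"] > log2fc_min)
    return GeneSet(
        name=f"{contrast}_top_regulated",
        description=f"mean_expr > {mean_expr_min}, log2fc > {log2fc_min}",
        genes=tuple(sorted(set(sub.loc[keep, "gene"]))),
    )
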