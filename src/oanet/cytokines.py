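"""Cytokine activity inference by ridge regression on response signatures.

A transcriptomic response profile y (log2 fold changes) is modelled as a
linear mix of per-cytokine response signatures S: y = S z + noise.  The
ridge estimate z_hat = (S'S + lambda I)^-1 S'y is scored against a null
built by permuting y over the shared genes, which preserves the correlation
structure of S; per-cytokine z-scores and empirical p-values follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAMBDA_GRID = (1e2, 1e3, 1e4)


@dataclass
class ActivityResult:
    cytokines: list[str]
    coef: pd.Series
    perm_z: pd.Series
    perm_p: pd.Series
    lambda_: float
    n_perm: int
    seed: int
    n_shared_genes: int

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"coef": self.coef, "perm_z": self.perm_z, "perm_p": self.perm_p}
        )
        return df.reindex(self.coef.abs().sort_values(ascending=False).index)


def _align(S: pd.DataFrame, y: pd.Series):
    shared = S.index.intersection(y.index)
    if len(shared) < 2:
        raise ValueError("signature/response gene overlap too small (< 2 genes)")
    return S.loc[shared].to_numpy(float), y.loc[shared].to_numpy(float), list(shared)


def _ridge(Sc: np.ndarray, lam: float) -> np.ndarray:
    """Return the linear operator mapping a centred response to coefficients."""
    k = Sc.shape[1]
    gram = Sc.T @ Sc + lam * np.eye(k)
    try:
        return np.linalg.solve(gram, Sc.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular system; use a positive ridge penalty") from exc


def cv_lambda(
    S: pd.DataFrame,
    y: pd.Series,
    grid: tuple[float, ...] = LAMBDA_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Pick the ridge penalty by k-fold cross-validated prediction error."""
    Sm, ym, _ = _align(S, y)
    Sm = Sm - Sm.mean(axis=0)
    ym = ym - ym.mean()
    rng = np.random.default_rng(seed)
    n = ym.size
    folds = rng.permutation(n) % n_folds
    errors = {}
    for lam in grid:
        sse = 0.0
        for f in range(n_folds):
            train, test = folds != f, folds == f
            op = _ridge(Sm[train], lam)
            z = op @ ym[train]
            resid = ym[test] - Sm[test] @ z
            sse += float(resid @ resid)
        errors[lam] = sse
    return min(grid, key=lambda l: (errors[l], l))


def fit_activity(
    S: pd.DataFrame,
    y: pd.Series,
    lambda_: float | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> ActivityResult:
    """Ridge cytokine activities with permutation z-scores and p-values.

    Genes are intersected between signature matrix and response; both are
    centred.  ``lambda_=None`` triggers 5-fold CV over the standard penalty
    grid.  The permutation null shuffles the response over the shared gene
    index ``n_perm`` times with a fixed seed; p-values are two-sided
    empirical with the +1 correction.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100 for stable p-values")
    if (np.asarray(S.abs().sum(axis=0)) == 0).any():
        raise ValueError("signature matrix has an all-zero cytokine column")
    if S.index.duplicated().any():
        raise ValueError("duplicate gene symbols in signature matrix")
    if lambda_ is None:
        lambda_ = cv_lambda(S, y, seed=seed)
    if lambda_ < 0:
        raise ValueError("ridge penalty must be >= 0")
    Sm, ym, shared = _align(S, y)
    Sm = Sm - Sm.mean(axis=0)
    ym = ym - ym.mean()
    op = _ridge(Sm, lambda_)
    z_hat = op @ ym

    rng = np.random.default_rng(seed)
    n = ym.size
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    null = op @ ym[perm_idx].T  # (k, n_perm)
    mu = null.mean(axis=1)
    sd = null.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        perm_z = np.where(sd > 0, (z_hat - mu) / sd, 0.0)
    exceed = (np.abs(null) >= np.abs(z_hat)[:, None]).sum(axis=1)
    perm_p = np.minimum(1.0, (1.0 + exceed) / (n_perm + 1.0))

    cyts = list(S.columns)
    return ActivityResult(
        cytokines=cyts,
        coef=pd.Series(z_hat, index=cyts, name="coef"),
        perm_z=pd.Series(perm_z, index=cyts, name="perm_z"),
        perm_p=pd.Series(perm_p, index=cyts, name="perm_p"),
        lambda_=float(lambda_),
        n_perm=n_perm,
        seed=seed,
        n_shared_genes=len(shared),
    )


def differential_activity(results: dict[str, ActivityResult]) -> pd.DataFrame:
    """Per-cytokine activity contrasts across labelled conditions.

    Returns a wide table of coefficients and permutation z-scores per
    condition plus an ``elevated_in_aged`` call: positive aged coefficient
    exceeding the matching young condition at every compared timepoint.
    Condition labels follow the ``contrast:timepoint`` convention.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 conditions")
    panels = [tuple(r.cytokines) for r in results.values()]
    if len(set(panels)) != 1:
        raise ValueError("cytokine panels differ across conditions")
    cyts = list(panels[0])
    out = pd.DataFrame(index=cyts)
    for label, r in results.items():
        out[f"coef[{label}]"] = r.coef
        out[f"z[{label}]"] = r.perm_z
    pairs = []
    for label in results:
        if label.startswith("aged:"):
            tp = label.split(":", 1)[1]
            young = f"young:{tp}"
            if young in results:
                pairs.append((label, young))
    if pairs:
        elevated = np.ones(len(cyts), dtype=bool)
        for aged, young in pairs:
            diff = results[aged].coef.to_numpy() - results[young].coef.to_numpy()
            elevated &= (results[aged].coef.to_numpy() > 0) & (diff > 0)
            out[f"delta_coef[{aged.split(':')[1]}]"] = diff
        out["elevated_in_aged"] = elevated
    return out


def intersect_source_filter(
    candidates: list[str],
    source_fraction: pd.DataFrame,
    source_tissue: str,
    target_tissue: str,
    source_min: float = 0.01,
    target_max: float = 0.01,
) -> list[str]:
    """Keep cytokines expressed in the source tissue but not the target.

    ``source_fraction`` is a cytokine x tissue table of expressing-cell
    fractions; candidates pass when the source fraction exceeds
    ``source_min`` and the target fraction stays below ``target_max``.
    """
    missing = [c for c in candidates if c not in source_fraction.index]
    if missing:
        raise ValueError(f"cytokines absent from expression table: {missing}")
    kept = []
    for c in candidates:
        src = float(source_fraction.loc[c, source_tissue])
        tgt = float(source_fraction.loc[c, target_tissue])
        if src > source_min and tgt < target_max:
            kept.append(c)
    return kept
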