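"""Standardized mean differences and DerSimonian-Laird random-effects pooling.

Implements the classic two-arm SMD (Cohen's d, optionally Hedges-corrected),
the method-of-moments DerSimonian-Laird estimator of between-study variance,
inverse-variance pooling with normal-approximation confidence intervals, and
the Cochran Q / I-squared heterogeneity statistics. Histology scores on
arbitrary semiquantitative scales are rescaled to 0-100 before pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EffectSize:
    d: float
    variance: float
    hedges_corrected: bool = False

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("effect-size variance must be positive")


@dataclass(frozen=True)
class PooledEffect:
    smd: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    I2: float
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.smd <= self.ci_high):
            raise ValueError("CI must bracket the pooled estimate")
        if self.tau2 < 0 or self.Q < 0 or not (0 <= self.I2 <= 100):
            raise ValueError("invalid heterogeneity statistics")


def smd(
    mean_trt: float,
    sd_trt: float,
    n_trt: int,
    mean_ctrl: float,
    sd_ctrl: float,
    n_ctrl: int,
    hedges: bool = True,
) -> EffectSize:
    """Standardized mean difference between two arms.

    d = (mean_trt - mean_ctrl) / s_p with the pooled SD
    s_p = sqrt(((n_t-1) sd_t^2 + (n_c-1) sd_c^2) / (n_t + n_c - 2));
    the Hedges correction J = 1 - 3/(4(n_t+n_c-2) - 1) is applied by default.
    Sampling variance: (n_t+n_c)/(n_t*n_c) + d^2/(2(n_t+n_c)).
    """
    if n_trt < 2 or n_ctrl < 2:
        raise ValueError("need n >= 2 per arm")
    if sd_trt < 0 or sd_ctrl < 0:
        raise ValueError("SDs must be non-negative")
    dof = n_trt + n_ctrl - 2
    sp2 = ((n_trt - 1) * sd_trt**2 + (n_ctrl - 1) * sd_ctrl**2) / dof
    if sp2 == 0:
        raise ValueError("degenerate pooled SD: both arm SDs are zero")
    d = (mean_trt - mean_ctrl) / np.sqrt(sp2)
    if hedges:
        d *= 1.0 - 3.0 / (4.0 * dof - 1.0)
    n = n_trt + n_ctrl
    var = n / (n_trt * n_ctrl) + d**2 / (2.0 * n)
    return EffectSize(d=float(d), variance=float(var), hedges_corrected=hedges)


def smd_from_row(row, hedges: bool = True) -> EffectSize:
    """SMD from a study-table row (mean/sd/n per arm, optional score range)."""
    lo, hi = row.get("score_min"), row.get("score_max")
    mc, mt = row["mean_ctrl"], row["mean_trt"]
    sc, st = row["sd_ctrl"], row["sd_trt"]
    if lo is not None and hi is not None and not pd.isna(lo) and not pd.isna(hi):
        span = hi - lo
        mc, mt = rescale_score(mc, lo, hi), rescale_score(mt, lo, hi)
        sc, st = 100.0 * sc / span, 100.0 * st / span
    return smd(mt, st, int(row["n_trt"]), mc, sc, int(row["n_ctrl"]), hedges=hedges)


def pool_dl(effects: list[EffectSize]) -> PooledEffect:
    """DerSimonian-Laird random-effects pooling of per-study effect sizes.

    Fixed-effect weights w_i = 1/v_i give the Q statistic; the
    method-of-moments between-study variance is
    tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); random-effects
    weights 1/(v_i + tau2) then give the pooled estimate, a z-based 95% CI,
    and I2 = max(0, (Q - (k-1)) / Q) * 100.
    """
    if len(effects) < 2:
        raise ValueError("pooling needs >= 2 studies; report the single smd() directly")
    d = np.array([e.d for e in effects])
    v = np.array([e.variance for e in effects])
    w = 1.0 / v
    d_fe = float(np.sum(w * d) / np.sum(w))
    Q = float(np.sum(w * (d - d_fe) ** 2))
    k = len(effects)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / c) if c > 0 else 0.0
    w_re = 1.0 / (v + tau2)
    pooled = float(np.sum(w_re * d) / np.sum(w_re))
    se = float(1.0 / np.sqrt(np.sum(w_re)))
    I2 = 0.0 if Q <= 0 else max(0.0, (Q - (k - 1)) / Q) * 100.0
    weights = tuple((w_re / w_re.sum()).tolist())
    return PooledEffect(
        smd=pooled,
        ci_low=pooled - 1.96 * se,
        ci_high=pooled + 1.96 * se,
        tau2=float(tau2),
        Q=Q,
        I2=float(I2),
        weights=weights,
    )


def pool_study_table(studies: pd.DataFrame, hedges: bool = True) -> PooledEffect:
    effects = [smd_from_row(row, hedges=hedges) for _, row in studies.iterrows()]
    return pool_dl(effects)


def rescale_score(x: float, lo: float, hi: float) -> float:
    """Map a semiquantitative score from [lo, hi] onto 0-100."""
    if hi <= lo:
        raise ValueError("need hi > lo")
    if not (lo <= x <= hi):
        raise ValueError(f"score {x} outside [{lo}, {hi}]")
    return 100.0 * (x - lo) / (hi - lo)


def average_effects(effects: list[EffectSize]) -> EffectSize:
    """Arithmetic mean of effect sizes across timepoints within one group.

    The variance is the mean of the per-effect variances — a documented
    simplification that ignores the correlation between timepoints.
    """
    if not effects:
        raise ValueError("cannot average an empty list of effects")
    if len(effects) == 1:
        return effects[0]
    d = float(np.mean([e.d for e in effects]))
    var = float(np.mean([e.variance for e in effects]))
    return EffectSize(d=d, variance=var, hedges_corrected=all(e.hedges_corrected for e in effects))
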