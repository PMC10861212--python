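"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates the *structure* of one real input — an age-stratified
trauma time-course DE table, a modular weighted gene network seeded with a
receptor, cytokine response profiles, two-arm histology summaries, a blocked
co-expression count matrix, a perturbation rank library — and returns the
planted truth alongside, so recovery by the downstream stage is testable.
Signal structure, not RNA-Seq realism, is the contract: counts are simple
log-normal/Poisson draws, null p-values are uniform, and effect sizes are
placed exactly where the corresponding analysis is supposed to find them.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet

CONTRASTS = ("young", "aged")
TIMEPOINTS = ("D1", "W1", "W2", "W6")
RESPONSE_TIMEPOINTS = ("W1", "W2")  # where the planted age signal lives
RECEPTOR = "RECEPTOR"


@dataclass
class SimTruth:
    """Planted ground truth accompanying a synthetic dataset."""

    planted_age_genes: list[str] = field(default_factory=list)
    planted_module_map: dict[str, int] = field(default_factory=dict)
    true_activities: dict[str, float] = field(default_factory=dict)
    true_smd: float = 0.0
    true_tau2: float = 0.0
    reverser_id: str | None = None
    rng_seed: int = 0


def _gene_names(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def gen_de_timecourse(
    n_genes: int = 2000,
    n_planted: int = 200,
    effect_log2fc: float = 2.0,
    noise_sd: float = 0.5,
    n_rep: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Two-group (young/aged) four-timepoint DE table with an aged-only signal.

    The first ``n_planted`` genes are up at W1 and W2 in the aged contrast only
    (log2FC centred on ``effect_log2fc``); everything else is null everywhere.
    ``noise_sd`` is the per-animal log2FC noise and ``n_rep`` the animals per
    group, so the observed estimate carries standard error
    noise_sd/sqrt(n_rep); p-values come from the z-test of the estimate
    against that SE (nulls are Uniform(0,1)); FDR is Benjamini-Hochberg
    within each contrast x timepoint.
    """
    if not (0 < n_planted < n_genes):
        raise ValueError("need 0 < n_planted < n_genes")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_rep < 1:
        raise ValueError("need n_rep >= 1")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    planted = genes[:n_planted]
    sem = noise_sd / np.sqrt(n_rep)
    se = max(sem, 1e-12)

    records = []
    for contrast in CONTRASTS:
        for tp in TIMEPOINTS:
            lfc = rng.normal(0.0, sem, size=n_genes)
            if contrast == "aged" and tp in RESPONSE_TIMEPOINTS:
                lfc[:n_planted] += effect_log2fc
            p = 2.0 * stats.norm.sf(np.abs(lfc) / se)
            p = np.clip(p, 0.0, 1.0)
            fdr = _bh_fdr(p)
            mean_expr = rng.lognormal(mean=3.0, sigma=1.0, size=n_genes)
            records.append(
                pd.DataFrame(
                    {
                        "gene": genes,
                        "contrast": contrast,
                        "timepoint": tp,
                        "log2fc": lfc,
                        "p": p,
                        "fdr": fdr,
                        "mean_expr": mean_expr,
                    }
                )
            )
    de = pd.concat(records, ignore_index=True)
    truth = SimTruth(planted_age_genes=list(planted), rng_seed=seed)
    return de, truth


def gen_network(
    n_nodes: int = 200,
    module_sizes: tuple[int, ...] = (40, 40, 40),
    p_in: float = 0.3,
    p_out: float = 0.02,
    receptor_module: int = 1,
    seed: int = 0,
) -> tuple["nx.Graph", SimTruth]:
    """Planted-partition weighted network with a designated RECEPTOR node.

    Nodes beyond ``sum(module_sizes)`` are unassigned background (module 0)
    wired at the between-module rate.  Edge weights ~ Uniform(0.1, 1.0).
    The RECEPTOR node attaches to ``receptor_module`` with >= 3 edges.
    """
    import networkx as nx

    if not module_sizes:
        raise ValueError("module_sizes must be nonempty")
    if sum(module_sizes) > n_nodes:
        raise ValueError("sum(module_sizes) exceeds n_nodes")
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("need 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_nodes)
    module_map: dict[str, int] = {}
    idx = 0
    for m, size in enumerate(module_sizes, start=1):
        for g in genes[idx : idx + size]:
            module_map[g] = m
        idx += size
    for g in genes[idx:]:
        module_map[g] = 0

    g = nx.Graph()
    g.add_nodes_from(genes)
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            mi, mj = module_map[genes[i]], module_map[genes[j]]
            p = p_in if (mi == mj and mi != 0) else p_out
            if p > 0 and rng.random() < p:
                g.add_edge(genes[i], genes[j], weight=float(rng.uniform(0.1, 1.0)))

    members = [v for v, m in module_map.items() if m == receptor_module]
    k = max(3, len(members) // 4)
    targets = rng.choice(members, size=min(k, len(members)), replace=False)
    for t in targets:
        g.add_edge(RECEPTOR, str(t), weight=float(rng.uniform(0.1, 1.0)))
    module_map[RECEPTOR] = receptor_module

    truth = SimTruth(planted_module_map=module_map, rng_seed=seed)
    return g, truth


def gen_signature_response(
    n_genes: int = 2000,
    cytokines: list[str] | None = None,
    active: dict[str, float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, SimTruth]:
    """Cytokine signature matrix S and response y = S @ z_true + noise.

    S entries are sparse +/- signals (10% nonzero), columns L2-normalized so
    every cytokine contributes comparable energy.  ``active`` maps cytokine
    names to their true activity coefficient; unlisted cytokines have zero.
    """
    if cytokines is None:
        cytokines = [f"CYT{i:02d}" for i in range(1, 41)]
    active = dict(active or {})
    unknown = set(active) - set(cytokines)
    if unknown:
        raise ValueError(f"active cytokines not in panel: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    mask = rng.random((n_genes, len(cytokines))) < 0.10
    signs = rng.choice([-1.0, 1.0], size=mask.shape)
    mags = rng.uniform(0.5, 2.0, size=mask.shape)
    S = mask * signs * mags
    norms = np.linalg.norm(S, axis=0)
    norms[norms == 0] = 1.0
    S = S / norms
    z = np.array([active.get(c, 0.0) for c in cytokines])
    y = S @ z + rng.normal(0.0, noise_sd, size=n_genes)
    S_df = pd.DataFrame(S, index=genes, columns=cytokines)
    y_s = pd.Series(y, index=genes, name="response")
    truth = SimTruth(true_activities={c: active.get(c, 0.0) for c in cytokines}, rng_seed=seed)
    return S_df, y_s, truth


def gen_meta_studies(
    k: int = 10,
    true_smd: float = 1.0,
    tau2: float = 0.2,
    n_per_arm: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-arm study summaries whose true effects are N(true_smd, tau2).

    Control arms ~ N(0, 1); treated arms ~ N(delta_i, 1); the table records
    observed per-arm means/SDs, which carry the usual sampling error.
    """
    if k < 2:
        raise ValueError("need at least 2 studies")
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    if n_per_arm < 3:
        raise ValueError("need n_per_arm >= 3")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(k):
        delta = rng.normal(true_smd, np.sqrt(tau2))
        ctrl = rng.normal(0.0, 1.0, size=n_per_arm)
        trt = rng.normal(delta, 1.0, size=n_per_arm)
        rows.append(
            {
                "study_id": f"study{i + 1:02d}",
                "mean_ctrl": ctrl.mean(),
                "sd_ctrl": ctrl.std(ddof=1),
                "n_ctrl": n_per_arm,
                "mean_trt": trt.mean(),
                "sd_trt": trt.std(ddof=1),
                "n_trt": n_per_arm,
            }
        )
    return pd.DataFrame(rows)


def gen_expr_modules(
    module_sizes: tuple[int, ...] = (60, 60, 60),
    n_samples: int = 20,
    within_cor: float = 0.9,
    n_background: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Blocked count matrix: one latent factor per module, Poisson counts.

    Genes in module m share a per-sample latent factor with weight
    sqrt(within_cor); background genes are independent noise.  Library sizes
    vary uniformly over x[0.5, 2].
    """
    if not (0 <= within_cor < 1):
        raise ValueError("need 0 <= within_cor < 1")
    if n_samples < 4:
        raise ValueError("need n_samples >= 4")
    small = [s for s in module_sizes if s < 30]
    if small:
        warnings.warn(
            f"modules below the default min size 30 will be unassigned: {small}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n_genes = sum(module_sizes) + n_background
    genes = _gene_names(n_genes)
    module_map: dict[str, int] = {}
    rows = []
    lib = rng.uniform(0.5, 2.0, size=n_samples)
    w = np.sqrt(within_cor)
    idx = 0
    for m, size in enumerate(module_sizes, start=1):
        factor = rng.normal(0.0, 1.0, size=n_samples)
        for g in genes[idx : idx + size]:
            module_map[g] = m
            latent = w * factor + np.sqrt(1 - within_cor) * rng.normal(0, 1, n_samples)
            mu = np.exp(5.5 + 0.8 * latent) * lib
            rows.append(rng.poisson(mu))
        idx += size
    for g in genes[idx:]:
        module_map[g] = 0
        latent = rng.normal(0, 1, n_samples)
        mu = np.exp(5.5 + 0.8 * latent) * lib
        rows.append(rng.poisson(mu))
    counts = pd.DataFrame(
        np.asarray(rows, dtype=float),
        index=genes,
        columns=[f"S{j + 1:02d}" for j in range(n_samples)],
    )
    truth = SimTruth(planted_module_map=module_map, rng_seed=seed)
    return counts, truth


def gen_perturbation_library(
    n_perts: int = 100,
    n_genes: int = 1000,
    query_up: GeneSet | None = None,
    plant_reverser: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Perturbation x gene signed rank-score library with an optional reverser.

    Each profile is a random permutation of centred rank scores.  If
    ``plant_reverser``, the perturbation ``PERT_REVERSER`` places every query
    gene at the bottom ranks (most negative scores), so its signature opposes
    the query by construction.
    """
    if query_up is not None and len(query_up) == 0:
        raise ValueError("query_up must be nonempty")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    base = np.arange(n_genes, dtype=float) - (n_genes - 1) / 2.0  # symmetric scores
    base = base[::-1].copy()  # descending
    profiles = {}
    for i in range(n_perts):
        perm = rng.permutation(n_genes)
        scores = np.empty(n_genes)
        scores[perm] = base
        profiles[f"PERT{i + 1:03d}"] = scores
    truth = SimTruth(rng_seed=seed)
    if plant_reverser:
        if query_up is None:
            raise ValueError("plant_reverser requires query_up")
        missing = query_up.as_set() - set(genes)
        if missing:
            raise ValueError(f"query genes outside universe: {sorted(missing)[:5]}")
        scores = np.empty(n_genes)
        q = [g for g in genes if g in query_up.as_set()]
        rest = [g for g in genes if g not in query_up.as_set()]
        order = rest + q  # query genes at the very bottom
        pos = {g: i for i, g in enumerate(order)}
        for j, g in enumerate(genes):
            scores[j] = base[pos[g]]
        truth.reverser_id = "PERT_REVERSER"
        profiles[truth.reverser_id] = scores
    lib = pd.DataFrame(profiles, index=genes).T
    return lib, truth
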