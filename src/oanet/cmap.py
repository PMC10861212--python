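"""Connectivity-map-style scoring of query gene sets against perturbations.

Each perturbation profile (signed gene scores over a common universe) is
ranked descending and the query set's weighted KS enrichment (alpha = 1)
computed; scores are normalized within cell line and sign class, and the
tau percentile places each normalized score against the rest of the library.
Strongly negative tau marks perturbations whose signatures oppose the query
— candidate signature reversers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneSet
from .ssgsea import enrichment_score, rank_genes


@dataclass
class ConnectivityResult:
    perturbation: str
    cell_line: str
    es: float
    ncs: float = float("nan")
    tau: float = float("nan")


def connectivity_es(
    query_up: GeneSet,
    profile: pd.Series,
    query_down: GeneSet | None = None,
) -> float:
    """Weighted KS enrichment (alpha=1, max-deviation form) of the query.

    With only an up set the score is ES_up; with both directions the
    two-sided form (ES_up - ES_down)/2 is used, zeroed when the two
    components share a sign (the ConnectivityMap null convention).
    """
    ranked = rank_genes(profile)
    if not query_up.as_set() & set(ranked.index):
        raise ValueError("no query gene present in the profile universe")
    es_up = enrichment_score(ranked, query_up, alpha=1.0).es_max_dev
    if query_down is None:
        return float(es_up)
    es_down = enrichment_score(ranked, query_down, alpha=1.0).es_max_dev
    if np.sign(es_up) == np.sign(es_down):
        return 0.0
    return float((es_up - es_down) / 2.0)


def score_library(
    library: pd.DataFrame,
    query_up: GeneSet,
    cell_lines: dict[str, str] | None = None,
    query_down: GeneSet | None = None,
) -> list[ConnectivityResult]:
    """ES for every perturbation (rows) of a library against one query."""
    results = []
    for pert, profile in library.iterrows():
        cl = (cell_lines or {}).get(pert, "default")
        es = connectivity_es(query_up, profile, query_down=query_down)
        results.append(ConnectivityResult(perturbation=str(pert), cell_line=cl, es=es))
    return results


def normalize_ncs(results: list[ConnectivityResult]) -> list[ConnectivityResult]:
    """Normalize ES within (cell line, sign) groups: ncs = es / mean |es|.

    Groups with a single member pass through unchanged with a warning.
    """
    groups: dict[tuple[str, int], list[ConnectivityResult]] = {}
    for r in results:
        groups.setdefault((r.cell_line, int(np.sign(r.es))), []).append(r)
    for (cl, sign), members in groups.items():
        if sign == 0:
            for r in members:
                r.ncs = 0.0
            continue
        if len(members) < 2:
            warnings.warn(
                f"single {['negative', '', 'positive'][sign + 1]} score in cell line "
                f"{cl}: ES passed through unnormalized",
                stacklevel=2,
            )
            for r in members:
                r.ncs = r.es
            continue
        denom = float(np.mean([abs(r.es) for r in members]))
        for r in members:
            r.ncs = r.es / denom
    return results


def tau(ncs_query: float, reference_ncs: list[float]) -> float:
    """Signed percentile of |ncs| within the same-sign reference scores."""
    if not reference_ncs:
        raise ValueError("reference list is empty")
    sign = np.sign(ncs_query)
    if sign == 0:
        return 0.0
    same = [r for r in reference_ncs if np.sign(r) == sign]
    if not same:
        warnings.warn("no same-sign reference scores; tau set to 0", stacklevel=2)
        return 0.0
    frac = sum(abs(r) < abs(ncs_query) for r in same) / len(same)
    return float(sign * 100.0 * frac)


def score_and_rank(
    library: pd.DataFrame,
    query_up: GeneSet,
    cell_lines: dict[str, str] | None = None,
    query_down: GeneSet | None = None,
) -> pd.DataFrame:
    """Full tau table: ES -> NCS -> tau (reference = rest of the library)."""
    results = normalize_ncs(
        score_library(library, query_up, cell_lines=cell_lines, query_down=query_down)
    )
    all_ncs = [r.ncs for r in results]
    for i, r in enumerate(results):
        reference = all_ncs[:i] + all_ncs[i + 1 :]
        r.tau = tau(r.ncs, reference)
    df = pd.DataFrame(
        {
            "perturbation": [r.perturbation for r in results],
            "cell_line": [r.cell_line for r in results],
            "es": [r.es for r in results],
            "ncs": [r.ncs for r in results],
            "tau": [r.tau for r in results],
        }
    )
    return df.sort_values("tau", kind="stable").reset_index(drop=True)


def shortlist(scored: pd.DataFrame, threshold: float = -90.0) -> list[str]:
    """Perturbations whose mean tau across cell lines is below threshold.

    Sorted ascending by summary tau (strongest reversers first).
    """
    if scored.empty:
        return []
    summary = scored.groupby("perturbation")["tau"].mean().sort_values()
    return [p for p, t in summary.items() if t < threshold]
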