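"""Random-walk-with-restart propagation and module detection on gene networks.

The walker restarts at the seed gene(s) with probability r each step and
otherwise moves along weighted edges; the stationary affinity vector
measures network proximity to the seeds.  Nodes with strictly positive
affinity are called "pseudo-activated" — on a sparse, partly disconnected
tissue network this is the reachable-influence set of the seeded receptor.
Communities come from greedy weighted-modularity agglomeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .io import GeneSet


@dataclass
class PropagationResult:
    seeds: tuple[str, ...]
    restart: float
    affinity: pd.Series  # node -> affinity, sums to 1
    iterations: int
    converged: bool
    tolerance: float


@dataclass
class ModulePartition:
    """node -> module id; 0 marks nodes left unassigned (below min size)."""

    assignments: dict[str, int]
    modularity: float

    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.assignments.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def members(self, module_id: int) -> list[str]:
        return sorted(v for v, m in self.assignments.items() if m == module_id)


def build_transition(net: nx.Graph, nodelist: list[str] | None = None) -> sparse.csr_matrix:
    """Column-stochastic transition operator M[u, v] = w(u, v) / deg_w(v).

    Columns of isolated nodes are the unit vector on themselves
    (self-absorbing), which keeps the operator stochastic.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = nodelist if nodelist is not None else sorted(net.nodes())
    a = nx.to_scipy_sparse_array(net, nodelist=nodes, weight="weight", format="csc")
    a = a.astype(float)
    deg = np.asarray(a.sum(axis=0)).ravel()
    isolated = deg == 0
    inv = np.zeros_like(deg)
    inv[~isolated] = 1.0 / deg[~isolated]
    m = a @ sparse.diags(inv)
    if isolated.any():
        idx = np.flatnonzero(isolated)
        m = m.tolil()
        m[idx, idx] = 1.0
    return sparse.csr_matrix(m)


def rwr(
    net: nx.Graph,
    seeds: GeneSet | list[str],
    restart: float = 0.7,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> PropagationResult:
    """Random walk with restart: iterate p <- (1-r) M p + r e until stable.

    The restart vector e is uniform over the seeds; convergence is declared
    when the L1 change drops below ``tol``.  Unreachable nodes keep exactly
    zero affinity because mass only ever flows along edges.
    """
    seed_list = tuple(sorted(set(seeds.genes if isinstance(seeds, GeneSet) else seeds)))
    missing = [s for s in seed_list if s not in net]
    if missing:
        raise ValueError(f"seed genes absent from network: {missing}")
    if not (0 < restart < 1):
        raise ValueError("restart probability must lie in (0, 1)")
    nodes = sorted(net.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    m = build_transition(net, nodelist=nodes)
    e = np.zeros(len(nodes))
    for s in seed_list:
        e[index[s]] = 1.0 / len(seed_list)
    p = e.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p_next = (1.0 - restart) * (m @ p) + restart * e
        delta = float(np.abs(p_next - p).sum())
        p = p_next
        if delta < tol:
            converged = True
            break
    return PropagationResult(
        seeds=seed_list,
        restart=restart,
        affinity=pd.Series(p, index=nodes, name="affinity"),
        iterations=it,
        converged=converged,
        tolerance=tol,
    )


def rwr_exact(net: nx.Graph, seeds: GeneSet | list[str], restart: float = 0.7) -> pd.Series:
    """Closed-form stationary affinity r (I - (1-r) M)^{-1} e (dense solve).

    Intended for small networks; serves as the reference the iterative
    solver is checked against.
    """
    seed_list = sorted(set(seeds.genes if isinstance(seeds, GeneSet) else seeds))
    nodes = sorted(net.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    m = build_transition(net, nodelist=nodes).toarray()
    e = np.zeros(len(nodes))
    for s in seed_list:
        e[index[s]] = 1.0 / len(seed_list)
    p = restart * np.linalg.solve(np.eye(len(nodes)) - (1.0 - restart) * m, e)
    return pd.Series(p, index=nodes, name="affinity")


def pseudo_activated(
    prop: PropagationResult,
    exclude: GeneSet | set[str] | None = None,
    drop_seeds: bool = True,
) -> GeneSet:
    """Nodes with strictly positive affinity, minus exclusions and seeds."""
    if not prop.converged:
        raise ValueError("propagation did not converge; increase max_iter or tol")
    excl = set()
    if exclude is not None:
        excl = exclude.as_set() if isinstance(exclude, GeneSet) else set(exclude)
    positive = set(prop.affinity.index[prop.affinity > 0])
    positive -= excl
    if drop_seeds:
        positive -= set(prop.seeds)
    return GeneSet(
        name="pseudo_activated",
        description=f"affinity > 0 from seeds {','.join(prop.seeds)} at r={prop.restart}",
        genes=tuple(sorted(positive)),
    )


def detect_modules(net: nx.Graph, min_size: int = 3) -> ModulePartition:
    """Greedy weighted-modularity communities; small ones relabelled 0.

    Modules are numbered 1..k in decreasing size (ties broken by the
    lexicographically smallest member) for deterministic output.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    comms = list(nx.community.greedy_modularity_communities(net, weight="weight"))
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    assignments: dict[str, int] = {}
    next_id = 1
    for comm in comms:
        if len(comm) >= min_size:
            for v in comm:
                assignments[v] = next_id
            next_id += 1
        else:
            for v in comm:
                assignments[v] = 0
    q = nx.community.modularity(net, comms, weight="weight") if net.number_of_edges() else 0.0
    return ModulePartition(assignments=assignments, modularity=float(q))


def annotate_module(
    partition: ModulePartition,
    module_id: int,
    annotation_sets: list[GeneSet],
    universe: GeneSet | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of one module against annotation gene sets.

    Returns a table ranked by p-value (then by name); the universe defaults
    to all partitioned nodes.
    """
    from .enrich import contingency_from_sets, fisher_test

    if not annotation_sets:
        raise ValueError("need at least one annotation set")
    if module_id not in set(partition.assignments.values()):
        raise ValueError(f"module id {module_id} not present in partition")
    members = GeneSet(name=f"module{module_id}", genes=tuple(partition.members(module_id)))
    if universe is None:
        universe = GeneSet(name="universe", genes=tuple(sorted(partition.assignments)))
    rows = []
    for s in annotation_sets:
        restricted = GeneSet(name=s.name, genes=tuple(g for g in s.genes if g in universe))
        table = contingency_from_sets(members, restricted, universe)
        res = fisher_test(table)
        rows.append(
            {
                "annotation": s.name,
                "overlap": table.a,
                "module_size": len(members),
                "set_size": len(restricted),
                "odds_ratio": res.odds_ratio,
                "p": res.p_two_sided,
            }
        )
    out = pd.DataFrame(rows).sort_values(["p", "annotation"], kind="stable")
    return out.reset_index(drop=True)
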