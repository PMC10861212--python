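import numpy as np
import pandas as pd
import pytest

from oanet.io import GeneSet


@pytest.fixture
def toy_de_table() -> pd.DataFrame:
    """Six genes covering every significance-membership combination.

    G1: up W1+W2 aged only (selected); G2: up W1+W2 both (shared);
    G3: up W1 aged only (fails intersection); G4: up W1+W2 aged, W1 young
    (excluded under 'any'); G5: down W1+W2 aged only; G6: never significant.
    """
    rows = []
    sig_up = dict(log2fc=2.0, p=1e-4, fdr=1e-3)
    sig_dn = dict(log2fc=-2.0, p=1e-4, fdr=1e-3)
    null = dict(log2fc=0.05, p=0.8, fdr=0.9)
    layout = {
        "G1": {("aged", "W1"): sig_up, ("aged", "W2"): sig_up},
        "G2": {(c, t): sig_up for c in ("young", "aged") for t in ("W1", "W2")},
        "G3": {("aged", "W1"): sig_up},
        "G4": {("aged", "W1"): sig_up, ("aged", "W2"): sig_up, ("young", "W1"): sig_up},
        "G5": {("aged", "W1"): sig_dn, ("aged", "W2"): sig_dn},
        "G6": {},
    }
    for gene, cells in layout.items():
        for contrast in ("young", "aged"):
            for tp in ("D1", "W1", "W2", "W6"):
                vals = cells.get((contrast, tp), null)
                rows.append(
                    dict(gene=gene, contrast=contrast, timepoint=tp, mean_expr=50.0, **vals)
                )
    return pd.DataFrame(rows)


@pytest.fixture
def small_gene_sets():
    universe = GeneSet(name="U", genes=tuple(f"G{i}" for i in range(1, 21)))
    a = GeneSet(name="A", genes=("G1", "G2", "G3", "G4", "G5"))
    b = GeneSet(name="B", genes=("G3", "G4", "G5", "G6", "G7", "G8"))
    return a, b, universe


def random_weighted_graph(n_nodes: int, p_edge: float, seed: int):
    """Erdos-Renyi graph with Uniform(0.1, 1] weights, possibly disconnected."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.Graph()
    nodes = [f"N{i:03d}" for i in range(n_nodes)]
    g.add_nodes_from(nodes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                g.add_edge(nodes[i], nodes[j], weight=float(rng.uniform(0.1, 1.0)))
    return g
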