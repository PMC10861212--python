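"""End-to-end orchestration: stage sequencing, seeding, and provenance.

A run takes a config mapping input paths and stage parameters, executes the
enabled stages (stress selection, meta-analysis, propagation, cytokine
inference, ssGSEA, enrichment, co-expression, connectivity scoring) in
order, and writes every intermediate as TSV/GMT/JSON plus a manifest with
parameters and input hashes so any stage can be replayed standalone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from . import cmap as cmap_mod
from . import coexpr as coexpr_mod
from . import cytokines as cyto_mod
from . import enrich as enrich_mod
from . import io as io_mod
from . import meta as meta_mod
from . import netprop as netprop_mod
from . import ssgsea as ssgsea_mod
from . import stress as stress_mod
from .io import GeneSet

logger = logging.getLogger(__name__)

DEFAULTS: dict[str, Any] = {
    "fdr_threshold": 0.05,
    "restart": 0.7,
    "alpha": 0.75,
    "ridge_lambda": None,
    "n_perm": 1000,
    "min_module_size": 30,
    "deep_split": 2,
    "tau_threshold": -90.0,
    "seed": 0,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: stable hash of the stage name.

    Adding or removing a stage never perturbs another stage's randomness.
    Kept below 2**31 so downstream RNGs accept it.
    """
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class PipelineConfig:
    out_dir: str = "results/run"
    seed: int = 0
    de_table: str | None = None
    network: str | None = None
    seeds_gene: str = "RECEPTOR"
    exclude_gmt: str | None = None
    signatures: str | None = None
    study_table: str | None = None
    counts: str | None = None
    groups: str | None = None
    library: str | None = None
    query_gmt: str | None = None
    universe_gmt: str | None = None
    params: dict[str, Any] = field(default_factory=dict)

    def param(self, key: str):
        return self.params.get(key, DEFAULTS[key])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        params = raw.pop("params", {})
        return cls(**raw, params=params)


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage whose inputs are configured; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: config.param(k) for k in DEFAULTS},
        "inputs": {},
        "stages": [],
    }
    for name in (
        "de_table",
        "network",
        "exclude_gmt",
        "signatures",
        "study_table",
        "counts",
        "groups",
        "library",
        "query_gmt",
        "universe_gmt",
    ):
        path = getattr(config, name)
        if path:
            manifest["inputs"][name] = {"path": path, "sha256": _hash_file(Path(path))}

    state: dict[str, Any] = {}
    stages = [
        ("stress", _stage_stress),
        ("meta", _stage_meta),
        ("propagate", _stage_propagate),
        ("cytokines", _stage_cytokines),
        ("ssgsea", _stage_ssgsea),
        ("enrich", _stage_enrich),
        ("coexpr", _stage_coexpr),
        ("cmap", _stage_cmap),
    ]
    for name, fn in stages:
        try:
            ran = fn(config, out, state)
        except Exception as exc:
            io_mod.write_json(manifest, out / "manifest.json")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        if ran:
            manifest["stages"].append(name)
            logger.info("stage %s complete", name)
    io_mod.write_json(manifest, out / "manifest.json")
    return manifest


def _stage_stress(config, out, state) -> bool:
    if not config.de_table:
        return False
    de = io_mod.read_de_table(config.de_table)
    rule = stress_mod.SelectionRule(fdr_threshold=config.param("fdr_threshold"))
    up = stress_mod.select_stress_response(de, rule)
    state["de"], state["stress_up"] = de, up
    io_mod.write_gmt([up], out / "stress_up.gmt")
    return True


def _stage_meta(config, out, state) -> bool:
    if not config.study_table:
        return False
    studies = pd.read_csv(config.study_table, sep="\t")
    pooled = meta_mod.pool_study_table(studies)
    io_mod.write_json(asdict(pooled), out / "meta_pooled.json")
    state["pooled"] = pooled
    return True


def _stage_propagate(config, out, state) -> bool:
    if not config.network:
        return False
    net = io_mod.read_edgelist(config.network)
    prop = netprop_mod.rwr(net, [config.seeds_gene], restart=config.param("restart"))
    exclude = None
    if config.exclude_gmt:
        exclude = io_mod.read_gmt(config.exclude_gmt)[0]
    activated = netprop_mod.pseudo_activated(prop, exclude=exclude)
    prop.affinity.to_csv(out / "affinity.tsv", sep="\t", header=True)
    io_mod.write_gmt([activated], out / "pseudo_activated.gmt")
    state["network"], state["prop"], state["activated"] = net, prop, activated
    return True


def _stage_cytokines(config, out, state) -> bool:
    if not config.signatures or "de" not in state:
        return False
    S = io_mod.read_matrix(config.signatures)
    results = {}
    de = state["de"]
    for (contrast, tp), sub in de.groupby(["contrast", "timepoint"]):
        y = pd.Series(sub["log2fc"].to_numpy(), index=sub["gene"])
        results[f"{contrast}:{tp}"] = cyto_mod.fit_activity(
            S,
            y,
            lambda_=config.param("ridge_lambda"),
            n_perm=config.param("n_perm"),
            seed=stage_seed(config.seed, f"cytokines:{contrast}:{tp}"),
        )
    table = cyto_mod.differential_activity(results)
    table.to_csv(out / "cytokine_activity.tsv", sep="\t", index_label="cytokine")
    state["cytokines"] = results
    return True


def _stage_ssgsea(config, out, state) -> bool:
    if "de" not in state:
        return False
    stiffness = ssgsea_mod.load_stiffness_set()
    try:
        results = ssgsea_mod.run_stiffness_ssgsea(
            state["de"],
            stiffness,
            alpha=config.param("alpha"),
            n_perm=config.param("n_perm"),
            seed=stage_seed(config.seed, "ssgsea"),
        )
    except ValueError:
        return False  # stiffness genes absent from this DE table
    rows = [
        {
            "condition": label,
            "es_integral": r.es_integral,
            "es_max_dev": r.es_max_dev,
            "nes": r.nes,
            "perm_p": r.perm_p,
            "leading_edge": ";".join(r.leading_edge.genes),
        }
        for label, r in results.items()
    ]
    pd.DataFrame(rows).to_csv(out / "ssgsea_stiffness.tsv", sep="\t", index=False)
    state["ssgsea"] = results
    return True


def _stage_enrich(config, out, state) -> bool:
    if "activated" not in state or "stress_up" not in state:
        return False
    if config.universe_gmt:
        universe = io_mod.read_gmt(config.universe_gmt)[0]
    else:
        universe = GeneSet(name="network_nodes", genes=tuple(sorted(state["network"].nodes())))
    activated = GeneSet(
        name="pseudo_activated",
        genes=tuple(g for g in state["activated"].genes if g in universe),
    )
    target = GeneSet(
        name="stress_up", genes=tuple(g for g in state["stress_up"].genes if g in universe)
    )
    table = enrich_mod.contingency_from_sets(activated, target, universe)
    result = enrich_mod.fisher_test(table)
    io_mod.write_json(
        {"table": asdict(table), **asdict(result)}, out / "enrichment.json"
    )
    state["enrichment"] = result
    return True


def _stage_coexpr(config, out, state) -> bool:
    if not config.counts or not config.groups:
        return False
    counts = io_mod.read_expr_matrix(config.counts)
    groups = io_mod.read_groups(config.groups)
    partition, st = coexpr_mod.detect_coexpr_modules(
        counts,
        groups,
        min_size=config.param("min_module_size"),
        deep_split=config.param("deep_split"),
    )
    pd.Series(partition.assignments, name="module").to_csv(
        out / "coexpr_modules.tsv", sep="\t", index_label="gene"
    )
    io_mod.write_json(asdict(st), out / "soft_threshold.json")
    state["coexpr"] = partition
    return True


def _stage_cmap(config, out, state) -> bool:
    if not config.library or not config.query_gmt:
        return False
    library = io_mod.read_matrix(config.library)
    query = io_mod.read_gmt(config.query_gmt)[0]
    scored = cmap_mod.score_and_rank(library, query)
    scored.to_csv(out / "cmap_tau.tsv", sep="\t", index=False)
    hits = cmap_mod.shortlist(scored, threshold=config.param("tau_threshold"))
    io_mod.write_json({"shortlist": hits}, out / "cmap_shortlist.json")
    state["cmap"] = scored
    return True


def driver_rank(
    network,
    candidate_seeds: GeneSet | list[str],
    target_set: GeneSet,
    exclude: GeneSet | None = None,
    universe: GeneSet | None = None,
    restart: float = 0.7,
) -> pd.DataFrame:
    """Rank candidate driver receptors by pseudo-activation enrichment.

    For each candidate: propagate, take the strictly-positive-affinity set
    (minus exclusions and the seed), and score its overlap with the target
    set by Fisher's exact test over the universe.  Ranked by odds ratio
    descending, ties by p ascending.
    """
    candidates = list(candidate_seeds.genes if isinstance(candidate_seeds, GeneSet) else candidate_seeds)
    missing = [c for c in candidates if c not in network]
    if missing:
        raise ValueError(f"candidate seeds absent from network: {missing}")
    if universe is None:
        universe = GeneSet(name="network_nodes", genes=tuple(sorted(network.nodes())))
    target = GeneSet(name=target_set.name, genes=tuple(g for g in target_set.genes if g in universe))
    rows = []
    for cand in candidates:
        prop = netprop_mod.rwr(network, [cand], restart=restart)
        activated = netprop_mod.pseudo_activated(prop, exclude=exclude)
        activated = GeneSet(
            name="pa", genes=tuple(g for g in activated.genes if g in universe and g != cand)
        )
        cand_universe = GeneSet(
            name="u", genes=tuple(g for g in universe.genes if g != cand)
        )
        cand_target = GeneSet(
            name="t", genes=tuple(g for g in target.genes if g != cand)
        )
        table = enrich_mod.contingency_from_sets(activated, cand_target, cand_universe)
        res = enrich_mod.fisher_test(table)
        rows.append(
            {
                "seed": cand,
                "n_activated": len(activated),
                "overlap": table.a,
                "odds_ratio": res.odds_ratio,
                "p": res.p_two_sided,
            }
        )
    df = pd.DataFrame(rows)
    df["_or"] = df["odds_ratio"].fillna(-1.0)
    df = df.sort_values(["_or", "p"], ascending=[False, True], kind="stable")
    return df.drop(columns="_or").reset_index(drop=True)
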