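"""Score the upregulated query signature against the perturbation library.

Connectivity-map-style tau scoring: weighted KS enrichment of the query in
each perturbation's rank profile, sign-stratified normalization, and the
tau percentile against the rest of the library.  The planted signature
reverser should shortlist at tau < -90.
"""

import json
from pathlib import Path

from oanet import cmap, io

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    lib = io.read_matrix(ROOT / "fixtures" / "library.tsv")
    query = io.read_gmt(ROOT / "fixtures" / "query.gmt")[0]
    truth = json.loads((ROOT / "fixtures" / "truth.json").read_text())

    scored = cmap.score_and_rank(lib, query)
    scored.to_csv(ROOT / "cmap_tau.tsv", sep="\t", index=False)
    hits = cmap.shortlist(scored, threshold=-90.0)
    reverser = truth["reverser_id"]
    row = scored[scored["perturbation"] == reverser].iloc[0]
    print(f"{len(scored)} perturbations scored; {len(hits)} below tau -90: {hits}")
    print(
        f"planted reverser {reverser}: es={row['es']:.3f}, ncs={row['ncs']:.3f}, "
        f"tau={row['tau']:.1f} -> {'shortlisted' if reverser in hits else 'MISSED'}"
    )
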