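"""Infer cytokine activities from the synthetic response profile.

Ridge regression of the response on the cytokine signature matrix with a
gene-label permutation null; the planted active cytokine should dominate
the |z| ranking.
"""

import json
from pathlib import Path

from oanet import cytokines, io

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    S = io.read_matrix(ROOT / "fixtures" / "signatures.tsv")
    y = io.read_matrix(ROOT / "fixtures" / "response.tsv").iloc[:, 0]
    truth = json.loads((ROOT / "fixtures" / "truth.json").read_text())
    planted = {c for c, z in truth["true_activities"].items() if z != 0}

    result = cytokines.fit_activity(S, y, lambda_=100.0, n_perm=1000, seed=11)
    table = result.table()
    table.to_csv(ROOT / "cytokine_activity.tsv", sep="\t", index_label="cytokine")

    top = list(table.index[:3])
    print(f"lambda = {result.lambda_:g}, {result.n_shared_genes} shared genes")
    print(f"planted active cytokines: {sorted(planted)}; top by |coef|: {top}")
    print(table.head(5).to_string())
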