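"""Select the age-specific trauma-response gene set from the DE time course.

Applies the selection algebra — significantly upregulated (FDR < 0.05) at
both week 1 and week 2 after injury in the aged contrast, at neither
timepoint in the young contrast — and reports recall against the planted
truth, plus a PCA of the log2FC trajectories showing the aged/young split.
"""

import json
from pathlib import Path

from oanet import io, stress

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    de = io.read_de_table(ROOT / "fixtures" / "de_table.tsv")
    truth = json.loads((ROOT / "fixtures" / "truth.json").read_text())

    selected = stress.select_stress_response(de, stress.SelectionRule())
    planted = set(truth["planted_age_genes"])
    recall = len(set(selected.genes) & planted) / len(planted)
    precision = len(set(selected.genes) & planted) / max(len(selected), 1)

    io.write_gmt([selected], ROOT / "stress_up.gmt")
    scores, var_frac, _ = stress.fc_trajectory_pca(de, selected)
    scores.to_csv(ROOT / "stress_trajectory_pca.tsv", sep="\t", index_label="condition")

    print(f"{len(selected)} age-specific response genes selected -> {ROOT/'stress_up.gmt'}")
    print(f"recall vs planted truth: {recall:.3f}; precision: {precision:.3f}")
    print(f"PC1 explains {100 * var_frac[0]:.1f}% of trajectory variance")
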