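"""Generate the complete synthetic input bundle for the downstream analyses.

Emits a fixture directory under results/fixtures/ containing every artifact
the pipeline consumes — the age-stratified trauma time-course DE table, the
modular weighted gene network seeded with a receptor, the cytokine signature
matrix and response profile, the two-arm histology study table, the blocked
co-expression count matrix, and the perturbation rank library — plus
truth.json recording the planted signals the later stages should recover.
"""

from pathlib import Path

from oanet.cli import main

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"

if __name__ == "__main__":
    main.main(
        ["simulate", "--out", str(OUT), "--seed", "1", "--n-genes", "2000", "--n-planted", "200"],
        standalone_mode=False,
    )
    print(f"Synthetic inputs with planted ground truth written to {OUT}")
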