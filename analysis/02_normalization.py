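#!/usr/bin/env python
"""Replicate depth normalization: the ten public runs and the simulated study.

Recomputes the per-replicate coefficients c_i = N_av/N_i within each growth
condition from the published perfect-match read depths, then shows the same
computation on the simulated replicates.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, ensure_study, publish

import pandas as pd

from divtss.study_runs import study_run_table


def main() -> None:
    table = study_run_table()
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "study_run_coefficients.tsv"
    table.to_csv(out, sep="\t", index=False, float_format="%.6f")
    print("per-run normalization coefficients (N_av/N_i within condition):")
    print(
        table[["accession", "condition", "perfect_match_reads", "coefficient_4dp"]]
        .to_string(index=False)
    )
    print(f"-> {out}")

    _, _, run_dir = ensure_study()
    sim = pd.read_csv(run_dir / "replicate_table.tsv", sep="\t")
    print("\nsimulated replicates (depths differ by design, so c_i != 1):")
    print(sim.to_string(index=False))
    publish(run_dir / "replicate_table.tsv", "replicate_table.tsv")


if __name__ == "__main__":
    main()
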