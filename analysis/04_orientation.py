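#!/usr/bin/env python
"""Orientation of each ncRNA against its nearest gene, and inter-TSS distances.

Classifies every annotated ncRNA (codirected / divergent / 5'-overlapping /
convergent), flags bona fide vs potential antisense ncRNAs, and summarizes
the TSS-to-TSS distance of divergent pairs.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import ensure_study, publish

import pandas as pd


def main() -> None:
    _, _, run_dir = ensure_study()
    arr = pd.read_csv(run_dir / "arrangements.tsv", sep="\t")
    publish(run_dir / "arrangements.tsv", "arrangements.tsv")
    print("arrangement counts:")
    print(arr["arrangement"].value_counts().to_string())
    antisense = arr[~arr["bona_fide_vs_annotation"]]
    print("\npotential antisense ncRNAs (overlap with an opposite-strand transcript):")
    print(antisense[["ncrna", "neighbor", "antisense_overlap"]].to_string(index=False))

    summary = pd.read_csv(run_dir / "inter_tss_summary.tsv", sep="\t")
    publish(run_dir / "inter_tss_summary.tsv", "inter_tss_summary.tsv")
    print("\ninter-TSS distances of divergent pairs (refined primary TSSs):")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
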