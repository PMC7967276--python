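#!/usr/bin/env python
"""Simulate the desk-scale study: genome, annotation, 5'-end reads, truth.

Writes the fixture (FASTA/GFF3/FASTQ/SAM plus truth tables) under
scratch/analysis/fixture and runs the full pipeline once into
scratch/analysis/run; prints what was planted.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import ensure_study, publish

import pandas as pd


def main() -> None:
    config, fixture_dir, run_dir = ensure_study()
    truth_pairs = pd.read_csv(fixture_dir / "truth_pairs.tsv", sep="\t")
    truth_reps = pd.read_csv(fixture_dir / "truth_replicates.tsv", sep="\t")
    print(f"genome: {config.genome_length:,} bp with {len(config.features)} planted features")
    print(f"ncRNA/gene pairs by arrangement:\n{truth_pairs['arrangement'].value_counts().to_string()}")
    print(f"replicates:\n{truth_reps.to_string(index=False)}")
    print(f"REP loci planted: {len(config.rep_loci)} "
          f"({sum(1 for r in config.rep_loci if r.tss)} with divergent TSS)")
    publish(fixture_dir / "truth_pairs.tsv", "truth_pairs.tsv")
    publish(fixture_dir / "truth_rep_loci.tsv", "truth_rep_loci.tsv")
    print(f"fixture: {fixture_dir}\npipeline run: {run_dir}")


if __name__ == "__main__":
    main()
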