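#!/usr/bin/env python
"""REP read-through screen over intergenic regions between collinear genes.

For every REP-containing IGR: divergent TSS evidence on the strand opposing
the flanking genes, the TSS-to-REP distance, and whether a candidate
intrinsic terminator (poly-T track preceded by a hairpin) would block
transcription from reading through the REP element.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import ensure_study, publish

import pandas as pd


def main() -> None:
    _, _, run_dir = ensure_study()
    rep = pd.read_csv(run_dir / "rep_report.tsv", sep="\t")
    publish(run_dir / "rep_report.tsv", "rep_report.tsv")
    print("REP-containing intergenic regions:")
    print(rep.to_string(index=False))
    with_tss = rep[rep["divergent_tss"].notna()]
    print(
        f"\n{len(with_tss)}/{len(rep)} REP loci show a divergent TSS; "
        f"{int(with_tss['read_through'].sum())} of those can read through "
        f"(no hairpin+poly-T terminator candidate between TSS and REP 5' end)"
    )
    if len(with_tss):
        dist = with_tss["tss_to_rep_distance"]
        print(f"TSS-to-REP distances: {sorted(int(d) for d in dist)} bp")


if __name__ == "__main__":
    main()
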