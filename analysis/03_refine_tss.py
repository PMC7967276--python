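#!/usr/bin/env python
"""TSS refinement: called peaks, signed shifts, and prediction concordance.

Reports every feature whose called primary TSS deviates from the annotated
5' end (negative offset = transcript extension, positive = shortening) and
the condition-dependent promoter switches.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import ensure_study, publish

import pandas as pd


def main() -> None:
    _, _, run_dir = ensure_study()
    calls = pd.read_csv(run_dir / "tss_calls.tsv", sep="\t")
    publish(run_dir / "tss_calls.tsv", "tss_calls.tsv")

    prim = calls[calls["rank"] == "primary"]
    shifted = prim[prim["offset"] != 0]
    print("primary TSSs shifted relative to the annotation:")
    print(shifted[["feature", "condition", "position", "offset"]].to_string(index=False))

    switches = (
        prim.groupby("feature")["position"].nunique().loc[lambda s: s > 1].index.tolist()
    )
    print(f"\nfeatures with condition-dependent primary promoters: {switches}")
    n_secondary = (calls["rank"] == "secondary").sum()
    matched = calls["matched_prediction"].mean()
    print(f"secondary TSS calls: {n_secondary}; fraction matching the predicted-TSS track: {matched:.2%}")


if __name__ == "__main__":
    main()
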