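"""The ten public 5'-end RNA-seq runs the pipeline is designed around.

Read counts are taken from the published per-run summaries of the two source
experiments (ENA runs ERR930221/ERR930222 and SRA runs SRR1173969-SRR1173986
mapped against *E. coli* K-12 MG1655, NC_000913.3).  They serve as the input
for recomputing the per-replicate normalization coefficients N_av/N_i and as
the reference depths the synthetic-data generator scales down from.
"""

from __future__ import annotations

import pandas as pd

from .pileup import normalization_coefficients

#: (accession, condition label, reads after adapter trimming and >=16 nt
#:  length filtering, reads perfectly matching the genome)
SEQUENCING_RUNS: list[tuple[str, str, int, int]] = [
    ("ERR930221", "M9 mid-log", 14_063_469, 11_015_459),
    ("ERR930222", "M9 mid-log", 9_184_197, 5_116_134),
    ("SRR1173969", "LB 0.4", 6_145_538, 4_886_330),
    ("SRR1173970", "LB 0.4", 5_834_605, 4_814_550),
    ("SRR1173974", "LB 2.0", 5_627_281, 3_341_088),
    ("SRR1173978", "LB 2.0", 6_967_456, 5_072_554),
    ("SRR1173979", "LB 2.0", 7_691_759, 5_861_466),
    ("SRR1173980", "LB 2.0", 6_214_631, 3_621_841),
    ("SRR1173985", "M63 0.4", 8_368_755, 5_128_824),
    ("SRR1173986", "M63 0.4", 8_445_228, 5_428_622),
]


def study_run_table() -> pd.DataFrame:
    """Recompute the per-run normalization coefficients from the run depths.

    Coefficients are computed per condition group (the replicates sharing a
    growth condition) and reported rounded to 4 decimal places, alongside the
    full-precision value.
    """
    df = pd.DataFrame(
        SEQUENCING_RUNS,
        columns=["accession", "condition", "reads_after_trim_and_length", "perfect_match_reads"],
    )
    coeffs: list[float] = []
    for _, sub in df.groupby("condition", sort=False):
        coeffs.extend(normalization_coefficients(sub["perfect_match_reads"].tolist()))
    df["coefficient"] = coeffs
    df["coefficient_4dp"] = df["coefficient"].round(4)
    return df
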