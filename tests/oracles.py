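"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: the SAM recount uses its
own text parsing and CIGAR walk, and the motif scanner compares the pattern
character by character at every offset on both strands.
"""

from __future__ import annotations

import re

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}
IUPAC_COMP = {
    "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_CIG = re.compile(r"(\d+)([A-Z=])")


def brute_force_recount(sam_path):
    """Recount perfect-match 5' ends from SAM text, line by line."""
    plus, minus = {}, {}
    n = 0
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            cols = line.rstrip("\n").split("\t")
            flag, pos, cigar = int(cols[1]), int(cols[3]), cols[5]
            if flag & 0x4 or flag & 0x100 or flag & 0x800:
                continue
            tags = dict(t.split(":", 2)[::2] for t in cols[11:])
            if tags.get("XM") != "0" or tags.get("NM") != "0":
                continue
            n += 1
            span = sum(int(m) for m, op in _CIG.findall(cigar) if op in "MDN=X")
            if flag & 0x10:
                p = pos + span - 1
                minus[p] = minus.get(p, 0) + 1
            else:
                plus[pos] = plus.get(pos, 0) + 1
    return plus, minus, n


def brute_force_scan(seq, pattern, max_mismatches):
    """All-offsets, both-strands degenerate match with early mismatch exit."""
    seq = seq.upper()
    rc_pattern = "".join(IUPAC_COMP[c] for c in reversed(pattern))
    hits = []
    for strand, pat in (("+", pattern), ("-", rc_pattern)):
        plen = len(pat)
        for i in range(len(seq) - plen + 1):
            mm = 0
            for p, g in zip(pat, seq[i : i + plen]):
                if g not in IUPAC[p] or (g == "N" and p != "N"):
                    mm += 1
                    if mm > max_mismatches:
                        break
            if mm <= max_mismatches:
                hits.append((i + 1, i + plen, strand, mm))
    return sorted(hits)
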