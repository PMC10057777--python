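"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's own code paths (and biopython's
aligner): identity comes from a lexicographic dynamic programme, feature
values from naive counting, confusion counts from a per-example loop.
"""

from __future__ import annotations


def identity_oracle(a: str, b: str) -> float:
    """Global identity = max matches / alignment length.

    DP maximizing (matches, aligned pairs) lexicographically; among all
    max-match global alignments the one with the most aligned (non-gap)
    columns has the fewest gaps, hence the shortest alignment:
    length = len(a) + len(b) - aligned_pairs.
    """
    la, lb = len(a), len(b)
    # cell = (matches, aligned_pairs), lexicographic max
    prev = [(0, 0)] * (lb + 1)
    for i in range(1, la + 1):
        cur = [(0, 0)] * (lb + 1)
        for j in range(1, lb + 1):
            m, p = prev[j - 1]
            diag = (m + (a[i - 1] == b[j - 1]), p + 1)
            cur[j] = max(diag, prev[j], cur[j - 1])
        prev = cur
    matches, pairs = prev[lb]
    aln_len = la + lb - pairs
    return matches / aln_len if aln_len else 0.0


def count_residues(seq: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for ch in seq:
        out[ch] = out.get(ch, 0) + 1
    return out


def count_dipeptides(seq: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for i in range(len(seq) - 1):
        dp = seq[i:i + 2]
        out[dp] = out.get(dp, 0) + 1
    return out


def recount_confusion(truths, predictions) -> tuple[int, int, int, int]:
    """Per-example TP/TN/FP/FN recount."""
    tp = tn = fp = fn = 0
    for t, p in zip(truths, predictions):
        if t == 1 and p == 1:
            tp += 1
        elif t == 1:
            fn += 1
        elif p == -1:
            tn += 1
        else:
            fp += 1
    return tp, tn, fp, fn
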