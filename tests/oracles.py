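"""Independent brute-force oracles used by the tests.

These deliberately avoid the library code paths they check: the alignment
oracle is a textbook Gotoh dynamic program, the frame oracle literally
translates the rebuilt reporter construct, and the anchor oracle is an
exhaustive sliding Hamming scan.
"""

from __future__ import annotations

from Bio.Seq import Seq

# first 15 codons of the GFP coding sequence downstream of the insert
GFP_CDS = "GTGAGCAAGGGCGAGGAGCTGTTCACCGGGGTGGTGCCCATCCTG"


def gotoh_score(a: str, b: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-1):
    """Exhaustive global affine-gap DP; gap of length L costs
    gap_open + (L-1)*gap_extend."""
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] + gap_open,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open,
                Y[i][j - 1] + gap_extend,
                X[i][j - 1] + gap_open,
            )
    return max(M[n][m], X[n][m], Y[n][m])


def gfp_frame_restored(target_region: str, pam: str) -> bool:
    """Rebuild ATG + insert + GFP and check by translation whether the GFP
    peptide is produced in frame."""
    construct = "ATG" + target_region + pam + GFP_CDS
    trimmed = construct[: len(construct) // 3 * 3]
    peptide = str(Seq(trimmed).translate())
    gfp_peptide = str(Seq(GFP_CDS).translate())
    return gfp_peptide in peptide


def brute_find_anchor(read: str, anchor: str, k: int, from_index: int = 0):
    width = len(anchor)
    for i in range(max(from_index, 0), len(read) - width + 1):
        if sum(x != y for x, y in zip(read[i : i + width], anchor)) <= k:
            return i
    return None
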