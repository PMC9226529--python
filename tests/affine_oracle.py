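"""Brute-force read-classification oracle, independent of the package's
alignment path.

Implements the declared scoring model directly: a full Gotoh dynamic
program (match 0, mismatch -1, gaps -(2 + k)) with free allele overhangs,
plus exhaustive enumeration of every gapless read placement. A read is
indel-free iff some gapless placement achieves the DP optimum.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)


@njit(cache=False)
def gotoh_glocal_score(read: np.ndarray, allele: np.ndarray) -> int:
    """Optimal glocal affine score of ``read`` (uint8 array, fully aligned)
    against ``allele`` (free overhangs)."""
    m, n = read.size, allele.size
    H = np.zeros(n + 1, np.int64)  # row 0: alignment may start anywhere
    Q = np.full(n + 1, NEG, np.int64)  # state: read char over a gap
    for i in range(1, m + 1):
        prev_diag = H[0]
        h0 = -(2 + i)  # leading read overhang: gap of length i
        Q[0] = h0
        prev_h = h0
        p_cur = NEG
        for j in range(1, n + 1):
            s = 0 if read[i - 1] == allele[j - 1] else -1
            diag = prev_diag + s
            qj = max(H[j] - 3, Q[j] - 1)
            p_cur = max(prev_h - 3, p_cur - 1)
            hij = max(diag, max(p_cur, qj))
            prev_diag = H[j]
            H[j] = hij
            Q[j] = qj
            prev_h = hij
        H[0] = h0
    best = NEG
    for j in range(n + 1):
        if H[j] > best:
            best = H[j]
    return best


def subs_only_best(read: str, allele: str) -> tuple[int, int]:
    """Exhaustive gapless placements: (min mismatches, smallest offset)."""
    a = np.frombuffer(read.encode(), np.uint8)
    b = np.frombuffer(allele.encode(), np.uint8)
    best_mm, best_off = len(read) + 1, 0
    for off in range(len(allele) - len(read) + 1):
        mm = int((a != b[off : off + len(read)]).sum())
        if mm < best_mm:
            best_mm, best_off = mm, off
    return best_mm, best_off


_LABEL = {"WT": "wt", "desired": "desired", "left_only": "single_side",
          "right_only": "single_side"}


def oracle_classify(read: str, alleles, max_mm_rate: float = 0.05) -> str:
    """Label a read against expected alleles (non-conversion designs) by
    running the DP against every allele."""
    per = []
    arr = np.frombuffer(read.encode(), np.uint8)
    for al in alleles:
        score = int(
            gotoh_glocal_score(arr, np.frombuffer(al.sequence.encode(), np.uint8))
        )
        mm, _ = subs_only_best(read, al.sequence)
        per.append((score, -mm == score, mm, al))
    best = max(p[0] for p in per)
    for score, indel_free, mm, al in per:
        if score == best and indel_free:
            if mm / len(read) > max_mm_rate:
                return "other"
            return _LABEL.get(al.name, "other")
    return "indel"
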