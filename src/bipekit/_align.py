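"""Read-to-allele alignment primitives.

The classification model is a glocal alignment: the read is aligned end to
end while the allele's overhanging ends are free. Scoring is fixed for
bit-for-bit reproducibility: match 0, mismatch -1, affine gaps costing
2 (open) + 1 per gapped base.
"""

from __future__ import annotations

import numpy as np
from Bio import Align

GAP_OPEN = 2
GAP_EXTEND = 1

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 0
_aligner.mismatch_score = -1
# Biopython charges open_gap_score for the first gapped base and
# extend_gap_score for each further base: open 2 + extend 1 => -3 / -1.
_aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
_aligner.extend_gap_score = -GAP_EXTEND
# allele (target) overhangs are free: unaligned target ends appear as end
# "deletions" relative to the read
_aligner.end_deletion_score = 0


def affine_score(read: str, allele_seq: str) -> float:
    """Optimal glocal affine alignment score (<= 0) of ``read`` against
    ``allele_seq``."""
    return _aligner.score(allele_seq, read)


def best_substitution_only(read: str, allele_seq: str) -> tuple[int, int]:
    """Best gapless placement of ``read`` inside ``allele_seq``.

    Returns ``(n_mismatches, offset)`` minimising mismatches; ties break to
    the smallest offset. Requires ``len(read) <= len(allele_seq)``.
    """
    if len(read) > len(allele_seq):
        raise ValueError("read longer than allele")
    a = np.frombuffer(read.encode(), dtype=np.uint8)
    b = np.frombuffer(allele_seq.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(b, len(a))
    mm = (windows != a).sum(axis=1)
    off = int(mm.argmin())
    return int(mm[off]), off
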