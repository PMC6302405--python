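"""Exhaustive gapless overlap alignment of a read pair.

Every possible gapless placement of reverse-complemented R2 against R1 is
scored; a placement is valid when its overlap spans at least ``min_overlap``
columns and its mismatch fraction is at most ``max_mismatch_frac``. Among
valid placements the one with the lowest mismatch fraction wins (ties:
larger overlap, then smaller absolute offset). Ambiguous bases (N) count as
neither matches nor mismatches.

The offset convention: ``offset`` is the position of the 5' end of
reverse-complemented R2 relative to the 5' end of R1 (0-based). Offsets < 0
and offsets with ``len1 - offset > len2`` are dovetailed configurations, in
which a read's 3' end extends past its mate's 5' end and the overhang is
adapter sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .fastq import ReadPair, reverse_complement

__all__ = [
    "AlignParams",
    "AlignmentResult",
    "enumerate_offsets",
    "score_overlap",
    "find_best_alignment",
]

_N_CODE = ord("N")


@dataclass(frozen=True)
class AlignParams:
    """Alignment acceptance thresholds (CLI: -m, -p, -d)."""

    min_overlap: int = 20
    max_mismatch_frac: float = 0.1
    allow_dovetail: bool = False

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0.0 <= self.max_mismatch_frac <= 1.0:
            raise ValueError("max_mismatch_frac must be in [0, 1]")


@dataclass(frozen=True)
class AlignmentResult:
    offset: int
    overlap_len: int
    matches: int
    mismatches: int
    n_positions: int
    dovetail: bool

    def __post_init__(self) -> None:
        if self.matches + self.mismatches + self.n_positions != self.overlap_len:
            raise ValueError("overlap column counts do not sum to overlap_len")

    @property
    def mismatch_frac(self) -> float:
        denom = self.matches + self.mismatches
        return self.mismatches / denom if denom > 0 else 0.0


def _overlap_len(len1: int, len2: int, offset: int) -> int:
    return min(len1, offset + len2) - max(0, offset)


def is_dovetail(len1: int, len2: int, offset: int) -> bool:
    """Dovetail: R2 overhang on the left (offset < 0) or R1 overhang on the
    right (len1 - offset > len2)."""
    return offset < 0 or len1 - offset > len2


def enumerate_offsets(len1: int, len2: int, params: AlignParams) -> list[int]:
    """All offsets whose geometric overlap is >= min_overlap, ascending.

    Dovetail placements are included only when ``params.allow_dovetail``.
    """
    if len1 < 1 or len2 < 1:
        raise ValueError("read lengths must be >= 1")
    offsets = []
    for offset in range(-(len2 - params.min_overlap), len1 - params.min_overlap + 1):
        if _overlap_len(len1, len2, offset) < params.min_overlap:
            continue
        if not params.allow_dovetail and is_dovetail(len1, len2, offset):
            continue
        offsets.append(offset)
    return offsets


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _score_arrays(
    a1: np.ndarray, a2: np.ndarray, offset: int
) -> tuple[int, int, int, int]:
    start = max(0, offset)
    end = min(len(a1), offset + len(a2))
    if end <= start:
        raise ValueError(f"offset {offset} implies zero overlap")
    w1 = a1[start:end]
    w2 = a2[start - offset : end - offset]
    n_mask = (w1 == _N_CODE) | (w2 == _N_CODE)
    n_positions = int(n_mask.sum())
    matches = int(((w1 == w2) & ~n_mask).sum())
    overlap_len = end - start
    mismatches = overlap_len - matches - n_positions
    return matches, mismatches, n_positions, overlap_len


def score_overlap(
    seq1: str, rc2: str, offset: int
) -> tuple[int, int, int, int]:
    """Count (matches, mismatches, n_positions, overlap_len) for one placement.

    ``rc2`` must be the reverse complement of R2. A column where either base
    is N increments only ``n_positions``.
    """
    return _score_arrays(_seq_to_array(seq1), _seq_to_array(rc2), offset)


_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _score_all_offsets(a1: np.ndarray, a2: np.ndarray):
    """Overlap statistics for every offset at once.

    Match counts per offset are sums of per-base indicator
    cross-correlations; N columns come from window sums (cumulative sums)
    minus the N-by-N cross-correlation. Returns integer arrays
    (offsets, overlap_len, matches, n_positions) over offsets
    -(len2-1) .. len1-1.
    """
    len1, len2 = len(a1), len(a2)
    offsets = np.arange(-(len2 - 1), len1)
    idx = offsets + len2 - 1
    n1 = a1 == _N_CODE
    n2 = a2 == _N_CODE
    corr = np.zeros(len1 + len2 - 1)
    for b in _ACGT:
        corr += np.correlate((a1 == b).astype(float), (a2 == b).astype(float), "full")
    cross_n = np.correlate(n1.astype(float), n2.astype(float), "full")
    start1 = np.maximum(0, offsets)
    end1 = np.minimum(len1, offsets + len2)
    overlap = end1 - start1
    c1 = np.concatenate([[0], np.cumsum(n1)])
    c2 = np.concatenate([[0], np.cumsum(n2)])
    s1 = c1[end1] - c1[start1]
    s2 = c2[end1 - offsets] - c2[start1 - offsets]
    npos = (s1 + s2 - np.rint(cross_n[idx])).astype(np.int64)
    matches = np.rint(corr[idx]).astype(np.int64)
    return offsets, overlap, matches, npos


def find_best_alignment(
    pair: ReadPair, params: AlignParams = AlignParams()
) -> Optional[AlignmentResult]:
    """Best valid gapless placement of the pair, or None if none qualifies.

    Equivalent to scoring every offset from :func:`enumerate_offsets` with
    :func:`score_overlap` and keeping the minimum-mismatch-fraction
    placement (ties broken by larger overlap, then smaller |offset|).
    """
    a1 = _seq_to_array(pair.r1.seq)
    a2 = _seq_to_array(reverse_complement(pair.r2.seq))
    len1, len2 = len(a1), len(a2)
    offsets, overlap, matches, npos = _score_all_offsets(a1, a2)
    valid = overlap >= params.min_overlap
    if not params.allow_dovetail:
        valid &= (offsets >= 0) & (len1 - offsets <= len2)
    if not valid.any():
        return None
    offsets, overlap, matches, npos = (
        x[valid] for x in (offsets, overlap, matches, npos)
    )
    mismatches = overlap - matches - npos
    denom = matches + mismatches
    frac = np.where(denom > 0, mismatches / np.maximum(denom, 1), 0.0)
    ok = frac <= params.max_mismatch_frac
    if not ok.any():
        return None
    order = np.lexsort((np.abs(offsets[ok]), -overlap[ok], frac[ok]))
    i = np.nonzero(ok)[0][order[0]]
    return AlignmentResult(
        offset=int(offsets[i]),
        overlap_len=int(overlap[i]),
        matches=int(matches[i]),
        mismatches=int(mismatches[i]),
        n_positions=int(npos[i]),
        dovetail=is_dovetail(len1, len2, int(offsets[i])),
    )
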