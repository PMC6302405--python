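"""Stitching read pairs into merged reads, and dovetail adapter removal.

Stitch mode builds a single read spanning the full DNA fragment: bases
outside the overlap are copied verbatim (R2's contribution is
reverse-complemented, with qualities reversed), and each overlap column is
resolved by :func:`resolve_position`. Dovetail overhangs — read 3' ends
extending past the mate's 5' end, i.e. adapter sequence — are never copied
into the merged read.

Adapter-removal mode leaves the pair as two reads but truncates each read's
3' overhang at the column where its mate's 5' end begins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .align import AlignmentResult
from .fastq import FastqRecord, ReadPair, reverse_complement
from .quality import QualityModel, merged_quality

__all__ = ["MergeEvent", "MergeOutcome", "resolve_position", "stitch", "remove_adapters"]


class MergeEvent(NamedTuple):
    """One overlap column of a merged read (events log row)."""

    position: int  # 0-based position in the merged read
    r1_base: str
    r1_qual: int
    r2_base: str
    r2_qual: int
    chosen_base: str
    chosen_qual: int
    cls: str  # match | mismatch | n_resolved | n_both


@dataclass
class MergeOutcome:
    merged: FastqRecord
    events: list[MergeEvent] = field(default_factory=list)


def resolve_position(
    b1: str, q1: int, b2: str, q2: int, model: QualityModel
) -> tuple[str, int]:
    """Resolve one overlap column to a (base, quality).

    Matching bases keep the base with the model's match quality. Disagreeing
    bases keep the higher-quality base with the model's mismatch quality; an
    exact quality tie yields 'N' (no evidence favours either base). A single
    N is resolved to the called base at its own quality; two Ns stay N at
    quality 0. Non-N outputs are floored at ``model.qual_floor``.
    """
    if b1 == "N" and b2 == "N":
        return "N", 0
    if b1 == "N":
        return b2, int(q2)
    if b2 == "N":
        return b1, int(q1)
    if b1 == b2:
        q = merged_quality(model, q1, q2, is_match=True)
        return b1, max(q, model.qual_floor)
    q = merged_quality(model, q1, q2, is_match=False)
    if q1 == q2:
        return "N", q
    base = b1 if q1 > q2 else b2
    return base, max(q, model.qual_floor)


def _classify(b1: str, b2: str) -> str:
    if b1 == "N" and b2 == "N":
        return "n_both"
    if b1 == "N" or b2 == "N":
        return "n_resolved"
    return "match" if b1 == b2 else "mismatch"


def stitch(
    pair: ReadPair,
    aln: AlignmentResult,
    model: QualityModel,
    collect_events: bool = True,
) -> MergeOutcome:
    """Build the merged read for an aligned pair.

    The merged read runs 5'(R1) -> 5'(R2) on R1's strand: columns
    [0, offset + len2), where column 0 is R1's first base and column
    offset + len2 - 1 is R2's (reverse-complemented) first base. Adapter
    overhangs (R1 columns past the fragment end, R2 columns before its
    start) are dropped.
    """
    r1, r2 = pair.r1, pair.r2
    len1, len2 = len(r1), len(r2)
    offset = aln.offset
    if not (-len2 < offset < len1) or min(len1, offset + len2) <= max(0, offset):
        raise ValueError("alignment inconsistent with read lengths")
    rc2 = reverse_complement(r2.seq)
    rcq2 = r2.quals[::-1]

    merged_len = offset + len2
    ov_start = max(0, offset)
    ov_end = min(len1, merged_len)

    seq = []
    quals = np.empty(merged_len, dtype=np.int16)
    # R1-only prefix
    seq.append(r1.seq[:ov_start])
    quals[:ov_start] = r1.quals[:ov_start]
    # overlap columns
    events: list[MergeEvent] = []
    for col in range(ov_start, ov_end):
        b1, q1 = r1.seq[col], int(r1.quals[col])
        b2, q2 = rc2[col - offset], int(rcq2[col - offset])
        base, q = resolve_position(b1, q1, b2, q2, model)
        seq.append(base)
        quals[col] = q
        if collect_events:
            events.append(
                MergeEvent(col, b1, q1, b2, q2, base, q, _classify(b1, b2))
            )
    # R2-only suffix (columns past R1's 3' end)
    if merged_len > ov_end:
        seq.append(rc2[ov_end - offset : merged_len - offset])
        quals[ov_end:] = rcq2[ov_end - offset : merged_len - offset]
    merged = FastqRecord(id=r1.name, seq="".join(seq), quals=quals)
    return MergeOutcome(merged=merged, events=events)


def remove_adapters(pair: ReadPair, aln: Optional[AlignmentResult]) -> ReadPair:
    """Clip 3' adapter overhangs of a dovetailed pair; otherwise no-op.

    Each read is truncated at the column where its mate's 5' end begins.
    Idempotent: re-processing an already-clipped pair changes nothing.
    """
    if aln is None or not aln.dovetail:
        return pair
    r1, r2 = pair.r1, pair.r2
    len1, len2 = len(r1), len(r2)
    keep1 = min(len1, aln.offset + len2)  # R1 up to R2's 5' end
    keep2 = min(len2, len2 + aln.offset)  # R2 up to R1's 5' end
    new1 = FastqRecord(id=r1.id, seq=r1.seq[:keep1], quals=r1.quals[:keep1])
    new2 = FastqRecord(id=r2.id, seq=r2.seq[:keep2], quals=r2.quals[:keep2])
    return ReadPair(new1, new2)
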