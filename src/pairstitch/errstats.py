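"""Per-quality-score error rates from aligned reads, and the PhiX reference.

The phiX174 spike-in control is the standard substrate for measuring
Illumina error rates: its genome is known, so every aligned base can be
checked. Two corrections matter before counting errors against the NCBI
reference (NC_001422.1, 5386 bp):

* five consistently observed substitutions relative to the NCBI record
  (:data:`PHIX_VARIANTS`) are applied — without them, real sequence
  differences masquerade as sequencing errors and inflate the apparent
  error rate, especially for high-quality bases;
* the genome is circular, so the first 1 kb is appended to the end
  (6386 bp total) to let fragments spanning the origin align contiguously.

:func:`count_errors_by_quality` consumes SAM alignments (or anything pysam
reads) and tallies, per claimed quality score, how many aligned bases
disagree with the reference. With a merge events log and the original read
lengths it additionally splits merged-read overlap columns into
match/mismatch/N classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional

import numpy as np
import pysam
from Bio import SeqIO

from .merge import MergeEvent

__all__ = [
    "VariantEdit",
    "PHIX_VARIANTS",
    "load_fasta",
    "phix_reference",
    "apply_variants",
    "circular_extend",
    "count_errors_by_quality",
    "ErrorByQuality",
]


@dataclass(frozen=True)
class VariantEdit:
    """A substitution: 1-based position, expected reference base, new base."""

    position: int
    ref_base: str
    alt_base: str


# The five substitutions consistently observed (>=95% allele frequency) in
# PhiX sequencing libraries, relative to NC_001422.1.
PHIX_VARIANTS = (
    VariantEdit(587, "G", "A"),
    VariantEdit(833, "G", "A"),
    VariantEdit(2731, "A", "G"),
    VariantEdit(2811, "C", "T"),
    VariantEdit(3133, "C", "T"),
)


def load_fasta(path) -> str:
    """First sequence of a FASTA file, uppercased."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq).upper()


def apply_variants(genome: str, edits: Iterable[VariantEdit] = PHIX_VARIANTS) -> str:
    """Apply substitutions, verifying each expected reference base."""
    seq = list(genome)
    for e in edits:
        if not 1 <= e.position <= len(seq):
            raise ValueError(f"edit position {e.position} outside genome")
        if seq[e.position - 1] != e.ref_base:
            raise ValueError(
                f"position {e.position}: expected {e.ref_base!r}, "
                f"found {seq[e.position - 1]!r}"
            )
        seq[e.position - 1] = e.alt_base
    return "".join(seq)


def circular_extend(genome: str, ext_len: int = 1000) -> str:
    """Append the first ``ext_len`` bases to the end (circular genome)."""
    if ext_len > len(genome):
        raise ValueError("extension longer than the genome")
    return genome + genome[:ext_len]


def phix_reference(
    edits: Iterable[VariantEdit] = PHIX_VARIANTS, ext_len: int = 1000
) -> str:
    """The corrected, circularly extended PhiX reference (6386 bp)."""
    data = resources.files("pairstitch.data") / "NC_001422.1.fasta"
    with resources.as_file(data) as path:
        genome = load_fasta(path)
    return circular_extend(apply_variants(genome, edits), ext_len)


@dataclass
class ErrorByQuality:
    """Tallies: per quality score, aligned base and error counts, per class.

    Classes: 'all' always; with an events log also 'match', 'mismatch', 'n'
    for merged-read overlap columns and 'nonoverlap' for the rest.
    """

    bases: dict[str, np.ndarray]
    errors: dict[str, np.ndarray]

    def rate(self, cls: str = "all") -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                self.bases[cls] > 0, self.errors[cls] / np.maximum(self.bases[cls], 1), np.nan
            )


_EVENT_CLS = {"match": "match", "mismatch": "mismatch", "n_resolved": "n", "n_both": "n"}


def count_errors_by_quality(
    alignments,
    reference: str,
    event_log: Optional[Mapping[str, Mapping[int, str]]] = None,
    read_lengths: Optional[tuple[int, int]] = None,
    qmax: int = 93,
) -> ErrorByQuality:
    """Count aligned bases and reference mismatches per quality score.

    ``alignments`` is a SAM/BAM path or an iterable of pysam AlignedSegment.
    Only mapped, properly paired (when paired), primary records are used.
    Insertions and soft-clips are excluded; deletions are not base errors;
    N bases are excluded from error counting. With ``event_log`` (read name
    -> {merged position: event class}) and ``read_lengths`` (len1, len2),
    overlap columns of merged reads are split into match/mismatch/N classes
    (overlap = merged positions [M - len2, len1) for a merged length M).
    """
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        handle = pysam.AlignmentFile(str(alignments), check_sq=False)
        records = handle.fetch(until_eof=True)
    else:
        records = alignments
    classes = ["all"]
    if event_log is not None:
        classes += ["match", "mismatch", "n", "nonoverlap"]
    bases = {c: np.zeros(qmax + 1, dtype=np.int64) for c in classes}
    errors = {c: np.zeros(qmax + 1, dtype=np.int64) for c in classes}
    used = 0
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.is_paired and not rec.is_proper_pair:
            continue
        seq = rec.query_sequence
        quals = rec.query_qualities
        if seq is None or quals is None:
            continue
        used += 1
        M = len(seq)
        ev: Mapping[int, str] = {}
        if event_log is not None:
            ev = event_log.get(rec.query_name, {})
        for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
            base = seq[qpos]
            if base == "N":
                continue
            q = quals[qpos]
            err = base != reference[rpos]
            bases["all"][q] += 1
            if err:
                errors["all"][q] += 1
            if event_log is not None and read_lengths is not None:
                len1, len2 = read_lengths
                mpos = M - 1 - qpos if rec.is_reverse else qpos
                if M - len2 <= mpos < len1:
                    cls = _EVENT_CLS.get(ev.get(mpos, "match"), "match")
                else:
                    cls = "nonoverlap"
                bases[cls][q] += 1
                if err:
                    errors[cls][q] += 1
    if used == 0:
        warnings.warn("no usable (mapped, properly paired) alignments found")
    return ErrorByQuality(bases=bases, errors=errors)


def events_to_log(
    named_events: Iterable[tuple[str, Iterable[MergeEvent]]]
) -> dict[str, dict[int, str]]:
    """Convert per-read merge events into the event_log mapping."""
    out: dict[str, dict[int, str]] = {}
    for name, events in named_events:
        out[name] = {ev.position: ev.cls for ev in events if ev.cls != "match"}
    return out
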