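"""Quality-aware paired-end read simulator with known per-base truth.

Emulates the geometry and error structure relevant to read merging:

* fragments drawn from a reference at random positions/strands, lengths
  from a truncated normal — short fragments produce dovetailed pairs whose
  3' ends run into adapter sequence;
* per-cycle Phred qualities (constant, noisy declining ramp, or a discrete
  set of levels), with independent substitution errors injected at exactly
  the rate each base's quality claims, 10^(-q/10);
* *shared first-strand errors*: with per-base probability rho an error is
  written into the fragment template itself before either read is taken,
  so both reads carry the same wrong base at full quality. This is the
  mechanism that makes paired-read errors non-independent on real flow
  cells (the fragment is copied once during first-strand synthesis and any
  error propagates through the whole cluster);
* optional N-masking of called bases.

Determinism: each pair derives its generator from (seed, pair index), so
output is byte-identical for a given seed and earlier pairs are unchanged
when n_pairs grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .fastq import FastqRecord, ReadPair, reverse_complement

__all__ = [
    "SimConfig",
    "PairTruth",
    "simulate",
    "random_reference",
    "truth_overlap_errors",
    "write_truth",
    "read_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_N = ord("N")

# Standard Illumina TruSeq adapter read-through prefixes (R1 / R2).
ADAPTER1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
ADAPTER2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated run.

    ``quality`` is one of ("constant", q), ("ramp", q_start, q_end, sd) —
    linear decline across the cycle with integer Gaussian noise — or
    ("levels", (q, ...)) drawing each base's quality uniformly from a
    discrete set. Qualities are clamped to [2, 41].
    """

    n_pairs: int
    read_len: int = 100
    reference: Optional[str] = None
    ref_len: int = 10000
    frag_mean: float = 150.0
    frag_sd: float = 20.0
    min_frag: int = 40
    max_frag: int = 400
    adapter1: str = ADAPTER1
    adapter2: str = ADAPTER2
    quality: tuple = ("ramp", 38.0, 27.0, 2.0)
    shared_error_rate: float = 0.0
    n_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_error_rate <= 1.0:
            raise ValueError("shared_error_rate must be in [0, 1]")
        if self.min_frag < 1 or self.max_frag < self.min_frag:
            raise ValueError("need 1 <= min_frag <= max_frag")
        if self.reference is not None and len(self.reference) < self.max_frag:
            raise ValueError("reference shorter than max_frag")


@dataclass
class PairTruth:
    """Ground truth for one simulated pair.

    ``frag_seq`` is the true (pre-error) fragment on R1's strand. Error
    position lists are 0-based read coordinates (for r1/r2) or fragment
    coordinates (shared); N lists are read coordinates. Error lists cover
    only fragment-derived read positions (adapter bases have no truth).
    """

    pair_id: str
    frag_start: int
    frag_end: int
    strand: str
    frag_seq: str
    dovetail: bool
    r1_errors: list[int] = field(default_factory=list)
    r2_errors: list[int] = field(default_factory=list)
    shared_errors: list[int] = field(default_factory=list)
    r1_n: list[int] = field(default_factory=list)
    r2_n: list[int] = field(default_factory=list)

    @property
    def frag_len(self) -> int:
        return self.frag_end - self.frag_start


def random_reference(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng([seed, 941])
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def _substitute(arr: np.ndarray, positions: np.ndarray, rng) -> None:
    # uniform choice among the 3 alternative bases
    for pos in positions:
        alts = _BASES[_BASES != arr[pos]]
        arr[pos] = alts[rng.integers(0, 3)]


def _draw_quals(quality: tuple, read_len: int, rng) -> np.ndarray:
    kind = quality[0]
    if kind == "constant":
        q = np.full(read_len, int(quality[1]), dtype=np.int16)
    elif kind == "ramp":
        _, q_start, q_end, sd = quality
        base = np.linspace(float(q_start), float(q_end), read_len)
        q = np.rint(base + rng.normal(0.0, float(sd), size=read_len)).astype(np.int16)
    elif kind == "levels":
        levels = np.asarray(quality[1], dtype=np.int16)
        q = levels[rng.integers(0, len(levels), size=read_len)]
    else:
        raise ValueError(f"unknown quality model {kind!r}")
    return np.clip(q, 2, 41)


def _make_read(
    template: np.ndarray,  # fragment (with shared errors), read orientation
    true_frag: np.ndarray,  # true fragment, same orientation
    adapter: str,
    cfg: SimConfig,
    rng,
) -> tuple[FastqRecord, list[int], list[int], np.ndarray]:
    L = len(template)
    rl = cfg.read_len
    if L >= rl:
        read = template[:rl].copy()
        truth = true_frag[:rl]
        n_frag = rl
    else:
        pad = adapter + "A" * max(0, rl - L - len(adapter))
        pad_arr = np.frombuffer(pad[: rl - L].encode("ascii"), dtype=np.uint8)
        read = np.concatenate([template, pad_arr])
        truth = true_frag
        n_frag = L
    quals = _draw_quals(cfg.quality, rl, rng)
    p_err = 10.0 ** (-quals / 10.0)
    err_pos = np.nonzero(rng.random(rl) < p_err)[0]
    _substitute(read, err_pos, rng)
    if cfg.n_rate > 0:
        n_pos = np.nonzero(rng.random(rl) < cfg.n_rate)[0]
    else:
        n_pos = np.empty(0, dtype=int)
    read[n_pos] = _N
    quals[n_pos] = 2
    # errors = fragment-covered positions where the called base differs from truth
    frag_part = read[:n_frag]
    diff = np.nonzero(frag_part != truth[:n_frag])[0]
    n_set = set(int(p) for p in n_pos if p < n_frag)
    errors = [int(p) for p in diff if int(p) not in n_set]
    rec_quals = quals
    return (
        FastqRecord(id="", seq=bytes(read).decode("ascii"), quals=rec_quals),
        errors,
        sorted(n_set),
        n_pos,
    )


def simulate(cfg: SimConfig) -> Iterator[tuple[ReadPair, PairTruth]]:
    """Yield (ReadPair, PairTruth) for each simulated fragment."""
    ref = cfg.reference if cfg.reference is not None else random_reference(cfg.ref_len, cfg.seed)
    ref_arr = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
    ref_len = len(ref_arr)
    if ref_len < cfg.max_frag:
        raise ValueError("reference shorter than max_frag")
    for i in range(cfg.n_pairs):
        rng = np.random.default_rng([cfg.seed, i])
        # truncated-normal fragment length
        L = 0
        for _ in range(100):
            L = int(round(rng.normal(cfg.frag_mean, cfg.frag_sd)))
            if cfg.min_frag <= L <= cfg.max_frag:
                break
        else:
            L = int(np.clip(L, cfg.min_frag, cfg.max_frag))
        start = int(rng.integers(0, ref_len - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = ref_arr[start : start + L]
        if strand == "-":
            frag = np.frombuffer(
                reverse_complement(bytes(frag).decode("ascii")).encode("ascii"),
                dtype=np.uint8,
            )
        frag = frag.copy()
        true_frag = frag.copy()
        # shared first-strand errors: written into the template before
        # either read is taken, at unreduced quality
        shared_pos = np.nonzero(rng.random(L) < cfg.shared_error_rate)[0]
        _substitute(frag, shared_pos, rng)
        rc_template = np.frombuffer(
            reverse_complement(bytes(frag).decode("ascii")).encode("ascii"),
            dtype=np.uint8,
        )
        rc_truth = np.frombuffer(
            reverse_complement(bytes(true_frag).decode("ascii")).encode("ascii"),
            dtype=np.uint8,
        )
        pair_id = f"sim{i}"
        r1, e1, n1, _ = _make_read(frag, true_frag, cfg.adapter1, cfg, rng)
        r2, e2, n2, _ = _make_read(rc_template, rc_truth, cfg.adapter2, cfg, rng)
        r1.id = f"{pair_id}/1"
        r2.id = f"{pair_id}/2"
        truth = PairTruth(
            pair_id=pair_id,
            frag_start=start,
            frag_end=start + L,
            strand=strand,
            frag_seq=bytes(true_frag).decode("ascii"),
            dovetail=L < cfg.read_len,
            r1_errors=e1,
            r2_errors=e2,
            shared_errors=[int(p) for p in shared_pos],
            r1_n=n1,
            r2_n=n2,
        )
        yield ReadPair(r1, r2), truth


def truth_overlap_errors(
    truth: PairTruth, read_len: int
) -> list[tuple[int, bool, bool, bool]]:
    """Per-overlap-column truth: (frag_pos, r1_correct, r2_correct, shared).

    The overlap is the fragment region covered by both reads; R1 covers
    fragment[0 : min(read_len, L)], R2 covers fragment[L - min(read_len, L) : L].
    N-masked columns report the read as correct=False only if the underlying
    call was an error; Ns are tracked separately by the caller via PairTruth.
    """
    L = truth.frag_len
    cov = min(read_len, L)
    lo, hi = max(0, L - cov), cov
    e1 = set(truth.r1_errors)
    e2 = set(truth.r2_errors)
    shared = set(truth.shared_errors)
    out = []
    for p in range(lo, hi):
        r1_pos = p
        r2_pos = L - 1 - p
        out.append((p, r1_pos not in e1, r2_pos not in e2, p in shared))
    return out


_TRUTH_COLS = [
    "pair_id", "frag_start", "frag_end", "strand", "dovetail", "frag_seq",
    "r1_errors", "r2_errors", "shared_errors", "r1_n", "r2_n",
]


def _fmt_list(xs) -> str:
    return ",".join(str(x) for x in xs) if xs else "."


def _parse_list(s: str) -> list[int]:
    return [] if s == "." else [int(x) for x in s.split(",")]


def write_truth(truths, path) -> None:
    """Write truth records as TSV (lists comma-joined, '.' when empty)."""
    with open(path, "w") as out:
        out.write("\t".join(_TRUTH_COLS) + "\n")
        for t in truths:
            out.write(
                "\t".join(
                    [
                        t.pair_id,
                        str(t.frag_start),
                        str(t.frag_end),
                        t.strand,
                        "1" if t.dovetail else "0",
                        t.frag_seq,
                        _fmt_list(t.r1_errors),
                        _fmt_list(t.r2_errors),
                        _fmt_list(t.shared_errors),
                        _fmt_list(t.r1_n),
                        _fmt_list(t.r2_n),
                    ]
                )
                + "\n"
            )


def read_truth(path) -> list[PairTruth]:
    out = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != _TRUTH_COLS:
            raise ValueError(f"{path}: unexpected truth-table header")
        for line in handle:
            f = line.rstrip("\n").split("\t")
            out.append(
                PairTruth(
                    pair_id=f[0],
                    frag_start=int(f[1]),
                    frag_end=int(f[2]),
                    strand=f[3],
                    dovetail=f[4] == "1",
                    frag_seq=f[5],
                    r1_errors=_parse_list(f[6]),
                    r2_errors=_parse_list(f[7]),
                    shared_errors=_parse_list(f[8]),
                    r1_n=_parse_list(f[9]),
                    r2_n=_parse_list(f[10]),
                )
            )
    return out
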