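"""Phred quality / error-probability conversions and merged-base quality models.

A Phred quality score encodes the probability that a called base is wrong:

    Q = -10 * log10(P(base wrong))        P = 10^(-Q/10)

so Q40 claims a 1-in-10,000 error chance and Q80 a 1-in-10^8 chance.

Three schemes for assigning a quality to a merged overlap base are provided:

* ``fastqjoin`` — matching bases take the higher of the two scores;
  disagreeing bases take the absolute difference. Simple and conservative.
* ``sum`` — matching bases take q1 + q2, the value implied by assuming the
  two reads' errors are independent; disagreeing bases take the higher
  score (no reduction), approximating PEAR's behaviour.
* ``matrix`` — table lookup in empirically trained match/mismatch matrices
  (see :mod:`pairstitch.profiles`), which capture the fact that paired-read
  errors are *not* independent: shared first-strand synthesis errors cap
  the achievable combined confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "qual_to_error",
    "error_to_qual",
    "QualityModel",
    "merged_quality",
    "load_matrix_file",
    "write_matrix_file",
    "read_matrix",
]


def qual_to_error(q):
    """Error probability implied by Phred score q: 10^(-q/10)."""
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr < 0):
        raise ValueError("quality score must be >= 0")
    out = 10.0 ** (-q_arr / 10.0)
    return float(out) if np.isscalar(q) or q_arr.ndim == 0 else out


def error_to_qual(p):
    """Phred score implied by error probability p: -10*log10(p)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr > 1):
        raise ValueError("probability must be in (0, 1]")
    out = -10.0 * np.log10(p_arr)
    return float(out) if np.isscalar(p) or p_arr.ndim == 0 else out


@dataclass
class QualityModel:
    """Rule mapping (q1, q2, match?) to a merged base quality.

    ``qual_max`` caps the output (None = uncapped); ``qual_floor`` is the
    minimum assigned to real (non-N) merged bases, applied by the merge
    layer rather than here so that raw scheme values remain inspectable.
    """

    kind: str
    qual_max: Optional[int] = None
    qual_floor: int = 2
    q1_labels: Optional[np.ndarray] = field(default=None, repr=False)
    q2_labels: Optional[np.ndarray] = field(default=None, repr=False)
    match_matrix: Optional[np.ndarray] = field(default=None, repr=False)
    mismatch_matrix: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("matrix", "fastqjoin", "sum"):
            raise ValueError(f"unknown quality model kind {self.kind!r}")
        if self.kind == "matrix":
            if self.match_matrix is None or self.mismatch_matrix is None:
                raise ValueError("matrix model requires both matrices")
            self.match_matrix = np.asarray(self.match_matrix, dtype=float)
            self.mismatch_matrix = np.asarray(self.mismatch_matrix, dtype=float)
            if self.q1_labels is None:
                self.q1_labels = np.arange(self.match_matrix.shape[0])
            if self.q2_labels is None:
                self.q2_labels = np.arange(self.match_matrix.shape[1])
            self.q1_labels = np.asarray(self.q1_labels, dtype=int)
            self.q2_labels = np.asarray(self.q2_labels, dtype=int)
            if self.match_matrix.shape != self.mismatch_matrix.shape:
                raise ValueError("match/mismatch matrices differ in shape")
            if self.match_matrix.shape != (
                len(self.q1_labels),
                len(self.q2_labels),
            ):
                raise ValueError("matrix shape does not match quality labels")

    @classmethod
    def fastqjoin(cls, qual_max: Optional[int] = 40) -> "QualityModel":
        return cls(kind="fastqjoin", qual_max=qual_max)

    @classmethod
    def sum(cls, qual_max: Optional[int] = 80) -> "QualityModel":
        return cls(kind="sum", qual_max=qual_max)

    @classmethod
    def matrix(
        cls,
        match_matrix,
        mismatch_matrix,
        q1_labels=None,
        q2_labels=None,
        qual_max: Optional[int] = 40,
    ) -> "QualityModel":
        return cls(
            kind="matrix",
            qual_max=qual_max,
            q1_labels=q1_labels,
            q2_labels=q2_labels,
            match_matrix=match_matrix,
            mismatch_matrix=mismatch_matrix,
        )

    def _lookup(self, q1: int, q2: int, is_match: bool) -> float:
        i = np.searchsorted(self.q1_labels, q1)
        j = np.searchsorted(self.q2_labels, q2)
        if (
            i >= len(self.q1_labels)
            or j >= len(self.q2_labels)
            or self.q1_labels[i] != q1
            or self.q2_labels[j] != q2
        ):
            raise KeyError(
                f"quality pair ({q1}, {q2}) outside trained matrix range"
            )
        table = self.match_matrix if is_match else self.mismatch_matrix
        return float(table[i, j])


def merged_quality(
    model: QualityModel, q1: int, q2: int, is_match: bool
) -> int:
    """Merged-base quality for a (q1, q2) overlap column under ``model``.

    Matching Q40 bases score 40 under ``fastqjoin`` and 80 under ``sum``.
    The result is capped at ``model.qual_max`` when that is set.
    """
    if q1 < 0 or q2 < 0:
        raise ValueError("quality scores must be >= 0")
    if model.kind == "fastqjoin":
        q = max(q1, q2) if is_match else abs(q1 - q2)
    elif model.kind == "sum":
        q = q1 + q2 if is_match else max(q1, q2)
    else:
        q = int(round(model._lookup(q1, q2, is_match)))
    if model.qual_max is not None:
        q = min(q, model.qual_max)
    return int(q)


# --- matrix file format -----------------------------------------------------
#
# '#' lines are comments; a comment line of the form "# table: match" (or
# mismatch) labels the block that follows. The first non-comment line is the
# tab-separated R2 quality header; each subsequent row is an R1 quality label
# followed by one value per R2 quality.


def _parse_block(
    lines: list[tuple[int, str]], path: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not lines:
        raise ValueError(f"{path}: empty matrix block")
    lineno, header = lines[0]
    try:
        q2 = np.array([int(x) for x in header.split("\t")])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-numeric header entry") from exc
    q1 = []
    rows = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(q2) + 1:
            raise ValueError(
                f"{path}:{lineno}: expected {len(q2) + 1} fields, got {len(fields)}"
            )
        try:
            q1.append(int(fields[0]))
            rows.append([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric cell") from exc
    if not rows:
        raise ValueError(f"{path}: matrix block has header but no rows")
    return np.array(q1), q2, np.array(rows)


def read_matrix(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parse a single-table matrix file -> (q1_labels, q2_labels, values)."""
    blocks = _read_blocks(path)
    if len(blocks) != 1:
        raise ValueError(f"{path}: expected a single matrix table")
    return _parse_block(next(iter(blocks.values())), str(path))


def _read_blocks(path) -> dict[str, list[tuple[int, str]]]:
    blocks: dict[str, list[tuple[int, str]]] = {}
    current = "table"
    with open(path) as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                label = line.lstrip("#").strip().lower()
                if label.startswith("table:"):
                    current = label.split(":", 1)[1].strip()
                continue
            blocks.setdefault(current, []).append((lineno, line))
    if not blocks:
        raise ValueError(f"{path}: no matrix data found")
    return blocks


def load_matrix_file(
    path, mismatch_path=None, qual_max: Optional[int] = 40
) -> QualityModel:
    """Load a matrix quality model.

    Either one file containing two labelled blocks ("# table: match" and
    "# table: mismatch"), or two single-table files (match, mismatch).
    """
    if mismatch_path is not None:
        q1m, q2m, match = read_matrix(path)
        q1x, q2x, mismatch = read_matrix(mismatch_path)
    else:
        blocks = _read_blocks(path)
        if set(blocks) != {"match", "mismatch"}:
            raise ValueError(
                f"{path}: expected 'match' and 'mismatch' blocks, "
                f"found {sorted(blocks)}"
            )
        q1m, q2m, match = _parse_block(blocks["match"], str(path))
        q1x, q2x, mismatch = _parse_block(blocks["mismatch"], str(path))
    if not (np.array_equal(q1m, q1x) and np.array_equal(q2m, q2x)):
        raise ValueError("match and mismatch tables cover different ranges")
    return QualityModel.matrix(
        match, mismatch, q1_labels=q1m, q2_labels=q2m, qual_max=qual_max
    )


def example_matrix_model(qual_max: Optional[int] = 40) -> QualityModel:
    """The packaged synthetic example profile (matrix kind).

    Trained on the package's own simulator output (see
    scripts/train_example_profile.py) — it demonstrates the matrix code
    path and file format, and reflects the simulator's shared-error
    conditions, not any real instrument's calibration.
    """
    from importlib import resources

    data = resources.files("pairstitch.data")
    with resources.as_file(data / "synthetic_match.tsv") as m, resources.as_file(
        data / "synthetic_mismatch.tsv"
    ) as x:
        return load_matrix_file(m, x, qual_max=qual_max)


def _write_block(out, label: str, q1, q2, values) -> None:
    out.write(f"# table: {label}\n")
    out.write("\t".join(str(int(q)) for q in q2) + "\n")
    for i, q in enumerate(q1):
        row = "\t".join(_fmt(v) for v in values[i])
        out.write(f"{int(q)}\t{row}\n")


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_matrix_file(model: QualityModel, path, mismatch_path=None) -> None:
    """Write a matrix model; round-trips exactly with load_matrix_file."""
    if model.kind != "matrix":
        raise ValueError("only matrix models can be written to file")
    if mismatch_path is None:
        with open(path, "w") as out:
            out.write("# pairstitch quality-score profile\n")
            _write_block(out, "match", model.q1_labels, model.q2_labels, model.match_matrix)
            _write_block(out, "mismatch", model.q1_labels, model.q2_labels, model.mismatch_matrix)
    else:
        with open(path, "w") as out:
            _write_block(out, "match", model.q1_labels, model.q2_labels, model.match_matrix)
        with open(mismatch_path, "w") as out:
            _write_block(out, "mismatch", model.q1_labels, model.q2_labels, model.mismatch_matrix)
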