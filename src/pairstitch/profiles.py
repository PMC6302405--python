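"""Training empirical merged-base quality profiles from truth-annotated reads.

The pipeline mirrors how merged-base quality tables are built from control
(PhiX-like) data:

1. tally every overlap column of every merged read by the two original
   reads' quality scores and by whether their bases agreed (match) or
   disagreed (mismatch), recording whether the merged base was correct
   against the known fragment sequence;
2. convert counts to error rates, giving zero-error cells a pseudo-error
   count of 0.5 (rate 0.5/count) and masking cells with fewer than 1000
   (match) / 100 (mismatch) observations;
3. fit a baseline profile — a local regression of log10(error rate) on
   quality score for the *original* reads — which converts observed error
   rates back into calibrated quality scores;
4. smooth each 2-D table of log10(rate) over (q1, q2) with a local linear
   (tricube-weighted) regression, map the smoothed rates through the
   baseline's inverse, and round to integer quality scores.

The match matrix is symmetrized (the two reads are physically
interchangeable); the mismatch matrix is not, since (q1, q2) encodes which
read supplied the surviving base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess

from .fastq import ReadPair
from .merge import MergeOutcome
from .quality import QualityModel
from .simulate import PairTruth

__all__ = [
    "ErrorTally3D",
    "BaselineProfile",
    "tally_from_truth",
    "tally_reads_by_quality",
    "rate_with_pseudocount",
    "filter_cells",
    "fit_baseline",
    "build_matrices",
    "train_from_pairs",
]

QMAX = 93
_CLS = {"match": 0, "mismatch": 1}


class ErrorTally3D:
    """Counts of correct/erroneous merged bases by (q1, q2, match/mismatch).

    ``counts[cls, q1, q2, outcome]`` with cls in {0: match, 1: mismatch} and
    outcome in {0: correct, 1: error}.
    """

    def __init__(self) -> None:
        self.counts = np.zeros((2, QMAX + 1, QMAX + 1, 2), dtype=np.int64)
        self.skipped = 0  # merged reads without usable truth

    def add(self, cls: str, q1: int, q2: int, error: bool) -> None:
        self.counts[_CLS[cls], q1, q2, 1 if error else 0] += 1

    def merge(self, other: "ErrorTally3D") -> "ErrorTally3D":
        out = ErrorTally3D()
        out.counts = self.counts + other.counts
        out.skipped = self.skipped + other.skipped
        return out

    def totals(self, cls: str) -> np.ndarray:
        return self.counts[_CLS[cls]].sum(axis=-1)

    def errors(self, cls: str) -> np.ndarray:
        return self.counts[_CLS[cls], :, :, 1]

    @property
    def total_columns(self) -> int:
        return int(self.counts.sum())


def tally_from_truth(
    merged: Iterable[tuple[MergeOutcome, PairTruth]],
    tally: Optional[ErrorTally3D] = None,
) -> ErrorTally3D:
    """Classify every overlap column of merged reads against fragment truth.

    A merged read whose length differs from its fragment's true length (the
    alignment did not recover the geometry) is skipped and counted in
    ``tally.skipped``. Columns involving an N in either read, or resolved to
    an N (equal-quality base conflicts), are excluded from both classes.
    """
    if tally is None:
        tally = ErrorTally3D()
    for outcome, truth in merged:
        if len(outcome.merged) != truth.frag_len:
            tally.skipped += 1
            continue
        frag = truth.frag_seq
        for ev in outcome.events:
            if ev.cls not in ("match", "mismatch") or ev.chosen_base == "N":
                continue
            tally.add(ev.cls, ev.r1_qual, ev.r2_qual, ev.chosen_base != frag[ev.position])
    if tally.skipped:
        warnings.warn(f"{tally.skipped} merged reads lacked usable truth; skipped")
    return tally


def tally_reads_by_quality(
    pairs: Iterable[tuple[ReadPair, PairTruth]], read_len: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-quality (bases, errors) over the original reads vs fragment truth.

    Only fragment-covered read positions are counted (adapter bases have no
    truth); N-masked bases are excluded. This is the input to
    :func:`fit_baseline` — the claimed-vs-observed quality relationship of
    unmerged reads.
    """
    bases = np.zeros(QMAX + 1, dtype=np.int64)
    errors = np.zeros(QMAX + 1, dtype=np.int64)
    for pair, truth in pairs:
        for rec, err_list, n_list in (
            (pair.r1, truth.r1_errors, truth.r1_n),
            (pair.r2, truth.r2_errors, truth.r2_n),
        ):
            rl = len(rec) if read_len is None else read_len
            cov = min(rl, truth.frag_len, len(rec))
            quals = rec.quals[:cov]
            keep = np.ones(cov, dtype=bool)
            for p in n_list:
                if p < cov:
                    keep[p] = False
            bases += np.bincount(quals[keep], minlength=QMAX + 1)
            epos = [p for p in err_list if p < cov and keep[p]]
            if epos:
                errors += np.bincount(quals[epos], minlength=QMAX + 1)
    return bases, errors


def rate_with_pseudocount(errors: int, total: int) -> float:
    """Observed error rate; zero-error cells get a pseudo-error count of 0.5."""
    if total <= 0:
        raise ValueError("rate undefined for zero observations")
    return errors / total if errors > 0 else 0.5 / total


def filter_cells(
    tally: ErrorTally3D, min_match: int = 1000, min_mismatch: int = 100
) -> tuple[np.ma.MaskedArray, np.ma.MaskedArray]:
    """Pseudocounted rate tables with low-count cells masked.

    Returns (match_rates, mismatch_rates) as masked arrays over the full
    quality grid; masked cells are left to the 2-D smoother to fill.
    """
    out = []
    for cls, thresh in (("match", min_match), ("mismatch", min_mismatch)):
        totals = tally.totals(cls)
        errs = tally.errors(cls)
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = np.where(errs > 0, errs / np.maximum(totals, 1), 0.5 / np.maximum(totals, 1))
        masked = np.ma.masked_array(rates, mask=totals < thresh)
        if masked.mask.all():
            warnings.warn(f"all {cls} cells below the count threshold {thresh}")
        out.append(masked)
    return out[0], out[1]


@dataclass
class BaselineProfile:
    """Smoothed, strictly monotone map between quality score and error rate.

    ``log_rates[i]`` is the fitted log10 error rate at ``qs[i]``; strictly
    decreasing, so the map is invertible. Outside the fitted range both
    directions extrapolate linearly with the terminal slope.
    """

    qs: np.ndarray
    log_rates: np.ndarray

    def __post_init__(self) -> None:
        self.qs = np.asarray(self.qs, dtype=float)
        self.log_rates = np.asarray(self.log_rates, dtype=float)
        if len(self.qs) != len(self.log_rates):
            raise ValueError("qs and log_rates differ in length")
        if np.any(np.diff(self.log_rates) >= 0):
            raise ValueError("baseline log rates must be strictly decreasing")

    def _slope(self, end: str) -> float:
        if end == "lo":
            return (self.log_rates[1] - self.log_rates[0]) / (self.qs[1] - self.qs[0])
        return (self.log_rates[-1] - self.log_rates[-2]) / (self.qs[-1] - self.qs[-2])

    def rate_at(self, q) -> np.ndarray | float:
        q = np.asarray(q, dtype=float)
        lr = np.interp(q, self.qs, self.log_rates)
        lo, hi = self.qs[0], self.qs[-1]
        lr = np.where(q < lo, self.log_rates[0] + self._slope("lo") * (q - lo), lr)
        lr = np.where(q > hi, self.log_rates[-1] + self._slope("hi") * (q - hi), lr)
        out = 10.0 ** lr
        return float(out) if out.ndim == 0 else out

    def qual_at(self, rate) -> np.ndarray | float:
        """Inverse map: observed error rate -> calibrated quality score."""
        lr = np.log10(np.asarray(rate, dtype=float))
        # log_rates decreasing: reverse for np.interp
        q = np.interp(lr, self.log_rates[::-1], self.qs[::-1])
        hi_lr, lo_lr = self.log_rates[0], self.log_rates[-1]
        q = np.where(lr > hi_lr, self.qs[0] + (lr - hi_lr) / self._slope("lo"), q)
        q = np.where(lr < lo_lr, self.qs[-1] + (lr - lo_lr) / self._slope("hi"), q)
        return float(q) if q.ndim == 0 else q


def fit_baseline(
    bases: np.ndarray,
    errors: np.ndarray,
    span: float = 0.3,
    min_count: int = 1000,
) -> BaselineProfile:
    """Local regression of log10(error rate) on quality score.

    Quality levels with at least ``min_count`` observed bases contribute one
    point each (pseudocounted rate). The smoothed curve is projected onto
    the strictly-decreasing cone (isotonic regression) so it stays
    invertible; a flat input therefore degenerates to a near-constant
    profile (with a warning).
    """
    qs = np.nonzero(bases >= max(1, min_count))[0]
    if len(qs) < 5:
        raise ValueError(
            f"only {len(qs)} quality levels with >= {min_count} bases; "
            "too few to fit a baseline — consider the theoretical relation "
            "rate = 10^(-q/10) instead"
        )
    y = np.array([np.log10(rate_with_pseudocount(int(errors[q]), int(bases[q]))) for q in qs])
    x = qs.astype(float)
    frac = min(1.0, max(span, 3.0 / len(x)))
    sm = lowess(y, x, frac=frac, it=1, return_sorted=True)
    xs, ys = sm[:, 0], sm[:, 1]
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    ys_mono = iso.fit_transform(xs, ys)
    if np.allclose(ys_mono.max(), ys_mono.min()):
        warnings.warn("baseline error rates show no quality dependence")
    # break ties so the map is strictly decreasing (hence invertible)
    ys_strict = ys_mono - np.arange(len(ys_mono)) * 1e-9
    return BaselineProfile(qs=xs, log_rates=ys_strict)


def _loess2d(
    points: np.ndarray, values: np.ndarray, targets: np.ndarray, span: float
) -> np.ndarray:
    """Local linear regression with tricube weights on the k-nearest points.

    ``points``: (n, 2) observed (q1, q2); ``values``: log10 rates;
    ``targets``: (m, 2) grid to predict on. k = span * n (minimum 8).
    """
    n = len(points)
    k = min(n, max(8, int(np.ceil(span * n))))
    preds = np.empty(len(targets))
    for t, (u, v) in enumerate(targets):
        d = np.hypot(points[:, 0] - u, points[:, 1] - v)
        idx = np.argpartition(d, k - 1)[:k]
        dk = d[idx]
        dmax = dk.max()
        if dmax == 0:
            preds[t] = values[idx].mean()
            continue
        w = (1.0 - (dk / dmax) ** 3) ** 3
        w = np.maximum(w, 1e-9)
        X = np.column_stack(
            [np.ones(k), points[idx, 0] - u, points[idx, 1] - v]
        )
        sw = np.sqrt(w)
        try:
            beta, *_ = np.linalg.lstsq(X * sw[:, None], values[idx] * sw, rcond=None)
            preds[t] = beta[0]
        except np.linalg.LinAlgError:
            preds[t] = np.average(values[idx], weights=w)
    return preds


def build_matrices(
    match_rates: np.ma.MaskedArray,
    mismatch_rates: np.ma.MaskedArray,
    baseline: BaselineProfile,
    qual_max: Optional[int] = 40,
    span: float = 0.3,
) -> QualityModel:
    """Smooth the rate tables and back-transform to quality matrices.

    Smoothed rates outside the baseline's invertible range follow its
    linear extension and are clamped to [2, qual_max]. The match matrix is
    symmetrized by averaging (q1,q2)/(q2,q1) before rounding.
    """
    cap = qual_max if qual_max is not None else QMAX
    label_cells = [np.nonzero(~t.mask) for t in (match_rates, mismatch_rates)]
    covered = np.concatenate([np.concatenate(c) for c in label_cells])
    if covered.size == 0:
        raise ValueError("no rate cells survive the count thresholds")
    lo, hi = int(covered.min()), int(covered.max())
    labels = np.arange(lo, hi + 1)
    grid = np.array([(a, b) for a in labels for b in labels], dtype=float)

    out = []
    for table in (match_rates, mismatch_rates):
        r, c = np.nonzero(~table.mask)
        if r.size == 0:
            raise ValueError("one rate table is fully masked")
        pts = np.column_stack([r, c]).astype(float)
        vals = np.log10(np.asarray(table[r, c]))
        if r.size == 1:
            smoothed = np.full(len(grid), vals[0])
        else:
            smoothed = _loess2d(pts, vals, grid, span)
        quals = baseline.qual_at(10.0 ** smoothed)
        quals = np.clip(quals, 2, cap)
        out.append(np.asarray(quals).reshape(len(labels), len(labels)))
    match_q = (out[0] + out[0].T) / 2.0
    return QualityModel.matrix(
        np.rint(match_q),
        np.rint(out[1]),
        q1_labels=labels,
        q2_labels=labels,
        qual_max=qual_max,
    )


def train_from_pairs(
    merged_with_truth: Iterable[tuple[MergeOutcome, PairTruth]],
    read_pairs_with_truth: Iterable[tuple[ReadPair, PairTruth]],
    qual_max: Optional[int] = 40,
    span: float = 0.3,
    min_match: int = 1000,
    min_mismatch: int = 100,
) -> tuple[QualityModel, BaselineProfile, ErrorTally3D]:
    """End-to-end training: tallies -> baseline -> smoothed matrices."""
    tally = tally_from_truth(merged_with_truth)
    bases, errors = tally_reads_by_quality(read_pairs_with_truth)
    baseline = fit_baseline(bases, errors, span=span)
    match_r, mismatch_r = filter_cells(tally, min_match, min_mismatch)
    model = build_matrices(match_r, mismatch_r, baseline, qual_max=qual_max, span=span)
    return model, baseline, tally
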