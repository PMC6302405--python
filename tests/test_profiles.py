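import warnings

import numpy as np
import pytest

from pairstitch.align import AlignParams, find_best_alignment
from pairstitch.merge import stitch
from pairstitch.profiles import (
    QMAX,
    BaselineProfile,
    ErrorTally3D,
    build_matrices,
    filter_cells,
    fit_baseline,
    rate_with_pseudocount,
    tally_from_truth,
    tally_reads_by_quality,
)
from pairstitch.quality import QualityModel, qual_to_error
from pairstitch.simulate import SimConfig, simulate


class TestPseudocount:
    @pytest.mark.parametrize(
        "errors,total,rate", [(0, 5000, 1e-4), (5, 1000, 0.005), (0, 1, 0.5)]
    )
    def test_examples(self, errors, total, rate):
        assert rate_with_pseudocount(errors, total) == pytest.approx(rate)

    def test_zero_total_undefined(self):
        with pytest.raises(ValueError):
            rate_with_pseudocount(0, 0)


class TestFilterCells:
    def _tally(self, cells):
        t = ErrorTally3D()
        for cls, q1, q2, correct, error in cells:
            t.counts[0 if cls == "match" else 1, q1, q2, 0] = correct
            t.counts[0 if cls == "match" else 1, q1, q2, 1] = error
        return t

    def test_count_thresholds(self):
        t = self._tally(
            [
                ("match", 30, 30, 999, 0),     # below 1000 -> masked
                ("match", 31, 31, 1000, 0),    # at threshold -> kept
                ("mismatch", 30, 30, 98, 1),   # total 99, below 100 -> masked
                ("mismatch", 31, 31, 99, 1),   # total 100 -> kept
            ]
        )
        match_r, mism_r = filter_cells(t)
        assert match_r.mask[30, 30] and not match_r.mask[31, 31]
        assert mism_r.mask[30, 30] and not mism_r.mask[31, 31]
        # kept zero-error cell uses the 0.5 pseudocount
        assert match_r[31, 31] == pytest.approx(0.5 / 1000)
        assert mism_r[31, 31] == pytest.approx(0.01)

    def test_fully_masked_warns(self):
        t = self._tally([("match", 30, 30, 10, 0)])
        with pytest.warns(UserWarning, match="below the count threshold"):
            filter_cells(t)


class TestTally:
    def _merged_with_truth(self, cfg, params=AlignParams()):
        model = QualityModel.fastqjoin()
        out = []
        for pair, truth in simulate(cfg):
            aln = find_best_alignment(pair, params)
            if aln is not None:
                out.append((stitch(pair, aln, model), truth))
        return out

    def test_error_free_run_has_no_match_errors(self, clean_pairs):
        model = QualityModel.fastqjoin()
        merged = []
        for pair, truth in clean_pairs[:150]:
            aln = find_best_alignment(pair, AlignParams(allow_dovetail=True))
            if aln:
                merged.append((stitch(pair, aln, model), truth))
        tally = tally_from_truth(merged)
        assert tally.counts[:, :, :, 1].sum() == 0
        assert tally.counts[0].sum() > 0

    def test_column_conservation(self):
        """Tallied columns == overlap columns minus N and ambiguous-tie
        columns."""
        cfg = SimConfig(n_pairs=150, seed=51, n_rate=0.01,
                        quality=("constant", 25))
        merged = self._merged_with_truth(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tally = tally_from_truth(merged)
        expected = sum(
            1
            for outcome, truth in merged
            if len(outcome.merged) == truth.frag_len
            for ev in outcome.events
            if ev.cls in ("match", "mismatch") and ev.chosen_base != "N"
        )
        assert tally.total_columns == expected

    def test_unusable_truth_skipped_with_warning(self, clean_pairs):
        model = QualityModel.fastqjoin()
        pair, truth = clean_pairs[0]
        aln = find_best_alignment(pair, AlignParams(allow_dovetail=True))
        outcome = stitch(pair, aln, model)
        import dataclasses

        bad = dataclasses.replace(truth, frag_end=truth.frag_end + 7)
        with pytest.warns(UserWarning, match="skipped"):
            tally = tally_from_truth([(outcome, bad)])
        assert tally.skipped == 1 and tally.total_columns == 0

    def test_read_tally_recovers_injected_rates(self):
        cfg = SimConfig(n_pairs=600, seed=52, quality=("constant", 30),
                        frag_mean=250.0, frag_sd=0.1, min_frag=250, max_frag=250)
        bases, errors = tally_reads_by_quality(simulate(cfg))
        assert bases[30] == 600 * 200
        p = 1e-3
        sd = np.sqrt(bases[30] * p)
        assert abs(errors[30] - bases[30] * p) < 3 * sd


class TestBaseline:
    def _phred_exact_counts(self, qs, n=10**7):
        bases = np.zeros(QMAX + 1, dtype=np.int64)
        errors = np.zeros(QMAX + 1, dtype=np.int64)
        for q in qs:
            bases[q] = n
            errors[q] = round(n * 10 ** (-q / 10))
        return bases, errors

    def test_self_consistency_on_phred_rates(self):
        """Rates generated exactly from the Phred relation fit the identity
        within 0.2 Q everywhere."""
        qs = list(range(5, 41))
        bases, errors = self._phred_exact_counts(qs)
        prof = fit_baseline(bases, errors)
        for q in qs:
            assert prof.qual_at(10 ** (-q / 10)) == pytest.approx(q, abs=0.2)
            assert prof.rate_at(q) == pytest.approx(10 ** (-q / 10), rel=0.05)

    def test_extrapolation_continues_terminal_slope(self):
        qs = list(range(10, 41))
        bases, errors = self._phred_exact_counts(qs)
        prof = fit_baseline(bases, errors)
        assert prof.qual_at(1e-6) == pytest.approx(60, abs=1.0)
        assert prof.qual_at(0.5) == pytest.approx(3.0, abs=1.0)

    def test_too_few_quality_levels(self):
        bases = np.zeros(QMAX + 1, dtype=np.int64)
        errors = np.zeros(QMAX + 1, dtype=np.int64)
        bases[30] = 10**6
        errors[30] = 1000
        with pytest.raises(ValueError, match="10\\^\\(-q/10\\)"):
            fit_baseline(bases, errors)

    def test_flat_rates_warn_and_degenerate(self):
        bases = np.zeros(QMAX + 1, dtype=np.int64)
        errors = np.zeros(QMAX + 1, dtype=np.int64)
        for q in range(10, 30):
            bases[q] = 10**6
            errors[q] = 1000
        with pytest.warns(UserWarning, match="no quality dependence"):
            prof = fit_baseline(bases, errors)
        assert prof.rate_at(10) == pytest.approx(1e-3, rel=0.01)
        assert prof.rate_at(29) == pytest.approx(1e-3, rel=0.01)

    def test_monotonicity_required(self):
        with pytest.raises(ValueError, match="decreasing"):
            BaselineProfile(qs=np.array([10.0, 20.0]), log_rates=np.array([-1.0, -1.0]))


class TestBuildMatrices:
    def _exact_baseline(self):
        qs = np.arange(2.0, 42.0)
        return BaselineProfile(qs=qs, log_rates=-qs / 10.0)

    def test_match_matrix_recovers_independence_prediction(self):
        """Agreeing-but-wrong columns occur at p1*p2/3 under independent
        errors, so the calibrated entry is q1+q2+10*log10(3)."""
        labels = np.arange(10, 26)
        rates = np.ma.masked_array(np.zeros((QMAX + 1, QMAX + 1)), mask=True)
        for a in labels:
            for b in labels:
                rates[a, b] = qual_to_error(a) * qual_to_error(b) / 3.0
        mism = rates.copy()
        model = build_matrices(rates, mism, self._exact_baseline(), qual_max=None)
        shift = 10 * np.log10(3)
        for a in (10, 15, 20, 25):
            for b in (10, 15, 20, 25):
                i = np.searchsorted(model.q1_labels, a)
                j = np.searchsorted(model.q2_labels, b)
                assert model.match_matrix[i, j] == pytest.approx(
                    a + b + shift, abs=2.0
                )

    def test_cap_applied(self):
        labels = np.arange(20, 31)
        rates = np.ma.masked_array(np.zeros((QMAX + 1, QMAX + 1)), mask=True)
        for a in labels:
            for b in labels:
                rates[a, b] = qual_to_error(a + b)
        model = build_matrices(rates, rates, self._exact_baseline(), qual_max=40)
        assert model.match_matrix.max() == 40
        assert model.match_matrix.min() >= 2

    def test_match_matrix_symmetric(self):
        rng = np.random.default_rng(8)
        rates = np.ma.masked_array(np.zeros((QMAX + 1, QMAX + 1)), mask=True)
        for a in range(15, 31):
            for b in range(15, 31):
                rates[a, b] = 10 ** (-(a + b) / 10 + rng.normal(0, 0.1))
        model = build_matrices(rates, rates, self._exact_baseline(), qual_max=None)
        assert np.array_equal(model.match_matrix, model.match_matrix.T)

    def test_fully_masked_rejected(self):
        empty = np.ma.masked_array(np.zeros((QMAX + 1, QMAX + 1)), mask=True)
        with pytest.raises(ValueError):
            build_matrices(empty, empty, self._exact_baseline())
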