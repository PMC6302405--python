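import numpy as np
import pytest
from scipy import stats

from pairstitch.fastq import reverse_complement
from pairstitch.simulate import (
    ADAPTER1,
    ADAPTER2,
    PairTruth,
    SimConfig,
    read_truth,
    simulate,
    truth_overlap_errors,
    write_truth,
)


class TestDeterminism:
    def test_same_seed_identical_output(self):
        cfg = SimConfig(n_pairs=50, seed=13, n_rate=0.01, shared_error_rate=0.001)
        a = list(simulate(cfg))
        b = list(simulate(cfg))
        for (pa, ta), (pb, tb) in zip(a, b):
            assert pa.r1 == pb.r1 and pa.r2 == pb.r2
            assert ta == tb

    def test_prefix_stable_when_n_pairs_grows(self):
        small = list(simulate(SimConfig(n_pairs=20, seed=13)))
        large = list(simulate(SimConfig(n_pairs=40, seed=13)))
        for (pa, _), (pb, _) in zip(small, large):
            assert pa.r1 == pb.r1 and pa.r2 == pb.r2

    def test_different_seeds_differ(self):
        a = next(iter(simulate(SimConfig(n_pairs=1, seed=1))))[0]
        b = next(iter(simulate(SimConfig(n_pairs=1, seed=2))))[0]
        assert a.r1.seq != b.r1.seq


class TestGeometry:
    def test_short_fragment_gets_adapter(self):
        cfg = SimConfig(n_pairs=30, seed=5, frag_mean=60.0, frag_sd=0.1,
                        min_frag=60, max_frag=60, quality=("constant", 41))
        for pair, truth in simulate(cfg):
            if truth.r1_errors or truth.r2_errors:
                continue
            assert truth.dovetail
            assert truth.frag_len == 60
            assert pair.r1.seq[:60] == truth.frag_seq
            assert pair.r1.seq[60:] == (ADAPTER1 + "A" * 40)[:40]
            assert pair.r2.seq[:60] == reverse_complement(truth.frag_seq)
            assert pair.r2.seq[60:] == (ADAPTER2 + "A" * 40)[:40]

    def test_long_fragment_reads_from_both_ends(self):
        cfg = SimConfig(n_pairs=20, seed=6, frag_mean=250.0, frag_sd=0.1,
                        min_frag=250, max_frag=250, quality=("constant", 41))
        for pair, truth in simulate(cfg):
            if truth.r1_errors or truth.r2_errors:
                continue
            assert not truth.dovetail
            assert pair.r1.seq == truth.frag_seq[:100]
            assert pair.r2.seq == reverse_complement(truth.frag_seq)[:100]

    def test_reference_too_short_rejected(self):
        with pytest.raises(ValueError, match="max_frag"):
            SimConfig(n_pairs=1, reference="ACGT" * 20, max_frag=400)


class TestErrorInjection:
    def test_constant_quality_rate_recovery(self):
        """Errors injected at the Phred-claimed rate: Q30 -> 1e-3."""
        cfg = SimConfig(n_pairs=1000, seed=21, quality=("constant", 30),
                        frag_mean=250.0, frag_sd=0.1, min_frag=250, max_frag=250)
        bases = errors = 0
        for _, truth in simulate(cfg):
            bases += 200
            errors += len(truth.r1_errors) + len(truth.r2_errors)
        p = 1e-3
        sd = np.sqrt(bases * p * (1 - p))
        assert abs(errors - bases * p) < 3 * sd

    def test_error_lists_match_sequences(self):
        cfg = SimConfig(n_pairs=40, seed=22, quality=("constant", 20))
        for pair, truth in simulate(cfg):
            L = truth.frag_len
            cov = min(100, L)
            for p in range(cov):
                expect_err = p in truth.r1_errors
                is_n = p in truth.r1_n
                actual = pair.r1.seq[p] != truth.frag_seq[p]
                if is_n:
                    assert pair.r1.seq[p] == "N"
                else:
                    assert actual == expect_err

    def test_n_masking(self):
        cfg = SimConfig(n_pairs=30, seed=23, n_rate=0.05)
        saw = 0
        for pair, truth in simulate(cfg):
            for p in truth.r1_n:
                assert pair.r1.seq[p] == "N"
                saw += 1
        assert saw > 0


class TestSharedErrors:
    def test_shared_error_signature(self):
        """A first-strand error puts the same wrong base in both reads."""
        cfg = SimConfig(n_pairs=300, seed=31, shared_error_rate=0.01,
                        quality=("constant", 41), frag_mean=150.0,
                        frag_sd=0.1, min_frag=150, max_frag=150)
        shared_cols = both_wrong_same = 0
        for pair, truth in simulate(cfg):
            rc2 = reverse_complement(pair.r2.seq)
            L = truth.frag_len
            for p, r1_ok, r2_ok, shared in truth_overlap_errors(truth, 100):
                if not shared:
                    continue
                shared_cols += 1
                b1 = pair.r1.seq[p]
                b2 = rc2[(100 - L) + p]  # rc2 column for fragment position p
                if not r1_ok and not r2_ok and b1 == b2 != truth.frag_seq[p]:
                    both_wrong_same += 1
        assert shared_cols > 100
        # independent errors on top may occasionally overwrite one copy
        assert both_wrong_same >= 0.95 * shared_cols

    def test_shared_rate_recovered(self):
        rho = 1e-2
        cfg = SimConfig(n_pairs=500, seed=32, shared_error_rate=rho,
                        quality=("constant", 41))
        frag_bases = shared = 0
        for _, truth in simulate(cfg):
            frag_bases += truth.frag_len
            shared += len(truth.shared_errors)
        sd = np.sqrt(frag_bases * rho * (1 - rho))
        assert abs(shared - frag_bases * rho) < 3 * sd

    def test_independence_without_shared_errors(self):
        """With rho=0, R1/R2 errors at the same fragment position are
        independent (chi-squared contingency test does not reject)."""
        cfg = SimConfig(n_pairs=2000, seed=33, quality=("constant", 25),
                        frag_mean=150.0, frag_sd=0.1, min_frag=150, max_frag=150)
        table = np.zeros((2, 2), dtype=int)
        for _, truth in simulate(cfg):
            for _, r1_ok, r2_ok, _ in truth_overlap_errors(truth, 100):
                table[int(not r1_ok), int(not r2_ok)] += 1
        assert table.sum() == 2000 * 50
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01


class TestTruthTable:
    def test_tsv_round_trip(self, tmp_path):
        cfg = SimConfig(n_pairs=25, seed=41, n_rate=0.02, shared_error_rate=0.005)
        truths = [t for _, t in simulate(cfg)]
        path = tmp_path / "truth.tsv"
        write_truth(truths, path)
        assert read_truth(path) == truths

    def test_error_free_run_all_columns_correct(self, clean_pairs):
        for _, truth in clean_pairs:
            for _, r1_ok, r2_ok, shared in truth_overlap_errors(truth, 100):
                assert r1_ok and r2_ok and not shared
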