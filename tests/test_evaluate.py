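import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arp300.datasets import (load_latency_table, load_participant_means,
                             load_run_accuracy_table)
from arp300.evaluate import (ITRParams, accuracy_table, auc_binary, crossval,
                             decode_trial, itr_bits_per_min, oneway_anova,
                             paired_ttest, summarize_accuracy_matrix,
                             wolpaw_bits)


class TestDecodeTrial:
    def test_argmax(self):
        assert decode_trial([0.1, .2, .3, .4, .5, .9, .4, .3, .2]) == 5

    def test_tie_lowest_index(self):
        assert decode_trial([0.5] * 9) == 0

    def test_count_checked(self):
        with pytest.raises(ValueError):
            decode_trial([0.1, 0.2], n_stimuli=9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            decode_trial([])


class TestWolpaw:
    def test_perfect_accuracy(self):
        assert wolpaw_bits(1.0, 9) == pytest.approx(math.log2(9), abs=1e-12)

    def test_chance_is_zero(self):
        assert wolpaw_bits(1 / 9, 9) == pytest.approx(0.0, abs=1e-12)

    def test_derived_value(self):
        assert wolpaw_bits(0.811, 9) == pytest.approx(1.9035501574782163, abs=1e-9)

    def test_p_zero_limit(self):
        assert wolpaw_bits(0.0, 9) == pytest.approx(math.log2(9 / 8), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            wolpaw_bits(1.2, 9)
        with pytest.raises(ValueError):
            wolpaw_bits(-0.1, 9)

    def test_strictly_increasing_above_chance(self):
        grid = np.linspace(1 / 9 + 1e-6, 1.0, 200)
        vals = [wolpaw_bits(p, 9) for p in grid]
        assert (np.diff(vals) > 0).all()


class TestITR:
    def test_perfect_9target_2s(self):
        assert itr_bits_per_min(1.0, 9, 2.0) == pytest.approx(30 * math.log2(9), rel=1e-12)
        assert itr_bits_per_min(1.0, 9, 2.0) == pytest.approx(95.098, abs=1e-3)

    def test_chance_zero_any_T(self):
        for T in (0.5, 2.0, 10.0):
            assert itr_bits_per_min(1 / 9, 9, T) == pytest.approx(0.0, abs=1e-12)

    def test_fixture_mean_itr(self):
        # per-participant ITR from the reference mean accuracies, averaged
        means = load_participant_means() / 100.0
        itrs = [itr_bits_per_min(p, 9, 2.0) for p in means]
        assert np.mean(itrs) == pytest.approx(57.90, rel=0.005)

    def test_bad_T_rejected(self):
        with pytest.raises(ValueError):
            itr_bits_per_min(0.5, 9, 0.0)


class TestAUC:
    def test_pair_counting_example(self):
        assert auc_binary([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auc_binary([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_ties_count_half(self):
        assert auc_binary([1.0, 1.0], [1, 0]) == pytest.approx(0.5)

    def test_matches_bruteforce_pair_counting(self, rng):
        scores = rng.standard_normal(60)
        labels = (rng.random(60) < 0.4).astype(int)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc_binary(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.standard_normal(200)
        labels = (rng.random(200) < 0.3).astype(int)
        assert auc_binary(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_null_distribution(self, rng):
        scores = rng.standard_normal(4000)
        labels = (rng.random(4000) < 0.5).astype(int)
        assert auc_binary(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_binary([1, 2], [1, 1])


class TestPairedTTest:
    def test_equal_arrays(self):
        t, p = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_closed_form(self):
        b = np.zeros(5)
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        t, p = paired_ttest(a, b)
        # mean 3, sd sqrt(2.5), SE sqrt(0.5) -> t = 3/sqrt(0.5)
        assert t == pytest.approx(3 / math.sqrt(0.5), rel=1e-12)
        assert p == pytest.approx(0.0132, abs=2e-4)

    def test_antisymmetric(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10)
        t1, p1 = paired_ttest(a, b)
        t2, p2 = paired_ttest(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_nonzero_diff_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0], [1.0, 2.0])

    def test_matches_scipy(self, rng):
        from scipy import stats

        a, b = rng.standard_normal((2, 15))
        t, p = paired_ttest(a, b)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestOnewayAnova:
    def test_df_structure_9x15(self, rng):
        groups = [rng.standard_normal(15) for _ in range(9)]
        F, dfb, dfw, p = oneway_anova(groups)
        assert (dfb, dfw) == (8, 126)

    def test_identical_constants_rejected(self):
        with pytest.raises(ValueError, match="zero within-group variance"):
            oneway_anova([np.ones(5), np.ones(5)])

    def test_null_F_near_one(self, rng):
        Fs = []
        for _ in range(300):
            groups = [rng.standard_normal(15) for _ in range(9)]
            Fs.append(oneway_anova(groups)[0])
        assert 0.7 <= np.mean(Fs) <= 1.4

    def test_matches_scipy(self, rng):
        from scipy import stats

        groups = [rng.standard_normal(10) + i * 0.3 for i in range(4)]
        F, dfb, dfw, p = oneway_anova(groups)
        ref = stats.f_oneway(*groups)
        assert F == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_degenerate_groups_rejected(self, rng):
        with pytest.raises(ValueError):
            oneway_anova([rng.standard_normal(5)])
        with pytest.raises(ValueError):
            oneway_anova([rng.standard_normal(5), np.array([1.0])])


class TestAccuracyFixtures:
    """Arithmetic on the bundled per-run reference accuracy table."""

    def test_p1_mean_from_runs(self):
        table = load_run_accuracy_table()
        means, _ = summarize_accuracy_matrix(table)
        assert means.loc["P1"] == pytest.approx(90.44, abs=0.005)

    def test_grand_mean_of_reference_means(self):
        grand = float(load_participant_means().mean())
        assert grand == pytest.approx(81.10, abs=0.005)

    def test_table_shape(self):
        table = load_run_accuracy_table()
        assert table.shape == (15, 10)
        assert ((0 <= table) & (table <= 100)).all().all()

    def test_latency_fixture_means(self):
        lat = load_latency_table()
        assert lat["cs_ms"].mean() == pytest.approx(434.53, abs=0.005)
        assert lat["ar_ms"].mean() == pytest.approx(482.47, abs=0.005)

    def test_accuracy_table_from_decisions(self):
        meta = pd.DataFrame({
            "participant": ["P1"] * 4 + ["P2"] * 4,
            "run": [0, 0, 1, 1] * 2,
        })
        decoded = np.array([0, 1, 2, 3, 0, 0, 0, 0])
        truth = np.array([0, 1, 0, 3, 1, 1, 1, 1])
        m = accuracy_table(decoded, truth, meta)
        assert m.loc["P1", 0] == 100.0
        assert m.loc["P1", 1] == 50.0
        assert m.loc["P2", 0] == 0.0

    def test_misaligned_meta_rejected(self):
        with pytest.raises(ValueError):
            accuracy_table([0], [0, 1], pd.DataFrame({"participant": ["a"], "run": [0]}))


class _OracleScorer:
    """Reads the label — decodes perfectly by construction."""

    def fit(self, epochs):
        return self

    def score(self, epochs):
        return epochs.labels.astype(float)


class _ConstantScorer:
    def fit(self, epochs):
        return self

    def score(self, epochs):
        return np.zeros(epochs.n_epochs)


class TestCrossval:
    def test_oracle_scorer_perfect(self, highsnr_epochs, small_schedule):
        rep = crossval(highsnr_epochs, _OracleScorer, small_schedule.target_of_block,
                       folds=5, seed=0)
        assert rep.mean_accuracy == 100.0
        assert rep.n_trials == 90
        assert rep.itr_bits_per_min == pytest.approx(30 * math.log2(9))
        assert set(rep.per_run_accuracy) == {0, 1}
        assert all(v == 100.0 for v in rep.per_run_accuracy.values())

    def test_constant_scorer_decodes_stimulus_zero(self, highsnr_epochs, small_schedule):
        rep = crossval(highsnr_epochs, _ConstantScorer, small_schedule.target_of_block,
                       folds=5, seed=0)
        # ties -> stimulus 0; only block 0 is decoded correctly
        assert rep.mean_accuracy == pytest.approx(100.0 / 9)

    def test_deterministic_given_seed(self, highsnr_epochs, small_schedule):
        a = crossval(highsnr_epochs, _OracleScorer, small_schedule.target_of_block,
                     folds=5, seed=3)
        b = crossval(highsnr_epochs, _OracleScorer, small_schedule.target_of_block,
                     folds=5, seed=3)
        assert a.to_dict() == b.to_dict()

    def test_trials_never_straddle_folds(self, highsnr_epochs, small_schedule):
        seen = {}

        class Spy(_OracleScorer):
            def score(self, epochs):
                for r, b, t in zip(epochs.meta["run"], epochs.meta["block"],
                                   epochs.meta["trial"]):
                    seen.setdefault((int(r), int(b), int(t)), 0)
                    seen[(int(r), int(b), int(t))] += 1
                return epochs.labels.astype(float)

        crossval(highsnr_epochs, Spy, small_schedule.target_of_block, folds=5, seed=0)
        # every trial scored exactly once as a full 9-epoch group
        assert all(v == 9 for v in seen.values())
        assert len(seen) == 90

    def test_too_many_folds_rejected(self, highsnr_epochs, small_schedule):
        with pytest.raises(ValueError, match="folds"):
            crossval(highsnr_epochs, _OracleScorer, small_schedule.target_of_block,
                     folds=91, seed=0)

    def test_folds_below_2_rejected(self, highsnr_epochs, small_schedule):
        with pytest.raises(ValueError):
            crossval(highsnr_epochs, _OracleScorer, small_schedule.target_of_block,
                     folds=1, seed=0)


@given(p=st.floats(0.0, 1.0), n=st.integers(2, 40))
@settings(max_examples=60, deadline=None)
def test_wolpaw_bounded(p, n):
    bits = wolpaw_bits(p, n)
    assert -1e-12 <= bits <= math.log2(n) + 1e-12
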