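import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from m6afgk import (
    ConfusionCounts,
    MiningConfig,
    TrainConfig,
    auroc,
    confusion,
    cross_validate,
    metrics,
    roc,
)
from m6afgk.errors import (
    DegenerateRocError,
    LabelError,
    M6afgkError,
    StratificationError,
)
from m6afgk.evaluation import stratified_folds
from m6afgk.sequence_data import SampleRecord


def pair_count_auroc(y, s):
    """Independent oracle: Mann-Whitney by exhaustive pair enumeration."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_mixed_example(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.TP, c.FN, c.TN, c.FP) == (1, 1, 1, 1)

    def test_perfect_and_inverted(self):
        y = [1, 0, 1, 0]
        c = confusion(y, y)
        assert c.FP == c.FN == 0
        c = confusion(y, [1 - v for v in y])
        assert c.TP == c.TN == 0

    def test_length_mismatch(self):
        with pytest.raises(M6afgkError):
            confusion([1, 0], [1])

    def test_non_binary(self):
        with pytest.raises(LabelError):
            confusion([1, 2], [1, 0])


class TestMetrics:
    def test_ninety_percent_example(self):
        m = metrics(ConfusionCounts(TP=90, TN=90, FP=10, FN=10))
        assert m == pytest.approx({"SN": 0.9, "SP": 0.9, "ACC": 0.9, "MCC": 0.8})

    def test_perfect_classifier_maxima(self):
        m = metrics(ConfusionCounts(TP=5, TN=5, FP=0, FN=0))
        assert m == {"SN": 1.0, "SP": 1.0, "ACC": 1.0, "MCC": 1.0}

    def test_perfect_inversion_mcc(self):
        m = metrics(ConfusionCounts(TP=0, TN=0, FP=7, FN=7))
        assert m["MCC"] == -1.0

    def test_zero_denominator_mcc_is_zero(self):
        m = metrics(ConfusionCounts(TP=3, TN=0, FP=0, FN=1))
        assert m["MCC"] == 0.0

    def test_undefined_sn_is_nan(self):
        m = metrics(ConfusionCounts(TP=0, TN=4, FP=1, FN=0))
        assert np.isnan(m["SN"])

    def test_empty_counts_rejected(self):
        with pytest.raises(M6afgkError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_balanced_acc_is_mean_of_sn_sp(self):
        m = metrics(ConfusionCounts(TP=80, FN=20, TN=60, FP=40))
        assert m["ACC"] == pytest.approx((m["SN"] + m["SP"]) / 2)


class TestRoc:
    def test_perfect_separation(self):
        assert roc([1, 0], [1.0, 0.0]) == [(0, 0), (0, 1), (1, 1)]

    def test_all_scores_tied(self):
        assert roc([1, 0], [0.5, 0.5]) == [(0, 0), (1, 1)]

    def test_four_point_example(self):
        pts = roc([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.1])
        assert pts[0] == (0, 0) and pts[-1] == (1, 1)
        xs = [p[0] for p in pts]
        assert xs == sorted(xs)
        assert auroc([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateRocError):
            roc([1, 1], [0.5, 0.6])
        with pytest.raises(DegenerateRocError):
            auroc([0, 0], [0.5, 0.6])

    def test_perfect_and_inverted_auroc(self):
        assert auroc([1, 1, 0], [0.9, 0.8, 0.1]) == 1.0
        assert auroc([1, 1, 0], [0.1, 0.2, 0.9]) == 0.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(n=st.integers(4, 40), seed=st.integers(0, 10 ** 6),
       quantize=st.booleans())
def test_auroc_equals_pair_counting(n, seed, quantize):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    y[:2] = [0, 1]
    s = rng.random(n)
    if quantize:  # force ties
        s = np.round(s, 1)
    assert auroc(y, s) == pytest.approx(pair_count_auroc(y, s), abs=1e-12)


def test_auroc_matches_sklearn(rng):
    sk = pytest.importorskip("sklearn.metrics")
    y = rng.integers(0, 2, size=200)
    y[:2] = [0, 1]
    s = np.round(rng.random(200), 2)
    assert auroc(y, s) == pytest.approx(sk.roc_auc_score(y, s), abs=1e-12)


def _toy_records():
    return [SampleRecord("p1", "GACGA", 1), SampleRecord("p2", "CGAGC", 1),
            SampleRecord("n1", "UUAUU", 0), SampleRecord("n2", "AUAAU", 0)]


class TestStratifiedFolds:
    def test_two_folds_balanced(self):
        folds = stratified_folds(_toy_records(), folds=2, seed=0)
        recs = _toy_records()
        for test_idx in folds:
            labels = [recs[i].label for i in test_idx]
            assert sorted(labels) == [0, 1]

    def test_class_smaller_than_folds_rejected(self):
        with pytest.raises(StratificationError):
            stratified_folds(_toy_records(), folds=3, seed=0)

    def test_partition_is_exact(self, small_corpus):
        folds = stratified_folds(small_corpus, folds=10, seed=4)
        flat = sorted(i for f in folds for i in f)
        assert flat == list(range(len(small_corpus)))

    def test_order_invariance(self, small_corpus, rng):
        perm = rng.permutation(len(small_corpus))
        shuffled = [small_corpus[i] for i in perm]
        a = stratified_folds(small_corpus, folds=5, seed=9)
        b = stratified_folds(shuffled, folds=5, seed=9)
        ids_a = [sorted(small_corpus[i].id for i in f) for f in a]
        ids_b = [sorted(shuffled[i].id for i in f) for f in b]
        assert ids_a == ids_b


MINI_MINING = MiningConfig(k=2, gamma=0.1, max_span=4)


class TestCrossValidate:
    def test_report_shape_and_counts(self, small_corpus):
        rep = cross_validate(small_corpus, MINI_MINING, folds=5, seed=1)
        assert len(rep.folds) == 5
        assert rep.pooled_counts.total == len(small_corpus)
        for f in rep.folds:
            assert f.counts.total == len(small_corpus) // 5
        assert 0.0 <= rep.pooled_auroc <= 1.0
        assert set(rep.pooled_metrics) == {"SN", "SP", "ACC", "MCC"}

    def test_seed_reproducibility(self, small_corpus):
        a = cross_validate(small_corpus, MINI_MINING, folds=5, seed=3)
        b = cross_validate(small_corpus, MINI_MINING, folds=5, seed=3)
        assert a.pooled_metrics == b.pooled_metrics
        assert a.pooled_auroc == b.pooled_auroc
        assert [f.test_ids for f in a.folds] == [f.test_ids for f in b.folds]

    def test_record_order_invariance(self, small_corpus, rng):
        perm = rng.permutation(len(small_corpus))
        shuffled = [small_corpus[i] for i in perm]
        a = cross_validate(small_corpus, MINI_MINING, folds=5, seed=3)
        b = cross_validate(shuffled, MINI_MINING, folds=5, seed=3)
        assert a.pooled_metrics == b.pooled_metrics
        assert a.pooled_auroc == b.pooled_auroc

    def test_report_files(self, small_corpus, tmp_path):
        rep = cross_validate(small_corpus, MINI_MINING, folds=5, seed=1)
        rep.to_json(tmp_path / "r.json")
        rep.to_tsv(tmp_path / "r.tsv")
        rep.write_roc_tsv(tmp_path / "roc.tsv")
        lines = (tmp_path / "r.tsv").read_text().splitlines()
        assert len(lines) == 1 + 5 + 2  # header + folds + pooled + fold_mean
        assert lines[-2].startswith("pooled\t")
        assert lines[-1].startswith("fold_mean\t")
        import json
        payload = json.loads((tmp_path / "r.json").read_text())
        assert payload["seed"] == 1
        assert len(payload["folds"]) == 5
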