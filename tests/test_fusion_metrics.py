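"""Score fusion (sum rule, view averaging, softmax) and the confusion
metrics, each checked against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bandfuse.fusion import (EnsembleMember, EnsembleSpec, ScoreMatrix,
                             average_views, fuse, softmax_rows)
from bandfuse.metrics import ConfusionCounts, confusion, metrics

rng = np.random.default_rng(0)


def _sm(scores, ids=None, normalized=False):
    scores = np.asarray(scores, dtype=float)
    ids = ids or [f"p{i}" for i in range(scores.shape[0])]
    return ScoreMatrix(scores=scores, pattern_ids=ids, normalized=normalized)


class TestSoftmaxRows:
    def test_symmetric_row(self):
        out = softmax_rows(_sm([[0.0, 0.0]]))
        np.testing.assert_allclose(out.scores, [[0.5, 0.5]])

    def test_extreme_logits_stable(self):
        out = softmax_rows(_sm([[1000.0, 0.0]]))
        assert np.isfinite(out.scores).all()
        np.testing.assert_allclose(out.scores, [[1.0, 0.0]], atol=1e-12)

    def test_argmax_preserved(self):
        scores = rng.normal(size=(1000, 6)) * 10
        out = softmax_rows(_sm(scores))
        np.testing.assert_array_equal(out.scores.argmax(axis=1),
                                      scores.argmax(axis=1))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            softmax_rows(_sm([[np.inf, 0.0]]))


class TestAverageViews:
    def test_idempotent_on_identical_views(self):
        row = rng.random(5)
        sm = _sm(np.tile(row, (16, 1)), ids=["p"] * 16)
        out = average_views(sm)
        assert out.scores.shape == (1, 5)
        np.testing.assert_allclose(out.scores[0], row)

    def test_two_view_mean(self):
        out = average_views(_sm([[1.0, 0.0], [0.0, 1.0]], ids=["p", "p"]))
        np.testing.assert_allclose(out.scores, [[0.5, 0.5]])

    def test_matches_brute_force_groups(self):
        ids = [f"p{i}" for i in range(20) for _ in range(16)]
        scores = rng.random((320, 7))
        out = average_views(_sm(scores, ids=ids))
        assert out.pattern_ids == [f"p{i}" for i in range(20)]
        for i in range(20):
            np.testing.assert_allclose(out.scores[i],
                                       scores[16 * i:16 * (i + 1)].mean(axis=0))


class TestFuse:
    def test_single_member_reduction(self):
        sm = _sm(rng.normal(size=(30, 5)))
        preds, fused = fuse(EnsembleSpec(members=[EnsembleMember("a")]), [sm])
        np.testing.assert_array_equal(preds, sm.scores.argmax(axis=1))

    def test_weight_three_equals_triple_summing(self):
        a, b = _sm(rng.normal(size=(10, 4))), _sm(rng.normal(size=(10, 4)))
        weighted = fuse(EnsembleSpec(members=[EnsembleMember("a", weight=3.0),
                                              EnsembleMember("b")]), [a, b])[1]
        tripled = fuse(EnsembleSpec(members=[EnsembleMember("a1"),
                                             EnsembleMember("a2"),
                                             EnsembleMember("a3"),
                                             EnsembleMember("b")]),
                       [a, a, a, b])[1]
        np.testing.assert_allclose(weighted.scores, tripled.scores)

    def test_five_members_match_elementwise_oracle(self):
        mats = [_sm(rng.normal(size=(50, 8))) for _ in range(5)]
        weights = [1.0, 2.0, 0.5, 1.0, 3.0]
        spec = EnsembleSpec(members=[EnsembleMember(f"m{i}", weight=w)
                                     for i, w in enumerate(weights)])
        preds, fused = fuse(spec, mats)
        # oracle: per-pattern loop over the softmaxed score vectors
        for p in range(50):
            total = np.zeros(8)
            for w, m in zip(weights, mats):
                z = np.exp(m.scores[p] - m.scores[p].max())
                total += w * z / z.sum()
            assert preds[p] == total.argmax()
            np.testing.assert_allclose(fused.scores[p], total, atol=1e-9)

    def test_equal_weight_permutation_invariance(self):
        mats = [_sm(rng.normal(size=(20, 5))) for _ in range(4)]
        spec = EnsembleSpec(members=[EnsembleMember(f"m{i}") for i in range(4)])
        a = fuse(spec, mats)[1].scores
        b = fuse(spec, mats[::-1])[1].scores
        np.testing.assert_allclose(a, b)

    @given(st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_weight_scaling_leaves_predictions(self, scale):
        mats = [_sm(np.random.default_rng(9).normal(size=(20, 5)))
                for _ in range(3)]
        base = EnsembleSpec(members=[EnsembleMember(f"m{i}") for i in range(3)])
        scaled = EnsembleSpec(members=[EnsembleMember(f"m{i}", weight=scale)
                                       for i in range(3)])
        np.testing.assert_array_equal(fuse(base, mats)[0],
                                      fuse(scaled, mats)[0])

    def test_shape_mismatch_names_member(self):
        good, bad = _sm(rng.normal(size=(5, 3))), _sm(rng.normal(size=(5, 4)))
        spec = EnsembleSpec(members=[EnsembleMember("ok"),
                                     EnsembleMember("broken")])
        with pytest.raises(ValueError, match="broken"):
            fuse(spec, [good, bad])


class TestMetrics:
    def test_perfect_predictions(self):
        labels = np.array([0, 1, 2, 0, 1, 2])
        rep = metrics(confusion(labels, labels, 3))
        assert rep["accuracy"] == 1.0
        assert rep["macro_f1"] == 1.0
        assert rep["macro_precision"] == 1.0

    def test_direct_formula_case(self):
        cc = ConfusionCounts(tp=np.array([8]), fp=np.array([2]),
                             tn=np.array([88]), fn=np.array([2]))
        rep = metrics(cc)
        assert rep["per_class"]["precision"][0] == pytest.approx(0.8)
        assert rep["per_class"]["recall"][0] == pytest.approx(0.8)
        assert rep["per_class"]["f1"][0] == pytest.approx(0.8)

    def test_matches_double_loop_oracle(self):
        for trial in range(500):
            r = np.random.default_rng(trial)
            n_classes = int(r.integers(2, 6))
            n = int(r.integers(5, 40))
            preds = r.integers(0, n_classes, size=n)
            labels = r.integers(0, n_classes, size=n)
            cc = confusion(preds, labels, n_classes)
            for c in range(n_classes):
                tp = fp = tn = fn = 0
                for p, y in zip(preds, labels):
                    if p == c and y == c:
                        tp += 1
                    elif p == c:
                        fp += 1
                    elif y == c:
                        fn += 1
                    else:
                        tn += 1
                assert (cc.tp[c], cc.fp[c], cc.tn[c], cc.fn[c]) == (tp, fp, tn, fn)

    def test_zero_denominator_policy(self):
        # class 1 never predicted and never present -> precision/recall 0
        preds = np.array([0, 0, 0])
        labels = np.array([0, 0, 0])
        with pytest.warns(UserWarning, match="zero denominator"):
            rep = metrics(confusion(preds, labels, 2))
        assert rep["per_class"]["precision"][1] == 0.0
        assert rep["per_class"]["f1"][1] == 0.0

    def test_counts_sum_to_total(self):
        preds = rng.integers(0, 4, size=100)
        labels = rng.integers(0, 4, size=100)
        cc = confusion(preds, labels, 4)
        assert ((cc.tp + cc.fp + cc.tn + cc.fn) == 100).all()
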