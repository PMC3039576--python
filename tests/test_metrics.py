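import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gotlm.metrics import (
    ConfusionMatrix,
    class_quantities,
    confusion_matrix,
    multiclass_mcc,
    overall_se,
    per_class_metrics,
    write_report,
)

from oracles import (
    oracle_aggregate_mcc,
    oracle_binary_mcc,
    oracle_overall_se,
    oracle_quantities,
)


def random_matrix(rng, L=None):
    L = L or int(rng.integers(2, 7))
    return ConfusionMatrix(
        rng.integers(0, 51, size=(L, L)), tuple(f"c{i}" for i in range(L))
    )


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        y = ["a"] * 6 + ["b"] * 4
        M = confusion_matrix(y, y, ["a", "b"])
        np.testing.assert_array_equal(M.counts, [[6, 0], [0, 4]])

    def test_direct_count(self):
        M = confusion_matrix(["a", "a", "b"], ["a", "b", "b"], ["a", "b"])
        np.testing.assert_array_equal(M.counts, [[1, 1], [0, 1]])

    def test_pair_order_invariance(self, rng):
        y_true = list(rng.choice(["a", "b", "c"], size=30))
        y_pred = list(rng.choice(["a", "b", "c"], size=30))
        perm = rng.permutation(30)
        M1 = confusion_matrix(y_true, y_pred, ["a", "b", "c"])
        M2 = confusion_matrix(
            [y_true[i] for i in perm], [y_pred[i] for i in perm], ["a", "b", "c"]
        )
        np.testing.assert_array_equal(M1.counts, M2.counts)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_matrix(["a"], ["z"], ["a", "b"])


class TestClassQuantities:
    def test_hand_counted_example(self):
        M = ConfusionMatrix(np.array([[1, 1], [0, 1]]), ("a", "b"))
        cq = class_quantities(M, 0)
        assert (cq.p, cq.q, cq.r, cq.s) == (1, 1, 0, 1)

    def test_identity_matrix_no_errors(self):
        M = ConfusionMatrix(np.diag([3, 4, 5]), ("a", "b", "c"))
        for l in range(3):
            cq = class_quantities(M, l)
            assert cq.r == 0 and cq.s == 0

    def test_row_and_column_identities_on_random_matrices(self, rng):
        for _ in range(100):
            M = random_matrix(rng, L=4)
            for l in range(4):
                cq = class_quantities(M, l)
                assert cq.p + cq.s == M.counts[l, :].sum()
                assert cq.p + cq.r == M.counts[:, l].sum()
                assert cq.p + cq.q + cq.r + cq.s == M.counts.sum()


class TestOverallSe:
    def test_identity_is_perfect(self):
        M = ConfusionMatrix(np.diag([2, 3]), ("a", "b"))
        assert overall_se(M) == 1.0

    def test_hand_example(self):
        M = ConfusionMatrix(np.array([[1, 1], [0, 1]]), ("a", "b"))
        assert overall_se(M) == pytest.approx(2 / 3)

    def test_empty_matrix_rejected(self):
        M = ConfusionMatrix(np.zeros((2, 2), dtype=int), ("a", "b"))
        with pytest.raises(ValueError, match="empty"):
            overall_se(M)


class TestMulticlassMcc:
    def test_identity_is_one(self):
        M = ConfusionMatrix(np.diag([2, 3, 4]), ("a", "b", "c"))
        assert multiclass_mcc(M) == pytest.approx(1.0)

    def test_single_column_prediction_is_zero(self):
        M = ConfusionMatrix(np.array([[5, 0], [5, 0]]), ("a", "b"))
        assert multiclass_mcc(M) == 0.0

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(200):
            M = random_matrix(rng)
            if M.total == 0:
                continue
            assert multiclass_mcc(M) == pytest.approx(
                oracle_aggregate_mcc(M.counts.tolist()), abs=1e-12
            )


class TestPerClassMetrics:
    def test_perfect_class(self):
        M = ConfusionMatrix(np.diag([3, 4]), ("a", "b"))
        row = per_class_metrics(M).iloc[0]
        assert (row.SP, row.SE, row.MCC) == (1.0, 1.0, 1.0)

    def test_never_predicted_class_flagged(self):
        M = ConfusionMatrix(np.array([[0, 2], [0, 3]]), ("a", "b"))
        row = per_class_metrics(M).iloc[0]
        assert row.SP == 0.0 and "SP" in row.undefined

    def test_binary_reduction_matches_textbook_mcc(self, rng):
        for _ in range(50):
            M = random_matrix(rng, L=2)
            if M.total == 0:
                continue
            cq = class_quantities(M, 0)
            expected = oracle_binary_mcc(tp=cq.p, tn=cq.q, fp=cq.r, fn=cq.s)
            assert per_class_metrics(M).iloc[0].MCC == pytest.approx(
                expected, abs=1e-12
            )


@given(st.integers(0, 2**31 - 1), st.integers(1, 7))
def test_scale_invariance_and_permutation_invariance(seed, scale):
    """Scaling all counts, or relabelling classes consistently, changes nothing."""
    rng = np.random.default_rng(seed)
    L = int(rng.integers(2, 6))
    counts = rng.integers(0, 20, size=(L, L))
    if counts.sum() == 0:
        counts[0, 0] = 1
    classes = tuple(f"c{i}" for i in range(L))
    M = ConfusionMatrix(counts, classes)
    scaled = ConfusionMatrix(counts * scale, classes)
    assert overall_se(scaled) == pytest.approx(overall_se(M), abs=1e-12)
    assert multiclass_mcc(scaled) == pytest.approx(multiclass_mcc(M), abs=1e-12)
    perm = rng.permutation(L)
    permuted = ConfusionMatrix(
        counts[np.ix_(perm, perm)], tuple(classes[i] for i in perm)
    )
    assert multiclass_mcc(permuted) == pytest.approx(multiclass_mcc(M), abs=1e-12)
    base = per_class_metrics(M).set_index("location")
    moved = per_class_metrics(permuted).set_index("location")
    for cls in classes:
        for col in ("SP", "SE", "MCC"):
            assert moved.loc[cls, col] == pytest.approx(base.loc[cls, col], abs=1e-12)


def test_report_writer_layout(tmp_path):
    M = confusion_matrix(["a", "a", "b"], ["a", "b", "b"], ["a", "b"])
    out = tmp_path / "report.tsv"
    write_report(M, out)
    text = out.read_text()
    assert text.startswith("location\t")
    assert "# overall_accuracy\t0.6667" in text
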