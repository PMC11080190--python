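"""Metric implementations against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from toothset.evaluation import (
    cohen_kappa,
    confusion,
    evaluate_probabilities,
    export_embeddings,
    feature_heatmaps,
    fleiss_kappa,
    fleiss_kappa_table,
    rank_of_true,
    regroup_probabilities,
    roc_auc,
    sensitivity_specificity,
    topk_accuracy,
)
from toothset.synthetic import default_rater_panel, simulate_annotators
from toothset.taxonomy import FINE_CLASSES


# ---------------------------------------------------------------------------
# top-k


def brute_force_topk(probs, true_idx, k):
    """Oracle: sort each row, check the true class is among the k largest
    (ties resolved in the truth's favor, mirroring the rank definition)."""
    hits = 0
    for row, t in zip(probs, true_idx):
        better = sum(1 for p in row if p > row[t])
        hits += better < k
    return hits / len(probs)


def test_topk_fixed_example():
    probs = np.array([[0.5, 0.3, 0.2], [0.2, 0.5, 0.3], [0.1, 0.2, 0.7]])
    classes = ["c1", "c2", "c3"]
    labels = ["c1", "c3", "c3"]
    assert topk_accuracy(probs, labels, classes, 1) == pytest.approx(2 / 3)
    assert topk_accuracy(probs, labels, classes, 2) == 1.0


def test_topk_against_brute_force_and_monotone_in_k():
    rng = np.random.default_rng(0)
    classes = [f"c{i}" for i in range(8)]
    for _ in range(50):
        n = rng.integers(2, 30)
        probs = rng.dirichlet(np.ones(8), size=n)
        true_idx = rng.integers(0, 8, size=n)
        labels = [classes[i] for i in true_idx]
        prev = 0.0
        for k in range(1, 9):
            got = topk_accuracy(probs, labels, classes, k)
            assert got == pytest.approx(brute_force_topk(probs, true_idx, k))
            assert got >= prev
            prev = got
        assert prev == 1.0  # k = C always hits


def test_topk_perfect_and_boundary_cases():
    probs = np.eye(4)
    classes = list("abcd")
    assert topk_accuracy(probs, list("abcd"), classes, 1) == 1.0
    with pytest.raises(ValueError):
        topk_accuracy(probs, list("abcd"), classes, 5)
    with pytest.raises(ValueError):
        topk_accuracy(probs, list("abce"), classes, 1)


def test_rank_ties_resolve_toward_truth():
    probs = np.array([[0.4, 0.4, 0.2]])
    assert rank_of_true(probs, np.array([0]))[0] == 1
    assert rank_of_true(probs, np.array([1]))[0] == 1
    assert rank_of_true(probs, np.array([2]))[0] == 3


# ---------------------------------------------------------------------------
# probability regrouping


def test_regroup_probabilities_identity_and_conservation():
    rng = np.random.default_rng(1)
    probs = rng.dirichlet(np.ones(16), size=20)
    same, cls = regroup_probabilities(probs, FINE_CLASSES, "16-type")
    assert np.array_equal(same, probs) and cls == FINE_CLASSES
    for level in ("6-type", "3-type"):
        coarse, _ = regroup_probabilities(probs, FINE_CLASSES, level)
        assert np.allclose(coarse.sum(axis=1), 1.0)


def test_regroup_uniform_row_reflects_group_sizes():
    uniform = np.full((1, 16), 1 / 16)
    coarse, cls = regroup_probabilities(uniform, FINE_CLASSES, "3-type")
    assert cls == ("A", "P", "M")
    assert np.allclose(coarse[0], [6 / 16, 4 / 16, 6 / 16])


# ---------------------------------------------------------------------------
# confusion / sensitivity / specificity


def test_confusion_hand_tally():
    labels = ["a", "a", "b", "b", "c", "c"]
    preds = ["a", "b", "b", "b", "a", "c"]
    got = confusion(labels, preds, ["a", "b", "c"])
    assert np.array_equal(got, [[1, 1, 0], [0, 2, 0], [1, 0, 1]])
    assert got.sum() == 6
    assert np.trace(got) / 6 == pytest.approx(
        np.mean(np.array(labels) == np.array(preds))
    )


def test_confusion_degenerate_shapes():
    assert np.array_equal(
        confusion(list("ab"), list("ab"), list("ab")), np.eye(2)
    )
    single_column = confusion(list("abab"), list("aaaa"), list("ab"))
    assert single_column[:, 1].sum() == 0
    with pytest.raises(ValueError):
        confusion(list("ab"), list("a"), list("ab"))


def test_sensitivity_specificity_hand_values():
    out = sensitivity_specificity(np.array([[8, 2], [4, 6]]))
    assert np.allclose(out["sensitivity"], [0.8, 0.6])
    assert np.allclose(out["specificity"], [0.6, 0.8])
    assert out["macro_sensitivity"] == pytest.approx(0.7)
    # TP+FN per class equals the row sum; TN+FP equals N minus it
    conf = np.array([[8, 2], [4, 6]])
    for c in range(2):
        tp, fn = conf[c, c], conf[c].sum() - conf[c, c]
        assert tp + fn == conf[c].sum()


def test_perfect_predictions_give_unit_rates():
    conf = np.diag([5, 3, 7])
    out = sensitivity_specificity(conf)
    assert np.allclose(out["sensitivity"], 1.0)
    assert np.allclose(out["specificity"], 1.0)


def test_zero_support_class_excluded_with_warning():
    conf = np.array([[5, 0, 1], [0, 0, 0], [0, 0, 4]])  # class 1 unsupported
    with pytest.warns(UserWarning, match="zero support"):
        out = sensitivity_specificity(conf)
    assert np.isnan(out["sensitivity"][1])
    assert out["macro_sensitivity"] == pytest.approx(
        np.mean([5 / 6, 1.0])
    )


# ---------------------------------------------------------------------------
# ROC / AUC


def pair_counting_auc(scores, positives):
    """Oracle: concordant pairs / total positive-negative pairs."""
    pos = [s for s, y in zip(scores, positives) if y]
    neg = [s for s, y in zip(scores, positives) if not y]
    total = concordant = 0
    for p in pos:
        for n in neg:
            total += 1
            concordant += (p > n) + 0.5 * (p == n)
    return concordant / total


def test_auc_fixed_example():
    probs = np.array([[0.9, 0.1], [0.8, 0.2], [0.4, 0.6], [0.3, 0.7]])
    out = roc_auc(probs, ["p", "n", "p", "n"], ["p", "n"])
    assert out["auc"][0] == pytest.approx(0.75)


def test_auc_matches_pair_counting_on_random_instances():
    rng = np.random.default_rng(2)
    for _ in range(30):
        n = int(rng.integers(4, 51))
        c = int(rng.integers(2, 5))
        probs = rng.dirichlet(np.ones(c), size=n)
        true_idx = rng.integers(0, c, size=n)
        if len(set(true_idx)) < 2:
            continue
        classes = [f"k{i}" for i in range(c)]
        labels = [classes[i] for i in true_idx]
        out = roc_auc(probs, labels, classes)
        for j in range(c):
            positives = true_idx == j
            if positives.all() or not positives.any():
                assert np.isnan(out["auc"][j])
                continue
            assert out["auc"][j] == pytest.approx(
                pair_counting_auc(probs[:, j], positives), abs=1e-9
            )


def test_auc_extremes():
    probs = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
    out = roc_auc(probs, ["p", "p", "n", "n"], ["p", "n"])
    assert np.allclose(out["auc"], 1.0)
    rng = np.random.default_rng(3)
    scores = rng.random(4000)
    labels = np.where(rng.random(4000) < 0.5, "p", "n")
    probs = np.column_stack([scores, 1 - scores])
    out = roc_auc(probs, labels, ["p", "n"])
    assert abs(out["auc"][0] - 0.5) < 0.03  # label-independent scores


# ---------------------------------------------------------------------------
# agreement


def test_cohen_kappa_hand_table():
    a = ["x"] * 60 + ["y"] * 40
    b = ["x"] * 45 + ["y"] * 15 + ["x"] * 25 + ["y"] * 15
    out = cohen_kappa(a, b)
    # p_o = 0.6, p_e = 0.6*0.7 + 0.4*0.3 = 0.54 -> kappa = 0.06/0.46
    assert out["kappa"] == pytest.approx(0.06 / 0.46, abs=1e-9)
    assert out["ci_low"] < out["kappa"] < out["ci_high"]


def test_cohen_kappa_identity_and_relabeling_invariance():
    rng = np.random.default_rng(4)
    a = [f"c{i}" for i in rng.integers(0, 5, 200)]
    b = [f"c{i}" for i in rng.integers(0, 5, 200)]
    assert cohen_kappa(a, a)["kappa"] == pytest.approx(1.0)
    mapping = {f"c{i}": f"z{4 - i}" for i in range(5)}
    renamed = cohen_kappa([mapping[x] for x in a], [mapping[x] for x in b])
    assert renamed["kappa"] == pytest.approx(cohen_kappa(a, b)["kappa"], abs=1e-12)


def test_cohen_kappa_degenerate_constant_labelings():
    with pytest.warns(UserWarning, match="degenerate"):
        out = cohen_kappa(["a"] * 5, ["a"] * 5)
    assert out["kappa"] == 1.0


def test_fleiss_unanimous_is_one():
    mat = np.array([["a"] * 4, ["b"] * 4, ["a"] * 4], dtype=object)
    assert fleiss_kappa(mat, n_boot=50, seed=0)["kappa"] == pytest.approx(1.0)


def test_fleiss_null_distribution_centers_near_zero():
    """Independent uniform raters give kappa ~ 0 on average (small negative
    finite-sample bias allowed)."""
    rng = np.random.default_rng(5)
    classes = np.array([f"c{i}" for i in range(16)], dtype=object)
    kappas = []
    for _ in range(200):
        mat = classes[rng.integers(0, 16, size=(40, 4))]
        kappas.append(fleiss_kappa(mat, n_boot=0)["kappa"])
    assert abs(np.mean(kappas)) < 0.03


def test_fleiss_requires_complete_panel():
    table = pd.DataFrame(
        {
            "specimen_id": ["s0", "s0", "s1"],
            "rater_id": ["A0", "A1", "A0"],
            "label": ["U1", "U1", "U2"],
        }
    )
    with pytest.raises(ValueError, match="unequal"):
        fleiss_kappa_table(table)


def test_fleiss_increases_with_coarser_granularity_on_adjacent_confusion():
    """Raters who err toward adjacent positions agree more once positions
    are pooled into types, so 3-type kappa >= 16-type kappa."""
    rng = np.random.default_rng(6)
    truth = [FINE_CLASSES[i % 16] for i in range(200)]
    table = simulate_annotators(truth, default_rater_panel(), seed=9)
    k16 = fleiss_kappa_table(table, "16-type", n_boot=0)["kappa"]
    k3 = fleiss_kappa_table(table, "3-type", n_boot=0)["kappa"]
    assert k3 >= k16


# ---------------------------------------------------------------------------
# the full report


def _random_report(seed=0, n=60):
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.ones(16) * 0.5, size=n)
    labels = [FINE_CLASSES[i] for i in rng.integers(0, 16, n)]
    return evaluate_probabilities(probs, labels, list(FINE_CLASSES)), probs, labels


def test_report_internal_consistency():
    report, _, _ = _random_report()
    assert set(report.granularities) == {"16-type", "6-type", "3-type"}
    for entry in report.granularities.values():
        conf = np.asarray(entry["confusion"])
        assert conf.sum() == report.n
        assert np.trace(conf) / report.n == pytest.approx(entry["topk"]["1"])
        assert entry["macro_sensitivity"] == pytest.approx(
            np.nanmean(entry["sensitivity"])
        )


def test_report_argmax_merge_monotone_across_granularities():
    for seed in range(5):
        report, _, _ = _random_report(seed)
        t16 = report.granularities["16-type"]["top1_argmax_merged"]
        t6 = report.granularities["6-type"]["top1_argmax_merged"]
        t3 = report.granularities["3-type"]["top1_argmax_merged"]
        assert t3 >= t6 >= t16


def test_perfect_probabilities_score_perfectly_everywhere():
    labels = list(FINE_CLASSES) * 2
    probs = np.zeros((32, 16))
    for i, lab in enumerate(labels):
        probs[i, FINE_CLASSES.index(lab)] = 1.0
    report = evaluate_probabilities(probs, labels, list(FINE_CLASSES))
    for entry in report.granularities.values():
        assert entry["topk"]["1"] == 1.0
        assert entry["cohen_kappa"]["kappa"] == pytest.approx(1.0)
        assert np.allclose(entry["sensitivity"], 1.0)


def test_report_serialization_is_nan_free():
    report, _, _ = _random_report(seed=7, n=8)  # sparse: some AUCs undefined
    doc = report.to_dict()

    def no_nan(obj):
        if isinstance(obj, dict):
            return all(no_nan(v) for v in obj.values())
        if isinstance(obj, list):
            return all(no_nan(v) for v in obj)
        if isinstance(obj, float):
            return np.isfinite(obj)
        return True

    assert no_nan(doc)


# ---------------------------------------------------------------------------
# embeddings and heatmaps (on a tiny fitted model)


@pytest.fixture(scope="module")
def tiny_fitted(small_separable_dataset):
    from toothset.model import MultiViewSetClassifier

    ds = small_separable_dataset
    y = [r.label for r in ds.records]
    clf = MultiViewSetClassifier(
        embedding_dim=32, fusion_layers=1, fusion_heads=4, mlp_ratio=2,
        image_size=32, epochs=1, warmup_epochs=0, batch_specimens=8, seed=0,
    )
    return clf.fit(ds.records, y), ds


def test_export_embeddings_shape_and_determinism(tiny_fitted):
    clf, ds = tiny_fitted
    frame = export_embeddings(clf, ds.records)
    assert len(frame) == len(ds.records)
    emb_cols = [c for c in frame.columns if c.startswith("e")]
    assert len(emb_cols) == 32
    dup = export_embeddings(clf, [ds.records[0], ds.records[0]])
    assert np.allclose(dup[emb_cols].iloc[0], dup[emb_cols].iloc[1])


def test_feature_heatmaps_contract(tiny_fitted):
    clf, ds = tiny_fitted
    record = ds.records[0]
    maps = feature_heatmaps(clf, record, n_channels=3)
    img = record.image("occlusal")
    assert set(maps) == set(record.views)
    assert maps["occlusal"].shape == (3, img.shape[0], img.shape[1], 3)
    with pytest.raises(ValueError, match="channels"):
        feature_heatmaps(clf, record, n_channels=999)
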