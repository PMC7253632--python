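"""Confusion metrics, fold plans and group time-course comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score)

from nirsmap.evaluation import (ConfusionCounts, compare_group_timecourses,
                                compute_metrics, kfold_split, metrics_table)
from nirsmap.pipeline import RunConfig, preprocess_stage
from nirsmap.simulate import CohortSpec, NoiseSpec, generate_cohort

FS = 8.138


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=9, tn=6, fp=0, fn=0))
        assert all(m[k] == 100.0 for k in ("accuracy", "recall", "precision", "f1"))

    def test_hand_worked_mixed_counts(self):
        m = compute_metrics(ConfusionCounts(tp=3, tn=2, fp=1, fn=2))
        assert m["accuracy"] == pytest.approx(62.50, abs=0.005)
        assert m["recall"] == pytest.approx(60.00, abs=0.005)
        assert m["precision"] == pytest.approx(75.00, abs=0.005)
        assert m["f1"] == pytest.approx(66.67, abs=0.005)

    def test_undefined_precision_reported_as_nan(self):
        m = compute_metrics(ConfusionCounts(tp=0, tn=8, fp=0, fn=4))
        assert m["accuracy"] == pytest.approx(66.67, abs=0.005)
        assert m["recall"] == 0.0
        assert np.isnan(m["precision"])
        assert np.isnan(m["f1"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)

    def test_accuracy_100_iff_no_errors(self):
        assert compute_metrics(ConfusionCounts(5, 5, 0, 0))["accuracy"] == 100.0
        assert compute_metrics(ConfusionCounts(5, 5, 1, 0))["accuracy"] < 100.0


@settings(max_examples=1000, deadline=None)
@given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
def test_metrics_agree_with_sklearn_oracle(tp, tn, fp, fn):
    """Independent cross-check on arbitrary count vectors: rebuild label
    arrays and compare against scikit-learn's implementations."""
    if tp + tn + fp + fn == 0:
        return
    y_true = np.array([1] * tp + [0] * tn + [0] * fp + [1] * fn)
    y_pred = np.array([1] * tp + [0] * tn + [1] * fp + [0] * fn)
    m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
    assert m["accuracy"] == pytest.approx(100 * accuracy_score(y_true, y_pred))
    if tp + fn > 0:
        assert m["recall"] == pytest.approx(
            100 * recall_score(y_true, y_pred, zero_division=np.nan))
    if tp + fp > 0:
        assert m["precision"] == pytest.approx(
            100 * precision_score(y_true, y_pred, zero_division=np.nan))
    if not np.isnan(m["f1"]):
        assert m["f1"] == pytest.approx(100 * f1_score(y_true, y_pred))
    # order invariance (NaN-aware comparison)
    perm = np.random.default_rng(0).permutation(y_true.size)
    c2 = ConfusionCounts.from_predictions(y_true[perm], y_pred[perm])
    m2 = compute_metrics(c2)
    for key in m:
        assert (np.isnan(m[key]) and np.isnan(m2[key])) or m[key] == m2[key]


class TestFoldPlan:
    def test_balanced_sample_mode_sizes(self):
        plan = kfold_split(72, k=5, seed=0)
        sizes = sorted(len(f) for f in plan.test_folds)
        assert sizes == [14, 14, 14, 15, 15]

    def test_union_disjoint_cover(self):
        plan = kfold_split(72, k=5, seed=1)
        all_idx = np.concatenate(plan.test_folds)
        assert len(all_idx) == 72
        assert len(np.unique(all_idx)) == 72

    def test_same_seed_same_partition(self):
        a = kfold_split(30, seed=9)
        b = kfold_split(30, seed=9)
        for fa, fb in zip(a.test_folds, b.test_folds):
            np.testing.assert_array_equal(fa, fb)

    def test_subject_mode_keeps_subjects_whole(self):
        subjects = np.repeat([f"S{i}" for i in range(8)], 3)
        plan = kfold_split(24, k=5, mode="subject", seed=0, subjects=subjects)
        for i, fold in enumerate(plan.test_folds):
            fold_subjects = set(subjects[fold])
            outside = set(subjects[plan.train_indices(i, 24)])
            assert not (fold_subjects & outside)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(3, k=5)


class TestMetricsTable:
    def test_average_row_is_arithmetic_mean(self):
        from nirsmap.evaluation import CVResults
        frames = {}
        for name, acc in (("a", 90.0), ("b", 70.0)):
            fm = pd.DataFrame([{"fold": 0, "accuracy": acc, "recall": acc,
                                "precision": acc, "f1": acc}]).set_index("fold")
            frames[name] = CVResults(fold_counts=[ConfusionCounts(1, 1, 0, 0)],
                                     fold_metrics=fm)
        table = metrics_table(frames)
        assert table.loc["Average", "accuracy"] == pytest.approx(80.0)
        assert table.loc["STD", "accuracy"] == pytest.approx(np.std([90, 70], ddof=1))


@pytest.fixture(scope="module")
def cohort():
    spec = CohortSpec(n_impaired=5, n_control=4, tasks=("n_back",),
                      amplitude_ratio_impaired=0.5, noise=NoiseSpec.low(),
                      seed=17)
    ds = generate_cohort(spec)
    epochs = preprocess_stage(RunConfig(cohort=spec), ds)
    return ds, epochs


def test_sample_mode_cv_leaks_subject_identity():
    """With per-subject idiosyncratic offsets and no group effect,
    sample-mode CV scores above subject-grouped CV (trials of one subject
    span folds, so the classifier can memorize subject fingerprints) —
    asserted as a trend over 20 replicate cohorts."""
    from nirsmap.cnn import CNNArchitecture, TrainConfig
    from nirsmap.evaluation import cross_validate

    arch = CNNArchitecture(input_hw=(16, 16))
    cfg = TrainConfig(epochs=8, batch_size=8, learning_rate=3e-3)
    diffs = []
    for rep in range(20):
        rng = np.random.default_rng(1000 + rep)
        n_sub, n_tr = 10, 3
        subject_labels = rng.permutation([0] * 5 + [1] * 5)
        offsets = rng.normal(0.0, 1.0, n_sub)
        images, labels, subjects = [], [], []
        for s in range(n_sub):
            for _ in range(n_tr):
                images.append(np.full((16, 16), offsets[s])
                              + 0.1 * rng.standard_normal((16, 16)))
                labels.append(subject_labels[s])
                subjects.append(s)
        images = np.stack(images).astype(np.float32)
        labels = np.array(labels)
        accs = {}
        for mode in ("sample", "subject"):
            plan = kfold_split(len(labels), k=5, mode=mode, seed=rep,
                               subjects=subjects)
            res = cross_validate(images, labels, arch, cfg, plan=plan, seed=rep)
            accs[mode] = res.mean()["accuracy"]
        diffs.append(accs["sample"] - accs["subject"])
    diffs = np.array(diffs)
    se = diffs.std(ddof=1) / np.sqrt(diffs.size)
    assert diffs.mean() > 3 * se


class TestGroupTimecourses:
    def test_reduced_amplitude_group_detected(self, cohort):
        ds, epochs = cohort
        res = compare_group_timecourses(epochs, ds.groups, FS, "n_back")
        assert res["t"] < 0  # impaired below control
        assert res["p"] < 0.001
        assert res["impaired_mean"].shape == res["control_mean"].shape

    def test_label_swap_flips_t_keeps_p(self, cohort):
        ds, epochs = cohort
        flipped = {s: ("control" if g == "impaired" else "impaired")
                   for s, g in ds.groups.items()}
        a = compare_group_timecourses(epochs, ds.groups, FS, "n_back")
        b = compare_group_timecourses(epochs, flipped, FS, "n_back")
        assert a["t"] == pytest.approx(-b["t"])
        assert a["p"] == pytest.approx(b["p"])

    def test_identical_groups_p_not_extreme(self):
        # null calibration (coarse): identical generative groups should not
        # produce systematically tiny p-values
        ps = []
        for seed in range(6):
            spec = CohortSpec(n_impaired=4, n_control=4, tasks=("n_back",),
                              n_channels=6, amplitude_ratio_impaired=1.0,
                              seed=100 + seed)
            ds = generate_cohort(spec)
            epochs = preprocess_stage(RunConfig(cohort=spec), ds)
            ps.append(compare_group_timecourses(epochs, ds.groups, FS, "n_back")["p"])
        assert np.median(ps) > 0.05

    def test_small_group_rejected(self, cohort):
        ds, epochs = cohort
        groups = dict(ds.groups)
        for s in list(groups)[:4]:
            groups[s] = "impaired"  # leaves < 2 controls
        lone = {s: g for s, g in groups.items()}
        lone = {s: ("impaired" if i < 8 else "control")
                for i, s in enumerate(sorted(lone))}
        with pytest.raises(ValueError):
            compare_group_timecourses(epochs, lone, FS, "n_back")
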