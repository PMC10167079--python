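"""Cross-validation geometry, the SVM wrapper, AUC, and the decoders."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom
from sklearn.metrics import roc_auc_score

from conftest import MASTER_SEED, make_epochs
from erpmvpa import decoder, simgen
from erpmvpa.decoder import CVPlan, SvmClassifier, WindowSpec


def dummy_dataset(group_sizes: dict[str, int]):
    """One 1-trial participant per entry; enough for CV geometry."""
    ds = []
    for g, n in group_sizes.items():
        for i in range(n):
            ds.append(make_epochs(np.zeros((1, 2, 4)), sfreq=64.0,
                                  pid=f"{g}-{i:03d}", group=g))
    return ds


TABLE1_SIZES = {"children": 46, "young": 39, "early-ma": 21,
                "late-ma": 25, "old<75": 40, "veryold>75": 38}


class TestGroupCV:
    def test_study_fold_geometry(self):
        ds = dummy_dataset(TABLE1_SIZES)
        folds = decoder.make_group_cv(ds, CVPlan(seed=0))
        test_sizes = [len(te) for _, te in folds]
        assert sorted(test_sizes) == [20] + [21] * 9   # modal 21, train 188
        assert {len(tr) for tr, _ in folds} == {188, 189}
        tested = [p for _, te in folds for p in te]
        assert sorted(tested) == sorted(ep.participant_id for ep in ds)
        # per-group fold sizes differ by at most one
        for g, n in TABLE1_SIZES.items():
            per_fold = [sum(p.startswith(g) for p in te) for _, te in folds]
            assert max(per_fold) - min(per_fold) <= 1

    def test_leave_one_out_boundary(self):
        ds = dummy_dataset({"g": 10})
        folds = decoder.make_group_cv(ds, CVPlan(seed=1))
        assert all(len(te) == 1 for _, te in folds)

    def test_exact_divisibility(self):
        ds = dummy_dataset({"a": 20, "b": 20})
        folds = decoder.make_group_cv(ds, CVPlan(seed=2))
        for _, te in folds:
            assert sum(p.startswith("a") for p in te) == 2
            assert sum(p.startswith("b") for p in te) == 2

    def test_group_smaller_than_folds_rejected(self):
        ds = dummy_dataset({"a": 20, "b": 5})
        with pytest.raises(ValueError):
            decoder.make_group_cv(ds, CVPlan(n_folds_or_splits=10))


class TestSubsample:
    def test_downsamples_to_minority(self):
        labels = np.array(["a"] * 100 + ["b"] * 60 + ["c"] * 60)
        idx = decoder.subsample_training(np.zeros((220, 1)), labels, seed=0)
        kept = labels[idx]
        assert all((kept == c).sum() == 60 for c in "abc")
        assert len(np.unique(idx)) == len(idx)

    def test_balanced_classes_identity_multiset(self):
        labels = np.array(["a", "b"] * 30)
        idx = decoder.subsample_training(np.zeros((60, 1)), labels, seed=3)
        assert sorted(idx.tolist()) == list(range(60))

    def test_deterministic(self):
        labels = np.array(["a"] * 50 + ["b"] * 20)
        i1 = decoder.subsample_training(np.zeros((70, 1)), labels, seed=9)
        i2 = decoder.subsample_training(np.zeros((70, 1)), labels, seed=9)
        np.testing.assert_array_equal(i1, i2)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            decoder.subsample_training(np.zeros((0, 1)), np.array([]), 0)


class TestWithinSplits:
    def test_proportional_allocation(self):
        labels = ["congruent"] * 80 + ["incongruent"] * 80
        ep = make_epochs(np.zeros((160, 2, 4)), sfreq=64.0, labels=labels)
        splits = decoder.make_within_splits(ep, CVPlan(
            mode="within_participant", seed=0))
        assert len(splits) == 10
        for tr, te in splits:
            assert len(te) == 32
            te_labels = ep.trial_labels[te]
            assert (te_labels == "congruent").sum() == 16
            assert (te_labels == "incongruent").sum() == 16

    def test_study_mean_test_size(self):
        labels = ["congruent"] * 72 + ["incongruent"] * 71
        ep = make_epochs(np.zeros((143, 2, 4)), sfreq=64.0, labels=labels)
        splits = decoder.make_within_splits(ep, CVPlan(
            mode="within_participant", seed=1))
        assert all(len(te) == 29 for _, te in splits)

    def test_degenerate_fraction_rejected(self):
        ep = make_epochs(np.zeros((40, 2, 4)), sfreq=64.0)
        with pytest.raises(ValueError):
            decoder.make_within_splits(
                ep, CVPlan(mode="within_participant", test_fraction=0.0))

    def test_too_few_trials_rejected(self):
        ep = make_epochs(np.zeros((6, 2, 4)), sfreq=64.0,
                         labels=["congruent"] * 4 + ["incongruent"] * 2)
        with pytest.raises(ValueError):
            decoder.make_within_splits(ep, CVPlan(mode="within_participant"))


class TestSvmClassifier:
    @staticmethod
    def blobs(rng, n=40, d=5, sep=10.0):
        X = rng.normal(size=(n, d))
        y = np.repeat([0, 1], n // 2)
        X[y == 1] += sep
        return X, y

    def test_separable_training_accuracy(self, rng):
        X, y = self.blobs(rng)
        clf = SvmClassifier().fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_shuffled_labels_held_out_at_chance(self, rng):
        X, y = self.blobs(rng, n=240)
        y = rng.permutation(y)
        clf = SvmClassifier().fit(X[:40], y[:40])
        acc = np.mean(clf.predict(X[40:]) == y[40:])
        lo = binom.ppf(0.025, 200, 0.5) / 200
        hi = binom.ppf(0.975, 200, 0.5) / 200
        assert lo <= acc <= hi

    def test_duplicated_training_set_invariance(self, rng):
        X, y = self.blobs(rng)
        Xt = rng.normal(size=(10, 5))
        d1 = SvmClassifier().fit(X, y).decision_scores(Xt)
        d2 = SvmClassifier().fit(np.vstack([X, X]),
                                 np.concatenate([y, y])).decision_scores(Xt)
        np.testing.assert_allclose(d1, d2, atol=1e-8)

    def test_single_class_rejected(self, rng):
        X, _ = self.blobs(rng)
        with pytest.raises(ValueError):
            SvmClassifier().fit(X, np.zeros(len(X)))


class TestAuc:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 1.0),
        ([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1], 0.0),
        ([0.5, 0.5, 0.5, 0.5], [0, 0, 1, 1], 0.5),
    ])
    def test_known_values(self, scores, labels, expected):
        assert decoder.score_auc(np.array(scores),
                                 np.array(labels)) == expected

    def test_matches_sklearn_on_random_data(self, rng):
        for _ in range(20):
            scores = rng.normal(size=50)
            labels = rng.integers(0, 2, size=50)
            if len(np.unique(labels)) < 2:
                continue
            assert decoder.score_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            decoder.score_auc(np.array([1.0, 2.0]), np.array([1, 1]))


class TestWindows:
    def test_study_window_count(self):
        assert WindowSpec(20, 1).n_windows(231) == 212

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(2, 60), st.integers(2, 60), st.integers(1, 60))
    def test_window_count_formula(self, n_samples, length, step):
        if step > length or length > n_samples:
            return
        w = WindowSpec(length, step)
        starts = w.starts(n_samples)
        # every window fits; advancing one more step would overrun
        assert starts[0] == 0
        assert starts[-1] + length <= n_samples
        assert starts[-1] + step + length > n_samples
        assert w.n_windows(n_samples) == (n_samples - length) // step + 1

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            WindowSpec(4, 5)
        with pytest.raises(ValueError):
            WindowSpec(20, 1).starts(10)


def separable_dataset(n_groups=2, n_per_group=4, n_trials=12):
    """Noise-free dataset whose groups have disjoint evoked patterns."""
    cfg = simgen.make_scaled_config(seed=5, n_per_group=n_per_group,
                                    trials_per_condition=n_trials // 2,
                                    sfreq=32.0, n_groups=n_groups)
    # no noise and no participant-level jitter: groups are point masses
    comps = [dataclasses.replace(c, latency_sd=0.0, amplitude_sd=0.0)
             for c in cfg.components]
    cfg = dataclasses.replace(cfg, noise_sd=0.0, components=comps)
    groups = []
    for gi, g in enumerate(cfg.groups):
        groups.append(dataclasses.replace(
            g, component_overrides={"P1": (60.0 * gi, 1.0 + gi)},
            condition_shift_ms=0.0))
    return simgen.simulate_dataset(dataclasses.replace(cfg, groups=groups))


class TestDecodeWholeTrial:
    def test_noise_free_groups_perfectly_classified(self):
        ds = separable_dataset()
        plan = CVPlan(n_folds_or_splits=2, seed=MASTER_SEED)
        conf = decoder.decode_whole_trial(ds, plan, n_components=3)
        assert conf.accuracy == 1.0
        assert np.all(conf.matrix - np.diag(np.diag(conf.matrix)) == 0)
        assert conf.accuracy == pytest.approx(
            np.trace(conf.matrix) / conf.matrix.sum())
        assert np.all(conf.precision == 1.0) and np.all(conf.recall == 1.0)

    def test_row_sums_are_true_test_counts(self):
        ds = separable_dataset()
        conf = decoder.decode_whole_trial(
            ds, CVPlan(n_folds_or_splits=2, seed=0), n_components=3)
        totals = {}
        for ep in ds:
            totals[ep.group_label] = totals.get(ep.group_label, 0) \
                + ep.n_trials
        for gi, g in enumerate(conf.class_labels):
            assert conf.matrix[gi].sum() == totals[g]


class TestDecodeTimeResolved:
    def test_within_participant_separable_auc(self):
        cfg = simgen.make_scaled_config(seed=6, n_per_group=1,
                                        trials_per_condition=20,
                                        sfreq=32.0, n_groups=2)
        cfg = dataclasses.replace(cfg, noise_sd=0.0)
        ep = simgen.simulate_dataset(cfg)[1]     # 'young', effect at 200 ms
        traj = decoder.decode_time_resolved(
            ep, CVPlan(mode="within_participant", n_folds_or_splits=4,
                       seed=0), window=WindowSpec(8, 4), n_components=2)
        # noise-free condition difference => perfect AUC somewhere
        assert traj.mean_curve.max() == 1.0
        assert traj.scores.shape == (WindowSpec(8, 4).n_windows(
            ep.n_samples), 4)

    def test_trajectory_metadata(self):
        cfg = simgen.make_scaled_config(seed=6, n_per_group=1,
                                        trials_per_condition=10,
                                        sfreq=32.0, n_groups=1)
        ep = simgen.simulate_dataset(cfg)[0]
        traj = decoder.decode_time_resolved(
            ep, CVPlan(mode="within_participant", n_folds_or_splits=3,
                       seed=0), window=WindowSpec(8, 8), n_components=2)
        assert traj.metric == "auc"
        assert traj.participant_id == ep.participant_id
        assert len(traj.fold_details) == 3
        assert np.all((traj.window_centers >= ep.times[0])
                      & (traj.window_centers <= ep.times[-1]))
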