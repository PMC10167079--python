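"""The two decoding experiments: age group and stimulus type.

Between participants: trial-level 6-class age-group decoding with
participant-wise stratified 10-fold cross-validation and random subsampling
of the training data to the minority class. Within participants: binary
congruent/incongruent decoding with 10 random stratified train/test splits
(test fraction 0.20). Both run whole-trial (all time samples as features)
and time-resolved (sliding windows of 20 samples advancing by 1, i.e. 19
samples of overlap).

Each fold fits xDAWN on the training partition only, projects both
partitions to virtual channels, standardizes features by training-set
mean/sd and classifies with an RBF-kernel SVM (C = 1, gamma = 'scale').
Scores are accuracy (group decoding) or midrank AUC (task decoding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import SVC

from . import xdawn
from .simgen import EpochSet

__all__ = [
    "WindowSpec",
    "CVPlan",
    "DecodeTrajectory",
    "ConfusionResult",
    "SvmClassifier",
    "make_group_cv",
    "subsample_training",
    "make_within_splits",
    "score_auc",
    "decode_whole_trial",
    "decode_time_resolved",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry, in samples."""

    length: int = 20
    step: int = 1

    def __post_init__(self):
        if not 1 <= self.step <= self.length:
            raise ValueError("require 1 <= step <= length")

    def starts(self, n_samples: int) -> np.ndarray:
        if n_samples < self.length:
            raise ValueError("window longer than the epoch")
        return np.arange(0, n_samples - self.length + 1, self.step)

    def n_windows(self, n_samples: int) -> int:
        return len(self.starts(n_samples))


@dataclass(frozen=True)
class CVPlan:
    """Cross-validation plan for either decoding experiment."""

    mode: str = "between_participants"   # or "within_participant"
    n_folds_or_splits: int = 10
    stratify_by: str = "group"
    subsample_to_minority: bool = True
    test_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("between_participants", "within_participant"):
            raise ValueError(f"unknown CV mode {self.mode!r}")
        if self.n_folds_or_splits < 2:
            raise ValueError("need at least 2 folds/splits")


@dataclass
class DecodeTrajectory:
    """Per-window, per-fold scores of a time-resolved decoder."""

    window_centers: np.ndarray           # seconds
    scores: np.ndarray                   # (n_windows, n_folds)
    metric: str                          # "accuracy" | "auc"
    fold_details: list[int] = field(default_factory=list)  # test sizes
    participant_id: str = ""
    group_label: str = ""

    def __post_init__(self):
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape[0] != len(self.window_centers):
            raise ValueError("scores rows must match window count")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("scores must lie in [0, 1]")

    @property
    def mean_curve(self) -> np.ndarray:
        return self.scores.mean(axis=1)

    @property
    def ci95(self) -> np.ndarray:
        """Per-window 95% CI half-width of the fold mean (t-based)."""
        n = self.scores.shape[1]
        if n < 2:
            return np.zeros(self.scores.shape[0])
        sem = self.scores.std(axis=1, ddof=1) / np.sqrt(n)
        return stats.t.ppf(0.975, n - 1) * sem


@dataclass
class ConfusionResult:
    """Aggregated confusion matrix with per-class precision/recall."""

    matrix: np.ndarray                   # rows = true class
    class_labels: list

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=int)
        k = len(self.class_labels)
        if self.matrix.shape != (k, k):
            raise ValueError("confusion matrix must be square in the classes")

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.matrix) / self.matrix.sum())

    @property
    def precision(self) -> np.ndarray:
        col = self.matrix.sum(axis=0).astype(float)
        col[col == 0] = np.nan
        return np.diag(self.matrix) / col

    @property
    def recall(self) -> np.ndarray:
        row = self.matrix.sum(axis=1).astype(float)
        row[row == 0] = np.nan
        return np.diag(self.matrix) / row


# ---------------------------------------------------------------------------
# cross-validation geometry
# ---------------------------------------------------------------------------

def make_group_cv(dataset: list[EpochSet], plan: CVPlan
                  ) -> list[tuple[list[str], list[str]]]:
    """Participant-level stratified folds, balanced in total size.

    Participants are partitioned so that every participant tests exactly
    once, per-group fold sizes differ by at most one, and the per-class
    remainders are spread greedily so total fold sizes are as equal as
    possible (209 participants in 10 folds gives nine folds of 21 and one
    of 20, i.e. 188 or 189 training participants).
    """
    k = plan.n_folds_or_splits
    rng = np.random.default_rng(plan.seed)
    by_group: dict[str, list[str]] = {}
    for ep in dataset:
        by_group.setdefault(ep.group_label, []).append(ep.participant_id)
    for g, pids in by_group.items():
        if len(pids) < k:
            raise ValueError(f"group {g!r} has fewer participants than folds")

    fold_members: list[list[str]] = [[] for _ in range(k)]
    fold_sizes = np.zeros(k, dtype=int)
    for g in sorted(by_group):
        pids = sorted(by_group[g])
        rng.shuffle(pids)
        base, extra = divmod(len(pids), k)
        counts = np.full(k, base)
        # give this group's remainder to the currently smallest folds
        order = np.lexsort((np.arange(k), fold_sizes))
        counts[order[:extra]] += 1
        pos = 0
        for f in range(k):
            fold_members[f].extend(pids[pos:pos + counts[f]])
            pos += counts[f]
        fold_sizes += counts

    all_ids = sorted(p for pids in by_group.values() for p in pids)
    folds = []
    for f in range(k):
        test = sorted(fold_members[f])
        train = sorted(set(all_ids) - set(test))
        folds.append((train, test))
    return folds


def subsample_training(trials: np.ndarray, group_labels: np.ndarray,
                       seed: int) -> np.ndarray:
    """Indices downsampling every class to the minority-class count.

    Sampling is without replacement within each class, operating on the
    class's sorted index list, so the selected multiset does not depend on
    the order trials were supplied in. Returned indices are sorted.
    """
    group_labels = np.asarray(group_labels)
    classes, counts = np.unique(group_labels, return_counts=True)
    if np.any(counts == 0) or len(classes) == 0:
        raise ValueError("every class needs at least one trial")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    chosen = []
    for c in classes:
        idx = np.sort(np.flatnonzero(group_labels == c))
        chosen.append(rng.choice(idx, size=n_min, replace=False))
    return np.sort(np.concatenate(chosen))


def make_within_splits(epochs: EpochSet, plan: CVPlan
                       ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified random train/test splits of one participant's trials."""
    if not 0 < plan.test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = epochs.trial_labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 5:
        raise ValueError("need at least 5 trials per condition")
    sss = StratifiedShuffleSplit(n_splits=plan.n_folds_or_splits,
                                 test_size=plan.test_fraction,
                                 random_state=plan.seed % (2**32))
    return [(tr, te) for tr, te in sss.split(np.zeros(len(labels)), labels)]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class SvmClassifier:
    """RBF-kernel SVM over training-standardized features.

    C = 1 and gamma = 1 / (n_features * pooled feature variance), the
    toolchain defaults. Deterministic given its inputs.
    """

    def __init__(self, C: float = 1.0):
        self._svc = SVC(C=C, kernel="rbf", gamma="scale")
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SvmClassifier":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self._sd = sd
        self._svc.fit((X - self._mu) / self._sd, y)
        return self

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if self._mu is None:
            raise RuntimeError("classifier is not fitted")
        return (X - self._mu) / self._sd

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._svc.predict(self._standardize(X))

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Signed distances to the decision boundary (binary: 1-D)."""
        return self._svc.decision_function(self._standardize(X))


def score_auc(decision_scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (midrank) AUC: Mann-Whitney U / (n1 * n2).

    ``labels`` must contain exactly two classes; the class with the larger
    sorted label is treated as positive.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("AUC requires exactly two classes")
    pos = labels == classes[1]
    n1, n2 = int(pos.sum()), int((~pos).sum())
    ranks = stats.rankdata(decision_scores)      # midranks on ties
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def _fit_score_window(X_train, y_train, X_test, y_test, metric):
    clf = SvmClassifier().fit(X_train, y_train)
    if metric == "auc":
        return score_auc(clf.decision_scores(X_test), y_test)
    return float(np.mean(clf.predict(X_test) == y_test))


def _pool(dataset: list[EpochSet], ids: list[str]
          ) -> tuple[np.ndarray, np.ndarray]:
    """Stack trials of the given participants; labels are group labels."""
    by_id = {ep.participant_id: ep for ep in dataset}
    data = np.concatenate([by_id[i].data for i in ids], axis=0)
    labels = np.concatenate([np.full(by_id[i].n_trials, by_id[i].group_label)
                             for i in ids])
    return data, labels


def _as_epochset(data: np.ndarray, template: EpochSet) -> EpochSet:
    n = data.shape[0]
    return EpochSet(data=data, sfreq=template.sfreq, times=template.times,
                    trial_labels=np.full(n, "x"), correctness=np.ones(n, bool),
                    rt=np.zeros(n), participant_id="pooled", group_label="",
                    ch_names=[f"ch{i}" for i in range(data.shape[1])])


def decode_whole_trial(dataset: list[EpochSet], plan: CVPlan,
                       n_components: int = xdawn.DEFAULT_N_COMPONENTS
                       ) -> ConfusionResult:
    """Age-group decoding on full epochs; confusion pooled over folds."""
    folds = make_group_cv(dataset, plan)
    classes = sorted({ep.group_label for ep in dataset})
    class_index = {c: i for i, c in enumerate(classes)}
    matrix = np.zeros((len(classes), len(classes)), dtype=int)
    template = dataset[0]
    for fi, (train_ids, test_ids) in enumerate(folds):
        X_train, y_train = _pool(dataset, train_ids)
        X_test, y_test = _pool(dataset, test_ids)
        if plan.subsample_to_minority:
            sub_seed = int(np.random.SeedSequence(
                [plan.seed, 1, fi]).generate_state(1)[0])
            idx = subsample_training(X_train, y_train, sub_seed)
            X_train, y_train = X_train[idx], y_train[idx]
        fs = xdawn.fit(_as_epochset(X_train, template), y_train,
                       n_components=n_components)
        V_train = xdawn.transform(fs, _as_epochset(X_train, template)).data
        V_test = xdawn.transform(fs, _as_epochset(X_test, template)).data
        clf = SvmClassifier().fit(V_train.reshape(len(V_train), -1), y_train)
        pred = clf.predict(V_test.reshape(len(V_test), -1))
        for t, p in zip(y_test, pred):
            matrix[class_index[t], class_index[p]] += 1
    return ConfusionResult(matrix=matrix, class_labels=classes)


def _window_centers(times: np.ndarray, window: WindowSpec,
                    starts: np.ndarray) -> np.ndarray:
    return np.array([(times[s] + times[s + window.length - 1]) / 2.0
                     for s in starts])


def decode_time_resolved(data: EpochSet | list[EpochSet], plan: CVPlan,
                         window: WindowSpec = WindowSpec(),
                         metric: str | None = None,
                         n_components: int = xdawn.DEFAULT_N_COMPONENTS,
                         labels: np.ndarray | None = None
                         ) -> DecodeTrajectory:
    """Sliding-window decoding; one score per window per fold.

    Pass a single EpochSet for within-participant task decoding (metric
    defaults to AUC) or a list for between-participant group decoding
    (metric defaults to accuracy). xDAWN is fit once per fold on the
    full-length training epochs; windows are cut from the filtered signal.
    """
    if isinstance(data, EpochSet):
        return _decode_tr_within(data, plan, window,
                                 metric or "auc", n_components, labels)
    return _decode_tr_between(data, plan, window,
                              metric or "accuracy", n_components)


def _score_windows(V_train, y_train, V_test, y_test, window, metric):
    starts = window.starts(V_train.shape[2])
    out = np.empty(len(starts))
    for wi, s in enumerate(starts):
        sl = slice(s, s + window.length)
        out[wi] = _fit_score_window(
            V_train[:, :, sl].reshape(len(V_train), -1), y_train,
            V_test[:, :, sl].reshape(len(V_test), -1), y_test, metric)
    return out


def _decode_tr_within(epochs, plan, window, metric, n_components, labels):
    y = np.asarray(epochs.trial_labels if labels is None else labels)
    splits = make_within_splits(_relabel(epochs, y), plan)
    starts = window.starts(epochs.n_samples)
    scores = np.empty((len(starts), len(splits)))
    test_sizes = []
    for si, (tr, te) in enumerate(splits):
        fs = xdawn.fit(epochs.select_trials(tr), y[tr],
                       n_components=n_components)
        V = xdawn.transform(fs, epochs).data
        scores[:, si] = _score_windows(V[tr], y[tr], V[te], y[te],
                                       window, metric)
        test_sizes.append(len(te))
    return DecodeTrajectory(
        window_centers=_window_centers(epochs.times, window, starts),
        scores=scores, metric=metric, fold_details=test_sizes,
        participant_id=epochs.participant_id,
        group_label=epochs.group_label)


def _relabel(epochs: EpochSet, labels: np.ndarray) -> EpochSet:
    out = epochs.copy()
    out.trial_labels = np.asarray(labels)
    return out


def _decode_tr_between(dataset, plan, window, metric, n_components):
    folds = make_group_cv(dataset, plan)
    template = dataset[0]
    starts = window.starts(template.n_samples)
    scores = np.empty((len(starts), len(folds)))
    test_sizes = []
    for fi, (train_ids, test_ids) in enumerate(folds):
        X_train, y_train = _pool(dataset, train_ids)
        X_test, y_test = _pool(dataset, test_ids)
        if plan.subsample_to_minority:
            sub_seed = int(np.random.SeedSequence(
                [plan.seed, 1, fi]).generate_state(1)[0])
            idx = subsample_training(X_train, y_train, sub_seed)
            X_train, y_train = X_train[idx], y_train[idx]
        fs = xdawn.fit(_as_epochset(X_train, template), y_train,
                       n_components=n_components)
        V_train = xdawn.transform(fs, _as_epochset(X_train, template)).data
        V_test = xdawn.transform(fs, _as_epochset(X_test, template)).data
        scores[:, fi] = _score_windows(V_train, y_train, V_test, y_test,
                                       window, metric)
        test_sizes.append(len(y_test))
    return DecodeTrajectory(
        window_centers=_window_centers(template.times, window, starts),
        scores=scores, metric=metric, fold_details=test_sizes)
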