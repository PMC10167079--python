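"""xDAWN spatial filtering for epoched data, written from first principles.

For each class c the algorithm estimates the evoked response E_c (the mean
over class-c trials), forms the signal covariance S_c = E_c E_c^T / n_samples
and the total covariance T = mean over all trials of X X^T / n_samples, and
finds spatial filters w maximizing the Rayleigh quotient

    rho(w) = (w^T S_c w) / (w^T T w),

the signal to signal-plus-noise power ratio of the filtered signal. The
generalized eigenproblem S_c w = lambda T w is solved by Cholesky-whitening
T (with a tiny diagonal shrinkage for numerical safety) and an ordinary
symmetric eigendecomposition in whitened space. The top ``n_components``
eigenvectors per class become filters; applying all classes' filters yields
n_classes x n_components "virtual channels" per trial.

This epoched-data variant (class-average evoked) coincides with the original
least-squares formulation when stimulus responses do not overlap across
trials, which holds for fixed-length epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .simgen import EpochSet

__all__ = ["SpatialFilterSet", "fit", "transform"]

DEFAULT_N_COMPONENTS = 5
SHRINKAGE = 1e-10   # diagonal loading, scaled by mean channel power


@dataclass
class SpatialFilterSet:
    """Fitted per-class xDAWN filters.

    ``filters``/``patterns``: (n_classes, n_components, n_channels); filter
    rows are unit-norm, patterns map virtual channels back to sensor space
    (T w, row-normalized). ``eigenvalues`` are the corresponding Rayleigh
    quotients, sorted descending within each class.
    """

    filters: np.ndarray
    patterns: np.ndarray
    eigenvalues: np.ndarray
    class_labels: list
    n_components: int

    def __post_init__(self):
        self.filters = np.asarray(self.filters, dtype=float)
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.filters.shape != self.patterns.shape:
            raise ValueError("filters and patterns shapes differ")
        if self.filters.shape[:2] != self.eigenvalues.shape:
            raise ValueError("eigenvalues shape inconsistent with filters")
        if self.filters.shape[0] != len(self.class_labels):
            raise ValueError("class_labels length inconsistent with filters")
        for ev in self.eigenvalues:
            if np.any(np.diff(ev) > 1e-9):
                raise ValueError("eigenvalues must be sorted descending")

    @property
    def n_channels(self) -> int:
        return self.filters.shape[2]

    def to_dict(self) -> dict:
        """JSON-serializable representation (row-major with shapes)."""
        return {
            "class_labels": [str(c) for c in self.class_labels],
            "n_components": int(self.n_components),
            "shape": list(self.filters.shape),
            "filters": self.filters.ravel().tolist(),
            "patterns": self.patterns.ravel().tolist(),
            "eigenvalues": self.eigenvalues.ravel().tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpatialFilterSet":
        shape = tuple(d["shape"])
        return cls(
            filters=np.asarray(d["filters"]).reshape(shape),
            patterns=np.asarray(d["patterns"]).reshape(shape),
            eigenvalues=np.asarray(d["eigenvalues"]).reshape(shape[:2]),
            class_labels=list(d["class_labels"]),
            n_components=int(d["n_components"]),
        )


def _covariances(data: np.ndarray, labels: np.ndarray,
                 classes: list) -> tuple[np.ndarray, list[np.ndarray]]:
    """Total covariance T and per-class signal covariances S_c."""
    n_trials, n_ch, n_samp = data.shape
    total = np.zeros((n_ch, n_ch))
    for x in data:
        total += x @ x.T
    total /= n_trials * n_samp
    signals = []
    for c in classes:
        evoked = data[labels == c].mean(axis=0)
        signals.append((evoked @ evoked.T) / n_samp)
    return total, signals


def fit(epochs: EpochSet, labels: np.ndarray | None = None,
        n_components: int = DEFAULT_N_COMPONENTS) -> SpatialFilterSet:
    """Fit per-class xDAWN filters on training epochs.

    ``labels`` defaults to the epochs' condition labels; pass group labels
    (one per trial) for between-participant decoding. Classes are taken in
    sorted label order. Requires at least 2 trials per class and
    ``n_components`` <= n_channels.
    """
    labels = np.asarray(epochs.trial_labels if labels is None else labels)
    if len(labels) != epochs.n_trials:
        raise ValueError("labels length must equal trial count")
    classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 trials")
    n_ch = epochs.n_channels
    if not 1 <= n_components <= n_ch:
        raise ValueError("n_components must be in [1, n_channels]")

    total, signals = _covariances(epochs.data, labels, classes)
    # Cholesky-whiten T with diagonal loading for near-singular covariances
    eps = SHRINKAGE * np.trace(total) / n_ch
    L = linalg.cholesky(total + eps * np.eye(n_ch), lower=True)
    L_inv = linalg.solve_triangular(L, np.eye(n_ch), lower=True)

    filters = np.empty((len(classes), n_components, n_ch))
    patterns = np.empty_like(filters)
    eigenvalues = np.empty((len(classes), n_components))
    for ci, S in enumerate(signals):
        M = L_inv @ S @ L_inv.T
        M = (M + M.T) / 2.0
        evals, evecs = linalg.eigh(M)
        order = np.argsort(evals, kind="stable")[::-1][:n_components]
        for k, idx in enumerate(order):
            w = L_inv.T @ evecs[:, idx]
            w /= np.linalg.norm(w)
            # deterministic sign: first coefficient of largest magnitude > 0
            lead = np.argmax(np.abs(w))
            if w[lead] < 0:
                w = -w
            a = total @ w
            filters[ci, k] = w
            patterns[ci, k] = a / np.linalg.norm(a)
            eigenvalues[ci, k] = float(evals[idx])

    return SpatialFilterSet(filters=filters, patterns=patterns,
                            eigenvalues=eigenvalues, class_labels=classes,
                            n_components=n_components)


def transform(filterset: SpatialFilterSet, epochs: EpochSet) -> EpochSet:
    """Project trials onto the fitted filters: virtual-channel epochs.

    Output has n_classes x n_components virtual channels per trial (filters
    concatenated in class-label order); the time axis is unchanged.
    """
    if epochs.n_channels != filterset.n_channels:
        raise ValueError("channel count does not match the fitted filters")
    F = filterset.filters.reshape(-1, filterset.n_channels)
    virtual = np.einsum("vc,tcs->tvs", F, epochs.data)
    out = epochs.copy()
    out.data = virtual
    out.ch_names = [f"xdawn-{c}-{k}" for c in filterset.class_labels
                    for k in range(filterset.n_components)]
    return out
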