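"""Per-participant peak metrics and between-group inference.

From each participant's decoding trajectory we extract the maximum
fold-mean score and the time at which it occurs (earliest window wins
ties). Group comparison follows a normality gate: if every group passes
Shapiro-Wilk at alpha = 0.05, a one-way ANOVA with all-pairs Welch t tests;
otherwise a tie-corrected Kruskal-Wallis omnibus with Dunn's z tests on
mean ranks. Post-hoc p-values are Benjamini-Hochberg adjusted within the
family, and post-hocs are only computed when the omnibus rejects.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decoder import DecodeTrajectory

__all__ = [
    "PeakMetrics",
    "GroupStatsResult",
    "extract_peak",
    "normality_gate",
    "omnibus_and_posthoc",
    "fdr_adjust",
    "dunn_posthoc",
]


@dataclass(frozen=True)
class PeakMetrics:
    """One participant's peak decoding performance and its latency."""

    participant_id: str
    group_label: str
    max_score: float
    peak_time: float                     # seconds
    significant: bool


@dataclass
class GroupStatsResult:
    """Omnibus test, optional post-hocs, and the normality-gate record."""

    omnibus: dict                        # test, statistic, df, p
    posthoc: dict[tuple[str, str], dict] | None
    normality_gate: dict                 # per-group p-values + route

    def __post_init__(self):
        if self.posthoc is not None:
            for pair, res in self.posthoc.items():
                if res["p_fdr"] + 1e-12 < res["p_raw"]:
                    raise ValueError(f"p_fdr < p_raw for {pair}")


def extract_peak(trajectory: DecodeTrajectory,
                 threshold: float | None = None) -> PeakMetrics:
    """Maximum of the fold-mean curve; earliest window wins ties.

    ``significant`` is True when the peak strictly exceeds ``threshold``
    (False when no threshold is supplied).
    """
    curve = trajectory.mean_curve
    if curve.size == 0:
        raise ValueError("empty trajectory")
    idx = int(np.argmax(curve))          # argmax returns the first maximum
    peak = float(curve[idx])
    return PeakMetrics(
        participant_id=trajectory.participant_id,
        group_label=trajectory.group_label,
        max_score=peak,
        peak_time=float(trajectory.window_centers[idx]),
        significant=bool(threshold is not None and peak > threshold),
    )


def normality_gate(values_by_group: dict[str, np.ndarray],
                   alpha: float = 0.05) -> tuple[str, dict[str, float]]:
    """Shapiro-Wilk per group; parametric only if every group passes.

    Degenerate (zero-variance) groups route to nonparametric. Returns
    ``(route, per-group p-values)`` with route in
    {"parametric", "nonparametric"}.
    """
    pvals: dict[str, float] = {}
    route = "parametric"
    for g, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")
        if np.ptp(vals) == 0:
            pvals[g] = 0.0
            route = "nonparametric"
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.shapiro(vals).pvalue)
        pvals[g] = p
        if p < alpha:
            route = "nonparametric"
    return route, pvals


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def dunn_posthoc(values_by_group: dict[str, np.ndarray]
                 ) -> dict[tuple[str, str], dict]:
    """Dunn's all-pairs z tests on mean ranks, with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups; two-sided normal p.
    """
    groups = sorted(values_by_group)
    pooled = np.concatenate([np.asarray(values_by_group[g], dtype=float)
                             for g in groups])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks, sizes = {}, {}
    pos = 0
    for g in groups:
        n = len(values_by_group[g])
        mean_ranks[g] = ranks[pos:pos + n].mean()
        sizes[g] = n
        pos += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 *
                                                            (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    out = {}
    for a, b in itertools.combinations(groups, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else np.inf
        out[(a, b)] = {"statistic": float(z),
                       "p_raw": float(2.0 * stats.norm.sf(abs(z)))}
    return out


def omnibus_and_posthoc(values_by_group: dict[str, np.ndarray],
                        route: str | None = None,
                        alpha: float = 0.05) -> GroupStatsResult:
    """Omnibus group comparison with FDR-adjusted post-hocs.

    ``route`` is decided by :func:`normality_gate` when not supplied.
    Parametric: one-way ANOVA then all-pairs Welch t tests; nonparametric:
    Kruskal-Wallis then Dunn's tests. Post-hocs are computed only when the
    omnibus p-value is below ``alpha``.
    """
    groups = sorted(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")

    if route is None:
        route, gate_p = normality_gate(values_by_group, alpha)
    else:
        gate_p = {}
    gate = {"route": route, "p_values": gate_p}

    n_total = sum(len(a) for a in arrays)
    k = len(groups)
    if route == "parametric":
        f, p = stats.f_oneway(*arrays)
        omnibus = {"test": "anova", "statistic": float(f),
                   "df": (k - 1, n_total - k), "p": float(p)}
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h, p = stats.kruskal(*arrays)
        omnibus = {"test": "kruskal", "statistic": float(h),
                   "df": k - 1, "p": float(p)}

    posthoc = None
    if omnibus["p"] < alpha:
        if route == "parametric":
            posthoc = {}
            for (a, va), (b, vb) in itertools.combinations(
                    zip(groups, arrays), 2):
                t, p_raw = stats.ttest_ind(va, vb, equal_var=False)
                posthoc[(a, b)] = {"statistic": float(t),
                                   "p_raw": float(p_raw)}
        else:
            posthoc = dunn_posthoc(values_by_group)
        raw = np.array([posthoc[pair]["p_raw"] for pair in posthoc])
        adj = fdr_adjust(raw)
        for pair, p_adj in zip(posthoc, adj):
            posthoc[pair]["p_fdr"] = float(p_adj)

    return GroupStatsResult(omnibus=omnibus, posthoc=posthoc,
                            normality_gate=gate)
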