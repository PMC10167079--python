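"""Run configuration and the end-to-end pipeline runner.

``RunConfig`` is a schema-validated document (unknown keys rejected)
holding every tunable of the chain simulate -> prep -> decode ->
significance -> group stats. :func:`run_full_pipeline` executes the chain,
writes tidy CSV/JSON artifacts plus a provenance manifest, and is
deterministic under a fixed seed: all randomness flows from
``RunConfig.seed`` through named substreams (simgen, cv, subsample,
permutation).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import decoder, groupstats, prep, sigtest
from .simgen import (SimConfig, make_default_config, make_null_config,
                     make_scaled_config, simulate_dataset)

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_full_pipeline",
    "smoke_config",
    "scaled_config",
    "derive_seed",
]

log = logging.getLogger("erpmvpa")

_SUBSTREAMS = {"simgen": 0, "cv": 1, "subsample": 2, "permutation": 3}


def derive_seed(master: int, name: str) -> int:
    """Named substream seed derived deterministically from the master."""
    ss = np.random.SeedSequence([int(master), _SUBSTREAMS[name]])
    return int(ss.generate_state(1)[0]) % (2**31)


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimSection(_Section):
    preset: str = "scaled"               # default | scaled | null
    n_groups: int | None = Field(default=None, ge=1, le=6)
    n_per_group: int | None = Field(default=None, ge=1)
    trials_per_condition: int | None = Field(default=None, ge=1)
    sfreq: float | None = Field(default=None, gt=0)
    snr_scale: float | None = Field(default=None, ge=0)
    noise_sd: float | None = Field(default=None, ge=0)


class PrepSection(_Section):
    enabled: bool = True
    l_freq: float = Field(default=1.0, gt=0)
    h_freq: float = Field(default=40.0, gt=0)
    sfreq: float = Field(default=256.0, gt=0)
    tmin_ms: float = -100.0
    tmax_ms: float = 800.0
    min_trials: int = Field(default=35, ge=0)


class DecodeSection(_Section):
    n_components: int = Field(default=5, ge=1)
    window_length: int = Field(default=20, ge=2)
    window_step: int = Field(default=1, ge=1)
    n_folds: int = Field(default=10, ge=2)
    n_splits: int = Field(default=10, ge=2)
    test_fraction: float = Field(default=0.20, gt=0, lt=1)
    group_time_resolved: bool = False


class StatsSection(_Section):
    alpha: float = Field(default=0.05, gt=0, lt=1)
    n_permutations: int = Field(default=100, ge=1)


class RunConfig(_Section):
    """All pipeline parameters in one validated document."""

    seed: int = 0
    sim: SimSection = SimSection()
    prep: PrepSection = PrepSection()
    decode: DecodeSection = DecodeSection()
    stats: StatsSection = StatsSection()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls.model_validate(yaml.safe_load(f) or {})

    def config_hash(self) -> str:
        doc = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def smoke_config(seed: int = 0) -> RunConfig:
    """Tiny end-to-end configuration: 2 groups x 4 participants, 32 Hz."""
    return RunConfig(
        seed=seed,
        sim=SimSection(preset="scaled", n_groups=2, n_per_group=4,
                       trials_per_condition=20, sfreq=32.0),
        prep=PrepSection(l_freq=1.0, h_freq=12.0, sfreq=32.0, min_trials=5),
        decode=DecodeSection(window_length=8, window_step=4, n_folds=2,
                             n_splits=4, group_time_resolved=True),
        stats=StatsSection(n_permutations=20),
    )


def scaled_config(seed: int = 0) -> RunConfig:
    """Desk-scale analogue of the full study (6 x 12 participants, 64 Hz)."""
    return RunConfig(
        seed=seed,
        sim=SimSection(preset="scaled"),
        prep=PrepSection(l_freq=1.0, h_freq=20.0, sfreq=64.0, min_trials=35),
        decode=DecodeSection(window_length=10, window_step=2),
        stats=StatsSection(n_permutations=50),
    )


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.message = message

    def record(self) -> dict:
        return {"stage": self.stage, "error": self.message}


def _build_sim_config(cfg: RunConfig) -> SimConfig:
    sim_seed = derive_seed(cfg.seed, "simgen")
    s = cfg.sim
    if s.preset == "default":
        base = make_default_config(seed=sim_seed)
    elif s.preset == "scaled":
        base = make_scaled_config(
            seed=sim_seed,
            n_per_group=s.n_per_group or 12,
            trials_per_condition=s.trials_per_condition or 50,
            sfreq=s.sfreq or 64.0,
            n_groups=s.n_groups or 6)
    elif s.preset == "null":
        base = make_null_config(
            seed=sim_seed,
            n_participants=s.n_per_group or 40,
            trials_per_condition=s.trials_per_condition or 50,
            sfreq=s.sfreq or 32.0)
    else:
        raise PipelineError("simulate", f"unknown sim preset {s.preset!r}")
    updates = {}
    if s.snr_scale is not None:
        updates["snr_scale"] = s.snr_scale
    if s.noise_sd is not None:
        updates["noise_sd"] = s.noise_sd
    return dataclasses.replace(base, **updates) if updates else base


FLOAT_FMT = "%.12g"


def _write_json(obj, path: Path):
    with open(path, "w") as f:
        json.dump(obj, f, indent=1, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return [float(f"{v:.12g}") for v in o.ravel()]
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_full_pipeline(config: RunConfig, out_dir: str | Path | None = None,
                      dataset=None, plots: bool = False) -> dict:
    """simulate (or ingest) -> prep -> decode -> thresholds -> stats.

    Returns a results bundle (dict) and, when ``out_dir`` is given, writes
    CSV/JSON artifacts plus a provenance manifest there. Any stage failure
    raises :class:`PipelineError` naming the stage.
    """
    results: dict = {"config": config.model_dump(),
                     "config_hash": config.config_hash()}

    # ---- simulate ----------------------------------------------------
    if dataset is None:
        try:
            sim_cfg = _build_sim_config(config)
            dataset = simulate_dataset(sim_cfg)
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError("simulate", str(e)) from e
    log.info("simulate: %d participants", len(dataset))

    # ---- prep --------------------------------------------------------
    try:
        if config.prep.enabled:
            params = prep.PrepParams(
                l_freq=config.prep.l_freq, h_freq=config.prep.h_freq,
                sfreq=config.prep.sfreq, tmin_ms=config.prep.tmin_ms,
                tmax_ms=config.prep.tmax_ms,
                min_trials=config.prep.min_trials)
            kept, qc = prep.run_prep(dataset, params)
        else:
            kept, qc = prep.apply_min_trial_filter(dataset,
                                                   config.prep.min_trials)
    except Exception as e:
        raise PipelineError("prep", str(e)) from e
    for r in qc:
        if r.excluded:
            log.info("prep: excluded %s (%s)", r.participant_id,
                     r.exclusion_reason)
    if not kept:
        raise PipelineError(
            "prep", f"all {len(qc)} participants excluded by QC "
            f"(min_trials={config.prep.min_trials})")
    results["qc"] = [dataclasses.asdict(r) for r in qc]

    groups = sorted({ep.group_label for ep in kept})
    dec = config.decode
    window = decoder.WindowSpec(dec.window_length, dec.window_step)

    # ---- group decoding ----------------------------------------------
    if len(groups) >= 2:
        try:
            plan = decoder.CVPlan(mode="between_participants",
                                  n_folds_or_splits=dec.n_folds,
                                  seed=derive_seed(config.seed, "cv"))
            conf = decoder.decode_whole_trial(kept, plan, dec.n_components)
            n_total = int(sum(ep.n_trials for ep in kept))
            thr = sigtest.binomial_threshold(n_total, len(groups),
                                             config.stats.alpha)
            results["group_decoding"] = {
                "confusion_matrix": conf.matrix.tolist(),
                "class_labels": conf.class_labels,
                "accuracy": conf.accuracy,
                "precision": conf.precision.tolist(),
                "recall": conf.recall.tolist(),
                "binomial_threshold": thr,
                "n_trials": n_total,
                "above_chance": conf.accuracy > thr,
            }
            if dec.group_time_resolved:
                traj = decoder.decode_time_resolved(kept, plan, window)
                results["group_trajectory"] = {
                    "window_centers_s": traj.window_centers,
                    "mean_curve": traj.mean_curve,
                    "ci95": traj.ci95,
                }
        except Exception as e:
            raise PipelineError("decode-group", str(e)) from e

    # ---- task decoding + permutation thresholds ----------------------
    try:
        plan_w = decoder.CVPlan(mode="within_participant",
                                n_folds_or_splits=dec.n_splits,
                                test_fraction=dec.test_fraction,
                                seed=derive_seed(config.seed, "cv"))
        stat_fn = sigtest.make_within_stat_fn(plan_w, window,
                                              dec.n_components)
        trajectories, nulls = [], []
        perm_master = derive_seed(config.seed, "permutation")
        for pi, ep in enumerate(kept):
            traj = decoder.decode_time_resolved(
                ep, plan_w, window=window, metric="auc",
                n_components=dec.n_components)
            trajectories.append(traj)
            nulls.append(sigtest.permutation_null(
                ep, stat_fn, config.stats.n_permutations,
                seed=int(np.random.SeedSequence(
                    [perm_master, pi]).generate_state(1)[0]) % (2**31)))
        sig = sigtest.group_threshold(nulls, config.stats.alpha)
        peaks = [groupstats.extract_peak(t, sig.threshold)
                 for t in trajectories]
        results["task_decoding"] = {
            "permutation_threshold": sig.threshold,
            "n_permutations": config.stats.n_permutations,
            "fraction_above_chance": float(
                np.mean([p.significant for p in peaks])),
            "peaks": [dataclasses.asdict(p) for p in peaks],
        }
        results["_trajectories"] = trajectories
    except Exception as e:
        raise PipelineError("decode-task", str(e)) from e

    # ---- group statistics on peak metrics ----------------------------
    if len(groups) >= 2 and all(
            sum(p.group_label == g for p in peaks) >= 3 for g in groups):
        try:
            stats_out = {}
            for field_name in ("max_score", "peak_time"):
                values = {g: np.array([getattr(p, field_name)
                                       for p in peaks
                                       if p.group_label == g])
                          for g in groups}
                res = groupstats.omnibus_and_posthoc(
                    values, alpha=config.stats.alpha)
                stats_out[field_name] = {
                    "omnibus": res.omnibus,
                    "normality_gate": res.normality_gate,
                    "posthoc": None if res.posthoc is None else {
                        f"{a}|{b}": v for (a, b), v in res.posthoc.items()},
                }
            results["group_stats"] = stats_out
        except Exception as e:
            raise PipelineError("stats", str(e)) from e

    if out_dir is not None:
        _write_artifacts(results, Path(out_dir), plots)
    results.pop("_trajectories", None)
    return results


def _write_artifacts(results: dict, out: Path, plots: bool):
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(results["qc"]).to_csv(out / "qc.csv", index=False)
    if "group_decoding" in results:
        _write_json(results["group_decoding"], out / "group_decoding.json")
    if "group_trajectory" in results:
        g = results["group_trajectory"]
        pd.DataFrame({
            "window_center_s": g["window_centers_s"],
            "mean_accuracy": g["mean_curve"],
            "ci95": g["ci95"],
        }).to_csv(out / "group_trajectory.csv", index=False,
                  float_format=FLOAT_FMT)
    task = results["task_decoding"]
    pd.DataFrame(task["peaks"]).to_csv(out / "peaks.csv", index=False,
                                       float_format=FLOAT_FMT)
    _write_json({k: v for k, v in task.items() if k != "peaks"},
                out / "task_decoding.json")
    rows = []
    for t in results.get("_trajectories", []):
        for wi, c in enumerate(t.window_centers):
            for fi in range(t.scores.shape[1]):
                rows.append((t.participant_id, t.group_label, fi,
                             c, t.metric, t.scores[wi, fi]))
    if rows:
        pd.DataFrame(rows, columns=["participant", "group", "fold",
                                    "window_center_s", "metric", "score"]
                     ).to_csv(out / "task_trajectories.csv", index=False,
                              float_format=FLOAT_FMT)
    if "group_stats" in results:
        _write_json(results["group_stats"], out / "group_stats.json")
    manifest = {"config": results["config"],
                "config_hash": results["config_hash"],
                "artifacts": sorted(p.name for p in out.iterdir()
                                    if p.name != "manifest.json")}
    _write_json(manifest, out / "manifest.json")
    _write_report(results, out / "report.txt")
    if plots:
        _write_plots(results, out)


def _write_report(results: dict, path: Path):
    lines = ["erpmvpa pipeline report", "=" * 24, ""]
    excluded = [r for r in results["qc"] if r["excluded"]]
    lines.append(f"participants analyzed: {len(results['qc']) - len(excluded)}"
                 f" (excluded: {len(excluded)})")
    if "group_decoding" in results:
        g = results["group_decoding"]
        lines += ["",
                  f"group decoding accuracy: {g['accuracy']:.3f} "
                  f"(binomial chance threshold "
                  f"{g['binomial_threshold']:.3f}, "
                  f"n={g['n_trials']} trials)"]
    t = results["task_decoding"]
    lines += ["",
              f"task decoding: permutation threshold "
              f"{t['permutation_threshold']:.3f} "
              f"({t['n_permutations']} permutations); "
              f"{100 * t['fraction_above_chance']:.2f}% of participants "
              f"above chance"]
    if "group_stats" in results:
        for name, s in results["group_stats"].items():
            o = s["omnibus"]
            lines.append(f"{name}: {o['test']} statistic={o['statistic']:.3f}"
                         f" p={o['p']:.4g}")
    path.write_text("\n".join(lines) + "\n")


def _write_plots(results: dict, out: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "group_decoding" in results:
        g = results["group_decoding"]
        fig, ax = plt.subplots()
        m = np.asarray(g["confusion_matrix"], dtype=float)
        ax.imshow(m / m.sum(axis=1, keepdims=True), cmap="viridis")
        ax.set_xticks(range(len(g["class_labels"])), g["class_labels"],
                      rotation=45)
        ax.set_yticks(range(len(g["class_labels"])), g["class_labels"])
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.set_title(f"group decoding (acc {g['accuracy']:.2f})")
        fig.tight_layout()
        fig.savefig(out / "confusion.png", dpi=120)
        plt.close(fig)
    if "group_trajectory" in results:
        g = results["group_trajectory"]
        fig, ax = plt.subplots()
        c = np.asarray(g["window_centers_s"])
        mu = np.asarray(g["mean_curve"])
        ci = np.asarray(g["ci95"])
        ax.plot(c, mu)
        ax.fill_between(c, mu - ci, mu + ci, alpha=0.3)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("accuracy")
        fig.tight_layout()
        fig.savefig(out / "group_trajectory.png", dpi=120)
        plt.close(fig)
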