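"""On-disk epoch container: one directory per dataset.

Each participant is stored as a raw little-endian float64 binary array
(row-major, trials x channels x samples, microvolts) next to a JSON sidecar
carrying sampling rate, channel names, the time axis and the trial table
(condition, correctness, reaction time). A dataset manifest lists every
participant file with a SHA-256 checksum, the creation seed and an optional
configuration hash. Round trips are bit-exact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .simgen import EpochSet

__all__ = ["write_container", "read_container", "ContainerError"]

MANIFEST_NAME = "manifest.json"
DTYPE = "<f8"                      # little-endian float64, row-major


class ContainerError(RuntimeError):
    """Malformed or inconsistent epoch container."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_container(dataset: list[EpochSet], path: str | Path,
                    seed: int | None = None,
                    config_hash: str | None = None) -> Path:
    """Write a dataset; participant order is preserved in the manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, ep in enumerate(dataset):
        stem = f"p{i:04d}"
        bin_path = path / f"{stem}.bin"
        np.ascontiguousarray(ep.data, dtype=DTYPE).tofile(bin_path)
        sidecar = {
            "participant_id": ep.participant_id,
            "group_label": ep.group_label,
            "sfreq": ep.sfreq,
            "ch_names": list(ep.ch_names),
            "times": ep.times.tolist(),
            "shape": list(ep.data.shape),
            "dtype": DTYPE,
            "trials": [
                {"condition": str(c), "correct": bool(ok), "rt_ms": float(rt)}
                for c, ok, rt in zip(ep.trial_labels, ep.correctness, ep.rt)
            ],
        }
        with open(path / f"{stem}.json", "w") as f:
            json.dump(sidecar, f)
        entries.append({"stem": stem,
                        "participant_id": ep.participant_id,
                        "sha256": _sha256(bin_path)})
    manifest = {"format": "erpmvpa-epochs-v1",
                "participants": entries,
                "seed": seed,
                "config_hash": config_hash}
    with open(path / MANIFEST_NAME, "w") as f:
        json.dump(manifest, f, indent=1)
    return path


def read_container(path: str | Path) -> list[EpochSet]:
    """Read a dataset back, validating shapes and checksums."""
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        raise ContainerError(f"missing manifest: {manifest_path}")
    with open(manifest_path) as f:
        manifest = json.load(f)
    dataset = []
    for entry in manifest["participants"]:
        stem = entry["stem"]
        bin_path = path / f"{stem}.bin"
        sidecar_path = path / f"{stem}.json"
        if not sidecar_path.exists():
            raise ContainerError(f"missing sidecar: {sidecar_path}")
        if not bin_path.exists():
            raise ContainerError(f"missing binary payload: {bin_path}")
        if _sha256(bin_path) != entry["sha256"]:
            raise ContainerError(f"checksum mismatch for {bin_path}")
        with open(sidecar_path) as f:
            sc = json.load(f)
        shape = tuple(sc["shape"])
        data = np.fromfile(bin_path, dtype=sc["dtype"])
        if data.size != int(np.prod(shape)):
            raise ContainerError(
                f"{bin_path}: payload has {data.size} values, sidecar "
                f"declares shape {shape}")
        trials = sc["trials"]
        if len(trials) != shape[0]:
            raise ContainerError(f"{sidecar_path}: trial table length "
                                 f"{len(trials)} != {shape[0]} trials")
        dataset.append(EpochSet(
            data=data.reshape(shape),
            sfreq=float(sc["sfreq"]),
            times=np.asarray(sc["times"], dtype=float),
            trial_labels=np.array([t["condition"] for t in trials]),
            correctness=np.array([t["correct"] for t in trials], dtype=bool),
            rt=np.array([t["rt_ms"] for t in trials], dtype=float),
            participant_id=sc["participant_id"],
            group_label=sc["group_label"],
            ch_names=list(sc["ch_names"]),
        ))
    return dataset
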