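"""Plain-text interchange for epochs, schedules, ratings and results.

Epochs are stored as one delimited matrix file per participant — the
trials x channels x samples tensor flattened to (trials * channels)
rows by samples columns — together with a JSON sidecar carrying the
sampling rate, epoch geometry, condition labels and group membership.
Schedules, ratings and result tables are CSV; configs and reports are
JSON/YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from msconn.preprocess import EpochedData

__all__ = ["write_epochs", "read_epochs", "write_cohort", "read_cohort"]

_SIDE_SUFFIX = ".json"
_DATA_SUFFIX = ".tsv"


def write_epochs(epochs: EpochedData, path: str | Path) -> tuple[Path, Path]:
    """Write one participant's epochs as ``<path>.tsv`` + ``<path>.json``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data_path = path.with_suffix(_DATA_SUFFIX)
    side_path = path.with_suffix(_SIDE_SUFFIX)
    n_trials, n_channels, n_samples = epochs.data.shape
    flat = epochs.data.reshape(n_trials * n_channels, n_samples)
    np.savetxt(data_path, flat, delimiter="\t", fmt="%.10g")
    sidecar = {
        "participant_id": epochs.participant_id,
        "group": epochs.group,
        "sampling_rate": epochs.sampling_rate,
        "time_start_ms": float(epochs.times[0]),
        "n_trials": int(n_trials),
        "n_channels": int(n_channels),
        "n_samples": int(n_samples),
        "conditions": [str(c) for c in epochs.conditions],
        "trial_ids": [int(t) for t in epochs.trial_ids],
        "units": "uV",
    }
    side_path.write_text(json.dumps(sidecar, indent=2))
    return data_path, side_path


def read_epochs(path: str | Path) -> EpochedData:
    """Read epochs written by :func:`write_epochs` (path with or
    without suffix)."""
    path = Path(path)
    stem = path.with_suffix("")
    data_path = stem.with_suffix(_DATA_SUFFIX)
    side_path = stem.with_suffix(_SIDE_SUFFIX)
    if not data_path.exists() or not side_path.exists():
        raise FileNotFoundError(f"missing epoch files for {stem}")
    if data_path.stat().st_size == 0:
        raise ValueError(f"empty epoch data file: {data_path}")
    meta = json.loads(side_path.read_text())
    required = {"sampling_rate", "n_trials", "n_channels", "n_samples", "conditions"}
    missing = required - set(meta)
    if missing:
        raise ValueError(f"sidecar {side_path} missing keys: {sorted(missing)}")
    if len(meta["conditions"]) != meta["n_trials"]:
        raise ValueError(
            f"sidecar {side_path}: {meta['n_trials']} trials but "
            f"{len(meta['conditions'])} condition labels"
        )
    flat = np.loadtxt(data_path, delimiter="\t", ndmin=2)
    expected = (meta["n_trials"] * meta["n_channels"], meta["n_samples"])
    if flat.shape != expected:
        raise ValueError(
            f"{data_path}: shape {flat.shape} does not match sidecar {expected}"
        )
    data = flat.reshape(meta["n_trials"], meta["n_channels"], meta["n_samples"])
    step = 1000.0 / meta["sampling_rate"]
    times = meta.get("time_start_ms", 0.0) + step * np.arange(meta["n_samples"])
    return EpochedData(
        data=data,
        sampling_rate=meta["sampling_rate"],
        times=times,
        conditions=np.array(meta["conditions"]),
        participant_id=meta.get("participant_id", "p0"),
        group=meta.get("group", "control"),
        trial_ids=np.array(meta.get("trial_ids", list(range(meta["n_trials"])))),
    )


def write_cohort(cohort: list[EpochedData], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for epochs in cohort:
        p, _ = write_epochs(epochs, out_dir / f"{epochs.participant_id}_epochs")
        paths.append(p)
    return paths


def read_cohort(in_dir: str | Path) -> list[EpochedData]:
    in_dir = Path(in_dir)
    stems = sorted(p.with_suffix("") for p in in_dir.glob(f"*_epochs{_DATA_SUFFIX}"))
    if not stems:
        raise FileNotFoundError(f"no *_epochs{_DATA_SUFFIX} files in {in_dir}")
    return [read_epochs(s) for s in stems]
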