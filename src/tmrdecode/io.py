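"""Reading and writing synthetic cohorts.

A cohort directory contains, per participant, one HDF5 epoch container per
state (variable-length sleep trials rule out fixed-epoch formats), plus one
tab-separated behavior table and one JSON truth file for the whole cohort:

    cohort/
        sub-00_sleep.h5
        sub-00_wake.h5
        ...
        behavior.tsv        # participant, session, sequence, block, rt_ms
        truth.json          # per-participant ground-truth parameters
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .epochs import EpochSet
from .synthetic import ParticipantRecord

__all__ = ["save_epochs_h5", "load_epochs_h5", "save_cohort", "load_behavior"]


def save_epochs_h5(epochs: EpochSet, path: str | Path) -> None:
    """Write an EpochSet to one HDF5 file (one dataset per trial)."""
    with h5py.File(path, "w") as f:
        f.attrs["state"] = epochs.state
        f.attrs["rate"] = epochs.rate
        f.attrs["tmin"] = epochs.tmin
        f.attrs["channel_names"] = [str(n) for n in epochs.channel_names]
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset(
            "condition", data=np.array(epochs.condition, dtype="S16")
        )
        f.create_dataset("lengths_s", data=epochs.lengths_s)
        g = f.create_group("trials")
        for i, t in enumerate(epochs.trials):
            g.create_dataset(f"{i:04d}", data=t)
        m = f.create_group("meta")
        for k, v in epochs.meta.items():
            m.create_dataset(k, data=np.asarray(v))


def load_epochs_h5(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        trials = [f["trials"][k][()] for k in sorted(f["trials"])]
        meta = {k: f["meta"][k][()] for k in f["meta"]}
        return EpochSet(
            trials=trials,
            labels=f["labels"][()],
            state=str(f.attrs["state"]),
            rate=float(f.attrs["rate"]),
            channel_names=[str(n) for n in f.attrs["channel_names"]],
            condition=np.array([c.decode() for c in f["condition"][()]]),
            tmin=float(f.attrs["tmin"]),
            lengths_s=f["lengths_s"][()],
            meta=meta,
        )


def save_cohort(records: list[ParticipantRecord], out_dir: str | Path) -> None:
    """Write a generated cohort to ``out_dir`` (created if needed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = {}
    tables = []
    for rec in records:
        pid = rec.truth.participant_id
        save_epochs_h5(rec.sleep, out / f"sub-{pid:02d}_sleep.h5")
        save_epochs_h5(rec.wake, out / f"sub-{pid:02d}_wake.h5")
        tables.append(rec.behavior)
        spec = rec.truth.reactivation
        truth[str(pid)] = {
            "seed": rec.truth.seed,
            "behavior_slope_ms": rec.truth.behavior_slope_ms,
            "compression_factor": spec.compression_factor,
            "embed_probability": spec.embed_probability,
            "snr": spec.snr,
            "latency_window": list(spec.latency_window),
            "spindle_coupling": spec.spindle_coupling,
            "baseline_burst_rate": spec.baseline_burst_rate,
        }
    pd.concat(tables, ignore_index=True).to_csv(
        out / "behavior.tsv", sep="\t", index=False
    )
    (out / "truth.json").write_text(json.dumps(truth, indent=2))


def load_behavior(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated behavior table."""
    return pd.read_csv(path, sep="\t")
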