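"""Study container I/O.

A study on disk is one HDF5 file per participant (datasets ``data``
[trials x channels x samples], ``times``, ``reference``; attrs ``fs``,
``participant``), a single tab-separated metadata table covering all
participants, and a JSON ground-truth sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import TrialSet
from .simulate import Participant, SimConfig, SimulatedStudy

METADATA_FILE = "metadata.tsv"
TRUTH_FILE = "ground_truth.json"


def save_study(study: SimulatedStudy, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_frames = []
    truth = {"config": _config_dict(study.config), "participants": {}}
    for part in study.participants:
        ts = part.trials
        with h5py.File(outdir / f"{ts.participant}.h5", "w") as f:
            f.create_dataset("data", data=ts.data)
            f.create_dataset("times", data=ts.times)
            f.create_dataset("reference", data=part.reference)
            f.attrs["fs"] = ts.fs
            f.attrs["participant"] = ts.participant
        meta_frames.append(ts.metadata)
        gt = part.ground_truth
        truth["participants"][ts.participant] = {
            "phase0": np.asarray(gt["phase0"]).tolist(),
            "patterns": {k: v.tolist() for k, v in gt["patterns"].items()},
            "target_pref_phase": gt["target_pref_phase"],
            "competitor_pref_phase": gt["competitor_pref_phase"],
        }
    pd.concat(meta_frames, ignore_index=True).to_csv(
        outdir / METADATA_FILE, sep="\t", index=False
    )
    (outdir / TRUTH_FILE).write_text(json.dumps(truth))
    return outdir


def load_study(indir) -> SimulatedStudy:
    indir = Path(indir)
    meta = pd.read_csv(indir / METADATA_FILE, sep="\t", keep_default_na=False)
    truth_path = indir / TRUTH_FILE
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    config = SimConfig(**truth["config"]) if "config" in truth else None

    participants = []
    for path in sorted(indir.glob("*.h5")):
        with h5py.File(path, "r") as f:
            pid = f.attrs["participant"]
            ts = TrialSet(
                data=f["data"][()],
                fs=float(f.attrs["fs"]),
                times=f["times"][()],
                metadata=meta[meta["participant"] == pid].reset_index(drop=True),
                participant=str(pid),
            )
            reference = f["reference"][()]
        gt = truth.get("participants", {}).get(str(pid), {})
        if "patterns" in gt:
            gt = dict(gt)
            gt["patterns"] = {k: np.asarray(v) for k, v in gt["patterns"].items()}
            gt["phase0"] = np.asarray(gt["phase0"])
        participants.append(Participant(trials=ts, reference=reference,
                                        ground_truth=gt))
    return SimulatedStudy(config=config, participants=participants,
                          ground_truth=truth.get("config", {}))


def _config_dict(config: SimConfig) -> dict:
    from dataclasses import asdict

    d = asdict(config)
    d["epoch_window"] = tuple(d["epoch_window"])
    d["activation_window"] = tuple(d["activation_window"])
    return d
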