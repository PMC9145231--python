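"""On-disk fixture sets for simulated participants.

Layout per participant directory:

* ``eeg.h5``     — epochs (trials x channels x samples), times, sfreq,
                   channel names, gain matrix + source positions, ROI members
* ``events.tsv`` — BIDS-style trial table (onset, duration, trial_type,
                   learned, block, artifact, run, item)
* ``bold.tsv``   — long-format ROI series (run, volume, roi, value)
* ``motion.tsv`` — six synthetic realignment parameters per volume
* ``behavior.tsv`` — final-test recall table
* ``truth.h5``   — per-trial latent ground truth
* ``manifest.json`` — file list with SHA-256 checksums

Round trips are bit-exact: arrays are stored without compression or scaling.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochedEEG, GainMatrix
from .synth import ROI_NAMES, SimulatedParticipant


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_set(part: SimulatedParticipant, directory: str | Path) -> dict:
    """Write one participant's dataset; returns the manifest dict."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    with h5py.File(d / "eeg.h5", "w") as f:
        f.create_dataset("epochs/data", data=part.epochs.data)
        f.create_dataset("epochs/times_ms", data=part.epochs.times)
        f.attrs["sfreq"] = part.epochs.sfreq
        f.create_dataset(
            "epochs/ch_names",
            data=np.array(part.epochs.ch_names, dtype="S"),
        )
        f.create_dataset("gain/matrix", data=part.gain.matrix)
        f.create_dataset("gain/positions", data=part.gain.positions)
        for roi in ROI_NAMES:
            f.create_dataset(f"roi_members/{roi}",
                             data=np.asarray(part.roi_members[roi]))

    ev = part.events.copy()
    ev["onset"] = ev["onset_s"]
    ev["duration"] = 3.0
    ev["trial_type"] = ev["condition"]
    ev[["onset", "duration", "trial_type", "learned", "block", "artifact",
        "run", "item"]].to_csv(d / "events.tsv", sep="\t", index=False)

    n_runs, n_vols, n_roi = part.bold_runs.shape
    rows = {
        "run": np.repeat(np.arange(n_runs), n_vols * n_roi),
        "volume": np.tile(np.repeat(np.arange(n_vols), n_roi), n_runs),
        "roi": np.tile(list(ROI_NAMES), n_runs * n_vols),
        "value": part.bold_runs.reshape(-1),
    }
    pd.DataFrame(rows).to_csv(d / "bold.tsv", sep="\t", index=False,
                              float_format="%.17g")
    mot = pd.DataFrame(
        part.motion.reshape(-1, 6), columns=[f"m{i}" for i in range(6)]
    )
    mot.insert(0, "run", np.repeat(np.arange(n_runs), n_vols))
    mot.to_csv(d / "motion.tsv", sep="\t", index=False, float_format="%.17g")

    part.behavior.to_csv(d / "behavior.tsv", sep="\t", index=False)

    with h5py.File(d / "truth.h5", "w") as f:
        for key in ("early_control", "conflict", "n2_amp", "n2_latency_ms",
                    "hipp_env"):
            f.create_dataset(key, data=np.asarray(part.truth[key]))
        f.attrs["participant_factor"] = part.truth["participant_factor"]

    files = ["eeg.h5", "events.tsv", "bold.tsv", "motion.tsv",
             "behavior.tsv", "truth.h5"]
    manifest = {
        "participant": part.index,
        "files": {name: _sha256(d / name) for name in files},
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_fixture_set(directory: str | Path) -> dict:
    """Read a fixture directory back into arrays/frames (bit-exact)."""
    d = Path(directory)
    out: dict = {}
    with h5py.File(d / "eeg.h5", "r") as f:
        data = f["epochs/data"][()]
        times = f["epochs/times_ms"][()]
        sfreq = float(f.attrs["sfreq"])
        ch_names = [s.decode() for s in f["epochs/ch_names"][()]]
        gain = GainMatrix(matrix=f["gain/matrix"][()],
                          positions=f["gain/positions"][()],
                          ch_names=ch_names)
        out["roi_members"] = {roi: f[f"roi_members/{roi}"][()].tolist()
                              for roi in ROI_NAMES}
    events = pd.read_csv(d / "events.tsv", sep="\t")
    events["onset_s"] = events["onset"]
    events["condition"] = events["trial_type"]
    out["epochs"] = EpochedEEG(data=data, sfreq=sfreq, times=times,
                               ch_names=ch_names, metadata=events)
    out["gain"] = gain
    out["events"] = events
    bold = pd.read_csv(d / "bold.tsv", sep="\t", float_precision="round_trip")
    n_runs = bold["run"].nunique()
    n_vols = bold["volume"].nunique()
    out["bold_runs"] = bold["value"].to_numpy().reshape(
        n_runs, n_vols, len(ROI_NAMES)
    )
    mot = pd.read_csv(d / "motion.tsv", sep="\t", float_precision="round_trip")
    out["motion"] = mot[[f"m{i}" for i in range(6)]].to_numpy().reshape(
        n_runs, n_vols, 6
    )
    out["behavior"] = pd.read_csv(d / "behavior.tsv", sep="\t")
    with h5py.File(d / "truth.h5", "r") as f:
        out["truth"] = {k: f[k][()] for k in f}
        out["truth"]["participant_factor"] = float(
            f.attrs["participant_factor"]
        )
    out["manifest"] = json.loads((d / "manifest.json").read_text())
    return out


def write_tfr(tfr, path: str | Path) -> None:
    """Store a TFRPower with full axis metadata in an HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=tfr.data)
        f.create_dataset("freqs_hz", data=tfr.freqs)
        f.create_dataset("times_ms", data=tfr.times)
        f.create_dataset("ch_names", data=np.array(tfr.ch_names, dtype="S"))
        f.attrs["state"] = tfr.state
        f.attrs["cycles"] = -1.0 if tfr.cycles is None else tfr.cycles


def read_tfr(path: str | Path):
    """Inverse of :func:`write_tfr` (bit-exact)."""
    from .containers import TFRPower

    with h5py.File(path, "r") as f:
        cycles = float(f.attrs["cycles"])
        return TFRPower(
            data=f["data"][()],
            freqs=f["freqs_hz"][()],
            times=f["times_ms"][()],
            ch_names=[s.decode() for s in f["ch_names"][()]],
            state=str(f.attrs["state"]),
            cycles=None if cycles < 0 else cycles,
        )
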