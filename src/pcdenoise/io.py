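"""File I/O: the HDF5 trial container, EDF and WAV readers, configs.

Container layout::

    /trials/<i>/X        channels x samples float64
    /trials/<i>/audio    samples float64
    /trials/<i>/truth/S  neural sources x samples      (optional)
    /trials/<i>/truth/A  channels x sources mixing
    /trials/<i>/truth    attrs: agr_db
    /trials/<i>          attrs: fs, channel_names, onset_index
    /models/...          serialized fitted models
    /reports/<name>      JSON strings

Epoched multimodal data with ground truth does not fit EDF cleanly, hence
the container; EDF stays supported for reading continuous clinical data.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml
from scipy.io import wavfile

from .containers import AudioTrace, Recording, SimTruth, TrialEpoch

__all__ = [
    "write_trials",
    "read_trials",
    "read_recording",
    "read_audio_wav",
    "write_audio_wav",
    "load_config",
    "write_report",
]


def write_trials(
    path: str | Path,
    trials: list[TrialEpoch],
    truths: list[SimTruth] | None = None,
    mode: str = "w",
) -> None:
    """Write trials (and optional ground truth) to the HDF5 container."""
    with h5py.File(path, mode) as h5:
        root = h5.require_group("trials")
        for i, trial in enumerate(trials):
            g = root.create_group(str(i))
            g.create_dataset("X", data=trial.X)
            g.create_dataset("audio", data=trial.audio)
            g.attrs["fs"] = trial.fs
            g.attrs["onset_index"] = trial.onset_index
            g.attrs["channel_names"] = [str(c) for c in trial.ch_names]
            if truths is not None:
                t = truths[i]
                tg = g.create_group("truth")
                tg.create_dataset("S", data=t.S_neural)
                tg.create_dataset("s_artifact", data=t.s_artifact)
                tg.create_dataset("A", data=t.A_mix)
                tg.attrs["agr_db"] = t.agr_db


def read_trials(
    path: str | Path,
) -> tuple[list[TrialEpoch], list[SimTruth | None]]:
    """Read all trials (sorted by index) from the HDF5 container."""
    trials: list[TrialEpoch] = []
    truths: list[SimTruth | None] = []
    with h5py.File(path, "r") as h5:
        root = h5["trials"]
        for key in sorted(root.keys(), key=int):
            g = root[key]
            trial = TrialEpoch(
                X=g["X"][()],
                audio=g["audio"][()],
                onset_index=int(g.attrs["onset_index"]),
                fs=float(g.attrs["fs"]),
                ch_names=[str(c) for c in g.attrs.get("channel_names", [])],
            )
            trials.append(trial)
            if "truth" in g:
                tg = g["truth"]
                truths.append(
                    SimTruth(
                        S_neural=tg["S"][()],
                        s_artifact=tg["s_artifact"][()],
                        A_mix=tg["A"][()],
                        agr_db=float(tg.attrs["agr_db"]),
                        fs=float(g.attrs["fs"]),
                    )
                )
            else:
                truths.append(None)
    return trials, truths


def read_recording(path: str | Path) -> Recording:
    """Read a continuous multichannel recording from EDF or the container.

    EDF channels must share one sampling rate; mixed rates are rejected
    (resampling is out of scope) with the offending channels named.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        trials, _ = read_trials(path)
        t = trials[0]
        return Recording(t.X, t.fs, ch_names=t.ch_names)
    if path.suffix.lower() == ".edf":
        import mne

        # the EDF reader resamples heterogeneous-rate files on load; check
        # the file header directly so mixed-rate files are rejected instead
        _check_edf_rates(path)
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return Recording(
            raw.get_data(), float(raw.info["sfreq"]), ch_names=list(raw.ch_names)
        )
    raise ValueError(f"unsupported recording format: {path.suffix!r}")


def _check_edf_rates(path: Path) -> None:
    """Reject EDF files whose channels have inconsistent sampling rates."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        n_sig = int(header[252:256].decode("ascii").strip())
        sig_header = fh.read(256 * n_sig)
    labels = [
        sig_header[16 * i : 16 * (i + 1)].decode("ascii").strip()
        for i in range(n_sig)
    ]
    off = n_sig * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    nsamp = [
        int(sig_header[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip())
        for i in range(n_sig)
    ]
    if len(set(nsamp)) > 1:
        groups: dict[int, list[str]] = {}
        for lab, ns in zip(labels, nsamp):
            groups.setdefault(ns, []).append(lab)
        raise ValueError(
            "inconsistent sampling rates across EDF channels: "
            + "; ".join(
                f"{ns} samples/record: {', '.join(chs)}"
                for ns, chs in sorted(groups.items())
            )
        )


def read_audio_wav(path: str | Path) -> AudioTrace:
    """Read a WAV file as a mono float waveform."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    return AudioTrace(data.astype(float), float(fs))


def write_audio_wav(path: str | Path, audio: AudioTrace) -> None:
    """Write a mono float32 WAV file."""
    wavfile.write(path, int(round(audio.fs)), audio.data.astype(np.float32))


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_report(path: str | Path, report: dict) -> None:
    """Write a JSON metrics/provenance report."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
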