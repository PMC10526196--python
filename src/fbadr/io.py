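"""HDF5 epoch container and EDF/FIF ingestion.

Layout of the container::

    /raw/{subject}/{modality}/{emotion}/trial{k}   channels x times, attrs fs, onset_index
    /epochs                                        n x K x T  + /epochs_labels
    /banded/band{j}                                n x K x T  + shared /epochs_labels
    /features/band{j}                              n x F      + /features_labels
    /meta                                          config YAML, seed, package version

Every dataset carries an aligned label table (subject, modality, emotion,
trial, window) stored as fixed-width byte strings and integers.  EDF and
FIF files are accepted only at the ingestion edge, read through MNE.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochSet, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "save_recordings",
    "load_recordings",
    "save_epochs",
    "load_epochs",
    "save_features",
    "load_features",
    "read_edf",
    "read_fif",
]

_LABEL_DTYPE = [
    ("subject", "i8"),
    ("modality", "S16"),
    ("emotion", "S16"),
    ("trial", "i8"),
    ("window", "i8"),
]


def _labels_to_array(labels: pd.DataFrame) -> np.ndarray:
    out = np.empty(len(labels), dtype=_LABEL_DTYPE)
    out["subject"] = labels["subject"].to_numpy()
    out["modality"] = labels["modality"].astype(str).to_numpy().astype("S16")
    out["emotion"] = labels["emotion"].astype(str).to_numpy().astype("S16")
    out["trial"] = labels["trial"].to_numpy()
    out["window"] = labels["window"].to_numpy()
    return out


def _decode(value) -> str:
    return value.decode() if isinstance(value, bytes) else str(value)


def _labels_from_array(arr: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": arr["subject"],
            "modality": [m.decode() for m in arr["modality"]],
            "emotion": [e.decode() for e in arr["emotion"]],
            "trial": arr["trial"],
            "window": arr["window"],
        }
    )


def _write_meta(h5: h5py.File, meta: dict | None) -> None:
    if not meta:
        return
    grp = h5.require_group("meta")
    for key, value in meta.items():
        grp.attrs[key] = value


def save_recordings(path, recordings, meta: dict | None = None) -> None:
    """Write raw trials to ``/raw/{subject}/{modality}/{emotion}/trial{k}``."""
    with h5py.File(path, "w") as h5:
        for rec in recordings:
            grp = h5.require_group(
                f"raw/{rec.subject}/{rec.modality}/{rec.emotion}"
            )
            ds = grp.create_dataset(f"trial{rec.trial}", data=rec.data)
            ds.attrs["fs"] = rec.fs
            ds.attrs["onset_index"] = rec.onset_index
            ds.attrs["channel_names"] = [n.encode() for n in rec.channel_names]
        _write_meta(h5, meta)


def load_recordings(path) -> list[Recording]:
    out: list[Recording] = []
    with h5py.File(path, "r") as h5:
        if "raw" not in h5:
            raise KeyError(f"{path}: container has no /raw group")
        for subject in h5["raw"]:
            for modality in h5[f"raw/{subject}"]:
                for emotion in h5[f"raw/{subject}/{modality}"]:
                    grp = h5[f"raw/{subject}/{modality}/{emotion}"]
                    for name in grp:
                        ds = grp[name]
                        out.append(
                            Recording(
                                data=ds[()],
                                fs=float(ds.attrs["fs"]),
                                onset_index=int(ds.attrs["onset_index"]),
                                subject=int(subject),
                                modality=modality,
                                emotion=emotion,
                                trial=int(name.removeprefix("trial")),
                                channel_names=[
                                    _decode(n) for n in ds.attrs["channel_names"]
                                ],
                            )
                        )
    out.sort(key=lambda r: (r.subject, r.modality, r.emotion, r.trial))
    return out


def save_epochs(path, epochset: EpochSet, group: str = "epochs",
                meta: dict | None = None) -> None:
    with h5py.File(path, "a") as h5:
        if group in h5:
            del h5[group]
        if f"{group}_labels" in h5:
            del h5[f"{group}_labels"]
        ds = h5.create_dataset(group, data=epochset.epochs)
        ds.attrs["fs"] = epochset.fs
        ds.attrs["channel_names"] = [n.encode() for n in epochset.channel_names]
        h5.create_dataset(f"{group}_labels", data=_labels_to_array(epochset.labels))
        _write_meta(h5, meta)


def load_epochs(path, group: str = "epochs") -> EpochSet:
    with h5py.File(path, "r") as h5:
        if group not in h5:
            raise KeyError(f"{path}: missing dataset /{group}")
        ds = h5[group]
        return EpochSet(
            epochs=ds[()],
            fs=float(ds.attrs["fs"]),
            labels=_labels_from_array(h5[f"{group}_labels"][()]),
            channel_names=[_decode(n) for n in ds.attrs["channel_names"]],
        )


def save_features(path, features: dict[int, np.ndarray], labels: pd.DataFrame,
                  group: str = "features", meta: dict | None = None) -> None:
    """Per-band feature matrices under ``/{group}/band{j}``."""
    with h5py.File(path, "a") as h5:
        if group in h5:
            del h5[group]
        grp = h5.require_group(group)
        for band, mat in features.items():
            grp.create_dataset(f"band{band}", data=mat)
        if f"{group}_labels" in h5:
            del h5[f"{group}_labels"]
        h5.create_dataset(f"{group}_labels", data=_labels_to_array(labels))
        _write_meta(h5, meta)


def load_features(path, group: str = "features"):
    with h5py.File(path, "r") as h5:
        if group not in h5:
            raise KeyError(f"{path}: missing group /{group}")
        feats = {
            int(name.removeprefix("band")): h5[group][name][()]
            for name in h5[group]
        }
        labels = _labels_from_array(h5[f"{group}_labels"][()])
    return feats, labels


def _raw_to_recording(raw, label_map: dict | None, path) -> Recording:
    if len(raw.ch_names) < 2:
        raise ValueError(f"{path}: fewer than 2 channels")
    labels = dict(subject=0, modality="audiovisual", emotion="pleasure", trial=0)
    if label_map:
        labels.update(label_map)
    else:
        logger.warning("%s: no label mapping supplied; labels set to defaults", path)
    return Recording(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        onset_index=int(label_map.get("onset_index", 0)) if label_map else 0,
        subject=int(labels["subject"]),
        modality=labels["modality"],
        emotion=labels["emotion"],
        trial=int(labels["trial"]),
        channel_names=list(raw.ch_names),
    )


def read_edf(path, label_map: dict | None = None) -> Recording:
    """Read one EDF file into a :class:`Recording`.

    ``label_map`` supplies subject/modality/emotion/trial/onset_index;
    missing entries fall back to defaults with a warning.
    """
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose=False)
    except Exception as exc:  # noqa: BLE001 - annotate with the file path
        raise OSError(f"could not read EDF file {path}: {exc}") from exc
    return _raw_to_recording(raw, label_map, path)


def read_fif(path, label_map: dict | None = None) -> Recording:
    """Read one FIF raw file into a :class:`Recording`."""
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_fif(path, preload=True, verbose=False)
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"could not read FIF file {path}: {exc}") from exc
    return _raw_to_recording(raw, label_map, path)
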