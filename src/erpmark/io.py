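"""File formats: EDF continuous data, TSV event schedules, single-file
array containers for epochs/evokeds, CSV feature tables and JSON results.

EDF is written by a small self-contained 16-bit encoder (one-second data
records, per-channel physical scaling) and read back through MNE's EDF
reader, so round-trips are checked against an independent implementation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import modality_of
from .montage import Montage, build_default_montage
from .preprocess import ContinuousRecording, EpochSet
from .average import Evoked
from .simulate import Event, EventSchedule

__all__ = [
    "write_edf", "read_edf", "write_events_tsv", "read_events_tsv",
    "save_epochs", "load_epochs", "save_evoked", "load_evoked",
    "write_feature_csv", "read_feature_csv", "write_anova_json",
]

_DIG_MAX = 32767


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii")[:n]
    return b + b" " * (n - len(b))


def write_edf(recording: ContinuousRecording, path) -> None:
    """Write a recording as 16-bit EDF (physical unit uV, 1 s records).

    The last record is zero-padded to a whole second; the true sample
    count is recoverable from the event schedule or ignored by epoching.
    """
    path = Path(path)
    data = np.asarray(recording.data, dtype=np.float64)
    labels = list(recording.montage.all_channels)
    ns, n_samples = data.shape
    spr = int(round(recording.fs))  # samples per 1 s record
    n_records = int(np.ceil(n_samples / spr))

    # physical bounds rounded *up* at two decimals so the printed header
    # range never clips the signal; the same printed values drive the
    # quantization, keeping writer and reader scaling in exact agreement
    phys_max = np.ceil(np.maximum(np.abs(data).max(axis=1), 1.0) * 100) / 100
    phys_min = -phys_max
    scale = _DIG_MAX / phys_max

    header = b"".join([
        _pad("0", 8),
        _pad(f"subject {recording.subject}", 80),
        _pad("erpmark synthetic EEG", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (1 + ns)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    fields = [
        ("".join(_pad(lab, 16).decode() for lab in labels), None),
        ("".join(_pad("AgAgCl electrode", 80).decode() for _ in labels), None),
        ("".join(_pad("uV", 8).decode() for _ in labels), None),
        ("".join(_pad(f"{phys_min[i]:.2f}"[:8], 8).decode()
                 for i in range(ns)), None),
        ("".join(_pad(f"{phys_max[i]:.2f}"[:8], 8).decode()
                 for i in range(ns)), None),
        ("".join(_pad(str(-_DIG_MAX), 8).decode() for _ in labels), None),
        ("".join(_pad(str(_DIG_MAX), 8).decode() for _ in labels), None),
        ("".join(_pad("HP:0.016Hz LP:70Hz", 80).decode() for _ in labels),
         None),
        ("".join(_pad(str(spr), 8).decode() for _ in labels), None),
        ("".join(_pad("", 32).decode() for _ in labels), None),
    ]
    header += "".join(f[0] for f in fields).encode("ascii")

    padded = np.zeros((ns, n_records * spr), dtype=np.float64)
    padded[:, :n_samples] = data
    digital = np.clip(np.round(padded * scale[:, None]),
                      -_DIG_MAX, _DIG_MAX).astype("<i2")

    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_records):
            f.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def read_edf(path, montage: Montage | None = None) -> ContinuousRecording:
    """Read an EDF file into a ContinuousRecording (microvolt).

    Channel labels must match ``montage.all_channels`` (default montage if
    none given). Uses MNE's EDF reader.
    """
    import mne

    if montage is None:
        montage = build_default_montage()
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    order = list(montage.all_channels)
    missing = [c for c in order if c not in raw.ch_names]
    if missing:
        raise ValueError(f"EDF lacks montage channels: {missing}")
    data = raw.get_data(picks=order, units="uV")
    subject = None
    return ContinuousRecording(
        data=data.astype(np.float32), fs=float(raw.info["sfreq"]),
        montage=montage, subject=subject,
    )


def write_events_tsv(schedule: EventSchedule, fs: float, path,
                     stimulus_duration_s: float = 1.5) -> None:
    """Event schedule as TSV: onset_s, duration_s, category, run, modality."""
    rows = [
        (e.onset / fs, stimulus_duration_s, e.category, e.run,
         modality_of(e.category))
        for e in schedule.entries
    ]
    pd.DataFrame(
        rows, columns=["onset_s", "duration_s", "category", "run", "modality"]
    ).to_csv(path, sep="\t", index=False)


def read_events_tsv(path, fs: float) -> EventSchedule:
    df = pd.read_csv(path, sep="\t")
    entries = tuple(
        Event(onset=int(round(r.onset_s * fs)), category=r.category,
              run=int(r.run))
        for r in df.itertuples()
    )
    return EventSchedule(entries=entries)


# --------------------------------------------------------------------------
# single-file array containers (npz payload + embedded JSON metadata)
# --------------------------------------------------------------------------

def save_epochs(epochs: EpochSet, path) -> None:
    meta = {
        "fs": epochs.fs,
        "subject": epochs.subject,
        "categories": list(map(str, epochs.categories)),
        "rejection_log": epochs.rejection_log,
        "n_dropped_out_of_bounds": epochs.n_dropped_out_of_bounds,
        "channels": list(epochs.montage.all_channels),
    }
    np.savez_compressed(
        path, tensor=epochs.tensor, time_ms=epochs.time_ms,
        kept=epochs.kept, meta=json.dumps(meta),
    )


def load_epochs(path, montage: Montage | None = None) -> EpochSet:
    if montage is None:
        montage = build_default_montage()
    z = np.load(path, allow_pickle=False)
    meta = json.loads(str(z["meta"]))
    if meta["channels"] != list(montage.all_channels):
        raise ValueError("stored channel order does not match montage")
    return EpochSet(
        tensor=z["tensor"], time_ms=z["time_ms"],
        categories=np.asarray(meta["categories"], dtype=object),
        fs=meta["fs"], montage=montage, subject=meta["subject"],
        kept=z["kept"],
        rejection_log=[tuple(x) for x in meta["rejection_log"]],
        n_dropped_out_of_bounds=meta["n_dropped_out_of_bounds"],
    )


def save_evoked(evoked: Evoked, path) -> None:
    meta = {
        "fs": evoked.fs, "category": evoked.category,
        "m_contributing": evoked.m_contributing, "level": evoked.level,
        "subject": evoked.subject,
        "channels": list(evoked.montage.all_channels),
    }
    np.savez_compressed(path, data=evoked.data, time_ms=evoked.time_ms,
                        meta=json.dumps(meta))


def load_evoked(path, montage: Montage | None = None) -> Evoked:
    if montage is None:
        montage = build_default_montage()
    z = np.load(path, allow_pickle=False)
    meta = json.loads(str(z["meta"]))
    if meta["channels"] != list(montage.all_channels):
        raise ValueError("stored channel order does not match montage")
    return Evoked(
        data=z["data"], time_ms=z["time_ms"], fs=meta["fs"],
        montage=montage, category=meta["category"],
        m_contributing=meta["m_contributing"], level=meta["level"],
        subject=meta["subject"],
    )


def evoked_to_csv(evoked: Evoked, path) -> None:
    """Waveform export: rows = samples (ms column), columns = channels."""
    df = pd.DataFrame(evoked.data.T, columns=evoked.montage.all_channels)
    df.insert(0, "time_ms", evoked.time_ms)
    df.to_csv(path, index=False)


def write_feature_csv(table: pd.DataFrame, path) -> None:
    cols = ["subject", "category", "marker", "electrode", "amplitude_uv"]
    table[cols].to_csv(path, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    from .montage import hemisphere_of

    table = pd.read_csv(path)
    table["hemisphere"] = [hemisphere_of(e) for e in table.electrode]
    return table


def write_anova_json(report: dict, path) -> None:
    """Serialize a contrast-battery report (AnovaResult objects included)."""
    def enc(x):
        from .stats import AnovaResult, EffectResult, PosthocResult
        if isinstance(x, dict):
            return {k: enc(v) for k, v in x.items()}
        if isinstance(x, AnovaResult):
            return x.as_dict()
        if isinstance(x, EffectResult):
            return x.as_dict()
        if isinstance(x, PosthocResult):
            return x.pairs.to_dict(orient="records")
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        if isinstance(x, pd.Series):
            return x.to_dict()
        return x

    with open(path, "w") as f:
        json.dump(enc(report), f, indent=1)
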