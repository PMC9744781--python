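"""Continuous-EEG preprocessing: band-pass filtering, stimulus-locked
epoching, peak-to-peak artifact rejection, and pre-stimulus baseline
correction.

Sample-index conventions used throughout the package
----------------------------------------------------
Millisecond bounds convert to sample indices by flooring
(``floor(ms / 1000 * fs)``) and every window is half-open ``[start, end)``.
At 512 Hz the canonical epoch is 51 baseline samples ([-100, 0) ms) plus
768 post-stimulus samples ([0, 1500) ms) = 819 samples; the 768-sample
post-stimulus block is the per-trial vector that trial averaging operates
on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

from .montage import Montage

__all__ = [
    "ContinuousRecording",
    "EpochSet",
    "ms_to_sample",
    "bandpass",
    "extract_epochs",
    "reject_artifacts",
    "baseline_correct",
    "DEFAULT_FS",
    "DEFAULT_BAND",
    "DEFAULT_REJECT_UV",
]

DEFAULT_FS = 512.0
DEFAULT_BAND = (0.016, 30.0)  # half-amplitude corner frequencies, Hz
DEFAULT_REJECT_UV = 50.0      # peak-to-peak rejection threshold, microvolt


def ms_to_sample(ms: float, fs: float) -> int:
    """Floor conversion of a millisecond bound to a sample index."""
    return math.floor(ms / 1000.0 * fs)


@dataclass
class ContinuousRecording:
    """A multichannel voltage record in microvolt.

    ``data`` rows follow ``montage.all_channels``: scalp channels first,
    then the ocular (EOG) channels.
    """

    data: np.ndarray  # (n_channels + n_eog, n_samples), microvolt
    fs: float
    montage: Montage
    subject: int | None = None

    def __post_init__(self):
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != self.montage.n_all:
            raise ValueError(
                f"channel count {self.data.shape[0]} does not match montage "
                f"({self.montage.n_all} incl. EOG)"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite samples in recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def eog_index(self) -> np.ndarray:
        n = self.montage.n_channels
        return np.arange(n, self.montage.n_all)


@dataclass
class EpochSet:
    """Stimulus-locked trial tensor with a kept/rejected mask.

    ``tensor`` is (m epochs, channels incl. EOG, t samples); ``time_ms``
    spans the epoch with 0 at stimulus onset. ``kept`` marks epochs that
    survived artifact rejection; the tensor itself always retains every
    extracted epoch. ``rejection_log`` has one entry per rejected epoch:
    (epoch index, worst channel label, peak-to-peak value in microvolt).
    """

    tensor: np.ndarray            # (m, n_channels + n_eog, t)
    time_ms: np.ndarray           # (t,)
    categories: np.ndarray        # (m,) object/str labels
    fs: float
    montage: Montage
    subject: int | None = None
    kept: np.ndarray = None       # (m,) bool
    rejection_log: list = field(default_factory=list)
    n_dropped_out_of_bounds: int = 0

    def __post_init__(self):
        if self.kept is None:
            self.kept = np.ones(self.tensor.shape[0], dtype=bool)
        if self.tensor.ndim != 3:
            raise ValueError("tensor must be epochs x channels x samples")
        if self.tensor.shape[2] != self.time_ms.size:
            raise ValueError("time axis does not match tensor")
        if self.tensor.shape[0] != self.categories.size:
            raise ValueError("category labels do not match epoch count")

    @property
    def n_epochs(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    @property
    def onset_index(self) -> int:
        """Index of the t = 0 (stimulus onset) sample."""
        return int(np.searchsorted(self.time_ms, 0.0))


def _design_sos(low_hz: float, high_hz: float, fs: float):
    if not (0 <= low_hz < high_hz < fs / 2):
        raise ValueError(
            f"invalid band ({low_hz}, {high_hz}) Hz at fs = {fs} Hz"
        )
    # An order-2 Butterworth band-pass applied forward-backward has squared
    # magnitude 0.5 at the corners: the corners are half-amplitude points.
    return scipy.signal.butter(
        2, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos"
    )


def bandpass(
    recording: ContinuousRecording,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
) -> ContinuousRecording:
    """Zero-phase band-pass filter (forward-backward order-2 Butterworth).

    Default corners 0.016 and 30 Hz; applied twice, the filter's gain at
    each corner is one half, i.e. the corners are half-amplitude points.
    """
    sos = _design_sos(low_hz, high_hz, recording.fs)
    # the sub-hertz high-pass pole has a seconds-long impulse response, so
    # reflect-pad generously to keep its start-up transient out of the data
    padlen = min(int(5 * recording.fs), recording.n_samples // 2 - 1)
    out = scipy.signal.sosfiltfilt(sos, recording.data, axis=-1,
                                   padtype="even", padlen=max(padlen, 0))
    return replace(recording, data=out.astype(recording.data.dtype, copy=False))


def extract_epochs(
    recording: ContinuousRecording,
    schedule,
    t_pre_ms: float = 100.0,
    t_post_ms: float = 1500.0,
) -> EpochSet:
    """Cut the continuous record into stimulus-locked epochs.

    One epoch per scheduled event, spanning ``[-t_pre_ms, t_post_ms)``
    around the onset sample. Events whose window falls outside the record
    are dropped (counted in ``n_dropped_out_of_bounds``), never padded.
    """
    n_pre = ms_to_sample(t_pre_ms, recording.fs)
    n_post = ms_to_sample(t_post_ms, recording.fs)
    t = n_pre + n_post
    time_ms = (np.arange(-n_pre, n_post) / recording.fs) * 1000.0

    onsets, labels = [], []
    dropped = 0
    for entry in schedule.entries:
        if entry.onset - n_pre < 0 or entry.onset + n_post > recording.n_samples:
            dropped += 1
            continue
        onsets.append(entry.onset)
        labels.append(entry.category)

    tensor = np.empty(
        (len(onsets), recording.data.shape[0], t), dtype=recording.data.dtype
    )
    for i, onset in enumerate(onsets):
        tensor[i] = recording.data[:, onset - n_pre : onset + n_post]

    return EpochSet(
        tensor=tensor,
        time_ms=time_ms,
        categories=np.asarray(labels, dtype=object),
        fs=recording.fs,
        montage=recording.montage,
        subject=recording.subject,
        n_dropped_out_of_bounds=dropped,
    )


def reject_artifacts(
    epochs: EpochSet, threshold_uv: float = DEFAULT_REJECT_UV
) -> EpochSet:
    """Flag epochs whose peak-to-peak amplitude exceeds the threshold.

    An epoch is rejected iff the within-epoch max-minus-min on *any*
    channel — scalp or ocular — is strictly greater than ``threshold_uv``
    (an exact 50.0 microvolt swing is kept). The tensor is retained; only
    ``kept`` and ``rejection_log`` change.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    ptp = epochs.tensor.max(axis=2) - epochs.tensor.min(axis=2)  # (m, ch)
    worst = ptp.argmax(axis=1)
    worst_ptp = ptp[np.arange(ptp.shape[0]), worst]
    kept = worst_ptp <= threshold_uv
    labels = epochs.montage.all_channels
    log = [
        (int(i), labels[worst[i]], float(worst_ptp[i]))
        for i in np.nonzero(~kept)[0]
    ]
    return replace(epochs, kept=kept, rejection_log=log)


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each channel's mean over the [-100, 0) ms pre-stimulus
    interval (or the full available pre-stimulus segment if shorter).

    Idempotent: the baseline mean of the output is zero to float precision.
    """
    onset = epochs.onset_index
    if onset == 0:
        raise ValueError("no pre-stimulus segment to baseline against")
    start = int(np.searchsorted(epochs.time_ms, -100.0))
    base = epochs.tensor[:, :, start:onset].mean(axis=2, keepdims=True)
    return replace(epochs, tensor=epochs.tensor - base)
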