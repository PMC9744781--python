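"""Trial averaging: per-subject evoked responses, grand averages across
subjects, and category pooling for summary waveforms.

Averaging m artifact-free trials attenuates the background-EEG residual by
1/sqrt(m), which is what makes the small category-specific components
measurable at all.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .montage import Montage
from .preprocess import EpochSet

__all__ = ["Evoked", "average_epochs", "average_by_category",
           "grand_average", "pool_categories"]


class EmptyAverageError(ValueError):
    """Raised when an average is requested over zero kept epochs."""


@dataclass
class Evoked:
    """An averaged ERP waveform (channels incl. EOG x samples, microvolt)."""

    data: np.ndarray
    time_ms: np.ndarray
    fs: float
    montage: Montage
    category: str
    m_contributing: int
    level: str = "subject"   # "subject" | "grand"
    subject: int | None = None

    def __post_init__(self):
        if self.m_contributing < 1:
            raise EmptyAverageError(
                f"evoked for {self.category!r} has no contributing epochs"
            )

    @property
    def onset_index(self) -> int:
        return int(np.searchsorted(self.time_ms, 0.0))


def average_epochs(epochs: EpochSet, category: str | None = None) -> Evoked:
    """Arithmetic mean over *kept* epochs, per channel per sample.

    If ``category`` is given only kept epochs of that category contribute;
    otherwise all kept epochs are pooled. Zero kept epochs is an explicit
    error, never a silent all-zero waveform.
    """
    mask = epochs.kept.copy()
    if category is not None:
        mask &= epochs.categories == category
    m = int(mask.sum())
    if m == 0:
        raise EmptyAverageError(
            f"no kept epochs for category {category!r} "
            f"(subject {epochs.subject})"
        )
    data = epochs.tensor[mask].mean(axis=0)
    return Evoked(
        data=data,
        time_ms=epochs.time_ms,
        fs=epochs.fs,
        montage=epochs.montage,
        category="all" if category is None else category,
        m_contributing=m,
        level="subject",
        subject=epochs.subject,
    )


def average_by_category(epochs: EpochSet) -> dict[str, Evoked]:
    """One evoked per category present among the kept epochs."""
    cats = sorted(set(epochs.categories[epochs.kept]))
    return {c: average_epochs(epochs, c) for c in cats}


def _check_compatible(evokeds, same_category: bool):
    first = evokeds[0]
    for ev in evokeds[1:]:
        if ev.data.shape != first.data.shape or ev.fs != first.fs:
            raise ValueError("evoked responses have mismatched shapes")
        if same_category and ev.category != first.category:
            raise ValueError(
                f"mixed categories: {ev.category!r} vs {first.category!r}"
            )


def grand_average(evokeds: list[Evoked]) -> Evoked:
    """Unweighted mean of subject-level evokeds (one category)."""
    if not evokeds:
        raise EmptyAverageError("no evoked responses to grand-average")
    _check_compatible(evokeds, same_category=True)
    data = np.mean([ev.data for ev in evokeds], axis=0)
    return replace(
        evokeds[0],
        data=data,
        level="grand",
        subject=None,
        m_contributing=len(evokeds),
    )


def pool_categories(
    evokeds: dict[str, Evoked], groups: dict[str, list[str]]
) -> dict[str, Evoked]:
    """Unweighted mean of member evokeds per named group.

    E.g. ``{"living": ["adult_face", "infant_face", "animal_face", "body"]}``
    pools the evokeds of the living visual categories. Pooling is a mean of
    already-averaged waveforms, not a re-average of the pooled trials.
    """
    out = {}
    for name, members in groups.items():
        missing = [m for m in members if m not in evokeds]
        if missing:
            raise KeyError(f"group {name!r}: missing categories {missing}")
        evs = [evokeds[m] for m in members]
        _check_compatible(evs, same_category=False)
        data = np.mean([ev.data for ev in evs], axis=0)
        out[name] = replace(
            evs[0], data=data, category=name, m_contributing=len(evs)
        )
    return out
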