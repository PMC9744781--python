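"""Marker registry and mean-area-amplitude feature extraction.

The registry enumerates the 16 category-sensitive ERP components analysed
by the pipeline: for each, its measurement window, electrode set, polarity,
and the expected ordering of category amplitudes ("larger" means more
positive for positive components and more negative for negative ones).
Feature extraction measures, per subject x category x electrode, the mean
baseline-referenced voltage over the marker window — the quantity the
repeated-measures ANOVAs and the decoder consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .average import Evoked
from .montage import build_default_montage, hemisphere_of
from .preprocess import ms_to_sample

__all__ = [
    "VISUAL_CATEGORIES", "AUDITORY_CATEGORIES", "CATEGORIES",
    "LIVING_CATEGORIES", "NONLIVING_CATEGORIES",
    "MarkerDefinition", "marker_registry",
    "mean_amplitude", "extract_feature_table", "modality_of",
]

VISUAL_CATEGORIES = (
    "infant_face", "adult_face", "animal_face", "body",
    "word_visual", "checkerboard", "object",
)
AUDITORY_CATEGORIES = ("word_auditory", "vocalization", "music")
CATEGORIES = VISUAL_CATEGORIES + AUDITORY_CATEGORIES

LIVING_CATEGORIES = ("infant_face", "adult_face", "animal_face", "body")
NONLIVING_CATEGORIES = ("word_visual", "checkerboard", "object")


def modality_of(category: str) -> str:
    if category in VISUAL_CATEGORIES:
        return "visual"
    if category in AUDITORY_CATEGORIES:
        return "auditory"
    raise KeyError(f"unknown category {category!r}")


@dataclass(frozen=True)
class MarkerDefinition:
    """One ERP component of interest.

    ``expected_contrast`` is an ordered tuple of category groups: every
    category in an earlier group is expected to exceed, in magnitude, every
    category in a later group. ``analysis_categories`` are the levels of
    the category factor in the corresponding ANOVA. ``polarity`` is '+'
    for positive components, '-' for negative ones, and 'modality' for the
    cross-modal deflection whose sign encodes the sensory modality.
    """

    name: str                 # unique key (e.g. "N170_nonliving")
    component: str            # display name as reported (e.g. "N170")
    modality: str             # "visual" | "auditory" | "cross-modal"
    window_ms: tuple[float, float]
    electrodes: tuple[str, ...]
    polarity: str
    analysis_categories: tuple[str, ...]
    expected_contrast: tuple[tuple[str, ...], ...] = ()
    hemisphere_analysis: bool = False

    def __post_init__(self):
        if not self.window_ms[0] < self.window_ms[1]:
            raise ValueError(f"{self.name}: empty window {self.window_ms}")

    @property
    def applicable_categories(self) -> tuple[str, ...]:
        """Categories the marker is measured on (all of its modality)."""
        if self.modality == "visual":
            return VISUAL_CATEGORIES
        if self.modality == "auditory":
            return AUDITORY_CATEGORIES
        return CATEGORIES


def marker_registry() -> list[MarkerDefinition]:
    """The 16 analysed components with their windows, sites and contrasts.

    Electrode membership in the default montage is asserted at construction.
    """
    M = MarkerDefinition
    registry = [
        # --- visual, living categories -----------------------------------
        M("N170_living", "N170", "visual", (150, 190),
          ("PPO9h", "PPO10h", "P7", "P8"), "-",
          ("adult_face", "infant_face", "animal_face"),
          (("adult_face", "infant_face"), ("animal_face",))),
        M("N2", "N2", "visual", (250, 350),
          ("AFp3h", "AFp4h", "Fpz", "CPz", "Cz"), "-",
          ("infant_face", "adult_face", "animal_face", "body"),
          (("infant_face",), ("adult_face", "animal_face"), ("body",))),
        M("P2", "P2", "visual", (300, 350), ("CPz", "Pz"), "+",
          ("body", "infant_face", "adult_face", "animal_face"),
          (("body",), ("infant_face", "adult_face", "animal_face"))),
        M("P300", "P300", "visual", (400, 600), ("AFz", "Fz"), "+",
          ("animal_face", "infant_face", "adult_face", "body"),
          (("animal_face",), ("infant_face", "adult_face", "body"))),
        M("CPP", "CPP", "visual", (400, 600), ("CPz", "Pz"), "+",
          ("infant_face", "body"),
          (("infant_face",), ("body",))),
        M("LCPP", "LCPP", "visual", (600, 900), ("CPz", "Pz"), "+",
          ("infant_face", "body"),
          (("infant_face",), ("body",))),
        M("AN", "AN", "visual", (200, 600),
          ("AFp3h", "AFp4h", "AFz", "Fpz", "Fz"), "-",
          ("infant_face", "adult_face", "animal_face", "body"),
          (("infant_face", "adult_face"), ("animal_face", "body"))),
        M("AP", "AP", "visual", (600, 800), ("AFz", "Fz"), "+",
          ("animal_face", "adult_face"),
          (("animal_face",), ("adult_face",))),
        # --- visual, non-living categories -------------------------------
        M("N80", "N80", "visual", (90, 130), ("Oz", "Iz"), "-",
          ("checkerboard", "word_visual", "object"),
          (("checkerboard",), ("word_visual", "object"))),
        M("N170_nonliving", "N170", "visual", (150, 190),
          ("PPO9h", "PPO10h", "P7", "P8"), "-",
          ("word_visual", "checkerboard", "object"),
          (("word_visual",), ("checkerboard",), ("object",)),
          hemisphere_analysis=True),
        # --- auditory categories -----------------------------------------
        M("P2_aud", "P2", "auditory", (150, 300),
          ("FFC1h", "FFC2h", "C1", "C2"), "+",
          AUDITORY_CATEGORIES,
          (("vocalization", "word_auditory"), ("music",))),
        M("P300_aud", "P300", "auditory", (400, 500),
          ("FFC1h", "FFC2h", "C1", "C2"), "+",
          AUDITORY_CATEGORIES,
          (("music",), ("vocalization", "word_auditory"))),
        M("N400", "N400", "auditory", (450, 650),
          ("CCP1h", "CCP2h", "P3", "P4"), "-",
          AUDITORY_CATEGORIES,
          (("word_auditory",), ("music", "vocalization"))),
        M("AN_aud", "AN", "auditory", (400, 600),
          ("AF3", "AF4", "AF7", "AF8"), "-",
          AUDITORY_CATEGORIES,
          (("vocalization",), ("word_auditory", "music"))),
        M("LP", "LP", "auditory", (900, 1200),
          ("AF3", "AF4", "AF7", "AF8"), "+",
          AUDITORY_CATEGORIES,
          (("vocalization", "word_auditory"), ("music",))),
        # --- cross-modal --------------------------------------------------
        M("PN300", "PN300", "cross-modal", (200, 400), ("Fz", "Cz"),
          "modality", CATEGORIES),
    ]
    mont = build_default_montage()
    for mk in registry:
        for el in mk.electrodes:
            if el not in mont:
                raise ValueError(
                    f"marker {mk.name}: electrode {el} not in default montage"
                )
        for grp in mk.expected_contrast:
            for cat in grp:
                if cat not in mk.analysis_categories:
                    raise ValueError(f"marker {mk.name}: contrast category "
                                     f"{cat!r} outside analysis set")
    return registry


def mean_amplitude(
    evoked: Evoked, marker: MarkerDefinition
) -> tuple[dict[str, float], float]:
    """Mean voltage over the marker window, per electrode and pooled.

    The window is half-open in samples (floor conversion of both bounds,
    relative to stimulus onset); the pooled value is the plain mean of the
    per-electrode values. The evoked is assumed baseline-corrected, so the
    result is a baseline-referenced mean area amplitude in microvolt.
    """
    onset = evoked.onset_index
    lo = onset + ms_to_sample(marker.window_ms[0], evoked.fs)
    hi = onset + ms_to_sample(marker.window_ms[1], evoked.fs)
    if lo < 0 or hi > evoked.data.shape[1] or lo >= hi:
        raise ValueError(
            f"marker {marker.name}: window {marker.window_ms} ms outside epoch"
        )
    per_electrode = {
        el: float(evoked.data[evoked.montage.index(el), lo:hi].mean())
        for el in marker.electrodes
    }
    pooled = float(np.mean(list(per_electrode.values())))
    return per_electrode, pooled


def extract_feature_table(
    evokeds: dict[int, dict[str, Evoked]],
    registry: list[MarkerDefinition] | None = None,
) -> pd.DataFrame:
    """Long-format amplitude table over subjects x categories x markers x
    electrodes.

    ``evokeds`` maps subject id -> category -> baseline-corrected Evoked.
    Each marker is measured on every category of its modality (the
    cross-modal marker on all categories). A missing evoked for an
    applicable category is an explicit error listing every omission.
    """
    if registry is None:
        registry = marker_registry()
    gaps = []
    for subj, by_cat in evokeds.items():
        for mk in registry:
            for cat in mk.applicable_categories:
                if cat not in by_cat:
                    gaps.append((subj, mk.name, cat))
    if gaps:
        raise ValueError(f"missing evoked responses for: {sorted(set(gaps))}")

    rows = []
    for subj in sorted(evokeds):
        for mk in registry:
            for cat in mk.applicable_categories:
                per_el, _ = mean_amplitude(evokeds[subj][cat], mk)
                for el, amp in per_el.items():
                    rows.append((subj, cat, mk.name, el,
                                 hemisphere_of(el), amp))
    table = pd.DataFrame(
        rows,
        columns=["subject", "category", "marker", "electrode",
                 "hemisphere", "amplitude_uv"],
    )
    if not np.isfinite(table["amplitude_uv"]).all():
        raise ValueError("non-finite amplitudes in feature table")
    return table


def pooled_features(table: pd.DataFrame) -> pd.DataFrame:
    """Electrode-pooled amplitudes: one row per subject x category x marker."""
    return (
        table.groupby(["subject", "category", "marker"], sort=True)
        ["amplitude_uv"].mean().reset_index()
    )
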