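"""High-density 10/5 scalp montage: labels, idealized spherical geometry,
hemisphere bookkeeping, and the 2-D head-disc projection used for topography.

The default montage is a frozen 126-channel subset of the extended 10/5
nomenclature (plus two bipolar ocular channels), shipped as a plain-text
asset ``data/montage_126.tsv`` with one row per electrode:
label, theta (degrees from the vertex), phi (azimuth, 0 = nasion,
+90 = right preauricular point).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "Montage",
    "build_default_montage",
    "hemisphere_of",
    "homolog",
    "project_2d",
]

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(\d+)(h?)$")

#: disc radius (degrees from vertex) mapped to r = 1 in the 2-D projection;
#: chosen just beyond the lowest ring in the default set so all radii stay < 1
_THETA_REF_DEG = 125.0

#: synthetic bipolar ocular derivations appended after the scalp channels
EOG_LABELS = ("HEOG", "VEOG")


@dataclass(frozen=True)
class Montage:
    """An ordered electrode set with spherical-head geometry.

    ``channels`` are scalp electrodes only; the ocular channels listed in
    ``eog_channels`` live at the end of any data array produced against this
    montage but carry no scalp position.
    """

    channels: tuple[str, ...]
    theta_deg: np.ndarray  # angle from vertex, per scalp channel
    phi_deg: np.ndarray    # azimuth, 0 = nasion, +90 = right ear
    eog_channels: tuple[str, ...] = EOG_LABELS
    reference: str = "averaged ears"
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate electrode labels")
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.channels)}
        )

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def all_channels(self) -> tuple[str, ...]:
        """Scalp channels followed by EOG channels (data-array row order)."""
        return self.channels + self.eog_channels

    @property
    def n_all(self) -> int:
        return len(self.channels) + len(self.eog_channels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"electrode {label!r} not in montage") from None

    def __contains__(self, label: str) -> bool:
        return label in self._index


def _parse(label: str):
    """Split a 10/5 label into (row letters, number, half-step flag).

    Midline labels (z-suffixed, e.g. ``Fz``, ``POOz``) return number ``None``.
    """
    if label.endswith("z") or label.endswith("Z"):
        return label[:-1], None, False
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"not a 10/5 electrode label: {label!r}")
    return m.group(1), int(m.group(2)), m.group(3) == "h"


def hemisphere_of(label: str, montage: Montage | None = None) -> str:
    """Return ``'left'``, ``'midline'`` or ``'right'`` for a 10/5 label.

    Odd electrode numbers are left-hemisphere, even numbers right, and a
    ``z`` suffix marks the midline. If a montage is given, the label must
    belong to it.
    """
    if montage is not None and label not in montage:
        raise KeyError(f"electrode {label!r} not in montage")
    _, num, _ = _parse(label)
    if num is None:
        return "midline"
    return "left" if num % 2 == 1 else "right"


def homolog(label: str, montage: Montage | None = None) -> str:
    """Mirror-image electrode (P7 -> P8, AF4 -> AF3, Oz -> Oz).

    An involution over the 10/5 nomenclature; midline labels map to
    themselves.
    """
    if montage is not None and label not in montage:
        raise KeyError(f"electrode {label!r} not in montage")
    row, num, half = _parse(label)
    if num is None:
        return label
    mirrored = num + 1 if num % 2 == 1 else num - 1
    out = f"{row}{mirrored}{'h' if half else ''}"
    if montage is not None and out not in montage:
        raise KeyError(f"homolog {out!r} of {label!r} not in montage")
    return out


def build_default_montage() -> Montage:
    """Load the frozen 126-channel 10/5 montage (plus HEOG/VEOG).

    Every electrode used by the marker registry is guaranteed present, the
    set is closed under ``homolog``, and all projected positions lie inside
    the unit head disc.
    """
    text = (
        resources.files("erpmark")
        .joinpath("data/montage_126.tsv")
        .read_text()
    )
    labels, thetas, phis = [], [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        lab, th, ph = line.split("\t")
        labels.append(lab)
        thetas.append(float(th))
        phis.append(float(ph))
    return Montage(
        channels=tuple(labels),
        theta_deg=np.asarray(thetas),
        phi_deg=np.asarray(phis),
    )


def project_2d(montage: Montage) -> np.ndarray:
    """Azimuthal-equidistant projection of the scalp channels onto the unit
    head disc, shape (n_channels, 2).

    The vertex (Cz) maps to the origin; x is lateral (left negative, right
    positive), y points toward the nasion. Radius is proportional to the
    angle from the vertex, normalized so the whole montage fits in r <= 1.
    """
    r = montage.theta_deg / _THETA_REF_DEG
    phi = np.radians(montage.phi_deg)
    return np.column_stack([r * np.sin(phi), r * np.cos(phi)])
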