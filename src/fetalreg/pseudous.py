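"""Pseudo-ultrasound synthesis and real-ultrasound preprocessing.

A pseudo-ultrasound image is an artefact-free rendition of a structure map in
which every structure receives a uniform intensity representing its average
echogenicity.  Since local NCC is invariant to affine intensity changes, only
the *order* of brightness matters for registration, not the exact values; the
default table below follows the clinically observed ordering from brightest
to darkest: skull; choroid plexus / septum pellucidum / falx; brain surface;
cerebellum; deep grey matter and brainstem; cerebral hemispheres.  Speckle is
deliberately not modelled — it cannot be predicted from MR — and real US
volumes are instead lightly smoothed before matching.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .imagecore import LabelVolume, ScalarVolume, gaussian_smooth

# brightest-to-darkest tiers; intensities strictly decreasing in [0, 1]
DEFAULT_TIERS: list[tuple[tuple[str, ...], float]] = [
    (("skull",), 1.00),
    (("choroid_plexus", "septum_pellucidum", "midline_falx"), 0.80),
    (("brain_surface",), 0.65),
    (("cerebellum",), 0.50),
    (("dgm", "brainstem"), 0.35),
    (("cortical_hemisphere_L", "cortical_hemisphere_R", "cerebellar_wm", "csf"), 0.20),
]


@dataclass
class EchogenicityTable:
    """Ordered (structure set, intensity) tiers; background is always 0."""

    tiers: list[tuple[tuple[str, ...], float]] = field(default_factory=lambda: list(DEFAULT_TIERS))

    def __post_init__(self) -> None:
        vals = [v for _, v in self.tiers]
        if any(not (0.0 <= v <= 1.0) for v in vals):
            raise ValueError("tier intensities must lie in [0, 1]")
        if any(b >= a for a, b in zip(vals, vals[1:])):
            raise ValueError("tier intensities must be strictly decreasing from brightest to darkest")

    def intensity_of(self) -> dict[str, float]:
        out: dict[str, float] = {"background": 0.0}
        for names, v in self.tiers:
            for n in names:
                out[n] = float(v)
        return out

    def remapped(self, fn) -> "EchogenicityTable":
        """Apply a strictly increasing intensity remapping to every tier."""
        return EchogenicityTable([(names, float(fn(v))) for names, v in self.tiers])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([{"structures": list(n), "intensity": v} for n, v in self.tiers], fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EchogenicityTable":
        with open(path) as fh:
            raw = json.load(fh)
        return cls([(tuple(e["structures"]), float(e["intensity"])) for e in raw])


def assign_pseudo_intensities(smap: LabelVolume, table: EchogenicityTable | None = None) -> ScalarVolume:
    """Piecewise-constant pseudo-ultrasound image from a structure map."""
    table = table or EchogenicityTable()
    lut_by_name = table.intensity_of()
    max_label = int(smap.labels.max())
    lut = np.zeros(max_label + 1)
    present = np.unique(smap.labels)
    for lab in present:
        name = smap.scheme[int(lab)]
        if name not in lut_by_name:
            raise ValueError(f"structure {name!r} (label {int(lab)}) missing from echogenicity table")
        lut[lab] = lut_by_name[name]
    return ScalarVolume(smap.grid, lut[smap.labels])


def preprocess_us(us: ScalarVolume, sigma_mm: float = 0.5) -> tuple[ScalarVolume, float]:
    """Lightly smooth a real US volume; returns the smoothed image and its
    intensity range (used for the block-variance threshold)."""
    smoothed = gaussian_smooth(us, sigma_mm)
    rng = float(np.ptp(smoothed.values))
    if rng == 0.0:
        warnings.warn("constant ultrasound volume: intensity range 0, all blocks will be rejected")
    return smoothed, rng
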