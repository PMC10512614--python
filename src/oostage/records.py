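"""Core domain objects: maturity labels, canonical region channels, oocyte records.

A single oocyte is represented by a grayscale image plus one binary mask per
annotated subcellular region and a meiotic-maturity label:

* ``PI``  (prophase I)  — immature; the germinal vesicle (GV) is visible.
* ``MI``  (metaphase I) — intermediate; neither GV nor first polar body.
* ``MII`` (metaphase II) — mature, fertilizable; a first polar body (FPB),
  possibly fragmented (FFPB), sits in the perivitelline space.

The channel numbering below is the canonical layer order used when stacking
region masks into a classifier input tensor; channel 1 is the grayscale image
itself, channels 2-15 are region masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LABELS: tuple[str, ...] = ("MI", "MII", "PI")

#: Canonical channel order (channel 1 first).
CANONICAL_CHANNELS: tuple[str, ...] = (
    "oocyte image",
    "clear cytoplasm",
    "diffuse cytoplasmic granularity",
    "cytoplasmic granular area",
    "smooth endoplasmic reticulum cluster",
    "vacuoles",
    "dark cytoplasm",
    "first polar body",
    "multi-polar body",
    "fragmented first polar body",
    "second polar body",
    "perivitelline space",
    "zona pellucida",
    "germinal vesicle",
    "cumulus/corona cells",
)

#: The 14 region-mask channels (everything but the image plane).
REGIONS: tuple[str, ...] = CANONICAL_CHANNELS[1:]

GV = "germinal vesicle"
FPB = "first polar body"
FFPB = "fragmented first polar body"


def region_slug(region: str) -> str:
    """Filesystem-safe name for a region channel."""
    return region.replace("/", "-").replace(" ", "_")


def check_label(label: str) -> str:
    if label not in LABELS:
        raise ValueError(f"unknown maturity label {label!r}; admissible labels: {', '.join(LABELS)}")
    return label


@dataclass
class OocyteRecord:
    """One oocyte: image, per-region binary masks, and a maturity label."""

    id: str
    image: np.ndarray  # 2-D uint8, intensities in [0, 255]
    masks: dict[str, np.ndarray] = field(default_factory=dict)  # region -> {0,1} uint8
    label: str = "MII"

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape  # type: ignore[return-value]

    def mask(self, region: str) -> np.ndarray:
        """Mask for ``region``; an all-zero plane if the region is absent."""
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}; canonical regions: {', '.join(REGIONS)}")
        m = self.masks.get(region)
        if m is None:
            return np.zeros(self.image.shape, dtype=np.uint8)
        return m

    def validate(self) -> "OocyteRecord":
        """Check all record invariants; return self (chainable)."""
        check_label(self.label)
        if self.image.ndim != 2 or min(self.image.shape) == 0:
            raise ValueError("image must be a non-degenerate 2-D array")
        for name, m in self.masks.items():
            if name not in REGIONS:
                raise ValueError(f"unknown region {name!r}")
            if m.shape != self.image.shape:
                raise ValueError(f"mask {name!r} shape {m.shape} != image shape {self.image.shape}")
            vals = np.unique(m)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"mask {name!r} is not binary")
        gv = bool(self.mask(GV).any())
        pb = bool(self.mask(FPB).any() or self.mask(FFPB).any())
        if self.label == "PI" and not (gv and not pb):
            raise ValueError("PI record must have a GV mask and no (F)FPB mask")
        if self.label == "MII" and not (pb and not gv):
            raise ValueError("MII record must have an (F)FPB mask and no GV mask")
        if self.label == "MI" and (gv or pb):
            raise ValueError("MI record must have neither GV nor (F)FPB masks")
        return self
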