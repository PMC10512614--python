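"""Synthetic oocyte phantom generator.

Real clinical oocyte micrographs cannot be redistributed, so every stage of
the staging pipeline is developed and tested against *phantoms*: ellipse-
composed single-cell images with ground-truth region masks whose composition
is class-conditional,

* PI  phantoms carry a germinal-vesicle (GV) disc inside the cytoplasm,
* MII phantoms carry a first polar body (FPB) — a single disc, or 2-4 small
  discs when fragmented (FFPB) — at the cytoplasm margin,
* MI  phantoms carry neither,

so that GV/FPB presence is the discriminative signal, mirroring the biology.
The cell is drawn as concentric ellipses: cytoplasm, perivitelline space
(PVS), and the bright zona pellucida (ZP) shell, optionally ringed by
cumulus/corona cell debris.  Region scale follows the convention that the GV
occupies ~11 % and the FPB ~12 % of the cytoplasm area.  Auxiliary organelle
regions (vacuoles, dark cytoplasm, granularity, ...) appear with
class-independent probabilities, so their channels are deliberately
uninformative for maturity.

Images are rendered in grayscale with Gaussian blur, additive noise and
multiplicative brightness jitter; only the masks carry ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse

from .records import FFPB, FPB, GV, LABELS, OocyteRecord, REGIONS, check_label, region_slug

__all__ = ["PhantomParams", "generate_phantom", "generate_dataset", "write_dataset", "read_dataset"]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and photometry of the phantom renderer.

    Radius/thickness ranges are fractions of the image side; area fractions
    are relative to the cytoplasm support.
    """

    side: int = 256
    outer_radius: tuple[float, float] = (0.36, 0.41)   # ZP outer boundary
    zp_thickness: tuple[float, float] = (0.050, 0.075)
    pvs_thickness: tuple[float, float] = (0.020, 0.035)
    gv_area_frac: tuple[float, float] = (0.095, 0.125)   # of cytoplasm area
    fpb_area_frac: tuple[float, float] = (0.108, 0.132)  # of cytoplasm area
    fragmentation_prob: float = 0.2   # MII polar body rendered as FFPB fragments
    blur_sigma: float = 1.2           # px
    noise_std: float = 6.0            # intensity units
    brightness_jitter: float = 0.1    # multiplicative, U[1-j, 1+j]
    aux_region_probs: dict[str, float] = field(
        default_factory=lambda: {
            "vacuoles": 0.25,
            "dark cytoplasm": 0.20,
            "diffuse cytoplasmic granularity": 0.30,
            "cytoplasmic granular area": 0.25,
            "smooth endoplasmic reticulum cluster": 0.10,
            "cumulus/corona cells": 0.30,
        }
    )

    # rendered mean intensities per structure
    intensities: dict[str, float] = field(
        default_factory=lambda: {
            "background": 30.0,
            "cumulus/corona cells": 62.0,
            "zona pellucida": 190.0,
            "perivitelline space": 60.0,
            "clear cytoplasm": 125.0,
            "diffuse cytoplasmic granularity": 118.0,
            "cytoplasmic granular area": 137.0,
            "smooth endoplasmic reticulum cluster": 142.0,
            "vacuoles": 144.0,
            "dark cytoplasm": 112.0,   # diffuse darkening, milder than the GV
            "germinal vesicle": 92.0,
            "first polar body": 215.0,
        }
    )

    def validate(self) -> "PhantomParams":
        if self.side < 32:
            raise ValueError("side must be at least 32 px")
        for name in ("outer_radius", "zp_thickness", "pvs_thickness", "gv_area_frac", "fpb_area_frac"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range must be positive and ordered")
        if not 0 <= self.fragmentation_prob <= 1:
            raise ValueError("fragmentation_prob must be in [0, 1]")
        for k, p in self.aux_region_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"aux region probability for {k!r} must be in [0, 1]")
        # GV/FPB must fit inside the cytoplasm
        if self.gv_area_frac[1] >= 1 or self.fpb_area_frac[1] >= 1:
            raise ValueError("GV/FPB area fractions must be < 1 (smaller than the cytoplasm)")
        return self


def _ellipse_mask(shape, cy, cx, a, b, rotation=0.0):
    m = np.zeros(shape, dtype=np.uint8)
    rr, cc = draw_ellipse(cy, cx, a, b, shape=shape, rotation=rotation)
    m[rr, cc] = 1
    return m


def _boundary_radius(a, b, phi, theta):
    """Radius of an ellipse (semi-axes a,b rotated by phi) in direction theta."""
    psi = theta - phi
    return a * b / math.hypot(b * math.cos(psi), a * math.sin(psi))


def generate_phantom(label: str, params: PhantomParams | None = None, seed: int = 0) -> OocyteRecord:
    """Render one phantom oocyte of maturity class ``label``.

    Deterministic: identical ``(label, params, seed)`` yield an identical
    record.
    """
    check_label(label)
    params = (params or PhantomParams()).validate()
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), LABELS.index(label)]))
    s = params.side
    shape = (s, s)
    inten = params.intensities

    # --- cell geometry -------------------------------------------------
    cy = s / 2 + rng.uniform(-0.03, 0.03) * s
    cx = s / 2 + rng.uniform(-0.03, 0.03) * s
    r_out = rng.uniform(*params.outer_radius) * s
    t_zp = rng.uniform(*params.zp_thickness) * s
    t_pvs = rng.uniform(*params.pvs_thickness) * s
    q = rng.uniform(0.92, 1.0)            # axis ratio
    phi = rng.uniform(0, math.pi)         # orientation
    a_out, b_out = r_out, r_out * q
    a_zin, b_zin = a_out - t_zp, b_out - t_zp
    a_cyt, b_cyt = a_zin - t_pvs, b_zin - t_pvs

    outer = _ellipse_mask(shape, cy, cx, a_out, b_out, phi)
    zp_in = _ellipse_mask(shape, cy, cx, a_zin, b_zin, phi)
    cyt = _ellipse_mask(shape, cy, cx, a_cyt, b_cyt, phi)
    masks: dict[str, np.ndarray] = {
        "zona pellucida": outer & ~zp_in,
        "perivitelline space": zp_in & ~cyt,
        "clear cytoplasm": cyt,
    }
    cyt_area = math.pi * a_cyt * b_cyt

    # --- class-conditional structures ----------------------------------
    if label == "PI":
        frac = rng.uniform(*params.gv_area_frac)
        r_gv = math.sqrt(frac * cyt_area / math.pi)
        r_off = rng.uniform(0, 0.5) * (min(a_cyt, b_cyt) - r_gv)
        th = rng.uniform(0, 2 * math.pi)
        masks[GV] = _ellipse_mask(shape, cy + r_off * math.sin(th), cx + r_off * math.cos(th), r_gv, r_gv)
    elif label == "MII":
        frac = rng.uniform(*params.fpb_area_frac)
        r_pb = math.sqrt(frac * cyt_area / math.pi)
        th = rng.uniform(0, 2 * math.pi)
        d = _boundary_radius(a_cyt, b_cyt, phi, th) - 0.25 * r_pb
        fragmented = rng.uniform() < params.fragmentation_prob
        if fragmented:
            k = int(rng.integers(2, 5))
            r_i = r_pb / math.sqrt(k)
            dphi = 2.4 * r_i / d
            pb = np.zeros(shape, dtype=np.uint8)
            for j in range(k):
                tj = th + (j - (k - 1) / 2) * dphi
                dj = _boundary_radius(a_cyt, b_cyt, phi, tj) - 0.25 * r_pb
                pb |= _ellipse_mask(shape, cy + dj * math.sin(tj), cx + dj * math.cos(tj), r_i, r_i)
            masks[FFPB] = pb & outer
        else:
            masks[FPB] = _ellipse_mask(shape, cy + d * math.sin(th), cx + d * math.cos(th), r_pb, r_pb) & outer

    # --- class-independent auxiliary regions ---------------------------
    for region, prob in params.aux_region_probs.items():
        if rng.uniform() >= prob:
            continue
        if region == "cumulus/corona cells":
            n = int(rng.integers(3, 8))
            th0 = rng.uniform(0, 2 * math.pi)
            m = np.zeros(shape, dtype=np.uint8)
            for j in range(n):
                tj = th0 + j * rng.uniform(0.15, 0.35)
                rj = _boundary_radius(a_out, b_out, phi, tj) + 0.02 * s
                m |= _ellipse_mask(shape, cy + rj * math.sin(tj), cx + rj * math.cos(tj), 0.025 * s, 0.025 * s)
            m &= ~outer
        else:
            sizes = {
                "vacuoles": (0.08, 0.14),
                "dark cytoplasm": (0.15, 0.30),
                "diffuse cytoplasmic granularity": (0.30, 0.50),
                "cytoplasmic granular area": (0.15, 0.35),
                "smooth endoplasmic reticulum cluster": (0.10, 0.18),
            }[region]
            n = int(rng.integers(1, 4)) if region == "vacuoles" else 1
            m = np.zeros(shape, dtype=np.uint8)
            for _ in range(n):
                r_reg = rng.uniform(*sizes) * min(a_cyt, b_cyt)
                r_off = rng.uniform(0, 0.9) * (min(a_cyt, b_cyt) - r_reg)
                th = rng.uniform(0, 2 * math.pi)
                m |= _ellipse_mask(shape, cy + r_off * math.sin(th), cx + r_off * math.cos(th), r_reg, r_reg)
            m &= cyt
        if m.any():
            masks[region] = m

    # --- rendering ------------------------------------------------------
    img = np.full(shape, inten["background"], dtype=np.float64)
    paint_order = [
        "cumulus/corona cells",
        "zona pellucida",
        "perivitelline space",
        "clear cytoplasm",
        "diffuse cytoplasmic granularity",
        "cytoplasmic granular area",
        "smooth endoplasmic reticulum cluster",
        "vacuoles",
        "dark cytoplasm",
        GV,
    ]
    for region in paint_order:
        if region in masks:
            img[masks[region] > 0] = inten.get(region, inten["clear cytoplasm"])
    for region in (FPB, FFPB):
        if region in masks:
            img[masks[region] > 0] = inten["first polar body"]
    if "diffuse cytoplasmic granularity" in masks:
        speckle = rng.normal(0, 8.0, size=shape)
        img += speckle * masks["diffuse cytoplasmic granularity"]
    img = gaussian_filter(img, params.blur_sigma)
    img += rng.normal(0, params.noise_std, size=shape)
    img *= 1 + rng.uniform(-params.brightness_jitter, params.brightness_jitter)
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)

    masks = {k: v for k, v in masks.items() if v.any()}
    return OocyteRecord(id=f"{label}-{seed}", image=image, masks=masks, label=label).validate()


def generate_dataset(
    counts: dict[str, int], params: PhantomParams | None = None, seed: int = 0
) -> tuple[list[OocyteRecord], pd.DataFrame]:
    """Generate ``counts[label]`` phantoms per class, with a manifest.

    Returns the records and a manifest DataFrame (columns ``id``, ``label``;
    path columns are filled in by :func:`write_dataset`).
    """
    params = (params or PhantomParams()).validate()
    records: list[OocyteRecord] = []
    for label in LABELS:
        n = int(counts.get(label, 0))
        if n < 0:
            raise ValueError(f"count for {label} must be >= 0")
        ci = LABELS.index(label)
        for i in range(n):
            child = int(np.random.SeedSequence([int(seed), ci, i]).generate_state(1)[0] % 2**31)
            rec = generate_phantom(label, params, child)
            rec.id = f"{label}-{i:04d}"
            records.append(rec)
    manifest = pd.DataFrame({"id": [r.id for r in records], "label": [r.label for r in records]})
    return records, manifest


def write_dataset(records: list[OocyteRecord], directory: str | Path) -> Path:
    """Write images, nonempty masks and a CSV manifest; return the manifest path.

    Masks are stored one PNG per region as ``<id>_<region>.png`` (0/255);
    empty regions emit no file and read back as all-zero planes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        rec.validate()
        img_path = directory / f"{rec.id}.png"
        Image.fromarray(rec.image, mode="L").save(img_path)
        row: dict[str, str] = {"id": rec.id, "label": rec.label, "image_path": img_path.name}
        for region in REGIONS:
            m = rec.masks.get(region)
            if m is not None and m.any():
                mp = directory / f"{rec.id}_{region_slug(region)}.png"
                Image.fromarray((m * 255).astype(np.uint8), mode="L").save(mp)
                row[region_slug(region)] = mp.name
            else:
                row[region_slug(region)] = ""
        rows.append(row)
    cols = ["id", "label", "image_path"] + [region_slug(r) for r in REGIONS]
    manifest = pd.DataFrame(rows, columns=cols)
    manifest_path = directory / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_dataset(manifest_path: str | Path) -> list[OocyteRecord]:
    """Read a dataset written by :func:`write_dataset` (pixel-identical)."""
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    records = []
    for _, row in manifest.iterrows():
        image = np.asarray(Image.open(directory / row["image_path"]), dtype=np.uint8)
        masks = {}
        for region in REGIONS:
            rel = row[region_slug(region)]
            if rel:
                m = np.asarray(Image.open(directory / rel), dtype=np.uint8)
                masks[region] = (m > 127).astype(np.uint8)
        records.append(OocyteRecord(id=row["id"], image=image, masks=masks, label=row["label"]).validate())
    return records
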