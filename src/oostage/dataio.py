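"""Record I/O helpers: resolution normalization and classifier-tensor assembly.

The classifier consumes an H×W×N tensor whose planes are drawn from the
canonical channel order (image plane scaled to [0,1]; region planes binary).
Oversized records are first downscaled with nearest-neighbor interpolation so
that both sides fit the 550 px training bound; undersized records are
symmetrically zero-padded up to the network input side just before training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .records import CANONICAL_CHANNELS, FFPB, FPB, OocyteRecord

__all__ = [
    "ChannelSelection",
    "InputTensor",
    "normalize_resolution",
    "merge_fpb_masks",
    "assemble_tensor",
    "pad_tensor",
    "save_tensor",
    "load_tensor",
]

RESOLUTION_LIMIT = 550  # px; training-time upper bound on either side


@dataclass(frozen=True)
class ChannelSelection:
    """Subset of canonical channels feeding the classifier.

    ``merge_fpb`` folds the fragmented-first-polar-body mask into the
    first-polar-body channel so both present as a single input feature.
    """

    channels: tuple[str, ...]
    merge_fpb: bool = False

    def __post_init__(self):
        seen = set()
        for c in self.channels:
            if c not in CANONICAL_CHANNELS:
                raise ValueError(
                    f"unknown channel {c!r}; canonical channels: {', '.join(CANONICAL_CHANNELS)}"
                )
            if c in seen:
                raise ValueError(f"duplicate channel {c!r}")
            seen.add(c)
        if self.merge_fpb and FFPB in seen:
            raise ValueError("with merge_fpb, the fragmented first polar body may not be a separate channel")

    @property
    def ordered(self) -> tuple[str, ...]:
        """Selected channels in canonical order (selection order is irrelevant)."""
        return tuple(c for c in CANONICAL_CHANNELS if c in self.channels)


@dataclass
class InputTensor:
    """H×W×N channel volume plus the names of its planes."""

    data: np.ndarray  # float32, H×W×N
    channel_names: tuple[str, ...]

    def __post_init__(self):
        if self.data.ndim != 3 or self.data.shape[2] != len(self.channel_names):
            raise ValueError("tensor depth must equal the number of channel names")

    @property
    def side(self) -> tuple[int, int]:
        return self.data.shape[:2]


def _nn_resize(plane: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resample by index mapping (exact, interpolation-free)."""
    h, w = plane.shape
    oh, ow = out_shape
    ri = np.minimum((np.arange(oh) * h / oh).astype(int), h - 1)
    ci = np.minimum((np.arange(ow) * w / ow).astype(int), w - 1)
    return plane[np.ix_(ri, ci)]


def normalize_resolution(record: OocyteRecord, limit: int = RESOLUTION_LIMIT) -> OocyteRecord:
    """Downscale oversized records (with their masks) to ``limit``×``limit``.

    Records already within the limit are returned unchanged.  Nearest-neighbor
    resampling is used for the image and every mask, so masks stay binary.
    """
    h, w = record.shape
    if h <= limit and w <= limit:
        return record
    out = (limit, limit)
    return OocyteRecord(
        id=record.id,
        image=_nn_resize(record.image, out),
        masks={k: _nn_resize(m, out) for k, m in record.masks.items()},
        label=record.label,
    )


def merge_fpb_masks(record: OocyteRecord) -> OocyteRecord:
    """Union the FFPB mask into the FPB mask; the FFPB plane is dropped."""
    masks = dict(record.masks)
    ffpb = masks.pop(FFPB, None)
    if ffpb is not None:
        fpb = masks.get(FPB)
        masks[FPB] = ffpb if fpb is None else (fpb | ffpb)
    return OocyteRecord(id=record.id, image=record.image, masks=masks, label=record.label)


def assemble_tensor(record: OocyteRecord, selection: ChannelSelection) -> InputTensor:
    """Stack the selected channels of ``record`` in canonical order.

    The image plane is scaled into [0,1]; mask planes are binary {0,1}.
    """
    rec = merge_fpb_masks(record) if selection.merge_fpb else record
    planes = []
    for name in selection.ordered:
        if name == "oocyte image":
            planes.append(rec.image.astype(np.float32) / 255.0)
        else:
            planes.append(rec.mask(name).astype(np.float32))
    return InputTensor(data=np.stack(planes, axis=-1), channel_names=selection.ordered)


def pad_tensor(t: InputTensor, side: int) -> InputTensor:
    """Symmetric zero-pad (or pass through) to a ``side``×``side`` frame."""
    h, w = t.side
    if h > side or w > side:
        raise ValueError(f"tensor {h}x{w} exceeds the requested side {side}")
    if (h, w) == (side, side):
        return t
    top, left = (side - h) // 2, (side - w) // 2
    data = np.zeros((side, side, t.data.shape[2]), dtype=t.data.dtype)
    data[top : top + h, left : left + w] = t.data
    return InputTensor(data=data, channel_names=t.channel_names)


def save_tensor(t: InputTensor, path: str | Path) -> None:
    """Store a tensor as a raw ``.npy`` with a sidecar JSON naming its planes."""
    path = Path(path)
    np.save(path, t.data)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"channel_names": list(t.channel_names), "shape": list(t.data.shape)}))


def load_tensor(path: str | Path) -> InputTensor:
    path = Path(path)
    data = np.load(path if path.suffix == ".npy" else path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return InputTensor(data=data, channel_names=tuple(meta["channel_names"]))
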