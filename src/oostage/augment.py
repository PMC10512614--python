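"""Rotation/translation augmentation of classifier tensors, with an on-disk cache.

Each base tensor (side B, canonically 550 px) is expanded into a grid of
``n_rot`` deterministic rotations — the i-th angle is 360/n_rot·(i−1) degrees —
crossed with ``n_shift`` random integer translations.  Translation is realised
by placing the rotated B×B frame into a larger zero-filled output frame of
side B + shift_range (590 px under the canonical 550+40 configuration) at a
uniformly drawn offset, so "shifting in the range of 40 px" and the enlarged
output side are two views of the same operation.

Mask planes are rotated with nearest-neighbor resampling (binarity is
preserved exactly); the image plane is rotated bilinearly.  Because the
augmentation is the slow step of training, variants are precomputed into a
cache directory once and memory-mapped afterwards.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import rotate as nd_rotate

from .dataio import ChannelSelection, InputTensor, assemble_tensor, load_tensor, normalize_resolution, pad_tensor, save_tensor

__all__ = ["AugmentConfig", "rotation_angles", "augment_tensor", "build_cache", "CacheDataset", "TensorDataset"]


@dataclass(frozen=True)
class AugmentConfig:
    n_rot: int = 12
    n_shift: int = 5
    shift_range: int = 40      # px of total frame expansion
    output_side: int = 590
    seed: int = 0

    def validate(self) -> "AugmentConfig":
        if self.n_rot < 1 or self.n_shift < 1 or self.shift_range < 0:
            raise ValueError("n_rot and n_shift must be >= 1 and shift_range >= 0")
        if self.output_side - self.shift_range < 1:
            raise ValueError("output_side must exceed shift_range")
        return self

    @property
    def base_side(self) -> int:
        return self.output_side - self.shift_range


def rotation_angles(n_rot: int) -> list[float]:
    """Deterministic rotation grid: the i-th (1-based) angle is 360/n_rot·(i−1)."""
    if n_rot < 1:
        raise ValueError("n_rot must be >= 1")
    return [360.0 / n_rot * i for i in range(n_rot)]


def _rotate_tensor(data: np.ndarray, angle: float, mask_planes: np.ndarray) -> np.ndarray:
    """Rotate H×W×N about the frame center; NN for masks, bilinear for the rest."""
    if angle % 360 == 0:
        return data.copy()
    out = np.empty_like(data)
    for k in range(data.shape[2]):
        order = 0 if mask_planes[k] else 1
        out[..., k] = nd_rotate(data[..., k], angle, reshape=False, order=order, mode="constant", cval=0.0)
    if mask_planes.any():
        out[..., mask_planes] = np.rint(out[..., mask_planes]).clip(0, 1)
    return out


def augment_tensor(t: InputTensor, cfg: AugmentConfig) -> list[InputTensor]:
    """Expand one base tensor into ``n_rot × n_shift`` shifted/rotated variants."""
    cfg.validate()
    h, w = t.side
    if h != cfg.base_side or w != cfg.base_side:
        raise ValueError(
            f"tensor side {h}x{w} does not match the expected base side "
            f"{cfg.base_side} (= output_side {cfg.output_side} - shift_range {cfg.shift_range})"
        )
    mask_planes = np.array([n != "oocyte image" for n in t.channel_names])
    rng = np.random.default_rng(cfg.seed)
    out: list[InputTensor] = []
    for angle in rotation_angles(cfg.n_rot):
        rotated = _rotate_tensor(t.data, angle, mask_planes)
        for _ in range(cfg.n_shift):
            dy, dx = rng.integers(0, cfg.shift_range + 1, size=2)
            frame = np.zeros((cfg.output_side, cfg.output_side, t.data.shape[2]), dtype=t.data.dtype)
            frame[dy : dy + h, dx : dx + w] = rotated
            out.append(InputTensor(data=frame, channel_names=t.channel_names))
    return out


def build_cache(records, selection: ChannelSelection, cfg: AugmentConfig, directory) -> Path:
    """Precompute augmented variants for every record; returns the manifest path.

    Layout: ``<dir>/<record_id>/rot<i>_shift<j>.npy`` plus a JSON manifest
    mapping record id → variant paths.  Re-running over an up-to-date cache is
    a no-op; files are written deterministically so a rebuild with the same
    seed is byte-identical.
    """
    cfg.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {"labels": {}, "variants": {}}
    for rec in records:
        rec_dir = directory / rec.id
        expected = [
            rec_dir / f"rot{i}_shift{j}.npy" for i in range(cfg.n_rot) for j in range(cfg.n_shift)
        ]
        manifest["labels"][rec.id] = rec.label
        manifest["variants"][rec.id] = [str(p.relative_to(directory)) for p in expected]
        if all(p.exists() for p in expected):
            continue
        rec_dir.mkdir(exist_ok=True)
        base = pad_tensor(assemble_tensor(normalize_resolution(rec, cfg.base_side), selection), cfg.base_side)
        # per-record seed keeps the cache independent of record ordering
        rec_cfg = AugmentConfig(
            cfg.n_rot, cfg.n_shift, cfg.shift_range, cfg.output_side,
            seed=int(np.random.SeedSequence([cfg.seed, zlib.crc32(rec.id.encode())]).generate_state(1)[0] % 2**31),
        )
        for path, variant in zip(expected, augment_tensor(base, rec_cfg)):
            save_tensor(variant, path)
    manifest_path = directory / "cache_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path


class CacheDataset:
    """Read-side view of an augmentation cache: ids, labels, variant loading."""

    def __init__(self, manifest_path):
        self.directory = Path(manifest_path).parent
        m = json.loads(Path(manifest_path).read_text())
        self.labels: dict[str, str] = m["labels"]
        self._variants: dict[str, list[str]] = m["variants"]

    def ids(self) -> list[str]:
        return list(self._variants)

    def n_variants(self, rec_id: str) -> int:
        return len(self._variants[rec_id])

    def load(self, rec_id: str, variant: int) -> InputTensor:
        return load_tensor(self.directory / self._variants[rec_id][variant])


class TensorDataset:
    """In-memory variant store with the same protocol as :class:`CacheDataset`.

    Convenient at desk scale, where the augmented variants of a few hundred
    small phantoms fit comfortably in memory.
    """

    def __init__(self):
        self.labels: dict[str, str] = {}
        self._variants: dict[str, list[InputTensor]] = {}

    @classmethod
    def from_records(cls, records, selection: ChannelSelection,
                     cfg: AugmentConfig | None = None, side: int | None = None) -> "TensorDataset":
        """Assemble (and optionally augment) tensors for every record.

        With ``cfg``, each record is normalized/padded to the base side and
        expanded into the rotation × shift grid; variant 0 is the unrotated,
        centred placement so deterministic evaluation paths have a canonical
        view.  Without ``cfg``, each record contributes a single tensor padded
        to ``side``.
        """
        ds = cls()
        for rec in records:
            if cfg is not None:
                cfg.validate()
                base = pad_tensor(
                    assemble_tensor(normalize_resolution(rec, cfg.base_side), selection), cfg.base_side
                )
                centred = pad_tensor(base, cfg.output_side)
                rec_cfg = AugmentConfig(
                    cfg.n_rot, cfg.n_shift, cfg.shift_range, cfg.output_side,
                    seed=int(np.random.SeedSequence([cfg.seed, zlib.crc32(rec.id.encode())]).generate_state(1)[0] % 2**31),
                )
                variants = [centred] + augment_tensor(base, rec_cfg)
            else:
                if side is None:
                    raise ValueError("side is required when no AugmentConfig is given")
                variants = [pad_tensor(assemble_tensor(normalize_resolution(rec, side), selection), side)]
            ds.labels[rec.id] = rec.label
            ds._variants[rec.id] = variants
        return ds

    def add(self, rec_id: str, label: str, variants: list[InputTensor]) -> None:
        self.labels[rec_id] = label
        self._variants[rec_id] = variants

    def ids(self) -> list[str]:
        return list(self._variants)

    def n_variants(self, rec_id: str) -> int:
        return len(self._variants[rec_id])

    def load(self, rec_id: str, variant: int) -> InputTensor:
        return self._variants[rec_id][variant]
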