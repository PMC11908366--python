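"""NIfTI volume I/O, intensity normalization, slice extraction, pairing.

All training and sampling happens in normalized intensity units.  A volume
pair is normalized with a single record computed from the HR volume and
applied to both members, so the residual ``lr - hr`` is meaningful; the
record inverts exactly on non-clipped voxels.  Axial slices are taken along
the last volume axis; pixel indexing is 0-based (row, column).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import nibabel as nib
import numpy as np

from .diffusion import PairedSlice

__all__ = [
    "NormalizationRecord",
    "VolumePair",
    "normalize",
    "denormalize",
    "load_volume",
    "save_volume",
    "load_pair",
    "iter_slices",
]


@dataclass(frozen=True)
class NormalizationRecord:
    """Affine map ``x -> (x - offset) / scale`` clipped to [0, 1]."""

    offset: float
    scale: float
    p_lo: float = 0.5
    p_hi: float = 99.5


def normalize(
    volume: np.ndarray, p_lo: float = 0.5, p_hi: float = 99.5
) -> tuple[np.ndarray, NormalizationRecord]:
    """Robust percentile normalization to [0, 1] with clipping.

    Raises on constant volumes (degenerate scale).
    """
    volume = np.asarray(volume, dtype=np.float64)
    lo, hi = np.percentile(volume, [p_lo, p_hi])
    if hi <= lo:
        raise ValueError(
            f"degenerate intensity scale: percentile {p_hi} ({hi}) <= percentile {p_lo} ({lo})"
        )
    record = NormalizationRecord(offset=float(lo), scale=float(hi - lo), p_lo=p_lo, p_hi=p_hi)
    return np.clip((volume - lo) / (hi - lo), 0.0, 1.0), record


def apply_record(volume: np.ndarray, record: NormalizationRecord) -> np.ndarray:
    """Normalize with an existing record (used for the LR member of a pair)."""
    return np.clip((np.asarray(volume, dtype=np.float64) - record.offset) / record.scale, 0.0, 1.0)


def denormalize(volume: np.ndarray, record: NormalizationRecord) -> np.ndarray:
    """Invert :func:`normalize`; exact on voxels that were not clipped."""
    return np.asarray(volume, dtype=np.float64) * record.scale + record.offset


@dataclass
class VolumePair:
    """Aligned HR/LR volumes in normalized units plus provenance."""

    hr: np.ndarray
    lr: np.ndarray
    spacing: tuple[float, ...]
    norm: NormalizationRecord
    hr_path: Optional[str] = None
    lr_path: Optional[str] = None


def load_volume(path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
    return data, spacing


def save_volume(path, data: np.ndarray, spacing: Optional[tuple[float, ...]] = None) -> None:
    data = np.asarray(data, dtype=np.float64)
    affine = np.eye(4)
    if spacing is not None:
        for i, z in enumerate(spacing[:3]):
            affine[i, i] = z
    img = nib.Nifti1Image(data, affine)
    if spacing is not None:
        img.header.set_zooms(tuple(spacing[: data.ndim]))
    nib.save(img, str(path))


def _nearest_upsample(lr: np.ndarray, hr_shape: tuple[int, ...]) -> np.ndarray:
    """Nearest-neighbor pre-upsampling onto the HR grid (integer factors)."""
    factors = []
    for hs, ls in zip(hr_shape, lr.shape):
        if hs % ls:
            raise ValueError(
                f"LR shape {lr.shape} is not an integer divisor of HR shape {hr_shape}"
            )
        factors.append(hs // ls)
    out = lr
    for axis, f in enumerate(factors):
        if f > 1:
            out = np.repeat(out, f, axis=axis)
    return out


def load_pair(hr_path, lr_path, p_lo: float = 0.5, p_hi: float = 99.5) -> VolumePair:
    """Load an HR/LR volume pair, align grids, normalize.

    The LR volume may already live on the HR grid (equal shapes) or on a
    coarser grid whose extents divide the HR extents, in which case it is
    nearest-neighbor pre-upsampled.  Intensities are normalized with the HR
    volume's record applied to both members.
    """
    hr, spacing = load_volume(hr_path)
    lr, _ = load_volume(lr_path)
    if lr.shape != hr.shape:
        lr = _nearest_upsample(lr, hr.shape)
    hr_n, record = normalize(hr, p_lo, p_hi)
    lr_n = apply_record(lr, record)
    return VolumePair(
        hr=hr_n, lr=lr_n, spacing=spacing, norm=record,
        hr_path=str(hr_path), lr_path=str(lr_path),
    )


def iter_slices(pair: VolumePair, axis: int = -1) -> list[PairedSlice]:
    """Split a volume pair into axial :class:`PairedSlice` objects."""
    hr = np.moveaxis(pair.hr, axis, 0) if pair.hr.ndim == 3 else pair.hr[None]
    lr = np.moveaxis(pair.lr, axis, 0) if pair.lr.ndim == 3 else pair.lr[None]
    return [PairedSlice(hr=h, lr=l) for h, l in zip(hr, lr)]
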