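"""Stain revelation by absolute thresholding and dirty-vs-clean differencing.

A stain that fluoresces into the filter passband is brighter than the
surrounding surface, so a single absolute intensity threshold on a normalized
frame splits every pixel into candidate stain (above) and background (at or
below).  Differencing against the cleaned surface acquired in identical
registration removes fixed bright features and leaves only what cleaning
removed — including stains invisible to the eye in the raw frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import Frame, Region
from .errors import ComparisonError, ParameterError


@dataclass
class StainMask:
    """Binary per-pixel stain map plus a description of how it was produced."""

    mask: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ParameterError(f"mask must be 2-D, got shape {self.mask.shape}")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class MaskSummary:
    pixel_count: int
    area_mm2: float
    bounding_box: Region | None


def _as_array(frame) -> tuple[np.ndarray, object]:
    if isinstance(frame, Frame):
        return np.asarray(frame.data, dtype=float), frame.meta
    return np.asarray(frame, dtype=float), None


def threshold_map(frame, threshold: float, source: str = "threshold") -> StainMask:
    """Mark every pixel strictly above ``threshold`` as candidate stain.

    Pixels exactly at the threshold count as background (strict ``>``).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError(f"threshold must be in [0, 1], got {threshold}")
    data, meta = _as_array(frame)
    desc = f"{source} > {threshold:g}" + (f" on {meta.light}/{meta.filter_nm:g} nm" if meta else "")
    return StainMask(mask=data > threshold, source=desc)


def differential_mask(dirty_frame, clean_frame, threshold: float) -> StainMask:
    """Pixels above threshold in the dirty frame but not in the clean one.

    Both frames must come from the same channel (same light, intensity and
    filter) and share dimensions; a fixed feature bright in both images is
    excluded, so the mask flags only what cleaning removed.
    """
    dirty, dmeta = _as_array(dirty_frame)
    clean, cmeta = _as_array(clean_frame)
    if dmeta is not None and cmeta is not None and dmeta != cmeta:
        raise ComparisonError(f"channel metadata differs: {dmeta} vs {cmeta}")
    if dirty.shape != clean.shape:
        raise ComparisonError(f"frame shapes differ: {dirty.shape} vs {clean.shape}")
    d = threshold_map(dirty, threshold)
    c = threshold_map(clean, threshold)
    desc = f"differential > {threshold:g}" + (
        f" on {dmeta.light}/{dmeta.filter_nm:g} nm" if dmeta else ""
    )
    return StainMask(mask=d.mask & ~c.mask, source=desc)


def mask_summary(mask: StainMask, pixel_scale: float) -> MaskSummary:
    """Pixel count, physical area (``count * pixel_scale^2`` mm²) and pixel
    bounding box of a mask; the box is ``None`` for an empty mask."""
    count = mask.pixel_count
    area = count * pixel_scale * pixel_scale
    if count == 0:
        return MaskSummary(pixel_count=0, area_mm2=0.0, bounding_box=None)
    rows, cols = np.nonzero(mask.mask)
    box = Region(
        x0=int(cols.min()),
        y0=int(rows.min()),
        width=int(cols.max() - cols.min() + 1),
        height=int(rows.max() - rows.min() + 1),
    )
    return MaskSummary(pixel_count=count, area_mm2=area, bounding_box=box)


def jaccard(a, b) -> float:
    """Jaccard index |A∩B| / |A∪B| between two masks; 1.0 if both are empty."""
    ma = a.mask if isinstance(a, StainMask) else np.asarray(a, dtype=bool)
    mb = b.mask if isinstance(b, StainMask) else np.asarray(b, dtype=bool)
    if ma.shape != mb.shape:
        raise ComparisonError(f"mask shapes differ: {ma.shape} vs {mb.shape}")
    union = int((ma | mb).sum())
    if union == 0:
        return 1.0
    return int((ma & mb).sum()) / union
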