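"""Registered multispectral image cubes: container, PNG/TSV I/O, cropping.

An acquisition session produces one grayscale frame per (excitation light,
bandpass filter) channel, all taken from a fixed camera position so the cube
is registered by construction.  Frames are stored on disk as 8-bit grayscale
PNGs next to a TSV manifest listing, per channel, the file name, light name,
light center wavelength, relative intensity and filter center wavelength.
In memory every frame is a float array on [0, 1]; 8-bit values map to
intensity by ``v / 255`` (16-bit by ``v / 65535``).  Normalisation is fixed,
not per-image min-max, so an absolute detection threshold such as 0.35 means
the same thing in every frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import (
    ChannelLookupError,
    FormatError,
    GeometryError,
    ManifestError,
)

logger = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.tsv"
MANIFEST_COLUMNS = ("filename", "light", "center_nm", "i_rel", "filter_nm")


@dataclass(frozen=True)
class ChannelMeta:
    """Identity of one cube channel.

    Parameters
    ----------
    light : str
        Name of the active excitation light (``red``/``green``/``blue``).
    center_nm : float
        Center wavelength of that light, nm.
    i_rel : int
        Relative drive intensity of the light, 0-255.
    filter_nm : float
        Center wavelength of the bandpass filter, nm.
    """

    light: str
    center_nm: float
    i_rel: int
    filter_nm: float

    @property
    def key(self) -> tuple:
        return (self.light, self.filter_nm, self.i_rel)

    def filename(self) -> str:
        return f"{self.light}_{self.i_rel}_{int(round(self.filter_nm))}.png"


@dataclass(frozen=True)
class Region:
    """Rectangular pixel region: 0-based top-left corner, half-open extent.

    ``x`` runs rightward (columns), ``y`` downward (rows); the region covers
    columns ``x0 .. x0+width-1`` and rows ``y0 .. y0+height-1``.
    """

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.x0 < 0 or self.y0 < 0:
            raise GeometryError(f"region origin must be non-negative, got ({self.x0}, {self.y0})")
        if self.width <= 0 or self.height <= 0:
            raise GeometryError(f"region extent must be positive, got {self.width}x{self.height}")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.y0, self.y0 + self.height), slice(self.x0, self.x0 + self.width))

    def fits_in(self, height: int, width: int) -> bool:
        return self.x0 + self.width <= width and self.y0 + self.height <= height


@dataclass
class ImageStack:
    """A registered cube of per-channel frames plus channel metadata.

    ``frames`` has shape ``(n_channels, height, width)`` with intensities in
    [0, 1]; ``channel_meta[i]`` describes ``frames[i]``.
    """

    frames: np.ndarray
    channel_meta: list[ChannelMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise FormatError(f"frames must be (channels, height, width), got shape {self.frames.shape}")
        if len(self.channel_meta) != self.frames.shape[0]:
            raise ManifestError(
                f"{self.frames.shape[0]} frames but {len(self.channel_meta)} metadata entries"
            )
        keys = [m.key for m in self.channel_meta]
        if len(set(keys)) != len(keys):
            raise ManifestError("duplicate (light, filter, i_rel) channel triples in stack")
        lo, hi = float(self.frames.min(initial=0.0)), float(self.frames.max(initial=0.0))
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise FormatError(f"intensities must lie in [0, 1], got range [{lo}, {hi}]")

    @property
    def n_channels(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]


@dataclass(frozen=True)
class Frame:
    """One channel's image together with its identity, as returned by
    :func:`select_channel`."""

    data: np.ndarray
    meta: ChannelMeta


def write_stack(stack: ImageStack, out_dir: str | Path) -> Path:
    """Write a stack as one 8-bit grayscale PNG per channel plus a TSV manifest.

    Intensities are quantized as ``round(255 * v)``.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for frame, meta in zip(stack.frames, stack.channel_meta):
        name = meta.filename()
        img = np.rint(np.clip(frame, 0.0, 1.0) * 255.0).astype(np.uint8)
        Image.fromarray(img, mode="L").save(out_dir / name)
        rows.append((name, meta.light, meta.center_nm, meta.i_rel, meta.filter_nm))
    manifest = out_dir / MANIFEST_NAME
    with open(manifest, "w") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for name, light, center, irel, filt in rows:
            fh.write(f"{name}\t{light}\t{center:g}\t{irel}\t{filt:g}\n")
    return manifest


def read_stack(manifest_path: str | Path) -> ImageStack:
    """Read a stack from its TSV manifest.

    Frames are loaded in manifest order.  8-bit pixels map to [0, 1] by
    ``v/255``; 16-bit PNGs are accepted and mapped by ``v/65535``.  Unknown
    extra manifest columns are ignored with a warning.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise OSError(f"manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in MANIFEST_COLUMNS if c not in header]
        if missing:
            raise ManifestError(f"manifest missing columns {missing}")
        extra = [c for c in header if c not in MANIFEST_COLUMNS]
        if extra:
            logger.warning("ignoring unknown manifest columns %s", extra)
        idx = {c: header.index(c) for c in MANIFEST_COLUMNS}
        frames: list[np.ndarray] = []
        meta: list[ChannelMeta] = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            name = parts[idx["filename"]]
            path = manifest_path.parent / name
            if not path.exists():
                raise OSError(f"channel image not found: {path}")
            arr = np.asarray(Image.open(path))
            if arr.ndim != 2:
                raise FormatError(f"{name}: expected single-channel image, got shape {arr.shape}")
            if arr.dtype == np.uint8:
                frames.append(arr.astype(np.float64) / 255.0)
            elif arr.dtype == np.uint16:
                frames.append(arr.astype(np.float64) / 65535.0)
            else:
                raise FormatError(f"{name}: unsupported bit depth {arr.dtype}")
            meta.append(
                ChannelMeta(
                    light=parts[idx["light"]],
                    center_nm=float(parts[idx["center_nm"]]),
                    i_rel=int(parts[idx["i_rel"]]),
                    filter_nm=float(parts[idx["filter_nm"]]),
                )
            )
    if not frames:
        raise ManifestError(f"manifest {manifest_path} lists no channels")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise FormatError(f"channel images disagree on dimensions: {sorted(shapes)}")
    return ImageStack(frames=np.stack(frames), channel_meta=meta)


def crop(stack: ImageStack, region: Region) -> ImageStack:
    """Crop every frame of the stack to ``region``; channel metadata is kept."""
    if not region.fits_in(stack.height, stack.width):
        raise GeometryError(
            f"region {region} does not fit inside {stack.height}x{stack.width} frames"
        )
    return ImageStack(
        frames=stack.frames[(slice(None),) + region.slices].copy(),
        channel_meta=list(stack.channel_meta),
    )


def select_channel(stack: ImageStack, light: str, filter_nm: float) -> Frame:
    """Return the unique frame acquired with ``light`` and filter ``filter_nm``."""
    hits = [
        i
        for i, m in enumerate(stack.channel_meta)
        if m.light == light and abs(m.filter_nm - filter_nm) < 1e-9
    ]
    if len(hits) != 1:
        raise ChannelLookupError(
            f"expected exactly one channel matching ({light}, {filter_nm} nm), found {len(hits)}"
        )
    i = hits[0]
    return Frame(data=stack.frames[i], meta=stack.channel_meta[i])
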