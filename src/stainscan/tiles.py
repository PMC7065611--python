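"""Tile-wise surface classification with a linear max-margin classifier.

Stains on real surfaces occur as small, unevenly spread clusters, so a
surface-level verdict is built bottom-up: the region of interest is divided
into small squares, each square is summarized by its per-channel mean and
standard deviation of intensity, a soft-margin linear SVM labels each square
dirty or clean, and the surface is called dirty as soon as a configurable
number of squares (one, by default) comes back dirty.  On a clean surface
every square classifies as clean; on a dirty one, clean and dirty squares
co-occur.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import LinearSVC

from .cube import ImageStack, Region
from .errors import GeometryError, InputError, TrainingError
from .threshold import StainMask

logger = logging.getLogger(__name__)

DIRTY, CLEAN = "dirty", "clean"


@dataclass(frozen=True)
class TileGrid:
    """Row-major disjoint tiling of a region by ``tile_size`` squares.

    A right/bottom remainder strip narrower than one tile is discarded (and
    logged) rather than padded.
    """

    region: Region
    tile_size: int
    tiles: tuple[Region, ...]

    @property
    def n_rows(self) -> int:
        return self.region.height // self.tile_size

    @property
    def n_cols(self) -> int:
        return self.region.width // self.tile_size


def make_grid(region: Region, tile_size_px: int) -> TileGrid:
    if tile_size_px < 2:
        raise GeometryError(f"tile size must be >= 2 px, got {tile_size_px}")
    if tile_size_px > region.width or tile_size_px > region.height:
        raise GeometryError(
            f"tile size {tile_size_px} exceeds the {region.width}x{region.height} region"
        )
    n_cols = region.width // tile_size_px
    n_rows = region.height // tile_size_px
    rem_x = region.width - n_cols * tile_size_px
    rem_y = region.height - n_rows * tile_size_px
    if rem_x or rem_y:
        logger.warning(
            "discarding %d px right / %d px bottom remainder of region %s", rem_x, rem_y, region
        )
    tiles = tuple(
        Region(
            x0=region.x0 + c * tile_size_px,
            y0=region.y0 + r * tile_size_px,
            width=tile_size_px,
            height=tile_size_px,
        )
        for r in range(n_rows)
        for c in range(n_cols)
    )
    return TileGrid(region=region, tile_size=tile_size_px, tiles=tiles)


def tile_features(stack: ImageStack, grid: TileGrid) -> np.ndarray:
    """Feature matrix (n_tiles, 2 * n_channels): per-channel mean then
    per-channel standard deviation of intensity over each tile's pixels."""
    if not grid.region.fits_in(stack.height, stack.width):
        raise GeometryError(f"grid region {grid.region} exceeds the stack frame")
    feats = np.empty((len(grid.tiles), 2 * stack.n_channels))
    for i, tile in enumerate(grid.tiles):
        block = stack.frames[(slice(None),) + tile.slices]
        feats[i, : stack.n_channels] = block.mean(axis=(1, 2))
        feats[i, stack.n_channels :] = block.std(axis=(1, 2))
    return feats


def labels_from_truth(truth: StainMask, grid: TileGrid, coverage: float = 0.5) -> np.ndarray:
    """Label each tile dirty iff the planted truth covers >= ``coverage`` of it."""
    labels = []
    for tile in grid.tiles:
        frac = truth.mask[tile.slices].mean()
        labels.append(DIRTY if frac >= coverage else CLEAN)
    return np.array(labels, dtype=object)


@dataclass
class TileClassifier:
    """Trained soft-margin linear separator over tile feature vectors.

    ``decision(x) = x . weights + bias``; positive means dirty.  Training
    minimizes hinge loss with an L2 penalty (regularization strength ``c``),
    which for linearly separable tiles yields the max-margin separator.
    """

    weights: np.ndarray
    bias: float
    n_samples: int = 0
    seed: int = 0
    regularization: float = 1.0

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != len(self.weights):
            raise InputError(
                f"feature dimension {features.shape[1]} does not match classifier "
                f"dimension {len(self.weights)}"
            )
        return features @ self.weights + self.bias

    def predict(self, features: np.ndarray) -> np.ndarray:
        d = self.decision_function(features)
        return np.where(d > 0, DIRTY, CLEAN).astype(object)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "weights": list(map(float, self.weights)),
            "bias": float(self.bias),
            "n_samples": self.n_samples,
            "seed": self.seed,
            "regularization": self.regularization,
            "feature_recipe": "per-channel mean then per-channel SD over tile pixels",
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TileClassifier":
        payload = json.loads(Path(path).read_text())
        return cls(
            weights=np.asarray(payload["weights"], dtype=float),
            bias=float(payload["bias"]),
            n_samples=int(payload.get("n_samples", 0)),
            seed=int(payload.get("seed", 0)),
            regularization=float(payload.get("regularization", 1.0)),
        )


def train(
    features: np.ndarray,
    labels: np.ndarray,
    regularization: float = 1.0,
    seed: int = 0,
) -> TileClassifier:
    """Fit the linear SVM on labeled tile features (labels ``dirty``/``clean``).

    Both classes must be present with at least two examples each.  Hinge
    penalties are inversely weighted by class frequency: stains cover few
    tiles of a surface by nature, and an unweighted soft margin would trade
    the whole minority class away.  The fit is deterministic given the seed
    and data order.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if features.ndim != 2 or len(features) != len(labels):
        raise TrainingError("features must be (n, d) with one label per row")
    counts = {lab: int((labels == lab).sum()) for lab in (CLEAN, DIRTY)}
    unknown = set(labels) - {CLEAN, DIRTY}
    if unknown:
        raise TrainingError(f"unknown labels {unknown}")
    if min(counts.values()) < 2:
        raise TrainingError(f"need >= 2 examples per class, got {counts}")
    y = np.where(labels == DIRTY, 1, -1)
    svc = LinearSVC(
        C=regularization,
        loss="hinge",
        class_weight="balanced",
        max_iter=200_000,
        tol=1e-6,
        random_state=seed,
    ).fit(features, y)
    return TileClassifier(
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        n_samples=len(features),
        seed=seed,
        regularization=regularization,
    )


@dataclass(frozen=True)
class SurfaceCall:
    tile_labels: tuple[str, ...]
    surface_call: str
    dirty_fraction: float


def classify_surface(
    classifier: TileClassifier, features: np.ndarray, min_dirty_tiles: int = 1
) -> SurfaceCall:
    """Label every tile and call the surface dirty iff at least
    ``min_dirty_tiles`` tiles classify dirty."""
    labels = classifier.predict(features)
    n_dirty = int((labels == DIRTY).sum())
    return SurfaceCall(
        tile_labels=tuple(labels),
        surface_call=DIRTY if n_dirty >= min_dirty_tiles else CLEAN,
        dirty_fraction=n_dirty / len(labels) if len(labels) else 0.0,
    )


def tile_mask(grid: TileGrid, tile_labels, shape: tuple[int, int]) -> StainMask:
    """Rasterize dirty tiles back to a pixel mask of the given frame shape."""
    mask = np.zeros(shape, dtype=bool)
    for tile, lab in zip(grid.tiles, tile_labels):
        if lab == DIRTY:
            mask[tile.slices] = True
    return StainMask(mask=mask, source=f"tile classifier, tile={grid.tile_size} px")
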