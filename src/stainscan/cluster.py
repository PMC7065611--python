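"""Pixel clustering in spectral feature space.

Two detectors live here.  The manual one plots each pixel of hand-picked
stain/background crops as a 2-D point whose coordinates are its intensities
under two chosen (light, filter) conditions; stained pixels separate from
background along the axis where the stain fluoresces.  The automatic one
runs k-means on full-cube per-pixel feature vectors (all lights, all
filters) over a region of interest and designates the stain cluster by its
brightness in the channel closest to the stain's expected emission (green
excitation, 500 nm filter by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .cube import ChannelMeta, ImageStack, Region, crop, select_channel
from .errors import (
    ChannelLookupError,
    ComparisonError,
    DegenerateInputError,
    GeometryError,
    InputError,
    ParameterError,
)
from .threshold import StainMask

#: cap on the separation score when within-group spread is exactly zero
SEPARATION_CAP = 1e6


@dataclass
class PixelFeatureSet:
    """Per-pixel feature vectors with provenance.

    ``features`` is (n_pixels, n_conditions); ``pixel_index`` the (row, col)
    of each vector in its source frame; ``labels`` an optional per-pixel
    annotation (e.g. ``stain`` / ``background`` / ``cleaned-stain``);
    ``conditions`` records the channel metadata of each feature axis so
    feature sets from different acquisitions can be checked for comparability.
    """

    features: np.ndarray
    pixel_index: np.ndarray
    labels: np.ndarray | None = None
    conditions: tuple[ChannelMeta, ...] = ()

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ParameterError("features must be (n_pixels, n_dims)")
        if not np.all(np.isfinite(self.features)):
            raise ParameterError("features must be finite")
        self.pixel_index = np.asarray(self.pixel_index, dtype=int)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.features):
                raise ParameterError("labels length must match features")

    def subset(self, label: str) -> np.ndarray:
        if self.labels is None:
            raise InputError("feature set carries no labels")
        return self.features[self.labels == label]


@dataclass
class ClusterResult:
    """Outcome of k-means over a region: per-pixel assignment (region-shaped),
    centroids in the clustering feature space, and the id designated as stain."""

    assignment: np.ndarray
    centroids: np.ndarray
    stain_cluster: int
    k: int
    seed: int
    region: Region
    inertia: float = 0.0
    background_channel: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.min(initial=0) < 0 or self.assignment.max(initial=0) >= self.k:
            raise ParameterError("cluster ids must lie in [0, k)")
        if not 0 <= self.stain_cluster < self.k:
            raise ParameterError("stain_cluster must be a valid cluster id")

    def stain_mask(self) -> StainMask:
        """Region-shaped boolean mask of the stain cluster."""
        return StainMask(
            mask=self.assignment == self.stain_cluster,
            source=f"k-means k={self.k} seed={self.seed} stain cluster {self.stain_cluster}",
        )


def two_channel_features(
    stack: ImageStack,
    cond_a: tuple[str, float],
    cond_b: tuple[str, float],
    regions: dict[str, Region],
) -> PixelFeatureSet:
    """One 2-D feature vector per pixel of each named region.

    Coordinates are the pixel's intensity under ``cond_a`` (x) and ``cond_b``
    (y), each a ``(light name, filter nm)`` pair present in the stack; each
    vector is labeled with its region's name.
    """
    frame_a = select_channel(stack, *cond_a)
    frame_b = select_channel(stack, *cond_b)
    feats, idx, labels = [], [], []
    for name, region in regions.items():
        if not region.fits_in(stack.height, stack.width):
            raise GeometryError(f"region {name!r} {region} exceeds the {stack.height}x{stack.width} frame")
        sl = region.slices
        a = frame_a.data[sl].ravel()
        b = frame_b.data[sl].ravel()
        rr, cc = np.mgrid[sl]
        feats.append(np.column_stack([a, b]))
        idx.append(np.column_stack([rr.ravel(), cc.ravel()]))
        labels.extend([name] * a.size)
    if not feats:
        raise InputError("at least one region is required")
    return PixelFeatureSet(
        features=np.vstack(feats),
        pixel_index=np.vstack(idx),
        labels=np.array(labels, dtype=object),
        conditions=(frame_a.meta, frame_b.meta),
    )


def separation_score(features: PixelFeatureSet, group_a: str, group_b: str) -> float:
    """Between-group centroid distance over pooled within-group RMS spread.

    Zero when the groups coincide; capped at ``SEPARATION_CAP`` when both
    groups are point masses at distinct locations.
    """
    xa = features.subset(group_a)
    xb = features.subset(group_b)
    if len(xa) == 0 or len(xb) == 0:
        raise InputError(f"groups {group_a!r}/{group_b!r} must both be non-empty")
    ca = xa.mean(axis=0)
    cb = xb.mean(axis=0)
    d = float(np.linalg.norm(ca - cb))
    ssw = float(((xa - ca) ** 2).sum() + ((xb - cb) ** 2).sum())
    spread = np.sqrt(ssw / (len(xa) + len(xb)))
    if spread == 0.0:
        return 0.0 if d == 0.0 else SEPARATION_CAP
    return min(d / spread, SEPARATION_CAP)


def cleaned_overlay(
    features_dirty: PixelFeatureSet, features_clean: PixelFeatureSet
) -> PixelFeatureSet:
    """Merge dirty and after-cleaning feature sets for a joint cluster plot.

    Points from the cleaned acquisition keep their region names prefixed with
    ``cleaned-``; both sets must have been extracted under the same two
    conditions.  On a well-cleaned surface the ``cleaned-stain`` points fall
    with the background cluster rather than with the dirty stain.
    """
    if features_dirty.conditions != features_clean.conditions:
        raise ComparisonError(
            f"feature conditions differ: {features_dirty.conditions} vs {features_clean.conditions}"
        )
    if len(features_clean.features) == 0 or len(features_dirty.features) == 0:
        raise ComparisonError("both feature sets must be non-empty")
    if features_dirty.labels is None or features_clean.labels is None:
        raise ComparisonError("both feature sets must be labeled")
    labels = np.concatenate(
        [features_dirty.labels, np.array([f"cleaned-{l}" for l in features_clean.labels], dtype=object)]
    )
    return PixelFeatureSet(
        features=np.vstack([features_dirty.features, features_clean.features]),
        pixel_index=np.vstack([features_dirty.pixel_index, features_clean.pixel_index]),
        labels=labels,
        conditions=features_dirty.conditions,
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    out = np.zeros_like(x)
    ok = sd > 1e-12
    out[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    return out


def kmeans_cluster(
    stack: ImageStack,
    region: Region,
    k: int = 2,
    seed: int = 0,
    background_channel: tuple[str, float] = ("green", 500.0),
    n_restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
    standardize: bool = True,
    stain_rule: str = "emission",
) -> ClusterResult:
    """k-means over full-cube per-pixel spectral vectors within ``region``.

    Each pixel contributes one vector of its intensities across every channel
    of the stack.  Channels are standardized to zero mean / unit variance
    within the region by default (constant channels are dropped to zero) so
    high-drive frames do not dominate the metric.  Lloyd's algorithm with
    k-means++ seeding, ``n_restarts`` restarts and a fixed seed makes the
    result reproducible.  The stain cluster is, under the default
    ``emission`` rule, the cluster with the highest mean raw intensity in the
    stack channel matching ``background_channel`` (where the stain's emission
    lands); the ``minority`` rule instead picks the smallest cluster.
    """
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    if stain_rule not in ("emission", "minority"):
        raise ParameterError(f"unknown stain rule {stain_rule!r}")
    sub = crop(stack, region)
    x = sub.frames.reshape(sub.n_channels, -1).T  # (pixels, channels)
    n_distinct = len(np.unique(x, axis=0))
    if n_distinct < k:
        raise DegenerateInputError(
            f"region has only {n_distinct} distinct spectral vectors; k={k} requires at least k"
        )
    feats = _standardize(x) if standardize else x
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(feats)
    assignment = km.labels_.reshape(region.height, region.width)

    if stain_rule == "minority":
        sizes = np.bincount(km.labels_, minlength=k)
        stain_id = int(np.argmin(sizes))
    else:
        try:
            frame = select_channel(sub, *background_channel)
            ref = frame.data.ravel()
        except ChannelLookupError:
            # nearest filter of the requested light
            cand = [
                (abs(m.filter_nm - background_channel[1]), i)
                for i, m in enumerate(sub.channel_meta)
                if m.light == background_channel[0]
            ]
            if not cand:
                raise
            ref = sub.frames[min(cand)[1]].ravel()
        means = [ref[km.labels_ == c].mean() for c in range(k)]
        stain_id = int(np.argmax(means))

    return ClusterResult(
        assignment=assignment,
        centroids=km.cluster_centers_,
        stain_cluster=stain_id,
        k=k,
        seed=seed,
        region=region,
        inertia=float(km.inertia_),
        background_channel=background_channel,
    )


#: highlight color painted over stain pixels in overlays (orange)
HIGHLIGHT_RGB = (1.0, 0.6, 0.0)


def overlay_render(result: ClusterResult, background_frame) -> np.ndarray:
    """Paint the stain cluster in orange over a grayscale background frame.

    Returns an (H, W, 3) float RGB image; pixels outside the stain cluster
    show the background frame unchanged.
    """
    bg = np.asarray(
        background_frame.data if hasattr(background_frame, "data") else background_frame,
        dtype=float,
    )
    if bg.ndim != 2:
        raise GeometryError(f"background frame must be 2-D, got shape {bg.shape}")
    region = result.region
    if not region.fits_in(*bg.shape):
        raise GeometryError(f"cluster region {region} does not fit in a {bg.shape} frame")
    rgb = np.repeat(bg[:, :, None], 3, axis=2)
    sl = region.slices
    stain = result.assignment == result.stain_cluster
    for c, val in enumerate(HIGHLIGHT_RGB):
        plane = rgb[:, :, c]
        block = plane[sl]
        block[stain] = val
        plane[sl] = block
    return rgb
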