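"""Synthetic multispectral phantoms of dirty and cleaned touch surfaces.

The simulator emulates a tunable-filter fluorescence imaging rig: three
narrow-band LEDs (red/green/blue) illuminate the surface one at a time while
a bandpass filter sweeps 420-720 nm in 20 nm steps, giving 48 co-registered
grayscale frames per scene.  A "dirty" scene carries one or more stain
regions whose fluorophore (riboflavin-like by default: broad blue-green
excitation, emission near 500 nm) re-emits into the filter passband; the
paired "clean" scene is the identical surface with the stains removed, in
perfect registration, so downstream detectors can difference the two.

Forward model per channel (light L, filter F), per pixel:

    I = background + leak(L, F) * I_rel/255          (excitation bleed-through)
        + sum over stains covering the pixel of
              c_s * Q * Ex(lambda_L) * I_rel/255 * Em*F integral
        + N(0, noise_sd),   clipped to [0, 1]

where Ex is the fluorophore's unit-peak Gaussian excitation spectrum
evaluated at the light's center wavelength, Em its unit-area Gaussian
emission density integrated against the filter's Gaussian transmission
(closed form: product of Gaussians), Q the fluorophore quantum scale and
c_s the stain concentration.  The leak term is a Gaussian in the light-filter
wavelength offset: when the LED sits inside the filter passband at full
drive (I_rel = 255) the background saturates, which is why real protocols
drive such channels at reduced intensity — lowering I_rel to 50 removes the
saturation.  Spectra are hard-zeroed beyond five FWHM of their peak.

All randomness flows from ``SceneSpec.seed``; identical specs render
bit-identical stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cube import ChannelMeta, ImageStack
from .errors import GeometryError, ParameterError, ProtocolError

#: conversion from full width at half maximum to Gaussian sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: beyond this many FWHM from a peak a spectrum is exactly zero
SPECTRUM_CUTOFF_FWHM = 5.0


@dataclass(frozen=True)
class ExcitationLight:
    """One LED of the illumination head.

    ``relative_intensity`` (I_rel) is the 0-255 drive level; operationally
    50-255 is used, with low drive chosen for lights whose wavelength sits
    near the filter passband to avoid overexposing the background.
    """

    name: str
    center_wavelength: float
    bandwidth: float = 25.0  # FWHM, nm
    relative_intensity: int = 255

    def __post_init__(self) -> None:
        if self.name not in ("red", "green", "blue"):
            raise ParameterError(f"light name must be red/green/blue, got {self.name!r}")
        if not 0 <= self.relative_intensity <= 255:
            raise ParameterError(f"relative_intensity must be in [0, 255], got {self.relative_intensity}")
        if not 380.0 <= self.center_wavelength <= 780.0:
            raise ParameterError(
                f"center_wavelength must be in the visible range [380, 780] nm, got {self.center_wavelength}"
            )
        if self.bandwidth <= 0:
            raise ParameterError("bandwidth must be positive")


@dataclass(frozen=True)
class BandpassFilter:
    """Tunable bandpass filter position, Gaussian transmission profile."""

    center_wavelength: float
    passband_fwhm: float = 10.0

    def __post_init__(self) -> None:
        if self.passband_fwhm <= 0:
            raise ParameterError("passband_fwhm must be positive")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Ordered list of (light, filter) channels plus the frame geometry.

    Exactly one light is active per channel; a full grid protocol enumerates
    every light x filter combination.
    """

    channels: tuple[tuple[ExcitationLight, BandpassFilter], ...]
    frame_height: int = 1040
    frame_width: int = 1393

    def __post_init__(self) -> None:
        if not self.channels:
            raise ProtocolError("protocol has no channels")
        if self.frame_height <= 0 or self.frame_width <= 0:
            raise ProtocolError("frame dimensions must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_meta(self) -> list[ChannelMeta]:
        return [
            ChannelMeta(
                light=light.name,
                center_nm=light.center_wavelength,
                i_rel=light.relative_intensity,
                filter_nm=filt.center_wavelength,
            )
            for light, filt in self.channels
        ]


@dataclass(frozen=True)
class Fluorophore:
    """Gaussian excitation/emission spectra of a stain's fluorescent species.

    Widths are FWHM in nm.  The Stokes shift must be non-negative
    (``emission_peak >= excitation_peak``).
    """

    name: str
    excitation_peak: float
    excitation_width: float
    emission_peak: float
    emission_width: float
    quantum_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.emission_peak < self.excitation_peak:
            raise ParameterError(
                f"{self.name}: emission_peak must be >= excitation_peak (non-negative Stokes shift)"
            )
        if self.excitation_width <= 0 or self.emission_width <= 0:
            raise ParameterError(f"{self.name}: spectral widths must be positive")
        if self.quantum_scale < 0:
            raise ParameterError(f"{self.name}: quantum_scale must be >= 0")


#: default stain fluorophore: broad blue-green excitation, green emission,
#: matching a riboflavin-rich organic soil visible under green and blue light
RIBOFLAVIN_LIKE = Fluorophore(
    name="riboflavin-like",
    excitation_peak=460.0,
    excitation_width=120.0,
    emission_peak=500.0,
    emission_width=60.0,
    quantum_scale=25.0,
)


@dataclass(frozen=True)
class StainRegion:
    """A stain patch in scene (mm) coordinates.

    ``center`` is (x, y) mm from the scene's top-left corner, ``extent`` the
    full (width, height) in mm.  Rectangles cover pixels whose centers fall in
    the half-open box ``[cx - w/2, cx + w/2) x [cy - h/2, cy + h/2)``;
    ellipses cover pixel centers with normalized radius <= 1.
    """

    shape: str
    center: tuple[float, float]
    extent: tuple[float, float]
    fluorophore: Fluorophore = RIBOFLAVIN_LIKE
    concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "ellipse"):
            raise ParameterError(f"stain shape must be rectangle or ellipse, got {self.shape!r}")
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ParameterError("stain extent must be strictly positive")
        if self.concentration < 0:
            raise ParameterError("stain concentration must be >= 0")

    def pixel_mask(self, height: int, width: int, pixel_scale: float) -> np.ndarray:
        """Boolean (height, width) coverage mask at ``pixel_scale`` mm/px."""
        cx, cy = self.center
        ex, ey = self.extent
        xs = (np.arange(width) + 0.5) * pixel_scale
        ys = (np.arange(height) + 0.5) * pixel_scale
        if self.shape == "rectangle":
            in_x = (xs >= cx - ex / 2) & (xs < cx + ex / 2)
            in_y = (ys >= cy - ey / 2) & (ys < cy + ey / 2)
            return np.outer(in_y, in_x)
        u = (xs - cx) / (ex / 2)
        v = (ys - cy) / (ey / 2)
        return (u[None, :] ** 2 + v[:, None] ** 2) <= 1.0


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of a synthetic surface.

    ``background_reflectance`` is the illumination-independent floor of every
    channel; the full per-channel background additionally carries the
    excitation leak term (see the module docstring).  The clean variant of a
    scene is the same spec with ``stains`` empty.
    """

    pixel_scale: float = 0.05  # mm / px
    background_reflectance: float = 0.2
    stains: tuple[StainRegion, ...] = ()
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_reflectance <= 1.0:
            raise ParameterError("background_reflectance must be in [0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.pixel_scale <= 0:
            raise ParameterError("pixel_scale must be positive")

    def cleaned(self) -> "SceneSpec":
        return replace(self, stains=())


def default_lights() -> list[ExcitationLight]:
    """The three LEDs at their usual drive levels: green is driven low (50)
    because its wavelength sits near the sweep's informative passbands; red
    and blue run at full drive (255)."""
    return [
        ExcitationLight(name="red", center_wavelength=625.0, relative_intensity=255),
        ExcitationLight(name="green", center_wavelength=525.0, relative_intensity=50),
        ExcitationLight(name="blue", center_wavelength=460.0, relative_intensity=255),
    ]


def make_protocol(
    light_specs: list[ExcitationLight],
    filter_min: float = 420.0,
    filter_max: float = 720.0,
    increment: float = 20.0,
    frame_height: int = 1040,
    frame_width: int = 1393,
    passband_fwhm: float = 10.0,
) -> AcquisitionProtocol:
    """Build the full light x filter grid protocol.

    Filter centers are ``filter_min, filter_min + increment, ... <= filter_max``;
    the channel count is ``len(light_specs) * n_filters`` (3 lights over
    420-720 nm in 20 nm steps give the standard 48 channels).
    """
    if increment <= 0:
        raise ProtocolError(f"filter increment must be positive, got {increment}")
    if filter_min > filter_max:
        raise ProtocolError(f"filter_min {filter_min} exceeds filter_max {filter_max}")
    if not light_specs:
        raise ProtocolError("at least one excitation light is required")
    names = [l.name for l in light_specs]
    if len(set(names)) != len(names):
        raise ProtocolError(f"duplicate light names in {names}")
    n_steps = int(math.floor((filter_max - filter_min) / increment + 1e-9)) + 1
    filters = [
        BandpassFilter(center_wavelength=filter_min + i * increment, passband_fwhm=passband_fwhm)
        for i in range(n_steps)
    ]
    channels = tuple((light, filt) for light in light_specs for filt in filters)
    return AcquisitionProtocol(channels=channels, frame_height=frame_height, frame_width=frame_width)


def _gauss(x: float, peak: float, fwhm: float) -> float:
    """Unit-peak Gaussian, hard-zeroed beyond the spectrum cutoff."""
    if abs(x - peak) > SPECTRUM_CUTOFF_FWHM * fwhm:
        return 0.0
    sigma = fwhm * FWHM_TO_SIGMA
    return math.exp(-0.5 * ((x - peak) / sigma) ** 2)


def channel_response(
    fluorophore: Fluorophore, light: ExcitationLight, filt: BandpassFilter
) -> float:
    """Fluorescence intensity contribution of a unit-concentration stain.

    Excitation efficiency is the unit-peak excitation spectrum at the light's
    center wavelength, scaled linearly by ``relative_intensity / 255``.  The
    collected emission is the unit-area Gaussian emission density integrated
    against the filter's unit-peak Gaussian transmission, which has the closed
    form ``s_f / sqrt(s_e^2 + s_f^2) * exp(-(mu_e - mu_f)^2 / (2 (s_e^2 + s_f^2)))``.
    The result is exactly zero when the light is more than five excitation
    widths from the excitation peak or the filter more than five emission
    widths from the emission peak.
    """
    ex = _gauss(light.center_wavelength, fluorophore.excitation_peak, fluorophore.excitation_width)
    if ex == 0.0:
        return 0.0
    if (
        abs(filt.center_wavelength - fluorophore.emission_peak)
        > SPECTRUM_CUTOFF_FWHM * fluorophore.emission_width
    ):
        return 0.0
    s_e = fluorophore.emission_width * FWHM_TO_SIGMA
    s_f = filt.passband_fwhm * FWHM_TO_SIGMA
    pooled = s_e * s_e + s_f * s_f
    collected = (s_f / math.sqrt(pooled)) * math.exp(
        -((fluorophore.emission_peak - filt.center_wavelength) ** 2) / (2.0 * pooled)
    )
    return fluorophore.quantum_scale * ex * (light.relative_intensity / 255.0) * collected


def excitation_leak(light: ExcitationLight, filt: BandpassFilter) -> float:
    """Fraction of reflected excitation light passing the filter (at full drive).

    Gaussian in the light-filter wavelength offset with the two FWHM widths
    added in quadrature; this is what saturates channels whose filter sits on
    the LED line at I_rel = 255.
    """
    s_l = light.bandwidth * FWHM_TO_SIGMA
    s_f = filt.passband_fwhm * FWHM_TO_SIGMA
    pooled = s_l * s_l + s_f * s_f
    return math.exp(
        -((light.center_wavelength - filt.center_wavelength) ** 2) / (2.0 * pooled)
    )


def channel_background(scene: SceneSpec, light: ExcitationLight, filt: BandpassFilter) -> float:
    """Noise-free background level of one channel (before clipping)."""
    return scene.background_reflectance + (light.relative_intensity / 255.0) * excitation_leak(
        light, filt
    )


def render_pair(scene: SceneSpec, protocol: AcquisitionProtocol):
    """Render the dirty scene, its cleaned twin, and the ground-truth mask.

    Returns ``(dirty, clean, truth)`` where ``truth`` is the exact boolean
    union of the planted stain footprints.  The clean stack is the same scene
    with stains removed, rendered in identical registration; with zero noise
    the two stacks differ exactly on the truth mask.  Dirty and clean noise
    fields are independent draws (two acquisitions) but fully determined by
    ``scene.seed``.
    """
    h, w = protocol.frame_height, protocol.frame_width
    scene_w = w * scene.pixel_scale
    scene_h = h * scene.pixel_scale
    truth = np.zeros((h, w), dtype=bool)
    stain_masks: list[np.ndarray] = []
    for stain in scene.stains:
        cx, cy = stain.center
        ex, ey = stain.extent
        if cx - ex / 2 < 0 or cx + ex / 2 > scene_w or cy - ey / 2 < 0 or cy + ey / 2 > scene_h:
            raise GeometryError(
                f"stain at ({cx}, {cy}) mm extent ({ex}, {ey}) mm exceeds the "
                f"{scene_w:g} x {scene_h:g} mm scene"
            )
        m = stain.pixel_mask(h, w, scene.pixel_scale)
        stain_masks.append(m)
        truth |= m

    rng = np.random.default_rng(scene.seed)
    meta = protocol.channel_meta()
    dirty = np.empty((protocol.n_channels, h, w))
    clean = np.empty_like(dirty)
    for i, (light, filt) in enumerate(protocol.channels):
        base = channel_background(scene, light, filt)
        signal = np.full((h, w), base)
        for stain, m in zip(scene.stains, stain_masks):
            resp = channel_response(stain.fluorophore, light, filt) * stain.concentration
            if resp > 0.0:
                signal = signal + resp * m
        if scene.noise_sd > 0:
            dirty_i = signal + rng.normal(0.0, scene.noise_sd, size=(h, w))
            clean_i = base + rng.normal(0.0, scene.noise_sd, size=(h, w))
        else:
            dirty_i = signal
            clean_i = np.full((h, w), base)
        dirty[i] = np.clip(dirty_i, 0.0, 1.0)
        clean[i] = np.clip(clean_i, 0.0, 1.0)

    from .threshold import StainMask  # local import to avoid a cycle

    return (
        ImageStack(frames=dirty, channel_meta=meta),
        ImageStack(frames=clean, channel_meta=list(meta)),
        StainMask(mask=truth, source="planted ground truth"),
    )


def default_scene(seed: int = 0, noise_sd: float = 0.02) -> SceneSpec:
    """The reference phantom: a 3 x 1.5 mm riboflavin-like stain, tile-aligned
    at the default 0.05 mm/px scale (60 x 30 px starting at pixel (30, 30))."""
    return SceneSpec(
        pixel_scale=0.05,
        background_reflectance=0.2,
        stains=(
            StainRegion(
                shape="rectangle",
                center=(3.0, 2.25),
                extent=(3.0, 1.5),
                fluorophore=RIBOFLAVIN_LIKE,
                concentration=1.0,
            ),
        ),
        noise_sd=noise_sd,
        seed=seed,
    )


def default_protocol(frame_height: int = 96, frame_width: int = 128) -> AcquisitionProtocol:
    """The full 48-channel grid at a desk-scale frame size (configurable)."""
    return make_protocol(
        default_lights(), 420.0, 720.0, 20.0, frame_height=frame_height, frame_width=frame_width
    )
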