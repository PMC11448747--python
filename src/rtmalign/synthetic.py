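"""Virtual microscope: synthetic graticule measurements and images.

Generates, for a chosen *true* objective-to-sample distance, the per-channel
pixel distances (and optionally full graticule images) that a real camera
would record, using the forward channel model to predict each channel's
magnification.  This makes the whole alignment pipeline testable without
hardware: measurements synthesized at a known true d_sample should be
inverted by the estimator back to that d_sample.

The default scene mirrors a 10 μm-pitch stage graticule imaged onto ~1.1 μm
camera pixels at 10x.  Rulings are rendered as Gaussian-profile dark lines on
a bright background (diffraction-blurred appearance, so subpixel detection is
exercised honestly) with optional extra blur and additive Gaussian noise.
What it does not emulate: NA-dependent PSF shape, vignetting, field
distortion, shot noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .alignment import MeasurementSet
from .channels import ChannelSpec, magnification_at
from .config import MicroscopeConfig
from .errors import GeometryError

__all__ = ["SyntheticScene", "forward_measurements", "render_graticule_image", "save_image"]


@dataclass(frozen=True)
class SyntheticScene:
    """Ground truth for the virtual microscope.

    grid_pitch_um: graticule ruling period at the sample (10 μm default).
    true_d_sample: actual objective-to-sample distance, mm.
    blur_sigma: extra Gaussian blur applied to rendered images, px.
    noise_sd: noise level — fractional (of distance) for measurements,
        fraction of dynamic range (additive) for images.
    seed: used when no external generator is supplied.
    """

    true_d_sample: float
    grid_pitch_um: float = 10.0
    blur_sigma: float = 1.0
    noise_sd: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.grid_pitch_um > 0:
            raise ValueError("grid_pitch_um must be positive")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _magnification_or_raise(channel: ChannelSpec, objective, d_sample: float) -> float:
    result = magnification_at(channel, objective, d_sample, warn=False)
    if result is None:
        raise GeometryError(
            f"channel {channel.label!r}: no imaging solution at "
            f"true d_sample = {d_sample:.6f} mm — the virtual microscope cannot "
            f"form an image there"
        )
    return result.magnification


def forward_measurements(
    config: MicroscopeConfig,
    scene: SyntheticScene,
    n_periods: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> MeasurementSet:
    """Pixel distance spanning ``n_periods`` graticule periods on each channel.

    distance_px = n_periods * pitch * |M(true_d_sample)| / pixel_pitch,
    optionally perturbed by multiplicative Gaussian noise of fractional sd
    ``scene.noise_sd`` (independent per channel).  Deterministic for a fixed
    seed/generator.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    span_um = n_periods * scene.grid_pitch_um
    distances: dict[str, float] = {}
    pitches: dict[str, float] = {}
    for channel in config.channels:
        mag = _magnification_or_raise(channel, config.objective, scene.true_d_sample)
        d = span_um * mag / channel.pixel_pitch
        if scene.noise_sd > 0:
            d *= 1.0 + rng.normal(0.0, scene.noise_sd)
        distances[channel.label] = d
        pitches[channel.label] = channel.pixel_pitch
    return MeasurementSet(
        distances_px=distances, pixel_pitch_um=pitches, feature_span_um=span_um
    )


def render_graticule_image(
    config: MicroscopeConfig,
    channel_label: str,
    scene: SyntheticScene,
    image_shape: tuple[int, int] = (1024, 1024),
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, dict]:
    """Render the graticule as seen by one channel; returns (uint8 image, metadata).

    Vertical dark rulings on a bright background at the model-predicted
    on-sensor period grid_pitch * |M| / pixel_pitch (px), line width tied to
    the period, then Gaussian blur of ``scene.blur_sigma`` px and additive
    Gaussian noise of ``scene.noise_sd`` x dynamic range.  The metadata
    records the programmed period as ground truth for tests.
    """
    channel = config.channel(channel_label)
    mag = _magnification_or_raise(channel, config.objective, scene.true_d_sample)
    period_px = scene.grid_pitch_um * mag / channel.pixel_pitch
    if period_px < 4.0:
        raise ValueError(
            f"channel {channel_label!r}: on-sensor period {period_px:.2f} px is "
            f"undersampled (< 4 px); increase magnification or bin less"
        )
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    n_rows, n_cols = image_shape
    x = np.arange(n_cols, dtype=float)
    # line centres, first one half a period in from the left edge
    centres = np.arange(period_px / 2.0, n_cols, period_px)
    line_sigma = max(1.0, period_px / 12.0)
    profile = np.ones(n_cols)
    for c in centres:
        profile -= 0.8 * np.exp(-0.5 * ((x - c) / line_sigma) ** 2)
    profile = np.clip(profile, 0.0, 1.0)
    image = np.tile(profile, (n_rows, 1))
    if scene.blur_sigma > 0:
        image = gaussian_filter(image, scene.blur_sigma, mode="nearest")
    if scene.noise_sd > 0:
        image = image + rng.normal(0.0, scene.noise_sd, size=image.shape)
    image8 = np.clip(image * 255.0, 0, 255).round().astype(np.uint8)
    metadata = {
        "channel": channel_label,
        "period_px": float(period_px),
        "magnification": float(mag),
        "grid_pitch_um": scene.grid_pitch_um,
        "pixel_pitch_um": channel.pixel_pitch,
        "true_d_sample_mm": scene.true_d_sample,
        "n_lines": int(len(centres)),
        "blur_sigma": scene.blur_sigma,
        "noise_sd": scene.noise_sd,
        "seed": scene.seed,
    }
    return image8, metadata


def save_image(image: np.ndarray, metadata: dict, path) -> None:
    """Write a rendered image as TIFF with a JSON sidecar of its ground truth."""
    path = Path(path)
    tifffile.imwrite(path, image)
    path.with_suffix(".json").write_text(json.dumps(metadata, indent=2) + "\n")
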