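"""Line-profile measurement of graticule images.

The pixel distance between two rulings of a calibrated grid is the raw
observable of the alignment method: a line profile is taken across the image,
ruling centres are located to subpixel precision, and the span of a known
number of grid periods is reported in pixels.  Spanning many periods
amortizes the per-line localization error.

Measure near the image centre where possible — simple high-magnification
optics can show field-dependent magnification, and the alignment model
assumes a distortion-free measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import InsufficientFeaturesError

__all__ = [
    "ProfileMeasurement",
    "extract_line_profile",
    "detect_feature_positions",
    "feature_distance",
    "measure_image",
]


@dataclass(frozen=True)
class ProfileMeasurement:
    """A measured profile: detected line centres and the period span used."""

    profile: np.ndarray
    feature_positions: np.ndarray  # subpixel, strictly increasing
    distance_px: float
    n_periods: int

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.feature_positions) > 0):
            raise ValueError("feature positions must be strictly increasing")
        if not self.distance_px > 0:
            raise ValueError("distance must be positive")
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")


def extract_line_profile(
    image: np.ndarray, row: int | None = None, averaging_halfwidth: int = 0
) -> np.ndarray:
    """Horizontal intensity profile at ``row``, averaged over +/- halfwidth rows.

    ``row`` defaults to the central row.  Averaging perpendicular to the
    profile suppresses pixel noise without biasing line positions.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    n_rows = image.shape[0]
    if row is None:
        row = n_rows // 2
    if not 0 <= row < n_rows:
        raise ValueError(f"row {row} outside image of {n_rows} rows")
    if averaging_halfwidth < 0:
        raise ValueError("averaging_halfwidth must be >= 0")
    lo = row - averaging_halfwidth
    hi = row + averaging_halfwidth + 1
    if lo < 0 or hi > n_rows:
        raise ValueError(
            f"rows {lo}..{hi - 1} outside image of {n_rows} rows; "
            f"reduce averaging_halfwidth"
        )
    return image[lo:hi].astype(float).mean(axis=0)


def _parabolic_refine(values: np.ndarray, i: int) -> float:
    """Subpixel extremum via a parabola through (i-1, i, i+1); falls back to i."""
    if i == 0 or i == len(values) - 1:
        return float(i)
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return float(i)
    delta = 0.5 * (y0 - y2) / denom
    if abs(delta) > 1.0:  # ill-conditioned fit; keep the integer position
        return float(i)
    return i + delta


def detect_feature_positions(
    profile: np.ndarray,
    polarity: str = "dark",
    min_separation: float = 5.0,
) -> np.ndarray:
    """Subpixel centres of dark (or bright) lines in a 1-D profile.

    Local extrema of the requested polarity at least ``min_separation`` pixels
    apart (the more extreme one wins within that distance), each refined by a
    three-point parabolic fit.  Graticule rulings are dark on a bright
    background, hence the default polarity.
    """
    profile = np.asarray(profile, dtype=float)
    if polarity not in ("dark", "bright"):
        raise ValueError("polarity must be 'dark' or 'bright'")
    if len(profile) <= 2 * min_separation:
        raise InsufficientFeaturesError(
            f"profile of {len(profile)} samples too short for "
            f"min_separation={min_separation}"
        )
    signal = -profile if polarity == "dark" else profile
    # prominence guard rejects plateau ripple on a constant background
    span = float(signal.max() - signal.min())
    if span == 0.0:
        raise InsufficientFeaturesError("profile is constant: no features")
    peaks, _ = find_peaks(signal, distance=max(1, int(round(min_separation))),
                          prominence=0.05 * span)
    if len(peaks) < 2:
        raise InsufficientFeaturesError(
            f"found {len(peaks)} feature(s); at least 2 required"
        )
    refined = np.array([_parabolic_refine(signal, int(i)) for i in peaks])
    return refined


def feature_distance(positions: np.ndarray, n_periods: int) -> float:
    """Pixel span of ``n_periods`` grid periods: positions[n] - positions[0]."""
    positions = np.asarray(positions, dtype=float)
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    if len(positions) < n_periods + 1:
        raise InsufficientFeaturesError(
            f"need {n_periods + 1} feature positions for {n_periods} periods, "
            f"got {len(positions)}"
        )
    return float(positions[n_periods] - positions[0])


def measure_image(
    image: np.ndarray,
    n_periods: int,
    *,
    row: int | None = None,
    averaging_halfwidth: int = 2,
    polarity: str = "dark",
    min_separation: float = 5.0,
) -> ProfileMeasurement:
    """End-to-end: profile -> line centres -> span of ``n_periods`` periods."""
    profile = extract_line_profile(image, row=row, averaging_halfwidth=averaging_halfwidth)
    positions = detect_feature_positions(
        profile, polarity=polarity, min_separation=min_separation
    )
    distance = feature_distance(positions, n_periods)
    return ProfileMeasurement(
        profile=profile,
        feature_positions=positions,
        distance_px=distance,
        n_periods=n_periods,
    )
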