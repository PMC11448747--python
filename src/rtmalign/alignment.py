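"""Working-distance estimation and the iterative alignment loop.

The procedure: image the same feature span on every channel, normalize the
measured pixel distances (pixel-pitch-compensated) to the reference channel,
and read the objective-to-sample distance off the model's normalized
magnification curve for the estimation channel by inverse interpolation.  The
signed working-distance error is then

    error = d_sample_interpolated - f_o

positive meaning the objective sits too far from the sample, negative too
close.  Moving the objective by -error and refocusing the tube lenses drives
the system toward alignment; the loop stops when |error| falls below the
axial resolution dz = 2 lambda / NA^2, the finest axial distinction the
optics can make.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .channels import (
    MagnificationCurve,
    magnification_curve,
    normalize_curves,
)
from .config import MicroscopeConfig
from .errors import (
    AlignmentWarning,
    MeasurementError,
    NonMonotonicCurveError,
    OutOfRangeError,
)

__all__ = [
    "MeasurementSet",
    "AlignmentEstimate",
    "IterationRecord",
    "normalized_measurement",
    "interpolate_d_sample",
    "working_distance_error",
    "axial_resolution",
    "estimate",
    "compute_normalized_curves",
    "run_simulated_alignment",
]


@dataclass(frozen=True)
class MeasurementSet:
    """Per-channel feature distances in pixels, with each camera's pixel pitch.

    ``distances_px`` are subpixel-valued counts between the same two physical
    points imaged on every channel; ``pixel_pitch_um`` converts them to
    on-sensor micrometres so differently-pixelled cameras are comparable.
    ``feature_span_um`` (graticule pitch x periods) is optional and only
    needed for absolute magnification calibration.
    """

    distances_px: Mapping[str, float]
    pixel_pitch_um: Mapping[str, float]
    feature_span_um: Optional[float] = None

    def __post_init__(self) -> None:
        for label, d in self.distances_px.items():
            if not (np.isfinite(d) and d > 0):
                raise MeasurementError(
                    f"channel {label!r}: distance must be a positive finite "
                    f"pixel count, got {d!r}"
                )
            if label not in self.pixel_pitch_um:
                raise MeasurementError(f"channel {label!r}: pixel pitch missing")

    @classmethod
    def from_csv(cls, path, config: Optional[MicroscopeConfig] = None) -> "MeasurementSet":
        """Read `channel,distance_px[,pixel_pitch_um]`; pitches default to config."""
        table = pd.read_csv(path)
        required = {"channel", "distance_px"}
        if not required.issubset(table.columns):
            raise MeasurementError(f"{path}: need columns {sorted(required)}")
        distances = dict(zip(table["channel"].astype(str), table["distance_px"].astype(float)))
        pitches: dict[str, float] = {}
        for _, row in table.iterrows():
            label = str(row["channel"])
            if "pixel_pitch_um" in table.columns and np.isfinite(row.get("pixel_pitch_um", np.nan)):
                pitches[label] = float(row["pixel_pitch_um"])
            elif config is not None:
                pitches[label] = config.channel(label).pixel_pitch
            else:
                raise MeasurementError(
                    f"{path}: no pixel_pitch_um column and no config for channel {label!r}"
                )
        return cls(distances_px=distances, pixel_pitch_um=pitches)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "channel": list(self.distances_px),
                "distance_px": [self.distances_px[c] for c in self.distances_px],
                "pixel_pitch_um": [self.pixel_pitch_um[c] for c in self.distances_px],
            }
        ).to_csv(path, index=False)


def normalized_measurement(
    measurements: MeasurementSet, reference: str
) -> dict[str, float]:
    """Measured normalized magnification per channel.

    ratio_i = (px_i * pitch_i) / (px_ref * pitch_ref); with identical cameras
    this is just the pixel-count ratio.  The reference channel maps to 1.
    """
    if reference not in measurements.distances_px:
        raise MeasurementError(f"reference channel {reference!r} not measured")
    ref_um = (
        measurements.distances_px[reference] * measurements.pixel_pitch_um[reference]
    )
    return {
        label: (d * measurements.pixel_pitch_um[label]) / ref_um
        for label, d in measurements.distances_px.items()
    }


def interpolate_d_sample(curve: MagnificationCurve, measured_ratio: float) -> float:
    """Invert the normalized curve: the d_sample whose model ratio matches.

    Piecewise-linear inverse interpolation on the contiguous solved branch of
    the curve containing f_o (gaps are never interpolated across).  The branch
    must be strictly monotonic; a ratio outside its value range raises
    OutOfRangeError rather than extrapolating.
    """
    if curve.normalized is None:
        raise ValueError("curve has no normalized values; run normalize_curves first")
    if not np.isfinite(measured_ratio) or measured_ratio <= 0:
        raise MeasurementError(f"measured ratio must be positive, got {measured_ratio!r}")
    branch = curve.primary_branch()
    grid = curve.d_sample_grid[branch]
    values = curve.normalized[branch]
    diffs = np.diff(values)
    if np.all(diffs > 0):
        xp, fp = values, grid
    elif np.all(diffs < 0):
        xp, fp = values[::-1], grid[::-1]
    else:
        raise NonMonotonicCurveError(
            f"channel {curve.channel.label!r}: normalized curve is not strictly "
            f"monotonic on the solved branch around f_o; inversion is ambiguous"
        )
    if not (xp[0] <= measured_ratio <= xp[-1]):
        raise OutOfRangeError(
            f"measured ratio {measured_ratio:.6f} outside the modelled range "
            f"[{xp[0]:.6f}, {xp[-1]:.6f}] for channel {curve.channel.label!r}; "
            f"re-scan with a wider d_sample range (or the misalignment exceeds "
            f"what a fixed-path system can image)"
        )
    return float(np.interp(measured_ratio, xp, fp))


def working_distance_error(d_sample_interpolated: float, f_o: float) -> float:
    """Signed error (mm): positive = objective too far from the sample."""
    return d_sample_interpolated - f_o


def axial_resolution(wavelength_nm: float, na: float) -> float:
    """Abbe axial resolution dz = 2 lambda / NA^2, in micrometres."""
    if not wavelength_nm > 0:
        raise ValueError("wavelength must be positive")
    if not na > 0:
        raise ValueError("NA must be positive")
    return 2.0 * (wavelength_nm * 1e-3) / (na * na)


@dataclass(frozen=True)
class AlignmentEstimate:
    """Outcome of one estimation pass."""

    ratios: Mapping[str, float]
    d_sample_interpolated: float  # mm
    working_distance_error_mm: float
    dz_um: float
    converged: bool
    direction: str  # "too far away" / "too close" / "aligned"
    per_channel_d_sample: Mapping[str, float]
    estimation_channel: str

    @property
    def working_distance_error_um(self) -> float:
        return self.working_distance_error_mm * 1e3

    def to_dict(self) -> dict:
        return {
            "normalized_magnifications": dict(self.ratios),
            "d_sample_interpolated_mm": self.d_sample_interpolated,
            "working_distance_error_mm": self.working_distance_error_mm,
            "working_distance_error_um": self.working_distance_error_um,
            "direction": self.direction,
            "axial_resolution_um": self.dz_um,
            "converged": self.converged,
            "per_channel_d_sample_mm": dict(self.per_channel_d_sample),
            "estimation_channel": self.estimation_channel,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def report(self) -> str:
        lines = [
            "alignment estimate",
            f"  estimation channel: {self.estimation_channel}",
            "  normalized magnifications: "
            + ", ".join(f"{k}={v:.5f}" for k, v in self.ratios.items()),
            f"  d_sample (interpolated): {self.d_sample_interpolated:.6f} mm",
            f"  working distance error:  {self.working_distance_error_mm:+.6f} mm "
            f"({self.working_distance_error_um:+.3f} um) -> objective {self.direction}",
            f"  axial resolution dz:     {self.dz_um:.3f} um",
            f"  converged (|error| < dz): {'yes' if self.converged else 'no'}",
        ]
        return "\n".join(lines)


def compute_normalized_curves(
    config: MicroscopeConfig,
    d_sample_min: Optional[float] = None,
    d_sample_max: Optional[float] = None,
    step: Optional[float] = None,
) -> dict[str, MagnificationCurve]:
    """Magnification curves for every channel, normalized to the reference."""
    kwargs = {} if step is None else {"step": step}
    curves = [
        magnification_curve(ch, config.objective, d_sample_min, d_sample_max, **kwargs)
        for ch in config.channels
    ]
    normalized = normalize_curves(curves, config.reference_channel)
    return {c.channel.label: c for c in normalized}


def estimate(
    config: MicroscopeConfig,
    measurements: MeasurementSet,
    curves: Optional[Mapping[str, MagnificationCurve]] = None,
    *,
    dz_um: Optional[float] = None,
    discrepancy_factor: float = 10.0,
) -> AlignmentEstimate:
    """Turn one set of per-channel distances into a working-distance estimate.

    The estimation channel's curve drives the estimate; the other non-reference
    channels are inverted too as a cross-check, and an AlignmentWarning is
    emitted when the per-channel estimates spread more than
    ``discrepancy_factor`` grid steps (possible field distortion or tube-lens
    focal-length tolerances).

    ``curves`` may be precomputed (e.g. once per alignment session); otherwise
    the default scan is computed here.  ``dz_um`` overrides the Abbe-derived
    convergence threshold.
    """
    if curves is None:
        curves = compute_normalized_curves(config)
    ratios = normalized_measurement(measurements, config.reference_channel)
    per_channel: dict[str, float] = {}
    for label, ratio in ratios.items():
        if label == config.reference_channel:
            continue  # its ratio is 1 by construction: no information
        try:
            per_channel[label] = interpolate_d_sample(curves[label], ratio)
        except OutOfRangeError:
            if label == config.estimation_channel:
                raise
    d_interp = per_channel[config.estimation_channel]
    curve = curves[config.estimation_channel]
    grid_step = float(np.median(np.diff(curve.d_sample_grid)))
    if len(per_channel) > 1:
        spread = max(per_channel.values()) - min(per_channel.values())
        if spread > discrepancy_factor * grid_step:
            warnings.warn(
                f"per-channel d_sample estimates spread {spread * 1e3:.1f} um "
                f"(> {discrepancy_factor:g} grid steps): check for field "
                f"distortion or tube-lens focal-length tolerances "
                f"({ {k: round(v, 4) for k, v in per_channel.items()} })",
                AlignmentWarning,
                stacklevel=2,
            )
    error_mm = working_distance_error(d_interp, config.objective.f_o)
    if dz_um is None:
        dz_um = axial_resolution(config.wavelength_nm, config.objective.na)
    converged = abs(error_mm) * 1e3 < dz_um  # compare in micrometres
    if converged:
        direction = "aligned"
    else:
        direction = "too far away" if error_mm > 0 else "too close"
    return AlignmentEstimate(
        ratios=ratios,
        d_sample_interpolated=d_interp,
        working_distance_error_mm=error_mm,
        dz_um=dz_um,
        converged=converged,
        direction=direction,
        per_channel_d_sample=per_channel,
        estimation_channel=config.estimation_channel,
    )


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    true_d_sample: float  # mm, before the correction of this iteration
    estimated_error_mm: float
    converged: bool


def run_simulated_alignment(
    config: MicroscopeConfig,
    true_d_sample_initial: float,
    *,
    noise_sd: float = 0.0,
    max_iterations: int = 10,
    seed: Optional[int] = None,
    n_periods: int = 10,
    grid_pitch_um: float = 10.0,
    curves: Optional[Mapping[str, MagnificationCurve]] = None,
) -> list[IterationRecord]:
    """Iterate measure -> estimate -> correct on the virtual microscope.

    Each iteration synthesizes pixel distances at the current true d_sample
    (multiplicative Gaussian noise of fractional sd ``noise_sd``, seeded),
    estimates the working-distance error, and moves the objective by its
    negative; tube lenses are refocused exactly by the imaging-condition
    solve.  Stops once the estimated |error| drops below dz.  Non-convergence
    within ``max_iterations`` is reported in the trajectory, not raised.
    """
    from .synthetic import SyntheticScene, forward_measurements

    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    if curves is None:
        curves = compute_normalized_curves(config)
    rng = np.random.default_rng(seed)
    trajectory: list[IterationRecord] = []
    true_d_sample = float(true_d_sample_initial)
    for iteration in range(1, max_iterations + 1):
        scene = SyntheticScene(
            true_d_sample=true_d_sample,
            grid_pitch_um=grid_pitch_um,
            noise_sd=noise_sd,
        )
        measurements = forward_measurements(config, scene, n_periods=n_periods, rng=rng)
        result = estimate(config, measurements, curves)
        trajectory.append(
            IterationRecord(
                iteration=iteration,
                true_d_sample=true_d_sample,
                estimated_error_mm=result.working_distance_error_mm,
                converged=result.converged,
            )
        )
        if result.converged:
            break
        true_d_sample -= result.working_distance_error_mm
    return trajectory
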