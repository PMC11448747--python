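"""Forward model of one infinite-conjugate imaging channel.

A channel is sample -> objective (focal length f_o) -> tube lens (focal length
f_t) -> camera, with the total sample-to-sensor path d_total fixed by the
optomechanics.  Three distances describe the layout::

    d_interlens = d_total - d_sample - d_cam

where d_sample is sample-to-objective and d_cam is tube-lens-to-sensor.  When
d_sample = f_o the infinity space is collimated, d_cam = f_t focuses it, and
the lateral magnification is M = f_t / f_o for every channel regardless of
d_total.  When d_sample deviates, an image can still be formed by refocusing
the tube lens (solving for the d_cam that zeroes the B entry of the system
matrix), but the magnification then depends on d_total — that dependence is
what makes image-based alignment possible.

The objective is treated as a single thin lens at its principal plane, so
``d_sample`` is the principal-plane-to-sample distance, NOT the mechanical
working distance printed on the barrel.  The difference is a fixed offset for
a given objective and does not affect the alignment method, which only ever
reasons about changes in d_sample relative to f_o.

For a fixed d_total there can be *no* tube-lens position that forms an image:
just above f_o the objective's intermediate image lands so close to the sensor
that the tube lens's minimum 4f throw no longer fits.  Such grid points are
reported as explicit gaps (NaN) and a `NoSolutionWarning` names the channel
and position; they are never interpolated over.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError, NoSolutionWarning
from .rtma import TransferMatrix, compose, free_space, thin_lens

__all__ = [
    "ChannelSpec",
    "ObjectiveSpec",
    "ChannelGeometry",
    "MagnificationResult",
    "MagnificationCurve",
    "system_matrix",
    "b_component",
    "solve_d_cam",
    "magnification_at",
    "magnification_curve",
    "normalize_curves",
    "curves_to_dataframe",
    "write_curves_csv",
    "focal_plane_from_front",
    "DEFAULT_SCAN_HALFWIDTH",
    "DEFAULT_SCAN_STEP",
    "B_TOL",
]

#: Half-width (mm) of the default d_sample scan around f_o.
DEFAULT_SCAN_HALFWIDTH = 0.25
#: Default d_sample grid step (mm): 1 micrometre.
DEFAULT_SCAN_STEP = 1e-3
#: |B| below this (mm) counts as an imaging solution.
B_TOL = 1e-9
#: Minimum clearance (mm) required of d_cam and d_interlens.
_MARGIN = 1.0


@dataclass(frozen=True)
class ChannelSpec:
    """One imaging channel: total path, tube lens and camera pixel pitch."""

    label: str
    d_total: float  # sample-to-sensor path length, mm
    f_t: float  # tube lens focal length, mm
    pixel_pitch: float  # camera pixel size, micrometres

    def __post_init__(self) -> None:
        if not self.d_total > 0:
            raise ValueError(f"channel {self.label!r}: d_total must be positive")
        if not self.f_t > 0:
            raise ValueError(f"channel {self.label!r}: f_t must be positive")
        if not self.pixel_pitch > 0:
            raise ValueError(f"channel {self.label!r}: pixel_pitch must be positive")
        if not self.d_total > self.f_t:
            raise ValueError(
                f"channel {self.label!r}: d_total ({self.d_total} mm) must exceed "
                f"the tube lens focal length ({self.f_t} mm)"
            )


@dataclass(frozen=True)
class ObjectiveSpec:
    """Objective effective focal length (mm) and numerical aperture."""

    f_o: float
    na: float

    def __post_init__(self) -> None:
        if not self.f_o > 0:
            raise ValueError("objective f_o must be positive")
        if not 0 < self.na < 1.52:
            raise ValueError("objective NA must be in (0, 1.52)")


@dataclass(frozen=True)
class ChannelGeometry:
    """A concrete layout of one channel; d_interlens follows from the other three."""

    d_sample: float
    d_cam: float
    d_total: float

    @property
    def d_interlens(self) -> float:
        return self.d_total - self.d_sample - self.d_cam

    @property
    def is_physical(self) -> bool:
        return self.d_sample > 0 and self.d_cam > 0 and self.d_interlens > 0


@dataclass(frozen=True)
class MagnificationResult:
    """Magnification at one solved layout: magnitude, signed value, d_cam (mm)."""

    magnification: float
    signed: float
    d_cam: float


def focal_plane_from_front(working_distance_um: float, coverslip_thickness_um: float) -> float:
    """Distance (μm) from the objective front surface to the focal plane.

    Coverslip-corrected objectives quote a working distance that excludes the
    coverslip, so the focal plane sits working-distance + coverslip-thickness
    from the front surface (e.g. 400 μm WD with a 170 μm coverslip -> 570 μm).
    """
    if working_distance_um < 0 or coverslip_thickness_um < 0:
        raise ValueError("distances must be non-negative")
    return working_distance_um + coverslip_thickness_um


def _system_matrix_unchecked(
    channel: ChannelSpec, objective: ObjectiveSpec, d_sample: float, d_cam: float
) -> TransferMatrix:
    d_interlens = channel.d_total - d_sample - d_cam
    return compose(
        [
            free_space(d_sample),
            thin_lens(objective.f_o),
            free_space(d_interlens),
            thin_lens(channel.f_t),
            free_space(d_cam),
        ]
    )


def system_matrix(
    channel: ChannelSpec, objective: ObjectiveSpec, d_sample: float, d_cam: float
) -> TransferMatrix:
    """ABCD matrix of the channel for a given d_sample and d_cam (both mm).

    Raises GeometryError when the implied objective-to-tube-lens separation is
    not positive.
    """
    geometry = ChannelGeometry(d_sample=d_sample, d_cam=d_cam, d_total=channel.d_total)
    if geometry.d_interlens <= 0:
        raise GeometryError(
            f"channel {channel.label!r}: d_interlens = {geometry.d_interlens:.3f} mm <= 0 "
            f"for d_sample={d_sample} mm, d_cam={d_cam} mm (d_total={channel.d_total} mm)"
        )
    return _system_matrix_unchecked(channel, objective, d_sample, d_cam)


def b_component(
    channel: ChannelSpec, objective: ObjectiveSpec, d_sample: float, d_cam: float
) -> float:
    """B entry (mm) of the system matrix; zero when the sensor holds an image."""
    return system_matrix(channel, objective, d_sample, d_cam).b


def _b_quadratic_coeffs(
    channel: ChannelSpec, objective: ObjectiveSpec, d_sample: float
) -> tuple[float, float, float]:
    # For fixed d_sample, B(d_cam) is exactly quadratic: the only d_cam
    # dependence enters through free_space(d_cam) and free_space(d_interlens),
    # both linear in d_cam.  Three matrix evaluations pin it down exactly.
    b0 = _system_matrix_unchecked(channel, objective, d_sample, 0.0).b
    b1 = _system_matrix_unchecked(channel, objective, d_sample, 1.0).b
    b2 = _system_matrix_unchecked(channel, objective, d_sample, 2.0).b
    a2 = (b2 - 2.0 * b1 + b0) / 2.0
    a1 = b1 - b0 - a2
    return a2, a1, b0


def _quadratic_roots(a2: float, a1: float, a0: float) -> list[float]:
    """Real roots of a2 x^2 + a1 x + a0, stable also when a2 ~ 0."""
    if abs(a2) < 1e-15 * max(1.0, abs(a1), abs(a0)):
        if a1 == 0.0:
            return []
        return [-a0 / a1]
    disc = a1 * a1 - 4.0 * a2 * a0
    if disc < 0.0:
        return []
    sq = float(np.sqrt(disc))
    # Citardauq form avoids cancellation for the small-magnitude root.
    q = -0.5 * (a1 + np.copysign(sq, a1) if a1 != 0.0 else -sq)
    roots = {q / a2}
    if q != 0.0:
        roots.add(a0 / q)
    else:
        roots.add(0.0)
    return sorted(roots)


def solve_d_cam(
    channel: ChannelSpec,
    objective: ObjectiveSpec,
    d_sample: float,
    *,
    margin: float = _MARGIN,
    warn: bool = True,
) -> Optional[float]:
    """Tube-lens-to-sensor distance (mm) that images the sample, or None.

    B(d_cam) is quadratic, so its real roots are found exactly (reconstructed
    from three matrix evaluations, polished by one Newton step) and filtered
    for physical feasibility: d_cam and d_interlens both at least ``margin``
    mm.  When both roots are feasible the one nearest f_t is returned — the
    aligned solution is d_cam = f_t and the alignment loop operates in its
    neighbourhood.  When no feasible root exists, None is returned and a
    NoSolutionWarning names the channel and position.
    """
    if not d_sample > 0:
        raise ValueError("d_sample must be positive")
    a2, a1, a0 = _b_quadratic_coeffs(channel, objective, d_sample)
    upper = channel.d_total - d_sample - margin
    feasible = []
    for root in _quadratic_roots(a2, a1, a0):
        deriv = 2.0 * a2 * root + a1
        if deriv != 0.0:  # one Newton polish
            root = root - (a2 * root * root + a1 * root + a0) / deriv
        if margin <= root <= upper:
            b = _system_matrix_unchecked(channel, objective, d_sample, root).b
            if abs(b) < B_TOL:
                feasible.append(root)
    if not feasible:
        if warn:
            warnings.warn(
                f"channel {channel.label!r}: no imaging solution for "
                f"d_sample = {d_sample:.6f} mm (d_total = {channel.d_total} mm)",
                NoSolutionWarning,
                stacklevel=2,
            )
        return None
    return min(feasible, key=lambda r: abs(r - channel.f_t))


def magnification_at(
    channel: ChannelSpec,
    objective: ObjectiveSpec,
    d_sample: float,
    *,
    warn: bool = True,
) -> Optional[MagnificationResult]:
    """|lateral magnification| at the solved tube-lens focus, or None (no solution)."""
    d_cam = solve_d_cam(channel, objective, d_sample, warn=warn)
    if d_cam is None:
        return None
    a = _system_matrix_unchecked(channel, objective, d_sample, d_cam).a
    return MagnificationResult(magnification=abs(a), signed=a, d_cam=d_cam)


@dataclass
class MagnificationCurve:
    """Tabulated (d_sample, solved d_cam, |M|) for one channel.

    Grid points with no imaging solution hold NaN in ``d_cam``,
    ``magnification`` and ``signed``; they are explicit gaps.  ``normalized``
    is populated by :func:`normalize_curves`.
    """

    channel: ChannelSpec
    objective: ObjectiveSpec
    d_sample_grid: np.ndarray
    d_cam: np.ndarray
    magnification: np.ndarray
    signed: np.ndarray
    normalized: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.d_sample_grid) > 0):
            raise ValueError("d_sample grid must be strictly increasing")

    @property
    def f_o_index(self) -> int:
        return int(np.argmin(np.abs(self.d_sample_grid - self.objective.f_o)))

    def primary_branch(self) -> slice:
        """Contiguous run of solved grid points containing d_sample = f_o.

        Uses ``normalized`` when present (a gap in either this channel or the
        reference breaks the branch), else ``magnification``.
        """
        values = self.normalized if self.normalized is not None else self.magnification
        finite = np.isfinite(values)
        i = self.f_o_index
        if not finite[i]:
            raise GeometryError(
                f"channel {self.channel.label!r}: no imaging solution at d_sample = f_o"
            )
        lo = i
        while lo > 0 and finite[lo - 1]:
            lo -= 1
        hi = i
        n = len(finite)
        while hi < n - 1 and finite[hi + 1]:
            hi += 1
        return slice(lo, hi + 1)


def _scan_grid(f_o: float, d_min: float, d_max: float, step: float) -> np.ndarray:
    # Anchor the grid on f_o so the aligned position is always a grid point.
    k_lo = int(np.ceil((d_min - f_o) / step - 1e-9))
    k_hi = int(np.floor((d_max - f_o) / step + 1e-9))
    return f_o + step * np.arange(k_lo, k_hi + 1)


def magnification_curve(
    channel: ChannelSpec,
    objective: ObjectiveSpec,
    d_sample_min: Optional[float] = None,
    d_sample_max: Optional[float] = None,
    step: float = DEFAULT_SCAN_STEP,
) -> MagnificationCurve:
    """Scan d_sample and tabulate the solved magnification for one channel.

    The default range is f_o ± 0.25 mm at 1 μm steps, centred on (and always
    containing) f_o.  Points with no imaging solution are retained as NaN.
    """
    f_o = objective.f_o
    if d_sample_min is None:
        d_sample_min = f_o - DEFAULT_SCAN_HALFWIDTH
    if d_sample_max is None:
        d_sample_max = f_o + DEFAULT_SCAN_HALFWIDTH
    if not (d_sample_min < f_o < d_sample_max):
        raise ValueError("scan range must bracket the objective focal length")
    if not step > 0:
        raise ValueError("step must be positive")
    if not d_sample_min > 0:
        raise ValueError("d_sample_min must be positive")

    grid = _scan_grid(f_o, d_sample_min, d_sample_max, step)
    d_cam = np.full(grid.shape, np.nan)
    mag = np.full(grid.shape, np.nan)
    signed = np.full(grid.shape, np.nan)
    with warnings.catch_warnings():
        # one summary warning below instead of one per missing grid point
        warnings.simplefilter("ignore", NoSolutionWarning)
        for i, ds in enumerate(grid):
            result = magnification_at(channel, objective, float(ds), warn=False)
            if result is not None:
                d_cam[i] = result.d_cam
                mag[i] = result.magnification
                signed[i] = result.signed
    n_missing = int(np.sum(~np.isfinite(mag)))
    if n_missing == len(grid):
        raise GeometryError(
            f"channel {channel.label!r}: no imaging solution anywhere in "
            f"[{d_sample_min}, {d_sample_max}] mm — range infeasible"
        )
    if n_missing:
        missing = grid[~np.isfinite(mag)]
        warnings.warn(
            f"channel {channel.label!r}: no imaging solution at {n_missing} of "
            f"{len(grid)} grid points (d_sample {missing.min():.4f}–{missing.max():.4f} mm)",
            NoSolutionWarning,
            stacklevel=2,
        )
    return MagnificationCurve(
        channel=channel,
        objective=objective,
        d_sample_grid=grid,
        d_cam=d_cam,
        magnification=mag,
        signed=signed,
    )


def normalize_curves(
    curves: Sequence[MagnificationCurve], reference: str
) -> list[MagnificationCurve]:
    """Divide each curve's |M| by the reference channel's |M|, point by point.

    All curves must share the same grid.  Where either value is missing the
    normalized value is missing.  Returns new curve objects; inputs untouched.
    """
    by_label = {c.channel.label: c for c in curves}
    if reference not in by_label:
        raise ValueError(f"reference channel {reference!r} not among curves")
    ref = by_label[reference]
    for c in curves:
        if c.d_sample_grid.shape != ref.d_sample_grid.shape or not np.allclose(
            c.d_sample_grid, ref.d_sample_grid, rtol=0, atol=1e-12
        ):
            raise ValueError(
                f"curve for channel {c.channel.label!r} is on a different grid "
                f"than the reference"
            )
    out = []
    with np.errstate(invalid="ignore", divide="ignore"):
        for c in curves:
            normalized = c.magnification / ref.magnification
            out.append(replace(c, normalized=normalized))
    return out


def curves_to_dataframe(curves: Sequence[MagnificationCurve]) -> pd.DataFrame:
    """Long-format table: channel, d_sample_mm, d_cam_mm, magnification, normalized."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "channel": c.channel.label,
                    "d_sample_mm": c.d_sample_grid,
                    "d_cam_mm": c.d_cam,
                    "magnification": c.magnification,
                    "normalized_magnification": (
                        c.normalized if c.normalized is not None else np.nan
                    ),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_curves_csv(curves: Sequence[MagnificationCurve], path) -> None:
    """Write the curve table as CSV; missing solutions become empty fields."""
    curves_to_dataframe(curves).to_csv(path, index=False, float_format="%.9g")
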