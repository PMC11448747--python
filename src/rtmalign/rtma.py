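"""Paraxial ray-transfer-matrix (ABCD) engine.

A ray at a plane along the optical axis is described by its lateral height
``y`` (mm) and its angle ``theta`` (radians) to the axis.  An optical element
or a stretch of free space maps the ray linearly, so a 2x2 matrix::

    [y_out]   [A  B] [y_in]
    [t_out] = [C  D] [t_in]

captures it completely within the small-angle approximation.  Systems are
modelled by multiplying element matrices in optical order (the element nearest
the object acts first, i.e. is the rightmost factor).  Two properties of the
composed matrix matter for alignment work:

* ``B == 0``  —  the output plane holds a real image of the input plane;
* when ``B == 0``, ``A`` is the lateral magnification and ``D`` the angular one.

Only free-space propagation and thin lenses are provided; in air these two
suffice to model an infinite-conjugate microscope channel, and every matrix
they produce has unit determinant.

All lengths are millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "RayVector",
    "TransferMatrix",
    "free_space",
    "thin_lens",
    "compose",
    "propagate",
    "is_imaging",
    "lateral_magnification",
    "angular_magnification",
]


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class RayVector:
    """A paraxial ray: height ``y`` (mm) and angle ``theta`` (rad) at a plane."""

    y: float
    theta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "y", _require_finite("y", self.y))
        object.__setattr__(self, "theta", _require_finite("theta", self.theta))


@dataclass(frozen=True)
class TransferMatrix:
    """An ABCD matrix.  ``a``/``d`` dimensionless, ``b`` in mm, ``c`` in 1/mm.

    Value object: composition returns new instances and never mutates.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))

    @property
    def det(self) -> float:
        """Determinant A*D - B*C; 1 for any lossless single-medium system."""
        return self.a * self.d - self.b * self.c

    def __matmul__(self, other: "TransferMatrix") -> "TransferMatrix":
        if not isinstance(other, TransferMatrix):
            return NotImplemented
        return TransferMatrix(
            a=self.a * other.a + self.b * other.c,
            b=self.a * other.b + self.b * other.d,
            c=self.c * other.a + self.d * other.c,
            d=self.c * other.b + self.d * other.d,
        )


IDENTITY = TransferMatrix(1.0, 0.0, 0.0, 1.0)


def free_space(d: float) -> TransferMatrix:
    """Propagation over a distance ``d`` (mm) of free space: [[1, d], [0, 1]].

    Negative ``d`` is algebraically valid and permitted.
    """
    return TransferMatrix(1.0, _require_finite("d", d), 0.0, 1.0)


def thin_lens(f: float) -> TransferMatrix:
    """A thin lens of focal length ``f`` (mm): [[1, 0], [-1/f, 1]]."""
    f = _require_finite("f", f)
    if f == 0.0:
        raise ValueError("thin lens focal length must be nonzero")
    return TransferMatrix(1.0, 0.0, -1.0 / f, 1.0)


def compose(elements: Iterable[TransferMatrix]) -> TransferMatrix:
    """Compose element matrices given in optical order (object side first).

    The first element acts on the ray first, so it is the rightmost factor of
    the product; the returned matrix is ``M_n @ ... @ M_2 @ M_1``.
    """
    elements = list(elements)
    if not elements:
        raise ValueError("compose requires at least one element")
    total = elements[0]
    for m in elements[1:]:
        total = m @ total
    return total


def propagate(ray: RayVector, m: TransferMatrix) -> RayVector:
    """Apply a transfer matrix to a ray: (A y + B theta, C y + D theta)."""
    return RayVector(
        y=m.a * ray.y + m.b * ray.theta,
        theta=m.c * ray.y + m.d * ray.theta,
    )


def is_imaging(m: TransferMatrix, tol: float = 1e-9) -> bool:
    """True when |B| < tol (mm): the output plane images the input plane."""
    if not tol > 0:
        raise ValueError("tol must be positive")
    return abs(m.b) < tol


def lateral_magnification(m: TransferMatrix) -> float:
    """Entry A, the signed lateral magnification of an imaging system.

    Meaningful only when ``is_imaging(m)``; the entry is returned regardless.
    """
    return m.a


def angular_magnification(m: TransferMatrix) -> float:
    """Entry D, the angular magnification of an imaging system (= 1/A when B=0)."""
    return m.d
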