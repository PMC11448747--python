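"""Independent closed-form oracle: sequential thin-lens conjugates.

Used to cross-check the matrix-based imaging-condition solver.  Deliberately
built from the scalar thin-lens equation (1/u + 1/v = 1/f, real-is-positive
convention, virtual objects as negative u), never from transfer matrices, so
agreement with the package is a genuine dual-route check.
"""

from __future__ import annotations

import math
from typing import Optional


def thin_lens_image(u: float, f: float) -> float:
    """Image distance v for object distance u (signed; u may be negative = virtual)."""
    return 1.0 / (1.0 / f - 1.0 / u)


def conjugate_d_cam(
    d_total: float, f_o: float, f_t: float, d_sample: float, margin: float = 1.0
) -> Optional[float]:
    """Tube-lens-to-sensor distance imaging the sample, or None.

    The objective forms an intermediate image at v1 = (1/f_o - 1/d_sample)^-1
    from itself.  With L = d_total - d_sample shared between d_interlens and
    d_cam, the tube lens sees an object at u2 = d_interlens - v1 and must
    image it onto the sensor: 1/u2 + 1/d_cam = 1/f_t.  Substituting
    d_interlens = L - d_cam gives d_cam^2 - S d_cam + f_t S = 0 with
    S = L - v1; both real roots are checked for feasibility and the one
    nearest f_t returned (the aligned neighbourhood).
    """
    L = d_total - d_sample
    if math.isclose(d_sample, f_o, rel_tol=0, abs_tol=1e-15):
        # collimated infinity space: tube lens focuses at its focal length
        return f_t if margin <= f_t <= L - margin else None
    v1 = thin_lens_image(d_sample, f_o)
    S = L - v1
    disc = S * S - 4.0 * f_t * S
    if disc < 0.0:
        return None
    root = math.sqrt(disc)
    feasible = [
        dc
        for dc in ((S + root) / 2.0, (S - root) / 2.0)
        if margin <= dc <= L - margin
    ]
    if not feasible:
        return None
    return min(feasible, key=lambda dc: abs(dc - f_t))


def conjugate_magnification(
    d_total: float, f_o: float, f_t: float, d_sample: float, d_cam: float
) -> float:
    """Signed product of the two conjugate magnifications, m1 * m2 = (v1/u1)(v2/u2)."""
    if math.isclose(d_sample, f_o, rel_tol=0, abs_tol=1e-15):
        return -f_t / f_o
    v1 = thin_lens_image(d_sample, f_o)
    m1 = -v1 / d_sample
    u2 = (d_total - d_sample - d_cam) - v1
    m2 = -d_cam / u2
    return m1 * m2
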