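"""Planar triangle embedding of three loci from their pairwise median distances.

Three chromatic-corrected median distances determine a triangle up to rigid
motion and reflection; the canonical pose puts locus A at the origin, B on
the positive x-axis, and C in the upper half-plane, so identical inputs
always yield identical coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_REL_TOL = 1e-9


@dataclass
class TriangleLayout:
    """Canonical planar embedding of a locus trio.

    ``feasible`` is False when the input distances violate the triangle
    inequality (possible after floor-corrected medians); the coordinates are
    then the nearest collinear configuration, and the recovered pairwise
    distances do not reproduce the inputs.
    """

    labels: tuple[str, str, str]
    coords: np.ndarray  # (3, 2) points in nm: rows A, B, C
    input_distances: tuple[float, float, float]  # (d_ab, d_bc, d_ac)
    feasible: bool

    def recovered_distances(self) -> tuple[float, float, float]:
        a, b, c = self.coords
        return (float(np.linalg.norm(a - b)), float(np.linalg.norm(b - c)),
                float(np.linalg.norm(a - c)))


def embed_triangle(d_ab: float, d_bc: float, d_ac: float,
                   labels: tuple[str, str, str] = ("A", "B", "C")) -> TriangleLayout:
    """Embed three loci in the plane from their pairwise distances (nm).

    A = (0, 0), B = (d_ab, 0); C is the upper intersection of the circles of
    radius d_ac around A and d_bc around B. When the triangle inequality
    fails, C is projected onto the x-axis (the nearest degenerate collinear
    layout) and ``feasible`` is set False rather than silently adjusting the
    inputs.
    """
    for name, d in (("d_ab", d_ab), ("d_bc", d_bc), ("d_ac", d_ac)):
        if not math.isfinite(d) or d < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {d}")
    a = np.array([0.0, 0.0])
    b = np.array([float(d_ab), 0.0])
    if d_ab == 0.0:
        # A and B coincide: C sits on the x-axis at the mean of its two radii
        feasible = math.isclose(d_ac, d_bc, rel_tol=_REL_TOL, abs_tol=0.0) \
            or (d_ac == d_bc)
        c = np.array([(d_ac + d_bc) / 2.0, 0.0])
    else:
        x = (d_ab ** 2 + d_ac ** 2 - d_bc ** 2) / (2.0 * d_ab)
        y_sq = d_ac ** 2 - x ** 2
        scale = max(d_ab, d_bc, d_ac) ** 2
        if y_sq >= -_REL_TOL * scale:
            feasible = True
            c = np.array([x, math.sqrt(max(y_sq, 0.0))])
        else:
            feasible = False
            c = np.array([min(max(x, -d_ac), d_ab + d_bc), 0.0])
    return TriangleLayout(labels=labels, coords=np.vstack([a, b, c]),
                          input_distances=(float(d_ab), float(d_bc), float(d_ac)),
                          feasible=feasible)
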