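"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from its definition (quadrature of
the diffuse differential line element, all-vertices-vs-all-planes convexity)
without touching the closed-form code paths they check.
"""

import numpy as np
from scipy.integrate import simpson


def line_source_quadrature(power, length, center, axis, point, normal,
                           nodes=10001):
    """Fluence rate and irradiance of a diffuse line source by quadrature.

    A slice dl at axial coordinate l emits intensity (P/(pi^2 L)) cos(gamma) dl,
    gamma measured from the plane perpendicular to the axis; only the part of
    the lamp above the point's tangent plane contributes.  Composite Simpson
    over the clipped interval.
    """
    center = np.asarray(center, float)
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    point = np.asarray(point, float)
    normal = np.asarray(normal, float)

    g0 = float(np.dot(normal, center - point))
    g1 = float(np.dot(normal, axis))
    lo, hi = -length / 2.0, length / 2.0
    if g1 > 0:
        lo = max(lo, -g0 / g1)
    elif g1 < 0:
        hi = min(hi, -g0 / g1)
    elif g0 < 0:
        return 0.0, 0.0
    if hi <= lo:
        return 0.0, 0.0

    l = np.linspace(lo, hi, nodes)
    pos = center[None, :] + l[:, None] * axis[None, :]
    rel = pos - point                                   # element -> ... point -> element
    rho = np.linalg.norm(rel, axis=1)
    perp = (point - center) - np.dot(point - center, axis) * axis
    d = np.linalg.norm(perp)
    base = power / (np.pi**2 * length) * (d / rho) / rho**2   # cos(gamma) = d/rho
    fluence_rate = float(simpson(base, x=l))
    cos_inc = np.einsum("ij,j->i", rel, normal) / rho
    irradiance = float(simpson(base * np.maximum(cos_inc, 0.0), x=l))
    return fluence_rate, irradiance


def convexity_brute_force(mesh, tol):
    """All-vertices-vs-all-planes convexity check (loops, no vectorization)."""
    violating = []
    for fi in range(mesh.n_facets):
        if mesh.degenerate[fi]:
            continue
        n = mesh.facet_normals[fi]
        v0 = mesh.vertices[mesh.facets[fi, 0]]
        for vertex in mesh.vertices:
            if np.dot(n, vertex - v0) > tol:
                violating.append(fi)
                break
    return len(violating) == 0, violating


def random_line_config(rng, min_axis_distance=0.05):
    """A seeded random off-axis line-source/point/normal configuration."""
    while True:
        center = rng.normal(size=3)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        length = rng.uniform(0.05, 0.6)
        power = rng.uniform(0.5, 10.0)
        point = rng.normal(size=3) * 0.5
        perp = (point - center) - np.dot(point - center, axis) * axis
        if np.linalg.norm(perp) < min_axis_distance:
            continue
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        return power, length, center, axis, point, normal
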