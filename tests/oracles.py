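"""Independent analytic oracles shared by the forward-model tests."""

import numpy as np


def homogeneous_sphere_potential(dipole, elec, radius, sigma):
    """Closed-form scalp potential of a dipole in a homogeneous sphere.

    Derived independently of the package's per-degree linear solve by
    summing the spherical-harmonic series in closed form (generating-
    function identities):

        V = (1/4 pi sigma) [ 2 q.(r-b)/d^3
            + (1/R) (q.r_hat + q.(r-b)/d) / (R - b.r_hat + d) ]
    """
    b = dipole.position
    q = dipole.orientation
    out = np.empty(len(elec))
    for i, r in enumerate(elec):
        d_vec = r - b
        d = np.linalg.norm(d_vec)
        r_hat = r / np.linalg.norm(r)
        term1 = 2.0 * (q @ d_vec) / d**3
        term2 = (q @ r_hat + (q @ d_vec) / d) / (radius - b @ r_hat + d) / radius
        out[i] = (term1 + term2) / (4.0 * np.pi * sigma)
    return out


def fibonacci_sphere(n):
    """Quasi-uniform unit-sphere grid (golden-angle spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.column_stack([
        np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)])
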