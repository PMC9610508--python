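"""Independent reference implementations used as oracles in tests.

These are deliberately written with plain loops / generic quadrature so
they share no code path with the package implementations they check.
"""

import numpy as np
from scipy.integrate import quad


def quadrature_potential(seg, point: np.ndarray) -> np.ndarray:
    """Straight-segment vector potential by adaptive quadrature of
    integral dl / |r - r'| along the wire."""
    a = np.array(seg.start_cm, dtype=float)
    b = np.array(seg.end_cm, dtype=float)
    length = np.linalg.norm(b - a)
    u = (b - a) / length

    def integrand(t):
        return 1.0 / np.linalg.norm(point - (a + t * u))

    val, _ = quad(integrand, 0.0, length, epsabs=1e-13, epsrel=1e-13)
    return seg.current_sign * val * u


def dense_reference_solution(sigma: np.ndarray, A: np.ndarray, params):
    """Dense Kirchhoff system built by explicit loops.

    Edge conductance = harmonic mean * h (face area h^2 / distance h); edge
    EMF = omega * mean-of-endpoint A component * h (trapezoid rule).  One
    node per conducting voxel; one node per connected component pinned by a
    unit diagonal entry (the source vector is compatible, so this leaves
    the solution unchanged and selects psi = 0 at the reference).
    """
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    shape = sigma.shape
    h = 1.0
    omega = params.omega
    nodes = {}
    for idx in np.ndindex(shape):
        if sigma[idx] > 0:
            nodes[idx] = len(nodes)
    n = len(nodes)
    L = np.zeros((n, n))
    f = np.zeros(n)
    for (i, j, k), a in nodes.items():
        for ax, nb in enumerate([(i + 1, j, k), (i, j + 1, k), (i, j, k + 1)]):
            if nb in nodes:
                b = nodes[nb]
                sa, sb = sigma[i, j, k], sigma[nb]
                g = 2 * sa * sb / (sa + sb) * h
                L[a, a] += g
                L[b, b] += g
                L[a, b] -= g
                L[b, a] -= g
                emf = omega * 0.5 * (A[i, j, k, ax] + A[nb][ax]) * h
                # current a->b is g * (psi_a - psi_b + emf)
                f[a] -= g * emf
                f[b] += g * emf
    adj = sp.csr_matrix(L != 0)
    ncomp, labels = connected_components(adj, directed=False)
    for c in range(ncomp):
        r = int(np.argmax(labels == c))
        L[r, r] += 1.0
    psi = np.linalg.solve(L, f)
    full = np.zeros(shape)
    for idx, a in nodes.items():
        full[idx] = psi[a]
    return full
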