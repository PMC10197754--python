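"""Array-level polygon geometry and analytic gradients.

All functions take a cycle of positions ``P`` with shape ``(n, 3)`` (planar
meshes are embedded with z = 0) and return values or gradients with respect
to the cycle positions.  The triangulation is the centroid fan: triangle k is
(P_k, P_{k+1}, C) with C the vertex mean, so the centroid depends on every
cycle vertex and all gradients carry the corresponding chain-rule terms.

Derivations (used throughout, verified against central finite differences in
the test suite):

* area A = 1/2 sum_k ||eta_k||, eta_k = (P_k - C) x (P_{k+1} - C)
  dA/dP_j = 1/2 [ u_j + w_{j-1} - mean_k(u_k + w_k) ]
  with u_k = b_k x eta_hat_k, w_k = eta_hat_k x a_k, a = P - C, b = roll(a).
* surface volume contribution V_S = 1/6 sum_k C . (P_k x P_{k+1})
  dV/dP_j = 1/6 [ mean_k(P_k x P_{k+1}) + P_{j+1} x C + C x P_{j-1} ].
* perimeter L = sum ||P_{k+1} - P_k||; dL/dP_j = e_hat_{j-1} - e_hat_j.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "triangle_normals", "triangle_areas", "polygon_area", "polygon_area_grad",
    "polygon_perimeter", "polygon_perimeter_grad", "surface_volume",
    "surface_volume_grad", "vertex_area_contribs", "polygon_normal",
    "best_fit_plane",
]


def triangle_normals(P: np.ndarray) -> np.ndarray:
    C = P.mean(axis=0)
    a = P - C
    return np.cross(a, np.roll(a, -1, axis=0))


def triangle_areas(P: np.ndarray) -> np.ndarray:
    return 0.5 * np.linalg.norm(triangle_normals(P), axis=1)


def polygon_area(P: np.ndarray) -> float:
    return float(triangle_areas(P).sum())


def polygon_normal(P: np.ndarray) -> np.ndarray:
    """Unit normal (zero vector when degenerate)."""
    total = triangle_normals(P).sum(axis=0)
    n = np.linalg.norm(total)
    return total / n if n > 1e-300 else np.zeros(3)


def polygon_area_grad(P: np.ndarray) -> np.ndarray:
    C = P.mean(axis=0)
    a = P - C
    b = np.roll(a, -1, axis=0)
    eta = np.cross(a, b)
    norms = np.linalg.norm(eta, axis=1)
    hat = np.zeros_like(eta)
    ok = norms > 1e-300
    hat[ok] = eta[ok] / norms[ok, None]
    u = np.cross(b, hat)
    w = np.cross(hat, a)
    return 0.5 * (u + np.roll(w, 1, axis=0) - (u + w).mean(axis=0))


def polygon_perimeter(P: np.ndarray) -> float:
    return float(np.linalg.norm(np.roll(P, -1, axis=0) - P, axis=1).sum())


def polygon_perimeter_grad(P: np.ndarray) -> np.ndarray:
    e = np.roll(P, -1, axis=0) - P
    L = np.linalg.norm(e, axis=1)
    ehat = np.zeros_like(e)
    ok = L > 1e-300
    ehat[ok] = e[ok] / L[ok, None]
    return np.roll(ehat, 1, axis=0) - ehat


def surface_volume(P: np.ndarray) -> float:
    """Signed divergence-theorem volume contribution of one surface."""
    C = P.mean(axis=0)
    return float(C @ np.cross(P, np.roll(P, -1, axis=0)).sum(axis=0)) / 6.0


def surface_volume_grad(P: np.ndarray) -> np.ndarray:
    C = P.mean(axis=0)
    cr = np.cross(P, np.roll(P, -1, axis=0))
    term = cr.mean(axis=0)
    nxt = np.roll(P, -1, axis=0)
    prv = np.roll(P, 1, axis=0)
    return (term + np.cross(nxt, C) + np.cross(C, prv)) / 6.0


def vertex_area_contribs(P: np.ndarray) -> np.ndarray:
    """A_{V,S} per cycle vertex: half the area of its two adjacent triangles."""
    t = triangle_areas(P)
    return 0.5 * (t + np.roll(t, 1))


def best_fit_plane(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane of a cycle: (point on plane, unit normal).

    The optimal plane passes through the centroid with normal along the
    eigenvector of the smallest eigenvalue of the position covariance.
    """
    C = P.mean(axis=0)
    X = P - C
    _, vecs = np.linalg.eigh(X.T @ X)
    return C, vecs[:, 0]
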