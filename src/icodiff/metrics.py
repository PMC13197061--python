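"""Map- and distribution-level comparison metrics.

``ssim_sphere`` transfers SSIM to the icosphere by using each vertex's 1-ring
patch (self + ring neighbors) as the local window — the canonical local
neighborhood on the mesh.  ``frechet_distance`` is the Gaussian Fréchet
distance between two embedded sample sets; combined with any embedding
function (default: per-ROI mean vectors) it plays the role FID plays for
generated-image evaluation.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .geometry import IcoSphere

__all__ = ["mse", "ssim_sphere", "frechet_distance"]


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean over vertices of the squared difference."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("maps must share a shape")
    return float(np.mean((a - b) ** 2))


def _patch_moments(x: np.ndarray, ico: IcoSphere):
    idx = ico.gather_indices()
    pad_self = ico.neighbors == np.arange(ico.n_vertices)[:, None]
    sizes = (1.0 + ico.valence).astype(np.float64)

    def pm(v):
        taps = v[idx]
        taps[:, 1:][pad_self] = 0.0
        return taps.sum(axis=1) / sizes

    mu = pm(x)
    ex2 = pm(x * x)
    return mu, ex2 - mu**2


def ssim_sphere(
    a: np.ndarray,
    b: np.ndarray,
    ico: IcoSphere,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float | None = None,
) -> float:
    """Structural similarity between two per-vertex maps.

    Local means, variances and covariance are computed over each vertex's
    1-ring patch (7 members, 6 at the pentagons); the per-vertex SSIM values
    are averaged over the sphere.  ``data_range`` defaults to the joint
    value range of the two maps.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.shape[0] != ico.n_vertices:
        raise ValueError("maps must share the sphere's vertex count")
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = hi - lo if hi > lo else 1.0
    if data_range <= 0:
        raise ValueError("data_range must be positive")

    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_a, var_a = _patch_moments(a, ico)
    mu_b, var_b = _patch_moments(b, ico)
    mu_ab, _ = _patch_moments(a * b, ico)
    cov = mu_ab - mu_a * mu_b

    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    return float(np.mean(num / den))


def frechet_distance(X: np.ndarray, Y: np.ndarray, eps: float = 1e-10) -> float:
    """Gaussian Fréchet distance between two embedded sample sets.

    ``||mu_X - mu_Y||^2 + tr(S_X + S_Y - 2 (S_X S_Y)^{1/2})`` with the
    symmetric matrix square root; near-singular covariances receive small
    diagonal loading.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("embedding dimensions differ")
    if X.shape[0] < 2 or Y.shape[0] < 2:
        raise ValueError("each set needs at least 2 points")

    mu_x, mu_y = X.mean(axis=0), Y.mean(axis=0)
    sx = np.atleast_2d(np.cov(X, rowvar=False))
    sy = np.atleast_2d(np.cov(Y, rowvar=False))

    def _sqrtm(mat):
        out = linalg.sqrtm(mat)
        if isinstance(out, tuple):  # older scipy returns (root, error estimate)
            out = out[0]
        return out

    covmean = _sqrtm(sx @ sy)
    if not np.isfinite(covmean).all():
        d = sx.shape[0]
        covmean = _sqrtm((sx + eps * np.eye(d)) @ (sy + eps * np.eye(d)))
    covmean = np.real(covmean)
    dist = float(np.sum((mu_x - mu_y) ** 2) + np.trace(sx + sy - 2.0 * covmean))
    return max(dist, 0.0) if abs(dist) < 1e-8 else dist
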