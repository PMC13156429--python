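"""Local principal-component denoising for multi-b-value series.

The decay curves inside a small spatial patch span a low-dimensional
subspace (signal level, perfusion fraction and diffusivities vary smoothly,
and a patch straddling a tissue boundary adds at most one more curve
family), while thermal noise is full-rank. Projecting each voxel's curve
onto the leading principal components of its patch therefore suppresses
noise without mixing voxel means across edges — unlike Gaussian smoothing,
which blurs partial-volume mixtures into thin structures.

This is a deliberately simple fixed-rank variant of the PCA family of DWI
denoisers; it is exposed as a pre-fit hook, and the fit itself never
depends on it.
"""

from __future__ import annotations

import numpy as np


def denoise_local_pca(
    series: np.ndarray,
    patch_radius: int = 1,
    rank: int = 4,
) -> np.ndarray:
    """Denoise a 4-D (x, y, z, b) series by patch-wise PCA rank truncation.

    For every voxel, the decay curves of its ``(2r+1)³`` neighbourhood are
    centered, the top ``rank`` principal components are kept, and the
    center voxel's curve is replaced by its projection. Edges of the volume
    use shrunken patches.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4:
        raise ValueError("series must be 4-D (x, y, z, b)")
    n_b = series.shape[3]
    if rank >= n_b:
        return series.copy()
    out = np.empty_like(series)
    nx, ny, nz = series.shape[:3]
    r = patch_radius
    for i in range(nx):
        i0, i1 = max(0, i - r), min(nx, i + r + 1)
        for j in range(ny):
            j0, j1 = max(0, j - r), min(ny, j + r + 1)
            for k in range(nz):
                k0, k1 = max(0, k - r), min(nz, k + r + 1)
                patch = series[i0:i1, j0:j1, k0:k1, :].reshape(-1, n_b)
                mean = patch.mean(axis=0)
                centered = patch - mean
                # principal axes from the small (n_b x n_b) scatter matrix
                cov = centered.T @ centered
                w, v = np.linalg.eigh(cov)
                basis = v[:, -rank:]
                curve = series[i, j, k, :] - mean
                out[i, j, k, :] = mean + basis @ (basis.T @ curve)
    return out
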