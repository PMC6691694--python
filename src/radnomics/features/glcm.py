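"""Gray-level co-occurrence matrix and the 22 Haralick-style texture features.

The GLCM is accumulated at distance 1 over the 13 unique 3D directions,
symmetrically (each voxel pair counted in both orders), summed over
directions and normalized to a joint probability matrix p(i, j) on 1-based
gray levels i, j = 1..n_bins.  Background voxels (level 0) never pair.

Feature definitions follow the standard Haralick conventions with
logarithms in base 2.  Degenerate guards: correlation of a zero-variance
matrix is 1 (a constant ROI is perfectly correlated with itself); IMC1/IMC2
are 0 when the marginal entropies vanish.
"""

from __future__ import annotations

import itertools

import numpy as np

GLCM_NAMES = [
    "GLCM_autocorrelation",
    "GLCM_cluster_prominence",
    "GLCM_cluster_shade",
    "GLCM_cluster_tendency",
    "GLCM_contrast",
    "GLCM_correlation",
    "GLCM_difference_entropy",
    "GLCM_difference_variance",
    "GLCM_dissimilarity",
    "GLCM_energy",
    "GLCM_entropy",
    "GLCM_homogeneity1",
    "GLCM_homogeneity2",
    "GLCM_IMC1",
    "GLCM_IMC2",
    "GLCM_IDMN",
    "GLCM_IDN",
    "GLCM_inverse_variance",
    "GLCM_maximum_probability",
    "GLCM_sum_average",
    "GLCM_sum_entropy",
    "GLCM_sum_variance",
]


def _unique_directions() -> list[tuple[int, int, int]]:
    """The 13 unique distance-1 3D directions (one per +/- pair)."""
    dirs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        if d > (0, 0, 0):  # lexicographic half-space picks one of each +/- pair
            dirs.append(d)
    assert len(dirs) == 13
    return dirs


DIRECTIONS_3D = _unique_directions()


def _shifted_views(arr: np.ndarray, d) -> tuple[np.ndarray, np.ndarray]:
    """Views a, b with b the neighbour of a at offset d (in-bounds pairs only)."""
    sl_a, sl_b = [], []
    for size, off in zip(arr.shape, d):
        if off == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif off > 0:
            sl_a.append(slice(0, size - off))
            sl_b.append(slice(off, size))
        else:
            sl_a.append(slice(-off, size))
            sl_b.append(slice(0, size + off))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


def glcm_matrix(quantized: np.ndarray, n_bins: int = 32) -> np.ndarray:
    """Build the direction-summed symmetric normalized GLCM.

    ``quantized`` holds integer levels 1..n_bins inside the ROI and 0
    outside.  Returns an (n_bins, n_bins) matrix summing to 1 (or a zero
    matrix if the ROI has no valid voxel pair in any direction).
    """
    q = np.asarray(quantized)
    counts = np.zeros((n_bins + 1) * (n_bins + 1), dtype=np.int64)
    for d in DIRECTIONS_3D:
        a, b = _shifted_views(q, d)
        valid = (a > 0) & (b > 0)
        if valid.any():
            pairs = a[valid].astype(np.int64) * (n_bins + 1) + b[valid]
            counts += np.bincount(pairs, minlength=counts.size)
    mat = counts.reshape(n_bins + 1, n_bins + 1)[1:, 1:].astype(np.float64)
    mat = mat + mat.T  # symmetric accumulation
    total = mat.sum()
    if total > 0:
        mat /= total
    return mat


def glcm_features(p: np.ndarray, check: bool = True) -> dict:
    """Compute the 22 GLCM features of a normalized symmetric matrix."""
    p = np.asarray(p, dtype=np.float64)
    n = p.shape[0]
    if check:
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"GLCM not normalized (sum={p.sum():.6g})")
        if not np.allclose(p, p.T, atol=1e-12):
            raise ValueError("GLCM not symmetric")

    i = np.arange(1, n + 1, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sig_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sig_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    # p_{x+y}(k), k = 2..2n and p_{x-y}(k), k = 0..n-1
    k_sum = np.arange(2, 2 * n + 1, dtype=np.float64)
    p_sum = np.zeros(2 * n - 1)
    k_diff = np.arange(0, n, dtype=np.float64)
    p_diff = np.zeros(n)
    np.add.at(p_sum, (I + J).astype(int).ravel() - 2, p.ravel())
    np.add.at(p_diff, np.abs(I - J).astype(int).ravel(), p.ravel())

    def _ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    entropy = _ent(p.ravel())
    hx = _ent(px)
    hy = _ent(py)
    pxpy = np.outer(px, py)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    hxy2 = _ent(pxpy.ravel())

    imc1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    contrast = float((((I - J) ** 2) * p).sum())
    dissimilarity = float((np.abs(I - J) * p).sum())
    diff_avg = float((k_diff * p_diff).sum())
    sum_avg = float((k_sum * p_sum).sum())

    offdiag = I != J
    inv_var = float((p[offdiag] / (I[offdiag] - J[offdiag]) ** 2).sum())

    if sig_x * sig_y > 0:
        correlation = float(((I * J * p).sum() - mu_x * mu_y) / (sig_x * sig_y))
    else:
        correlation = 1.0

    return {
        "GLCM_autocorrelation": float((I * J * p).sum()),
        "GLCM_cluster_prominence": float((((I + J - mu_x - mu_y) ** 4) * p).sum()),
        "GLCM_cluster_shade": float((((I + J - mu_x - mu_y) ** 3) * p).sum()),
        "GLCM_cluster_tendency": float((((I + J - mu_x - mu_y) ** 2) * p).sum()),
        "GLCM_contrast": contrast,
        "GLCM_correlation": correlation,
        "GLCM_difference_entropy": _ent(p_diff),
        "GLCM_difference_variance": float((((k_diff - diff_avg) ** 2) * p_diff).sum()),
        "GLCM_dissimilarity": dissimilarity,
        "GLCM_energy": float((p**2).sum()),
        "GLCM_entropy": entropy,
        "GLCM_homogeneity1": float((p / (1.0 + np.abs(I - J))).sum()),
        "GLCM_homogeneity2": float((p / (1.0 + (I - J) ** 2)).sum()),
        "GLCM_IMC1": float(imc1),
        "GLCM_IMC2": imc2,
        "GLCM_IDMN": float((p / (1.0 + (I - J) ** 2 / n**2)).sum()),
        "GLCM_IDN": float((p / (1.0 + np.abs(I - J) / n)).sum()),
        "GLCM_inverse_variance": inv_var,
        "GLCM_maximum_probability": float(p.max()),
        "GLCM_sum_average": sum_avg,
        "GLCM_sum_entropy": _ent(p_sum),
        "GLCM_sum_variance": float((((k_sum - sum_avg) ** 2) * p_sum).sum()),
    }
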