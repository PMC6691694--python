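"""Gray-level run-length matrices and the 11 run-emphasis features.

A run is a maximal set of collinear ROI voxels of equal quantized gray
level along one of the 13 unique 3D directions; background (level 0)
breaks runs.  One run-length matrix r(i, l) is built per direction; the 11
features are computed per direction and averaged over the 13 directions.

For every direction, sum_i sum_l l * r(i, l) equals the number of ROI
voxels (each voxel belongs to exactly one run per direction).
"""

from __future__ import annotations

import numpy as np

from radnomics.features.glcm import DIRECTIONS_3D

GLRLM_NAMES = [
    "GLRLM_SRE",
    "GLRLM_LRE",
    "GLRLM_GLN",
    "GLRLM_RLN",
    "GLRLM_RP",
    "GLRLM_LGLRE",
    "GLRLM_HGLRE",
    "GLRLM_SRLGLE",
    "GLRLM_SRHGLE",
    "GLRLM_LRLGLE",
    "GLRLM_LRHGLE",
]


def _shift_full(arr: np.ndarray, d, fill) -> np.ndarray:
    """out[x] = arr[x + d] where in bounds, else fill."""
    out = np.full_like(arr, fill)
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
    out[tuple(sl_a)] = arr[tuple(sl_b)]
    return out


def _runs_one_direction(q: np.ndarray, d, n_bins: int) -> np.ndarray:
    """Run-length matrix r(i, l) for one direction; shape (n_bins, max_len)."""
    roi = q > 0
    qn = _shift_full(q, d, 0)
    same_next = roi & (qn > 0) & (q == qn)

    # forward run length C[x]: voxels from x (inclusive) to the run's end.
    # Process planes along the leading nonzero axis of d from far to near so
    # C[x + d] is available when C[x] is formed.
    axis = next(k for k in range(3) if d[k] != 0)
    step = d[axis]  # +1 by construction of the canonical direction set
    other = tuple(off for k, off in enumerate(d) if k != axis)
    C = np.zeros(q.shape, dtype=np.int32)
    n_planes = q.shape[axis]
    order = range(n_planes - 1, -1, -1) if step > 0 else range(n_planes)
    prev_idx = None
    for i in order:
        plane = [slice(None)] * 3
        plane[axis] = i
        plane = tuple(plane)
        c_here = roi[plane].astype(np.int32)
        if prev_idx is not None:
            c_next = _shift_full(C[prev_idx], other, 0)
            c_here = c_here + np.where(same_next[plane], c_next, 0)
        C[plane] = c_here
        prev_idx = plane

    # a voxel starts a run iff its predecessor (x - d) does not share its level
    neg_d = tuple(-off for off in d)
    same_prev = _shift_full(same_next, neg_d, False)
    starts = roi & ~same_prev

    levels = q[starts].astype(np.int64)
    lengths = C[starts].astype(np.int64)
    max_len = int(lengths.max()) if lengths.size else 1
    mat = np.zeros((n_bins, max_len), dtype=np.float64)
    np.add.at(mat, (levels - 1, lengths - 1), 1.0)
    return mat


def glrlm_matrices(quantized: np.ndarray, n_bins: int = 32) -> list[np.ndarray]:
    """Run-length matrices for all 13 directions."""
    q = np.asarray(quantized)
    return [_runs_one_direction(q, d, n_bins) for d in DIRECTIONS_3D]


def glrlm_features_single(r: np.ndarray) -> dict:
    """The 11 features of one run-length matrix r(i, l), 1-based i and l."""
    r = np.asarray(r, dtype=np.float64)
    n_runs = r.sum()
    if n_runs == 0:
        raise ValueError("empty run-length matrix")
    n_levels, max_len = r.shape
    i = np.arange(1, n_levels + 1, dtype=np.float64)[:, None]
    l = np.arange(1, max_len + 1, dtype=np.float64)[None, :]
    n_vox = (r * l).sum()
    return {
        "GLRLM_SRE": float((r / l**2).sum() / n_runs),
        "GLRLM_LRE": float((r * l**2).sum() / n_runs),
        "GLRLM_GLN": float((r.sum(axis=1) ** 2).sum() / n_runs),
        "GLRLM_RLN": float((r.sum(axis=0) ** 2).sum() / n_runs),
        "GLRLM_RP": float(n_runs / n_vox),
        "GLRLM_LGLRE": float((r / i**2).sum() / n_runs),
        "GLRLM_HGLRE": float((r * i**2).sum() / n_runs),
        "GLRLM_SRLGLE": float((r / (i**2 * l**2)).sum() / n_runs),
        "GLRLM_SRHGLE": float((r * i**2 / l**2).sum() / n_runs),
        "GLRLM_LRLGLE": float((r * l**2 / i**2).sum() / n_runs),
        "GLRLM_LRHGLE": float((r * i**2 * l**2).sum() / n_runs),
    }


def glrlm_features(matrices: list[np.ndarray]) -> dict:
    """Direction-averaged GLRLM features."""
    if not matrices:
        raise ValueError("no run-length matrices given")
    acc = {name: 0.0 for name in GLRLM_NAMES}
    for r in matrices:
        f = glrlm_features_single(r)
        for name in GLRLM_NAMES:
            acc[name] += f[name]
    return {name: v / len(matrices) for name, v in acc.items()}
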