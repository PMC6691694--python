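"""Shape and size features of the binary tumor mask.

Volume is voxel count times voxel volume.  Surface area counts exposed voxel
faces (a face is exposed when its neighbour across that face is background
or outside the grid), each weighted by its physical face area — an exact,
integer-based definition on the digital mask.  Derived descriptors follow
the standard conventions:

    sphericity             pi^(1/3) (6V)^(2/3) / A
    compactness1           V / (sqrt(pi) A^(3/2))
    compactness2           36 pi V^2 / A^3
    spherical disproportion  A / (4 pi R^2),  R = (3V / 4pi)^(1/3)

Maximum 3D diameter is the largest pairwise distance between centres of
surface voxels (in mm).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist

SHAPE_NAMES = [
    "Volume",
    "Surface_area",
    "Surface_to_volume_ratio",
    "Sphericity",
    "Compactness1",
    "Compactness2",
    "Maximum_3D_diameter",
    "Spherical_disproportion",
]


def _exposed_face_area(mask: np.ndarray, spacing) -> tuple[float, np.ndarray]:
    """Total exposed-face area (mm^2) and the boolean surface-voxel mask."""
    sx, sy, sz = spacing
    face_area = {0: sy * sz, 1: sx * sz, 2: sx * sy}
    padded = np.pad(mask, 1, mode="constant")
    total = 0.0
    surface = np.zeros_like(mask, dtype=bool)
    core = (slice(1, -1),) * 3
    for axis in range(3):
        for step in (1, -1):
            neigh = np.roll(padded, step, axis=axis)[core]
            exposed = mask & ~neigh
            total += face_area[axis] * exposed.sum()
            surface |= exposed
    return float(total), surface


def shape_features(mask: np.ndarray, spacing) -> dict:
    """Compute the 8 shape features of a binary mask with given spacing (mm)."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("shape features require a nonempty mask")
    spacing = tuple(float(s) for s in spacing)
    voxel_volume = spacing[0] * spacing[1] * spacing[2]
    volume = n * voxel_volume
    area, surface = _exposed_face_area(mask, spacing)

    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area
    compactness1 = volume / (np.sqrt(np.pi) * area**1.5)
    compactness2 = 36.0 * np.pi * volume**2 / area**3
    r_equiv = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    spherical_disproportion = area / (4.0 * np.pi * r_equiv**2)

    coords = np.argwhere(surface) * np.asarray(spacing)
    if len(coords) > 1:
        if len(coords) > 2000:
            # the diameter is attained on the convex hull; prune first
            from scipy.spatial import ConvexHull

            try:
                coords = coords[ConvexHull(coords).vertices]
            except Exception:  # degenerate (planar) point sets
                pass
        max_diam = float(pdist(coords).max())
    else:
        max_diam = float(max(spacing))
    return {
        "Volume": float(volume),
        "Surface_area": float(area),
        "Surface_to_volume_ratio": float(area / volume),
        "Sphericity": float(sphericity),
        "Compactness1": float(compactness1),
        "Compactness2": float(compactness2),
        "Maximum_3D_diameter": max_diam,
        "Spherical_disproportion": float(spherical_disproportion),
    }
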