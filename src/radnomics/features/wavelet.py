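"""Single-level undecimated 3D wavelet decomposition (Coiflet-1).

The stationary (undecimated) transform keeps every subband on the original
voxel grid, so the tumor mask applies to each subband unchanged.  The 8
subbands are indexed 1..8 by the low/high (L/H) filter choice per axis in
axis order:

    1 = LLL, 2 = LLH, 3 = LHL, 4 = LHH, 5 = HLL, 6 = HLH, 7 = HHL, 8 = HHH

Odd-sized axes are symmetrically padded to even length for the transform
and the subbands are cropped back.
"""

from __future__ import annotations

import numpy as np
import pywt

WAVELET = "coif1"

# subband index -> pywt swtn key ('a' = approximation/low, 'd' = detail/high)
SUBBAND_INDEX = {
    1: "aaa",
    2: "aad",
    3: "ada",
    4: "add",
    5: "daa",
    6: "dad",
    7: "dda",
    8: "ddd",
}


def wavelet_subbands(volume: np.ndarray) -> dict[int, np.ndarray]:
    """Decompose a 3D volume into its 8 undecimated subbands.

    Raises
    ------
    ValueError
        If any axis is shorter than 8 voxels.
    """
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError("expected a 3D volume")
    if any(s < 8 for s in vol.shape):
        raise ValueError(f"volume too small for wavelet decomposition: {vol.shape}")
    pad = [(0, s % 2) for s in vol.shape]
    padded = np.pad(vol, pad, mode="symmetric") if any(p[1] for p in pad) else vol
    coeffs = pywt.swtn(padded, WAVELET, level=1, norm=True)[0]
    crop = tuple(slice(0, s) for s in vol.shape)
    return {idx: coeffs[key][crop] for idx, key in SUBBAND_INDEX.items()}
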