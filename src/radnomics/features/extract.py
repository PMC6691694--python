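"""Per-patient and per-cohort radiomic feature extraction.

For each modality: 8 shape features on the original mask, then the 53
intensity features (first-order, GLCM, GLRLM) on the original image and on
each of the 8 undecimated wavelet subbands.  Texture matrices use 32
equal-width gray-level bins on the native anisotropic grid, distance 1,
all 13 3D directions.
"""

from __future__ import annotations

import pandas as pd

from radnomics.features.firstorder import first_order_features
from radnomics.features.glcm import glcm_features, glcm_matrix
from radnomics.features.glrlm import glrlm_features, glrlm_matrices
from radnomics.features.inventory import FeatureInventory, MODALITIES
from radnomics.features.shape import shape_features
from radnomics.features.wavelet import wavelet_subbands
from radnomics.io import TumorMask, VolumePair, quantize_roi

N_BINS = 32

_INVENTORY = FeatureInventory()


def _bbox(mask):
    """Slices of the mask's bounding box (texture is unchanged by cropping:
    every voxel pair / run involves only ROI voxels)."""
    sl = []
    for ax in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != ax))
        nz = proj.nonzero()[0]
        sl.append(slice(nz[0], nz[-1] + 1))
    return tuple(sl)


def _intensity_block(volume, mask, n_bins=N_BINS) -> dict:
    vals = volume[mask]
    feats = first_order_features(vals, n_bins=n_bins)
    q = quantize_roi(volume, mask, n_bins=n_bins)
    feats.update(glcm_features(glcm_matrix(q, n_bins), check=False))
    feats.update(glrlm_features(glrlm_matrices(q, n_bins)))
    return feats


def extract_patient(pair: VolumePair, mask: TumorMask, n_bins: int = N_BINS) -> pd.Series:
    """Extract the full 970-value named feature vector for one patient."""
    mask.check_compatible(pair)
    m = mask.voxels
    box = _bbox(m)
    m_crop = m[box]
    values: dict[str, float] = {}
    for mod, volume in (("CET1-w", pair.cet1w), ("T2-w", pair.t2w)):
        for name, v in shape_features(m, pair.spacing).items():
            values[f"{mod}_{name}"] = v
        for name, v in _intensity_block(volume[box], m_crop, n_bins).items():
            values[f"{mod}_{name}"] = v
        for sub, subvol in wavelet_subbands(volume).items():
            for name, v in _intensity_block(subvol[box], m_crop, n_bins).items():
                values[f"{mod}_{sub}_{name}"] = v
    out = pd.Series(values, name=pair.patient_id)
    return out.reindex(_INVENTORY.names)


def extract_cohort(patients, patient_ids=None, n_bins: int = N_BINS) -> pd.DataFrame:
    """Extract features for an iterable of (VolumePair, TumorMask) pairs.

    Returns a patients x 970 DataFrame indexed by patient id.
    """
    rows = []
    for k, (pair, mask) in enumerate(patients):
        s = extract_patient(pair, mask, n_bins=n_bins)
        if patient_ids is not None:
            s.name = patient_ids[k]
        rows.append(s)
    table = pd.DataFrame(rows)
    table.index.name = "patient_id"
    return table
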