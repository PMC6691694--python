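"""The fixed 485-per-modality / 970-total radiomic feature inventory.

Naming convention (matching the published feature labels):

    <MOD>_<Shape_name>                   shape features, original image only
    <MOD>_<class>_<feature>              intensity features, original image
    <MOD>_<subband>_<class>_<feature>    intensity features, wavelet subband 1..8

with ``<MOD>`` in {"CET1-w", "T2-w"} and ``<class>`` in {fos, GLCM, GLRLM},
e.g. ``CET1-w_1_GLCM_cluster_shade`` or ``T2-w_1_GLRLM_LRHGLE``.
"""

from __future__ import annotations

from radnomics.features.firstorder import FIRST_ORDER_NAMES
from radnomics.features.glcm import GLCM_NAMES
from radnomics.features.glrlm import GLRLM_NAMES
from radnomics.features.shape import SHAPE_NAMES

MODALITIES = ("CET1-w", "T2-w")
INTENSITY_NAMES = FIRST_ORDER_NAMES + GLCM_NAMES + GLRLM_NAMES  # 20 + 22 + 11 = 53
N_SUBBANDS = 8
FEATURES_PER_MODALITY = 485
FEATURES_TOTAL = 970


class FeatureInventory:
    """Ordered feature names: 485 per modality, 970 in total.

    Cardinality is asserted at construction; names are unique by build.
    """

    def __init__(self, modalities=MODALITIES):
        self.modalities = tuple(modalities)
        self.per_modality: dict[str, list[str]] = {}
        for mod in self.modalities:
            names = [f"{mod}_{s}" for s in SHAPE_NAMES]
            names += [f"{mod}_{f}" for f in INTENSITY_NAMES]
            for sub in range(1, N_SUBBANDS + 1):
                names += [f"{mod}_{sub}_{f}" for f in INTENSITY_NAMES]
            assert len(names) == FEATURES_PER_MODALITY, len(names)
            assert len(set(names)) == FEATURES_PER_MODALITY
            self.per_modality[mod] = names
        self.names = [n for mod in self.modalities for n in self.per_modality[mod]]
        if len(self.modalities) == 2:
            assert len(self.names) == FEATURES_TOTAL

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def modality_of(self, name: str) -> str:
        for mod in self.modalities:
            if name.startswith(mod + "_"):
                return mod
        raise KeyError(name)
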