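"""The fixed 8-channel default-mode-network ROI montage.

The pipeline operates on eight regional time series whose labels follow the
EEG electrodes overlying the corresponding DMN nodes: medial prefrontal
cortex (FZ/F3/F4), posterior cingulate / precuneus (PZ), lateral parietal
cortex (P3/P4) and the supramarginal gyri (CP5/CP6).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class RoiMontage:
    """Ordered ROI label set with anatomical metadata.

    ``labels`` fixes the channel order used by every array in the package
    (row/column i of a connectivity matrix is ``labels[i]``).
    """

    labels: tuple[str, ...]
    region: dict[str, str] = field(repr=False)
    mni: dict[str, tuple[float, float, float]] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("montage labels must be unique")
        missing = set(self.labels) - set(self.region)
        if missing or set(self.labels) - set(self.mni):
            raise ValueError("region/mni maps must cover every label")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


#: Default DMN montage: 8 ROIs with MNI centroids (mm).
DEFAULT_MONTAGE = RoiMontage(
    labels=("FZ", "F3", "F4", "PZ", "P3", "P4", "CP5", "CP6"),
    region={
        "FZ": "mPFC-central",
        "F3": "mPFC-left",
        "F4": "mPFC-right",
        "PZ": "PCC/precuneus",
        "P3": "LPC-left",
        "P4": "LPC-right",
        "CP5": "supramarginal-left",
        "CP6": "supramarginal-right",
    },
    mni={
        "FZ": (0.6, 40.9, 53.9),
        "F3": (-35.5, 40.9, 32.1),
        "F4": (40.2, 47.6, 32.1),
        "PZ": (0.2, -62.1, 64.5),
        "P3": (-39.5, -76.3, 47.4),
        "P4": (38.8, -74.9, 49.2),
        "CP5": (-62.0, -42.0, 32.0),
        "CP6": (66.0, -34.0, 40.0),
    },
)
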