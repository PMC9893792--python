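"""264-ROI parcellation with resting-state network labels.

The parcellation assigns each of 264 spherical ROI centers (mm coordinates)
to one of ten named resting-state networks or to an ``unassigned`` remainder.
The ten networks of interest and their ROI counts are fixed:

==========================  =====
network                     ROIs
==========================  =====
Somatomotor Hand (Hand)       30
Visual (Vis)                  31
Somatomotor Mouth (Mouth)      5
Auditory (Aud)                13
Default Mode (DMN)            58
Salience (Sal)                18
Cingulo-Opercular (CO)        14
Frontoparietal (FP)           25
Dorsal Attention (DAN)        11
Ventral Attention (VAN)        9
==========================  =====

The remaining 50 ROIs carry the label ``unassigned`` and are excluded from
all network summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_ROIS = 264

#: Named networks of interest, in canonical order, with their ROI counts.
NETWORK_SIZES: dict[str, int] = {
    "Hand": 30,
    "Vis": 31,
    "Mouth": 5,
    "Aud": 13,
    "DMN": 58,
    "Sal": 18,
    "CO": 14,
    "FP": 25,
    "DAN": 11,
    "VAN": 9,
}

UNASSIGNED = "unassigned"

NETWORKS: tuple[str, ...] = tuple(NETWORK_SIZES)

COLUMNS = ("roi_id", "x_mm", "y_mm", "z_mm", "network")


@dataclass(frozen=True)
class Parcellation:
    """ROI table: id, center coordinates in mm, and network label.

    Validated on construction: exactly 264 ROIs, unique ids, and the ten
    named networks present at exactly their canonical counts.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        missing = set(COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
        if len(df) != N_ROIS:
            raise ValueError(f"parcellation must have {N_ROIS} ROIs, got {len(df)}")
        if df["roi_id"].duplicated().any():
            raise ValueError("duplicate roi_id values")
        counts = df["network"].value_counts()
        for net, n in NETWORK_SIZES.items():
            if counts.get(net, 0) != n:
                raise ValueError(
                    f"network {net!r} must have {n} ROIs, got {counts.get(net, 0)}"
                )
        extra = set(counts.index) - set(NETWORK_SIZES) - {UNASSIGNED}
        if extra:
            raise ValueError(f"unknown network labels: {sorted(extra)}")

    @property
    def coords(self) -> np.ndarray:
        """(264, 3) array of ROI center coordinates in mm."""
        return self.table[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.table["network"].to_numpy()

    @property
    def roi_ids(self) -> np.ndarray:
        return self.table["roi_id"].to_numpy()

    def network_indices(self, network: str) -> np.ndarray:
        """Positional indices of the ROIs in one network."""
        return np.flatnonzero(self.labels == network)

    def pairwise_distances(self) -> np.ndarray:
        """(264, 264) Euclidean distances between ROI centers, mm."""
        c = self.coords
        diff = c[:, None, :] - c[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Parcellation":
        return cls(pd.read_csv(path, sep="\t"))
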