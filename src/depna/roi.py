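"""ROI rosters and network membership.

A :class:`RoiSet` fixes the node order used by every matrix in the
package: row/column ``i`` of any correlation or dependency matrix always
refers to ``roiset.labels[i]``.  Each ROI belongs to exactly one of two
a-priori sub-networks — an emotional *reactivity* network (limbic/salience
regions) and a *regulation* network (prefrontal–parietal control regions,
including the vmPFC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import pandas as pd

REACTIVITY = "reactivity"
REGULATION = "regulation"
NETWORK_TAGS = (REACTIVITY, REGULATION)

Coord = Tuple[float, float, float]


@dataclass(frozen=True)
class RoiSet:
    """Ordered set of named ROIs with network membership.

    Parameters
    ----------
    labels
        Unique, non-empty ROI names.  Their order is the single source of
        truth for matrix indexing throughout the package.
    network
        Map label -> network tag (``"reactivity"`` or ``"regulation"``).
    coords_mm
        Optional map label -> (x, y, z) in millimeters, used only for
        graph export; analysis never touches coordinates.
    """

    labels: Tuple[str, ...]
    network: Mapping[str, str]
    coords_mm: Optional[Mapping[str, Coord]] = field(default=None)

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if not labels:
            raise ValueError("RoiSet needs at least one label")
        if len(set(labels)) != len(labels):
            raise ValueError("ROI labels must be unique")
        if any(not lbl for lbl in labels):
            raise ValueError("ROI labels must be non-empty strings")
        missing = [lbl for lbl in labels if lbl not in self.network]
        if missing:
            raise ValueError(f"labels without a network tag: {missing}")
        bad = {lbl: t for lbl, t in self.network.items() if t not in NETWORK_TAGS}
        if bad:
            raise ValueError(f"unknown network tags: {bad}")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def members(self, net: str) -> Tuple[str, ...]:
        """Labels belonging to network ``net``, in roster order."""
        if net not in NETWORK_TAGS:
            raise ValueError(f"unknown network tag {net!r}")
        return tuple(lbl for lbl in self.labels if self.network[lbl] == net)

    def member_indices(self, net: str) -> Tuple[int, ...]:
        return tuple(i for i, lbl in enumerate(self.labels) if self.network[lbl] == net)

    def subset(self, labels: Sequence[str]) -> "RoiSet":
        """A new RoiSet containing ``labels`` in roster order."""
        keep = [lbl for lbl in self.labels if lbl in set(labels)]
        coords = None
        if self.coords_mm is not None:
            coords = {lbl: self.coords_mm[lbl] for lbl in keep if lbl in self.coords_mm}
        return RoiSet(tuple(keep), {lbl: self.network[lbl] for lbl in keep}, coords)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lbl in self.labels:
            x = y = z = None
            if self.coords_mm is not None and lbl in self.coords_mm:
                x, y, z = self.coords_mm[lbl]
            rows.append({"label": lbl, "network": self.network[lbl], "x": x, "y": y, "z": z})
        return pd.DataFrame(rows)


# The 14-region roster used throughout: six reactivity (limbic/salience)
# regions and eight regulation (prefrontal-parietal) regions.  Peak
# coordinates were taken from meta-analyses in the source literature and
# are not part of this roster; supply a coordinate-bearing CSV for
# spatial export.
_DEFAULT_ROIS = [
    ("L Amy", REACTIVITY),
    ("R Amy", REACTIVITY),
    ("L midIns", REACTIVITY),
    ("R midIns", REACTIVITY),
    ("PAG", REACTIVITY),
    ("dACC", REACTIVITY),
    ("L IFG", REGULATION),
    ("R IFG", REGULATION),
    ("L MiFG", REGULATION),
    ("R MiFG", REGULATION),
    ("L SPL", REGULATION),
    ("R SPL", REGULATION),
    ("preSMA", REGULATION),
    ("vmPFC", REGULATION),
]


def default_roiset() -> RoiSet:
    """The packaged 14-node reactivity/regulation roster (no coordinates)."""
    return RoiSet(
        tuple(lbl for lbl, _ in _DEFAULT_ROIS),
        {lbl: net for lbl, net in _DEFAULT_ROIS},
        None,
    )
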