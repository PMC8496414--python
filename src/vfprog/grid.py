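"""Static geometry of the 24-2 visual-field test pattern.

The 24-2 pattern of the Humphrey Field Analyzer tests 54 locations on a 6-degree
lattice spanning the central 24 degrees; two locations fall on the physiological
blind spot and carry no information about glaucomatous damage.  The remaining 52
informative locations are grouped into six clusters corresponding to optic-nerve-head
(ONH) sectors, following the published structure-function map of Garway-Heath and
colleagues.  The cluster level sits between the whole field and individual locations
in the hierarchical progression models.

Coordinate convention: right-eye orientation, x positive towards the nasal visual
field, y positive superior, in degrees of visual angle.  The blind spot therefore
sits at (-15, +/-3).  Left-eye data are mirrored into this frame on import.

The location->sector table is a transcription of the published 6-sector ONH map
(sector boundaries drawn on the 24-2 chart); it is shipped as static data because
the map is a fixed anatomical prior, not something refitted per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid24_2", "load_grid", "CLUSTER_NAMES"]

#: ONH sector names indexed by cluster_id - 1.  Superior visual field projects to
#: the inferior disc and vice versa.
CLUSTER_NAMES = {
    1: "inferotemporal",
    2: "inferonasal",
    3: "temporal",
    4: "nasal",
    5: "superotemporal",
    6: "superonasal",
}

# Rows of the 24-2 lattice, top (superior) to bottom, temporal to nasal within a
# row.  x nasal-positive, right-eye frame.
_ROWS = [
    (21, (-9, -3, 3, 9)),
    (15, (-15, -9, -3, 3, 9, 15)),
    (9, (-21, -15, -9, -3, 3, 9, 15, 21)),
    (3, (-21, -15, -9, -3, 3, 9, 15, 21, 27)),
    (-3, (-21, -15, -9, -3, 3, 9, 15, 21, 27)),
    (-9, (-21, -15, -9, -3, 3, 9, 15, 21)),
    (-15, (-15, -9, -3, 3, 9, 15)),
    (-21, (-9, -3, 3, 9)),
]

_BLIND_SPOT = {(-15, 3), (-15, -3)}

# (x, y) -> cluster_id.  Approximate transcription of the 6-sector ONH map.
_SECTOR_OF = {}
_SECTOR_OF.update({xy: 1 for xy in [  # inferotemporal disc <- superior central VF
    (-9, 21), (-3, 21), (3, 21),
    (-15, 15), (-9, 15), (-3, 15), (3, 15),
    (-9, 9), (-3, 9), (3, 9), (9, 9),
]})
_SECTOR_OF.update({xy: 2 for xy in [  # inferonasal disc <- superior nasal VF
    (9, 21),
    (9, 15), (15, 15),
    (15, 9), (21, 9),
    (9, 3), (15, 3), (21, 3), (27, 3),
]})
_SECTOR_OF.update({xy: 3 for xy in [  # temporal disc <- central VF (papillomacular)
    (-9, 3), (-3, 3), (3, 3),
    (-9, -3), (-3, -3), (3, -3),
]})
_SECTOR_OF.update({xy: 4 for xy in [  # nasal disc <- temporal VF
    (-15, 9), (-21, 9),
    (-21, 3),
    (-21, -3),
    (-15, -9), (-21, -9),
]})
_SECTOR_OF.update({xy: 5 for xy in [  # superotemporal disc <- inferior central VF
    (-9, -21), (-3, -21), (3, -21),
    (-15, -15), (-9, -15), (-3, -15), (3, -15),
    (-9, -9), (-3, -9), (3, -9), (9, -9),
]})
_SECTOR_OF.update({xy: 6 for xy in [  # superonasal disc <- inferior nasal VF
    (9, -21),
    (9, -15), (15, -15),
    (15, -9), (21, -9),
    (9, -3), (15, -3), (21, -3), (27, -3),
]})


@dataclass(frozen=True)
class Grid24_2:
    """Geometry and cluster structure of the 24-2 test pattern.

    Attributes
    ----------
    location_id : (54,) int array, 1-based ids in reading order.
    x_deg, y_deg : (54,) arrays of visual-field coordinates (degrees,
        right-eye frame, nasal-positive x).
    is_blind_spot : (54,) bool array, True for the two blind-spot locations.
    cluster_id : (54,) int array in 1..6 for informative locations, 0 at the
        blind spot.
    """

    location_id: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    is_blind_spot: np.ndarray
    cluster_id: np.ndarray

    @property
    def informative(self) -> np.ndarray:
        """Boolean mask over the 54 locations excluding the blind spot."""
        return ~self.is_blind_spot

    @property
    def n_informative(self) -> int:
        return int(self.informative.sum())

    @property
    def n_clusters(self) -> int:
        return int(len(np.unique(self.cluster_id[self.informative])))

    @property
    def informative_cluster_index(self) -> np.ndarray:
        """(52,) zero-based cluster index of each informative location."""
        return self.cluster_id[self.informative] - 1

    def cluster_members(self, cluster_id: int) -> np.ndarray:
        """1-based location ids belonging to a cluster."""
        return self.location_id[self.cluster_id == cluster_id]


def load_grid() -> Grid24_2:
    """Return the packaged static 24-2 grid with ONH-sector clusters."""
    ids, xs, ys, bs, cl = [], [], [], [], []
    i = 0
    for y, row in _ROWS:
        for x in row:
            i += 1
            ids.append(i)
            xs.append(x)
            ys.append(y)
            blind = (x, y) in _BLIND_SPOT
            bs.append(blind)
            cl.append(0 if blind else _SECTOR_OF[(x, y)])
    return Grid24_2(
        location_id=np.array(ids, dtype=int),
        x_deg=np.array(xs, dtype=int),
        y_deg=np.array(ys, dtype=int),
        is_blind_spot=np.array(bs, dtype=bool),
        cluster_id=np.array(cl, dtype=int),
    )
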