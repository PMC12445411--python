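"""AHA 16-segment parcellation of short-axis myocardial slices.

Basal and mid slices are split into six 60-degree sectors (segments 1-6 and
7-12), the apical slice into four 90-degree sectors (13-16), all anchored at
the anterior RV-insertion point and proceeding counterclockwise in the (x, y)
frame.  The apical cap (segment 17) is deliberately absent: the model here is
the 16-segment one used for perfusion territories.

Territory grouping follows the standard assignment:
LAD {1, 2, 7, 8, 13, 14}, RCA {3, 4, 9, 10, 15}, LCX {5, 6, 11, 12, 16}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ContourSet, GeometryError, LayerMasks

TERRITORIES = ("LAD", "RCA", "LCX")

_TERRITORY_OF = {
    1: "LAD", 2: "LAD", 7: "LAD", 8: "LAD", 13: "LAD", 14: "LAD",
    3: "RCA", 4: "RCA", 9: "RCA", 10: "RCA", 15: "RCA",
    5: "LCX", 6: "LCX", 11: "LCX", 12: "LCX", 16: "LCX",
}

_SLICE_SEGMENTS = {
    "basal": tuple(range(1, 7)),
    "mid": tuple(range(7, 13)),
    "apical": tuple(range(13, 17)),
}


@dataclass
class SegmentModel:
    """Per-pixel AHA segment labels for one slice.

    ``labels`` is an integer grid, 0 for background and the AHA segment ID on
    the myocardium; ``reference_angle`` is the anterior RV-insertion angle in
    degrees that anchors the sector boundaries.
    """

    labels: np.ndarray
    slice_label: str
    reference_angle: float

    @property
    def segment_ids(self) -> tuple[int, ...]:
        return _SLICE_SEGMENTS[self.slice_label]

    def mask(self, segment: int) -> np.ndarray:
        if segment not in self.segment_ids:
            raise ValueError(
                f"segment {segment} does not belong to the {self.slice_label} slice")
        return self.labels == segment

    def territory_mask(self, territory: str) -> np.ndarray:
        ids = [s for s in self.segment_ids if _TERRITORY_OF[s] == territory]
        return np.isin(self.labels, ids)


def territory_of_segments() -> dict[int, str]:
    """Fixed AHA segment-to-coronary-territory map (16-segment model)."""
    return dict(_TERRITORY_OF)


def territory_of(segment: int) -> str:
    if segment not in _TERRITORY_OF:
        raise ValueError(f"segment {segment} outside the 16-segment model")
    return _TERRITORY_OF[segment]


def slice_segments(slice_label: str) -> tuple[int, ...]:
    """Segment IDs belonging to one short-axis slice."""
    try:
        return _SLICE_SEGMENTS[slice_label]
    except KeyError:
        raise ValueError(f"unknown slice label {slice_label!r}") from None


def build_segments(masks: LayerMasks, contours: ContourSet,
                   slice_label: str) -> SegmentModel:
    """Label each myocardial pixel with its AHA segment ID.

    Sectors are anchored at the angle of the RV-insertion landmark as seen
    from the blood-pool centre and advance counterclockwise; basal/mid slices
    get six 60-degree sectors, the apical slice four 90-degree sectors.
    """
    if slice_label not in _SLICE_SEGMENTS:
        raise ValueError(f"unknown slice label {slice_label!r}")
    if contours.rv_insertion is None:
        raise GeometryError("RV-insertion landmark is required for parcellation")
    seg_ids = _SLICE_SEGMENTS[slice_label]
    n_sectors = len(seg_ids)

    center = contours.blood_pool_center
    rv = np.asarray(contours.rv_insertion, dtype=float)
    ref_angle = np.arctan2(rv[1] - center[1], rv[0] - center[0])

    rows, cols = masks.myocardium.shape
    y = (np.arange(rows) + 0.5) * masks.pixel_spacing[0]
    x = (np.arange(cols) + 0.5) * masks.pixel_spacing[1]
    X, Y = np.meshgrid(x, y)
    theta = np.arctan2(Y - center[1], X - center[0])
    offset = np.mod(theta - ref_angle, 2 * np.pi)
    sector = np.minimum((offset / (2 * np.pi / n_sectors)).astype(int),
                        n_sectors - 1)
    labels = np.zeros((rows, cols), dtype=int)
    labels[masks.myocardium] = sector[masks.myocardium] + seg_ids[0]
    return SegmentModel(labels, slice_label, float(np.degrees(ref_angle)))
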