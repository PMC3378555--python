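"""Visual-field segment ROIs and per-trial matching/mismatching regions.

Two four-way segmentations of each visual area's retinotopic map are used:

* ``quadrant`` — polar angle binned into the four quadrants of the stimulus
  cross (0–90°, 90–180°, 180–270°, 270–360°, clockwise from the upper
  vertical meridian); used for the categorical instruction.
* ``ring`` — eccentricity binned around the four stimulus radii
  (1.875, 3.75, 5.625, 7.5°), with boundaries at the midpoints between
  adjacent radii; used for the coordinate instruction.

A trial's *matching* region is where a match-response S2 would appear given
S1 and the instruction: the diagonally opposite quadrant (categorical) or
S1's own ring (coordinate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from retinowm.protocol import DOT_RADII, OPPOSITE_QUADRANT

POLAR_BOUNDARIES = (0.0, 90.0, 180.0, 270.0, 360.0)


@dataclass
class SegmentMap:
    """Voxel → segment (1..4) assignment for one segmentation mode.

    ``table`` has columns voxel_id, area, segment; only voxels that survived
    the retinotopy significance mask are assigned.
    """

    mode: str  # "quadrant" | "ring"
    table: pd.DataFrame

    def voxels_in(self, area: str, segment: int) -> np.ndarray:
        t = self.table
        return t.loc[(t["area"] == area) & (t["segment"] == segment), "voxel_id"].to_numpy()

    def for_area(self, area: str) -> pd.DataFrame:
        return self.table[self.table["area"] == area]


@dataclass(frozen=True)
class RegionAssignment:
    trial_id: int
    mode: str
    s1_segment: int
    matching_segment: int
    mismatching_segments: tuple[int, ...]


def polar_to_quadrant(polar_deg: np.ndarray) -> np.ndarray:
    """Quadrant index 1..4 from polar angle (half-open 90° bins, 360→Q1)."""
    p = np.mod(np.asarray(polar_deg, dtype=float), 360.0)
    return (p // 90.0).astype(int) + 1


def ecc_to_ring(ecc_deg: np.ndarray, radii: tuple[float, ...] = DOT_RADII) -> np.ndarray:
    """Ring index 1..4: nearest stimulus radius, midpoint ties to the lower ring.

    Eccentricities below the lowest / above the highest radius clamp to
    rings 1 and 4.
    """
    radii_arr = np.asarray(radii, dtype=float)
    mids = (radii_arr[:-1] + radii_arr[1:]) / 2.0
    return np.searchsorted(mids, np.asarray(ecc_deg, dtype=float), side="left") + 1


def assign_polar_segments(estimates: pd.DataFrame, significant_only: bool = True) -> SegmentMap:
    """Bin decoded polar angles into the four quadrant segments.

    ``estimates`` must carry voxel_id, area, polar_deg and (if
    ``significant_only``) boolean ``significant``.
    """
    est = estimates
    if significant_only and "significant" in est.columns:
        est = est[est["significant"]]
    table = pd.DataFrame(
        {
            "voxel_id": est["voxel_id"].to_numpy(),
            "area": est["area"].to_numpy(),
            "segment": polar_to_quadrant(est["polar_deg"].to_numpy()),
        }
    )
    return SegmentMap(mode="quadrant", table=table)


def assign_ecc_segments(
    estimates: pd.DataFrame,
    radii: tuple[float, ...] = DOT_RADII,
    significant_only: bool = True,
) -> SegmentMap:
    """Bin decoded eccentricities into the four ring segments."""
    est = estimates
    if significant_only and "significant" in est.columns:
        est = est[est["significant"]]
    table = pd.DataFrame(
        {
            "voxel_id": est["voxel_id"].to_numpy(),
            "area": est["area"].to_numpy(),
            "segment": ecc_to_ring(est["ecc_deg"].to_numpy(), radii),
        }
    )
    return SegmentMap(mode="ring", table=table)


def segment_map_from_truth(sheet, mode: str) -> SegmentMap:
    """Ground-truth segmentation straight from a simulated sheet's labels."""
    df = sheet.table
    seg = df["quadrant"] if mode == "quadrant" else df["ring"]
    table = pd.DataFrame(
        {
            "voxel_id": df["voxel_id"].to_numpy(),
            "area": df["area"].to_numpy(),
            "segment": seg.to_numpy(int),
        }
    )
    return SegmentMap(mode=mode, table=table)


def resolve_regions(
    trial: pd.Series,
    include_own_quadrant: bool = False,
) -> RegionAssignment:
    """Matching and mismatching segments for one trial.

    Categorical: matching = quadrant diagonally opposite S1; mismatching =
    the remaining two quadrants.  S1's own quadrant is excluded from the
    mismatching set by default so residual stimulus activation is not
    attributed to the delay-mismatch factor (``include_own_quadrant=True``
    restores it for sensitivity analyses).

    Coordinate: matching = S1's ring; mismatching = the other three rings.
    """
    instruction = trial["instruction"]
    if instruction == "categorical":
        s1_seg = int(trial["s1_quadrant"])
        match = OPPOSITE_QUADRANT[s1_seg]
        mismatch = [q for q in (1, 2, 3, 4) if q != match and (include_own_quadrant or q != s1_seg)]
        mode = "quadrant"
    elif instruction == "coordinate":
        s1_seg = int(trial["s1_ring"])
        match = s1_seg
        mismatch = [r for r in (1, 2, 3, 4) if r != match]
        mode = "ring"
    else:
        raise ValueError(f"unknown instruction {instruction!r}")
    return RegionAssignment(
        trial_id=int(trial["trial_id"]),
        mode=mode,
        s1_segment=s1_seg,
        matching_segment=match,
        mismatching_segments=tuple(mismatch),
    )


def resolve_all_regions(trials: pd.DataFrame, include_own_quadrant: bool = False):
    """RegionAssignment for every trial of a session, in table order."""
    return [resolve_regions(row, include_own_quadrant) for _, row in trials.iterrows()]
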