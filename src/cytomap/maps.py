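"""Probabilistic cytoarchitectonic maps and the maximum probability map.

After each subject's areas are brought to a common reference grid, the
probabilistic map of an area holds, per voxel, the fraction of subjects
whose delineation covers that voxel (for 10 subjects: multiples of 0.1,
the familiar 10%–100% color scale).  The maximum probability map (MPM)
assigns every voxel to the area with the highest probability; where an
area borders unmapped cortex (no competing mapped area present) a voxel
needs at least a 40% probability to be included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ProbabilisticMap",
    "MaxProbabilityMap",
    "probability_map",
    "compute_mpm",
    "mpm_area_volume",
    "overlap_summary",
]


def _as_array(vol):
    """Accept a plain array or a nibabel spatial image; return (data, affine)."""
    if hasattr(vol, "get_fdata") and hasattr(vol, "affine"):
        return np.asanyarray(vol.dataobj), np.asarray(vol.affine)
    return np.asarray(vol), None


@dataclass(frozen=True)
class ProbabilisticMap:
    """Per-voxel subject-overlap fraction of one area."""

    data: np.ndarray
    affine: np.ndarray
    area_id: int
    n_subjects: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.min() < 0 or d.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))


@dataclass(frozen=True)
class MaxProbabilityMap:
    """Integer label volume (0 = unassigned) with assignment provenance."""

    labels: np.ndarray
    affine: np.ndarray
    threshold: float
    area_ids: tuple
    tie_rule: str
    n_ties_neighborhood: int = 0
    n_ties_fallback: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


def probability_map(label_volumes, area_id: int, affine=None) -> ProbabilisticMap:
    """Fraction of subjects whose label volume carries ``area_id`` per voxel.

    Parameters
    ----------
    label_volumes : sequence of ndarray or nibabel images
        One integer label volume per subject, on a shared grid.
    area_id : int
    affine : (4, 4) array, optional
        Voxel-to-world transform; taken from the first nibabel image if
        present, identity otherwise.
    """
    vols = list(label_volumes)
    if not vols:
        raise ValueError("need at least one subject")
    arrays = []
    for v in vols:
        arr, aff = _as_array(v)
        if affine is None and aff is not None:
            affine = aff
        elif aff is not None and affine is not None and not np.allclose(aff, affine):
            raise ValueError("subject volumes disagree in affine geometry")
        arrays.append(arr)
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError("subject volumes disagree in grid shape")
    if affine is None:
        affine = np.eye(4)
    n = len(arrays)
    count = np.zeros(shapes.pop(), dtype=np.int32)
    for a in arrays:
        count += a == area_id
    return ProbabilisticMap(
        data=count / n, affine=affine, area_id=int(area_id), n_subjects=n
    )


def _neighborhood_mean(data: np.ndarray) -> np.ndarray:
    """Mean over the 26-neighborhood (full 3x3x3 box minus the centre),
    with zero padding at the volume faces."""
    from scipy.ndimage import uniform_filter

    k = 3
    box = uniform_filter(data, size=k, mode="constant", cval=0.0) * k**data.ndim
    return (box - data) / (k**data.ndim - 1)


def compute_mpm(
    prob_maps,
    unmapped_threshold: float = 0.4,
    tie_rule: str = "neighborhood",
) -> MaxProbabilityMap:
    """Assign each voxel to the area with the highest probability.

    Voxels where some area has nonzero probability get the argmax label.
    The ``unmapped_threshold`` applies only at borders with unmapped
    cortex — voxels where no *second* mapped area competes (at most one
    area has p > 0): there the single candidate must reach the threshold
    (default 0.4) or the voxel stays unassigned.  Argmax ties are resolved
    by the higher mean probability over the 26-neighborhood; remaining
    ties fall back to the lowest area id and are counted and logged.

    Parameters
    ----------
    prob_maps : sequence of ProbabilisticMap
    unmapped_threshold : float in [0, 1]
    tie_rule : {"neighborhood", "lowest_id"}
    """
    maps = list(prob_maps)
    if not maps:
        raise ValueError("need at least one probabilistic map")
    if not 0 <= unmapped_threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    if tie_rule not in ("neighborhood", "lowest_id"):
        raise ValueError("tie_rule must be 'neighborhood' or 'lowest_id'")
    shapes = {m.data.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("probability maps disagree in grid shape")
    for m in maps[1:]:
        if not np.allclose(m.affine, maps[0].affine):
            raise ValueError("probability maps disagree in affine geometry")
    ids = [m.area_id for m in maps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate area ids among probability maps")
    order = np.argsort(ids)  # ascending id so argmax fallback = lowest id
    maps = [maps[k] for k in order]
    ids = [m.area_id for m in maps]

    P = np.stack([m.data for m in maps])  # (n_areas, *grid)
    maxp = P.max(axis=0)
    n_nonzero = (P > 0).sum(axis=0)
    winner = P.argmax(axis=0)

    n_tie_nb = 0
    n_tie_fb = 0
    is_tie = (P == maxp[None]).sum(axis=0) > 1
    is_tie &= maxp > 0
    if is_tie.any() and tie_rule == "neighborhood":
        nb = np.stack([_neighborhood_mean(m.data) for m in maps])
        tied_mask = P == maxp[None]
        nb_masked = np.where(tied_mask, nb, -np.inf)
        nb_winner = nb_masked.argmax(axis=0)
        nb_best = nb_masked.max(axis=0)
        still_tied = (np.isclose(nb_masked, nb_best[None]) & tied_mask).sum(axis=0) > 1
        winner = np.where(is_tie, nb_winner, winner)
        n_tie_nb = int(is_tie.sum())
        n_tie_fb = int((is_tie & still_tied).sum())
        # argmax already returns the lowest index (= lowest id) on residual ties
    elif is_tie.any():
        n_tie_fb = int(is_tie.sum())
    if n_tie_fb:
        logger.info("MPM: %d voxel(s) resolved by lowest-area-id fallback", n_tie_fb)

    labels = np.zeros(maxp.shape, dtype=np.int16)
    assigned = maxp > 0
    # the 0.4 rule applies where no second mapped area competes
    border_unmapped = n_nonzero <= 1
    assigned &= ~(border_unmapped & (maxp < unmapped_threshold))
    id_arr = np.asarray(ids, dtype=np.int16)
    labels[assigned] = id_arr[winner[assigned]]
    return MaxProbabilityMap(
        labels=labels,
        affine=maps[0].affine,
        threshold=float(unmapped_threshold),
        area_ids=tuple(int(i) for i in ids),
        tie_rule=tie_rule,
        n_ties_neighborhood=n_tie_nb,
        n_ties_fallback=n_tie_fb,
    )


def mpm_area_volume(mpm: MaxProbabilityMap, area_id: int) -> float:
    """Volume (mm³) of one area in the MPM: voxel count × voxel volume."""
    if area_id not in mpm.area_ids:
        raise ValueError(f"unknown area id {area_id}")
    return float((mpm.labels == area_id).sum()) * mpm.voxel_volume_mm3


def overlap_summary(prob_maps) -> "pandas.DataFrame":
    """Probability-weighted centre of gravity and extent per area.

    Centres and bounding boxes are reported in world coordinates through
    each map's affine (columns cog_x/y/z, min_x/…, max_x/…, plus the voxel
    count of nonzero support).
    """
    import pandas as pd

    maps = list(prob_maps)
    if not maps:
        raise ValueError("need at least one probabilistic map")
    rows = []
    for m in maps:
        w = m.data
        tot = w.sum()
        if tot <= 0:
            raise ValueError(f"area {m.area_id}: all-zero probability map")
        idx = np.nonzero(w)
        vox = np.column_stack(idx).astype(float)
        weights = w[idx]
        cog_vox = (vox * weights[:, None]).sum(axis=0) / weights.sum()
        A, t = m.affine[:3, :3], m.affine[:3, 3]
        cog = A @ cog_vox + t
        corners_world = (A @ vox.T).T + t
        lo, hi = corners_world.min(axis=0), corners_world.max(axis=0)
        rows.append(
            {
                "area_id": m.area_id,
                "cog_x": cog[0],
                "cog_y": cog[1],
                "cog_z": cog[2],
                "min_x": lo[0],
                "min_y": lo[1],
                "min_z": lo[2],
                "max_x": hi[0],
                "max_y": hi[1],
                "max_z": hi[2],
                "n_voxels": int(len(weights)),
            }
        )
    return pd.DataFrame(rows)
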