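"""Volume and shape-similarity metrics for label masks.

Masks produced at different voxel geometries are compared on a common
high-resolution reference grid: the coarse mask is up-sampled by
nearest-neighbor assignment (each reference voxel takes the value of the
coarse voxel whose centre is nearest), which preserves the blocky geometry
of the coarse labeling and — for the rational voxel-size ratios of the
factorial design — preserves physical volume exactly.  Shape agreement is
the Dice coefficient 2|A∩B|/(|A|+|B|); volume accuracy is the signed
percentage deviation from the ground-truth volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import GridSpec
from .raters import GridMismatchError, LabelMask

__all__ = [
    "MetricRecord",
    "mask_volume",
    "pct_deviation",
    "upsample_nearest",
    "dice",
    "evaluate_mask",
    "relative_voxel_volume",
]


@dataclass(frozen=True)
class MetricRecord:
    """Per-mask accuracy: volumes (mm^3), signed % deviation, and Dice."""

    labeled_volume: float
    truth_volume: float
    pct_deviation: float
    dcs: float


def mask_volume(mask: LabelMask) -> float:
    """Physical volume of a mask: occupied voxels times voxel volume, mm^3."""
    return mask.volume


def pct_deviation(labeled_volume: float, truth_volume: float) -> float:
    """Signed percentage deviation of a labeled volume from the ground truth."""
    if truth_volume <= 0:
        raise ValueError("truth volume must be positive")
    return 100.0 * (labeled_volume - truth_volume) / truth_volume


def _nearest_index(grid_src: GridSpec, grid_ref: GridSpec, axis: int) -> np.ndarray:
    """Source-voxel index nearest to each reference voxel centre on one axis.

    Ties at exact half-voxel boundaries round toward the lower index
    (round-half-down in index space); with the cell-centred coordinate
    convention and the design's rational size ratios such ties do not occur.
    Reference centres outside the source extent map to -1.
    """
    w = grid_ref.axis_coords(axis)
    lo = -grid_src.fov[axis] / 2.0
    cont = (w - lo) / grid_src.voxel_dims[axis] - 0.5
    idx = np.ceil(cont - 0.5).astype(int)  # round half down
    n = grid_src.matrix_dims[axis]
    idx[(w < lo) | (w > lo + grid_src.fov[axis])] = -1
    idx[idx > n - 1] = -1
    idx[idx < 0] = -1
    return idx


def upsample_nearest(mask: LabelMask, reference_grid: GridSpec) -> LabelMask:
    """Resample a mask onto a finer reference grid by nearest neighbor.

    Every reference voxel takes the value of the source voxel whose centre
    is nearest to its own centre (reference voxels outside the source FoV
    are background).  Because both grids are cell-centred on the same FoV
    centre, odd and even matrix sizes align without padding or shifting;
    when each source voxel size is an integer multiple of the reference
    size the source content is replicated exactly and the physical volume
    is unchanged.
    """
    src = mask.grid
    if src == reference_grid:
        return mask
    for axis in range(3):
        if reference_grid.voxel_dims[axis] > src.voxel_dims[axis] + 1e-12:
            raise ValueError(
                "reference grid must be at least as fine as the source grid"
            )
        if abs(reference_grid.fov[axis] - src.fov[axis]) > 1e-9:
            raise GridMismatchError("upsampling across different FoVs")
    ix = _nearest_index(src, reference_grid, 0)
    iy = _nearest_index(src, reference_grid, 1)
    iz = _nearest_index(src, reference_grid, 2)
    out = mask.data[np.ix_(np.clip(ix, 0, None), np.clip(iy, 0, None), np.clip(iz, 0, None))]
    for axis, idx in enumerate((ix, iy, iz)):
        if (idx < 0).any():
            sl = [slice(None)] * 3
            sl[axis] = idx < 0
            out[tuple(sl)] = False
    return LabelMask(data=out, grid=reference_grid)


def dice(a: LabelMask, b: LabelMask) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|) on a common grid; 1.0 if both empty."""
    if a.grid != b.grid:
        raise GridMismatchError("dice requires masks on a common grid")
    na, nb = a.count, b.count
    if na + nb == 0:
        return 1.0
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


def evaluate_mask(
    mask: LabelMask, truth_volume: float, reference: LabelMask
) -> MetricRecord:
    """Volume deviation and Dice of a mask against a reference labeling.

    The mask is up-sampled to the reference grid before the overlap is
    computed; the volume deviation uses the mask's native volume.
    """
    up = upsample_nearest(mask, reference.grid)
    vol = mask.volume
    return MetricRecord(
        labeled_volume=vol,
        truth_volume=truth_volume,
        pct_deviation=pct_deviation(vol, truth_volume),
        dcs=dice(up, reference),
    )


def relative_voxel_volume(grid: GridSpec, truth_volume: float) -> float:
    """Voxel volume as a percentage of the ground-truth structure volume."""
    if truth_volume <= 0:
        raise ValueError("truth volume must be positive")
    return 100.0 * grid.voxel_volume / truth_volume
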