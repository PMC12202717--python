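"""Comparison metrics between two maps: MAPE, Pearson r, heatmaps, summaries.

All metrics ignore undefined (NaN) voxels symmetrically: a voxel excluded in
either map is excluded from both.  The concentric-region partition splits
the foreground into center / middle / outer thirds of the normalised radial
distance to the foreground centroid, so spatially structured errors (e.g.
boundary artefacts) can be localised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .volgrid import VolumeGrid

__all__ = [
    "RegionPartition",
    "make_region_partition",
    "mape",
    "pearson",
    "distribution_summary",
    "heatmap2d",
]

REGION_CODES = {1: "center", 2: "middle", 3: "outer"}


@dataclass
class RegionPartition:
    """Concentric center/middle/outer thirds of the foreground.

    ``regions`` is 0 outside the foreground and 1/2/3 inside, by equal-width
    thirds of the normalised distance to the foreground centroid (distance
    measured in mm).
    """

    regions: np.ndarray

    def mask(self, name: str | None) -> np.ndarray:
        if name is None:
            return self.regions > 0
        code = {v: k for k, v in REGION_CODES.items()}.get(name)
        if code is None:
            raise ValueError(f"unknown region {name!r}; expected center/middle/outer")
        return self.regions == code


def make_region_partition(foreground: np.ndarray, spacing) -> RegionPartition:
    """Partition a foreground mask into concentric thirds."""
    fg = np.asarray(foreground, dtype=bool)
    if not fg.any():
        raise ValueError("empty foreground mask")
    idx = np.argwhere(fg).astype(float) * np.asarray(spacing, dtype=float)
    centroid = idx.mean(axis=0)
    dist = np.sqrt(((idx - centroid) ** 2).sum(axis=1))
    dmax = dist.max()
    norm = dist / dmax if dmax > 0 else dist
    # equal-width thirds; the outermost voxel (norm == 1) belongs to "outer"
    codes = np.minimum((norm * 3).astype(int) + 1, 3)
    regions = np.zeros(fg.shape, dtype=np.int32)
    regions[fg] = codes
    return RegionPartition(regions)


def _joint_defined(a: VolumeGrid, b: VolumeGrid, region_mask: np.ndarray | None):
    if a.shape != b.shape:
        raise ValueError("maps must share geometry")
    da = np.asarray(a.data, dtype=float)
    db = np.asarray(b.data, dtype=float)
    sel = np.isfinite(da) & np.isfinite(db)
    if region_mask is not None:
        sel &= region_mask
    return da[sel], db[sel]


def mape(
    a: VolumeGrid,
    b: VolumeGrid,
    partition: RegionPartition | None = None,
    region: str | None = None,
) -> float:
    """Mean absolute percentage error of a against reference b, percent.

    ``mean(|a - b| / |b|) * 100`` over jointly defined voxels; voxels where
    the reference is zero are excluded.
    """
    mask = partition.mask(region) if partition is not None else None
    va, vb = _joint_defined(a, b, mask)
    nz = vb != 0
    if not nz.any():
        raise ValueError("no voxels with a nonzero reference value")
    return float(np.mean(np.abs(va[nz] - vb[nz]) / np.abs(vb[nz])) * 100.0)


def pearson(
    a: VolumeGrid,
    b: VolumeGrid,
    partition: RegionPartition | None = None,
    region: str | None = None,
) -> tuple[float, float]:
    """Product-moment correlation over jointly defined voxels; two-sided p."""
    mask = partition.mask(region) if partition is not None else None
    va, vb = _joint_defined(a, b, mask)
    if va.size < 2:
        raise ValueError("need at least two jointly defined voxels")
    r, p = stats.pearsonr(va, vb)
    return float(r), float(p)


def distribution_summary(v: VolumeGrid, mask: np.ndarray | None = None) -> dict[str, float]:
    """Median, IQR (linear-interpolation quartiles), adjusted skewness, min, max."""
    data = np.asarray(v.data, dtype=float)
    sel = np.isfinite(data)
    if mask is not None:
        sel &= mask
    vals = data[sel]
    if vals.size == 0:
        raise ValueError("no defined voxels to summarise")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
    return {
        "median": float(med),
        "iqr": float(q3 - q1),
        "skewness": float(stats.skew(vals, bias=False)),  # adjusted Fisher-Pearson
        "min": float(vals.min()),
        "max": float(vals.max()),
        "n": int(vals.size),
    }


def heatmap2d(
    a: VolumeGrid, b: VolumeGrid, bins: int = 64
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxelwise joint histogram of two maps over jointly defined voxels.

    Returns (counts, a_edges, b_edges); counts sum to the number of compared
    voxels.
    """
    va, vb = _joint_defined(a, b, None)
    counts, ea, eb = np.histogram2d(va, vb, bins=bins)
    return counts, ea, eb
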