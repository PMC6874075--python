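"""Spatial distribution of densitometric parameters over the tibia.

The densitometric VOI starts just distal to the growth plate, spans 80% of
the tibia length and excludes the fibula. It is divided into ten
longitudinal sections (01 proximal → 10 distal) and four quadrants
(lateral, anterior, medial, posterior), yielding 40 partitions per bone.
Per partition: BMC (mg), mean TMD (mg HA/cc), BMD (mg HA/cc) and BV/TV (%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imgproc import BoneMask, VoxelImage, tibia_length

QUADRANTS = ("L", "A", "M", "P")
N_SECTIONS = 10


@dataclass
class PartitionGrid:
    """Per-voxel partition labels over the densitometric VOI.

    ``labels`` is -1 outside the VOI and ``4 * section + quadrant`` inside
    (section 0..9 proximal → distal, quadrant index into
    ``quadrant_names``). Partitions are disjoint and cover the VOI exactly.
    """

    labels: np.ndarray
    slice_range: tuple
    spacing: float
    quadrant_names: tuple = QUADRANTS

    def partition_ids(self):
        return range(4 * N_SECTIONS)

    def name(self, pid: int) -> tuple:
        section, quad = divmod(pid, 4)
        return (f"{section + 1:02d}", self.quadrant_names[quad])


def densitometric_voi(mask: BoneMask, start_slice: int,
                      length_mm: float | None = None,
                      exclude_fibula: bool = True):
    """Bone mask of the densitometric VOI (80% of length, fibula excluded).

    ``start_slice`` is the first slice distal to the growth plate (an input
    parameter; phantoms carry it in their ground truth). The fibula is
    excluded by per-slice 2-D component tracking: the principal tibial
    component is seeded as the largest component on the first VOI slice and
    followed down the stack by maximal overlap with the previous tibial
    envelope (the filled periosteal region); every component lying inside
    that envelope (trabecular struts in the medullary canal) is kept, while
    components outside it — the fibula — are dropped.

    Returns ``(voi_mask, (z0, z1))`` with the half-open slice range.
    """
    if length_mm is None:
        length_mm = tibia_length(mask)
    sp_mm = mask.spacing / 1000.0
    nsl = int(round(0.8 * length_mm / sp_mm))
    z0, z1 = start_slice, start_slice + nsl
    if z0 < 0 or z1 > mask.shape[0]:
        raise ValueError(
            f"densitometric VOI [{z0}, {z1}) exceeds image of {mask.shape[0]} slices"
        )
    out = np.zeros(mask.shape, dtype=bool)
    prev_env = None
    for z in range(z0, z1):
        sl = mask.data[z]
        if not sl.any():
            prev_env = None
            continue
        if not exclude_fibula:
            out[z] = sl
            continue
        labels, n = ndimage.label(sl)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        if prev_env is not None:
            overlap = np.bincount(labels[prev_env].ravel(), minlength=n + 1)
            overlap[0] = 0
            principal = int(np.argmax(overlap)) if overlap.any() \
                else int(np.argmax(counts))
        else:
            principal = int(np.argmax(counts))
        envelope = ndimage.binary_fill_holes(labels == principal)
        inside = np.unique(labels[envelope & (labels > 0)])
        tib = np.isin(labels, inside[inside > 0]) | (labels == principal)
        out[z] = tib
        prev_env = envelope
    return BoneMask(out, mask.spacing), (z0, z1)


def partition(voi_mask: BoneMask, slice_range: tuple,
              quadrant_names: tuple = QUADRANTS) -> PartitionGrid:
    """Divide the VOI into 10 longitudinal sections × 4 quadrants.

    Sections are of equal slice count, with remainder slices assigned to
    the most distal section. Within each section, every VOI voxel is
    assigned a quadrant by the orientation of its XY offset from the
    section's bone centroid: boundaries are the two vertical planes through
    the centroid at ±45° to the image X axis, and the mapping of the four
    sectors to anatomical labels (default lateral = +X, anterior = +Y,
    medial = -X, posterior = -Y) is a configurable orientation convention.
    Sector membership is decided by exact sign tests on the rotated
    coordinates ``dy ± dx`` (half-open sectors), so a 90° grid rotation
    permutes the quadrants exactly.

    The partition labels cover every voxel of the slice range (the full
    cross-section), so partition volumes are section × quadrant blocks of
    the VOI; bone-phase restriction happens in :func:`partition_metrics`.
    """
    z0, z1 = slice_range
    nsl = z1 - z0
    if nsl < N_SECTIONS:
        raise ValueError("VOI shorter than the number of longitudinal sections")
    per = nsl // N_SECTIONS
    labels = np.full(voi_mask.shape, -1, dtype=np.int16)
    ny, nx = voi_mask.shape[1:]
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    for s in range(N_SECTIONS):
        a = z0 + s * per
        b = z0 + (s + 1) * per if s < N_SECTIONS - 1 else z1
        bone = voi_mask.data[a:b]
        if not bone.any():
            raise ValueError(f"longitudinal section {s + 1:02d} contains no bone")
        coords = np.argwhere(bone)
        nb = coords.shape[0]
        sy = int(coords[:, 1].sum())
        sx = int(coords[:, 2].sum())
        # centroid offsets scaled by the voxel count: exact integers, so
        # sector boundaries behave identically under grid rotations
        dy = nb * yy.astype(np.int64) - sy
        dx = nb * xx.astype(np.int64) - sx
        u = dy + dx  # rotated axes: boundaries at ±45°
        v = dy - dx
        sector = np.empty((ny, nx), dtype=np.int16)
        sector[(u >= 0) & (v < 0)] = 0  # angle in [-45, 45): lateral (+X)
        sector[(u > 0) & (v >= 0)] = 1  # [45, 135): anterior (+Y)
        sector[(u <= 0) & (v > 0)] = 2  # [135, 225): medial (-X)
        sector[(u < 0) & (v <= 0)] = 3  # [225, 315): posterior (-Y)
        sector[(u == 0) & (v == 0)] = 0  # exact centroid hit
        labels[a:b] = 4 * s + sector[None, :, :]
    return PartitionGrid(labels, (z0, z1), voi_mask.spacing, quadrant_names)


def partition_metrics(tmd_image: VoxelImage, bone_mask: BoneMask,
                      grid: PartitionGrid) -> pd.DataFrame:
    """BMC, TMD, BMD and BV/TV per partition (40 rows).

    Per voxel, BMC = TMD × voxel volume (in cm³, so BMC is in mg). Per
    partition: BMC sums over bone voxels; TMD is their mean (missing when
    the partition holds no bone); BMD is the partition BMC divided by the
    partition's total volume; BV/TV is the bone voxel fraction.
    """
    if tmd_image.value_kind != "tmd":
        raise ValueError("partition_metrics needs a calibrated TMD image")
    v_cm3 = (grid.spacing * 1e-4) ** 3
    labels = grid.labels
    bone = bone_mask.data & (labels >= 0)
    lab_b = labels[bone]
    tmd_b = np.asarray(tmd_image.data)[bone]
    np_part = 4 * N_SECTIONS
    bmc = np.bincount(lab_b, weights=tmd_b, minlength=np_part) * v_cm3
    nbone = np.bincount(lab_b, minlength=np_part)
    ntot = np.bincount(labels[labels >= 0].ravel(), minlength=np_part)
    with np.errstate(invalid="ignore", divide="ignore"):
        tmd_mean = np.where(nbone > 0,
                            bmc / v_cm3 / np.maximum(nbone, 1), np.nan)
        bmd = np.where(ntot > 0, bmc / (ntot * v_cm3), np.nan)
        bvtv = np.where(ntot > 0, 100.0 * nbone / np.maximum(ntot, 1), np.nan)
    rows = []
    for pid in range(np_part):
        sec, quad = grid.name(pid)
        rows.append({
            "section": sec, "quadrant": quad,
            "BMC_mg": bmc[pid],
            "TMD": tmd_mean[pid],
            "BMD": bmd[pid],
            "BVTV": bvtv[pid],
            "n_bone_voxels": int(nbone[pid]),
            "n_voxels": int(ntot[pid]),
        })
    return pd.DataFrame(rows)


def total_bmc(tmd_image: VoxelImage, bone_mask: BoneMask) -> float:
    """Whole-mask bone mineral content in mg."""
    if tmd_image.value_kind != "tmd":
        raise ValueError("total_bmc needs a calibrated TMD image")
    v_cm3 = (bone_mask.spacing * 1e-4) ** 3
    return float(np.asarray(tmd_image.data)[bone_mask.data].sum() * v_cm3)


def paired_partition_difference(left: pd.DataFrame,
                                right: pd.DataFrame,
                                metrics=("BMC_mg", "TMD", "BMD", "BVTV")) -> pd.DataFrame:
    """Per-partition percent difference ``100 * (right - left) / left``.

    Partitions with a zero or missing left value yield a missing
    difference. Group-level summaries (median ± SD across animals) are
    produced by :func:`cohort_partition_summary`.
    """
    if not (left["section"].equals(right["section"])
            and left["quadrant"].equals(right["quadrant"])):
        raise ValueError("partition tables do not share a grid")
    out = left[["section", "quadrant"]].copy()
    for m in metrics:
        denom = left[m].to_numpy(dtype=float)
        num = right[m].to_numpy(dtype=float) - denom
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(denom != 0, 100.0 * num / denom, np.nan)
        out[f"{m}_pct_diff"] = pct
    return out


def cohort_partition_summary(diffs: list[pd.DataFrame],
                             metric: str = "BMC_mg") -> pd.DataFrame:
    """Median ± SD of per-animal percent differences, per partition."""
    col = f"{metric}_pct_diff"
    stacked = np.stack([d[col].to_numpy(dtype=float) for d in diffs])
    out = diffs[0][["section", "quadrant"]].copy()
    out["median_pct"] = np.nanmedian(stacked, axis=0)
    out["sd_pct"] = np.nanstd(stacked, axis=0, ddof=1)
    return out
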