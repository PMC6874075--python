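"""Standard trabecular and cortical morphometry on segmented VOIs.

Thickness and separation use the model-independent maximal-sphere
definition: the local thickness at a voxel is the diameter of the largest
sphere that lies entirely within the phase and contains the voxel. The
implementation computes, for every candidate radius present in the
Euclidean distance transform, the morphological opening of the phase with
the corresponding digital ball — the union of all such balls — which is the
exact sphere-fitting map without enumerating sphere centres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imgproc import BoneMask, close_cortical_pores


@dataclass
class VOIConfig:
    """Volume-of-interest placement for the standard morphometric analysis.

    ``trab_offset_mm`` and ``trab_height_mm`` place the trabecular VOI below
    the reference slice (the point where the growth plate merges, supplied
    as an input); ``cort_height_mm`` is the height of the cortical VOI
    centred at the midshaft (50% of tibia length).
    """

    trab_offset_mm: float = 0.2
    trab_height_mm: float = 1.0
    cort_height_mm: float = 1.0
    reference_slice: int = 0

    def __post_init__(self) -> None:
        if self.trab_height_mm <= 0 or self.cort_height_mm <= 0:
            raise ValueError("VOI heights must be positive")


@dataclass
class TrabecularMetrics:
    bvtv_pct: float  # Tb.BV/TV, %
    tb_th_um: float  # Tb.Th
    tb_sp_um: float  # Tb.Sp
    tb_n_per_mm: float  # Tb.N


@dataclass
class CorticalMetrics:
    tt_ar_mm2: float  # total cross-sectional area
    ct_ar_mm2: float  # cortical bone area
    ct_ar_tt_ar_pct: float  # cortical area fraction
    ct_th_um: float  # cortical thickness (3-D direct)
    open_section_warning: bool = False


# ---------------------------------------------------------------------------
# local thickness
# ---------------------------------------------------------------------------

def local_thickness(mask: np.ndarray) -> np.ndarray:
    """Maximal-sphere local thickness map, in voxel units.

    For each foreground voxel the value is ``2*r - 1`` where ``r`` is the
    distance (to the nearest background voxel centre) of the largest
    inscribed digital ball covering it; a ball of distance ``r`` covers the
    voxels strictly closer than ``r`` to its centre. Everything outside the
    array is treated as background, so thickness is bounded by the extent
    of the supplied grid.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no thickness")
    padded = np.pad(mask, 1)
    d = ndimage.distance_transform_edt(padded)
    radii = np.unique(d[padded])[::-1]
    th = np.zeros(padded.shape)
    for r in radii:
        centers = d >= r
        # distance from every voxel to the nearest qualifying centre
        dist_to_center = ndimage.distance_transform_edt(~centers)
        covered = padded & (dist_to_center < r) & (th == 0)
        th[covered] = 2.0 * r - 1.0
    return th[1:-1, 1:-1, 1:-1]


def bvtv(mask_phase: np.ndarray, mask_total: np.ndarray) -> float:
    """Bone volume fraction, percent: ``100 * |phase| / |total|``."""
    phase = np.asarray(mask_phase, dtype=bool)
    total = np.asarray(mask_total, dtype=bool)
    if not total.any():
        raise ValueError("empty total volume")
    if (phase & ~total).any():
        raise ValueError("phase must be contained in the total volume")
    return 100.0 * phase.sum() / total.sum()


def tb_th(phase: np.ndarray, spacing: float) -> float:
    """Mean trabecular thickness (μm): volume-weighted mean local thickness."""
    phase = np.asarray(phase, dtype=bool)
    if not phase.any():
        raise ValueError("empty phase")
    box = _bounding_box(phase, pad=1)
    th = local_thickness(phase[box])
    return float(th[phase[box]].mean() * spacing)


def tb_sp(bone: np.ndarray, total: np.ndarray, spacing: float) -> float:
    """Mean trabecular separation (μm): thickness of the background phase.

    The background phase is the VOI minus the bone phase; space outside the
    VOI is treated as background boundary, so separation is bounded by the
    VOI extent (the complement identity ``tb_sp = tb_th of complement``
    holds within the VOI grid).
    """
    bone = np.asarray(bone, dtype=bool)
    total = np.asarray(total, dtype=bool)
    backg = total & ~bone
    if not backg.any():
        raise ValueError("empty background phase")
    box = _bounding_box(total, pad=1)
    th = local_thickness(backg[box])
    return float(th[backg[box]].mean() * spacing)


def tb_n(bvtv_pct: float, tb_th_um: float) -> float:
    """Trabecular number (1/mm): ``(BV/TV) / Tb.Th`` (plate-model ratio)."""
    if bvtv_pct == 0:
        return 0.0
    if tb_th_um <= 0:
        raise ValueError("thickness must be positive")
    return (bvtv_pct / 100.0) / (tb_th_um / 1000.0)


def _bounding_box(mask: np.ndarray, pad: int = 0) -> tuple:
    coords = np.argwhere(mask)
    lo = np.maximum(coords.min(axis=0) - pad, 0)
    hi = np.minimum(coords.max(axis=0) + 1 + pad, mask.shape)
    return tuple(slice(a, b) for a, b in zip(lo, hi))


# ---------------------------------------------------------------------------
# trabecular VOI
# ---------------------------------------------------------------------------

def extract_trabecular_voi(mask: BoneMask, voi: VOIConfig,
                           closing_radius_px: int = 10):
    """Endosteal volume of interest for trabecular analysis.

    The VOI spans ``[ref + trab_offset, ref + trab_offset + trab_height]``
    below the reference slice. Within each slice, the cortical shell is
    removed automatically: the shell (largest 2-D component of the
    pore-closed bone) is filled, eroded by its own maximal depth plus one
    pixel, and the remaining interior is the trabecular region. Slices in
    which the bone encloses no cavity (no cortical shell present) keep the
    full slice. Returns a boolean region of the full image shape.

    The manual slice-by-slice contouring used by scanner software is
    operator-dependent; this automatic endosteal contour is its
    reproducible surrogate.
    """
    sp_mm = mask.spacing / 1000.0
    z0 = voi.reference_slice + int(round(voi.trab_offset_mm / sp_mm))
    nsl = int(round(voi.trab_height_mm / sp_mm))
    if z0 < 0 or z0 + nsl > mask.shape[0]:
        raise ValueError(
            f"trabecular VOI [{z0}, {z0 + nsl}) exceeds image of {mask.shape[0]} slices"
        )
    region = np.zeros(mask.shape, dtype=bool)
    for z in range(z0, z0 + nsl):
        region[z] = _endosteal_interior(mask.data[z], closing_radius_px)
    return region, (z0, z0 + nsl)


def _endosteal_interior(bone_slice: np.ndarray,
                        closing_radius_px: int) -> np.ndarray:
    """Interior of the cortical shell in one slice; full slice if no shell.

    The shell is the largest 2-D component of the raw bone slice (trabecular
    struts are separate, smaller components); it is pore-closed, filled and
    eroded one pixel past its own maximal depth, leaving the endosteal
    region that hosts the trabecular phase.
    """
    from .imgproc import _disk_closing

    if not bone_slice.any():
        return np.ones_like(bone_slice)
    labels, _ = ndimage.label(bone_slice)
    counts = np.bincount(labels.ravel())[1:]
    shell = labels == (int(np.argmax(counts)) + 1)
    closed = _disk_closing(shell, closing_radius_px) | shell
    filled = ndimage.binary_fill_holes(closed)
    if not (filled & ~closed).any():  # no enclosed cavity: no cortex here
        return np.ones_like(bone_slice)
    depth = ndimage.distance_transform_edt(filled)[closed].max()
    return ndimage.distance_transform_edt(filled) > depth + 1.0


def trabecular_metrics(mask: BoneMask, voi: VOIConfig) -> TrabecularMetrics:
    """Tb.BV/TV, Tb.Th, Tb.Sp and Tb.N in the trabecular VOI."""
    region, _ = extract_trabecular_voi(mask, voi)
    bone = mask.data & region
    if not bone.any():
        raise ValueError("no bone in the trabecular VOI")
    frac = bvtv(bone, region)
    th = tb_th(bone, mask.spacing)
    sp = tb_sp(bone, region, mask.spacing)
    return TrabecularMetrics(frac, th, sp, tb_n(frac, th))


# ---------------------------------------------------------------------------
# cortical VOI
# ---------------------------------------------------------------------------

def cortical_metrics(mask: BoneMask, voi: VOIConfig,
                     closing_radius_px: int = 10) -> CorticalMetrics:
    """Cortical morphometry in a VOI centred at the midshaft.

    Midshaft is taken as 50% of the computed tibia length. Per slice, after
    pore closing: Tt.Ar is the pixel area of the filled periosteal region
    and Ct.Ar the pixel area of the closed bone; both are averaged over the
    VOI. Ct.Th is the mean 3-D local thickness of the closed cortical phase.
    A non-annular (open) cross-section is flagged but still measured.
    """
    occ = np.flatnonzero(mask.data.any(axis=(1, 2)))
    if occ.size == 0:
        raise ValueError("empty mask")
    mid = 0.5 * (occ[0] + occ[-1])
    sp_mm = mask.spacing / 1000.0
    half = voi.cort_height_mm / 2.0
    z0 = max(int(round(mid - half / sp_mm)), 0)
    z1 = min(z0 + int(round(voi.cort_height_mm / sp_mm)), mask.shape[0])
    slab = BoneMask(np.zeros_like(mask.data), mask.spacing)
    slab.data[z0:z1] = mask.data[z0:z1]
    closed = close_cortical_pores(slab, radius_px=closing_radius_px)
    tt_px, ct_px = [], []
    open_warn = False
    for z in range(z0, z1):
        sl = closed.data[z]
        filled = ndimage.binary_fill_holes(sl)
        if sl.any() and not (filled & ~sl).any():
            open_warn = True  # no enclosed cavity: open or solid section
        tt_px.append(filled.sum())
        ct_px.append(sl.sum())
    area = (sp_mm) ** 2
    tt_ar = float(np.mean(tt_px) * area)
    ct_ar = float(np.mean(ct_px) * area)
    cort_phase = closed.data[z0:z1]
    box = _bounding_box(cort_phase, pad=1)
    th_map = local_thickness(cort_phase[box])
    ct_th = float(th_map[cort_phase[box]].mean() * mask.spacing)
    return CorticalMetrics(tt_ar, ct_ar, 100.0 * ct_ar / tt_ar, ct_th, open_warn)
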