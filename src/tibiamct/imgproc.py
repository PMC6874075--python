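"""Image I/O, densitometric calibration and the preprocessing/segmentation chain.

Conventions used throughout the package:

* images are 3-D arrays indexed ``(z, y, x)`` with isotropic spacing in μm;
* the Z axis is the longitudinal axis of the bone, slice 0 is proximal;
* greyscale values are mapped to tissue mineral density (TMD, mg HA/cc)
  through an affine calibration curve ``TMD = intercept + slope * grey``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """Raised for unsupported grid geometry (anisotropic spacing, bad shape)."""


class AmbiguityError(ValueError):
    """Raised when an automatic decision (threshold, axis) is not well posed."""


# six-connected 3-D structuring element (face neighbours only)
STRUCT_6 = ndimage.generate_binary_structure(3, 1)
# 26-connected (faces, edges and corners)
STRUCT_26 = ndimage.generate_binary_structure(3, 3)


@dataclass
class VoxelImage:
    """3-D scalar grid with isotropic spacing.

    Parameters
    ----------
    data
        Array of shape ``(nz, ny, nx)``; Z longitudinal, slice 0 proximal.
    spacing
        Isotropic voxel size in μm.
    value_kind
        ``"grey"`` for raw scanner values, ``"tmd"`` for calibrated
        mineral-density values in mg HA/cc.
    """

    data: np.ndarray
    spacing: float
    value_kind: str = "grey"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"expected a 3-D image, got ndim={self.data.ndim}")
        if not self.spacing > 0:
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        if self.value_kind not in ("grey", "tmd"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "VoxelImage":
        return VoxelImage(self.data.copy(), self.spacing, self.value_kind)


@dataclass
class BoneMask:
    """Binary grid marking the segmented bone phase."""

    data: np.ndarray
    spacing: float
    threshold: float | None = None  # provenance: threshold used, if any

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise GeometryError("mask must be 3-D")
        if not self.spacing > 0:
            raise GeometryError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def copy(self) -> "BoneMask":
        return BoneMask(self.data.copy(), self.spacing, self.threshold)


@dataclass
class CalibrationCurve:
    """Affine grey → TMD map, ``TMD = intercept + slope * grey``."""

    slope: float  # (mg HA/cc) per grey unit
    intercept: float  # mg HA/cc
    source_densities: tuple = ()
    residuals: tuple = ()

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be non-zero")

    def grey_to_tmd(self, grey):
        return self.intercept + self.slope * np.asarray(grey, dtype=float)

    def tmd_to_grey(self, tmd):
        return (np.asarray(tmd, dtype=float) - self.intercept) / self.slope


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_image(image: VoxelImage, path: str | Path, format: str | None = None) -> Path:
    """Write a :class:`VoxelImage` as TIFF stack, MetaImage (MHD+RAW) or NIfTI-1.

    The format is inferred from the suffix when not given
    (``.tif/.tiff``, ``.mhd``, ``.nii/.nii.gz``).
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff-stack":
        import tifffile

        tifffile.imwrite(
            path,
            np.asarray(image.data),
            metadata={"spacing_um": image.spacing, "value_kind": image.value_kind},
        )
    elif fmt == "mhd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.asarray(image.data))
        img.SetSpacing((float(image.spacing),) * 3)
        sitk.WriteImage(img, str(path))
    elif fmt == "nifti":
        import nibabel as nib

        affine = np.diag([image.spacing, image.spacing, image.spacing, 1.0])
        # nibabel is x-fastest: store transposed so that on disk axes are (x, y, z)
        nib.save(nib.Nifti1Image(np.asarray(image.data).T, affine), str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_image(path: str | Path, format: str | None = None,
               spacing: float | None = None) -> VoxelImage:
    """Read an image stack and normalise it to the package axis convention."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff-stack":
        import tifffile

        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        sp = spacing if spacing is not None else meta.get("spacing_um")
        if sp is None:
            raise GeometryError("TIFF stack carries no spacing; pass spacing=")
        kind = meta.get("value_kind", "grey")
        return VoxelImage(data, float(sp), kind)
    if fmt == "mhd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        sp3 = img.GetSpacing()
        if not np.allclose(sp3, sp3[0]):
            raise GeometryError(f"anisotropic spacing unsupported: {sp3}")
        return VoxelImage(sitk.GetArrayFromImage(img), float(sp3[0]))
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0]):
            raise GeometryError(f"anisotropic spacing unsupported: {zooms}")
        sp = spacing if spacing is not None else float(zooms[0])
        return VoxelImage(np.asarray(img.dataobj).T, sp)
    raise ValueError(f"unknown format {fmt!r}")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".tif", ".tiff")):
        return "tiff-stack"
    if name.endswith(".mhd"):
        return "mhd"
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    raise ValueError(f"cannot infer image format from {path.name!r}")


def write_mask(mask: BoneMask, path: str | Path, format: str | None = None) -> Path:
    """Store a mask as an 8-bit {0,1} image."""
    return write_image(
        VoxelImage(mask.data.astype(np.uint8), mask.spacing), path, format
    )


def read_mask(path: str | Path, format: str | None = None,
              spacing: float | None = None) -> BoneMask:
    img = read_image(path, format, spacing)
    return BoneMask(img.data > 0, img.spacing)


# ---------------------------------------------------------------------------
# Densitometric calibration
# ---------------------------------------------------------------------------

def fit_calibration(insert_means) -> CalibrationCurve:
    """Least-squares line mapping mean insert grey values to known densities.

    Parameters
    ----------
    insert_means
        Sequence of ``(grey, density_mg_ha_cc)`` pairs, one per insert of the
        densitometric quality-control phantom.
    """
    pts = np.asarray(insert_means, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need at least two (grey, density) points")
    grey, dens = pts[:, 0], pts[:, 1]
    if np.ptp(grey) == 0:
        raise ValueError("grey values are all identical; line is undetermined")
    A = np.stack([grey, np.ones_like(grey)], axis=1)
    (slope, intercept), *_ = np.linalg.lstsq(A, dens, rcond=None)
    resid = dens - (intercept + slope * grey)
    return CalibrationCurve(
        float(slope), float(intercept),
        source_densities=tuple(dens), residuals=tuple(resid),
    )


def to_tmd(image: VoxelImage, curve: CalibrationCurve) -> VoxelImage:
    """Convert a greyscale image to TMD (mg HA/cc), clamping negatives to 0.

    Density is physically non-negative and the background insert of the
    calibration phantom is defined at 0 mg HA/cc, so values mapping below
    zero are clamped.
    """
    if image.value_kind != "grey":
        raise ValueError("image is already calibrated (value_kind != 'grey')")
    tmd = np.maximum(curve.grey_to_tmd(image.data), 0.0)
    return VoxelImage(tmd, image.spacing, value_kind="tmd")


# ---------------------------------------------------------------------------
# Preprocessing / segmentation
# ---------------------------------------------------------------------------

def gaussian_filter(image: VoxelImage, sigma: float = 0.65) -> VoxelImage:
    """Gaussian low-pass with a 3×3×3 support (σ in voxel units).

    The discrete kernel is the normalised tabulation of
    ``exp(-r² / (2σ²))`` over the 27 offsets of the 3³ neighbourhood;
    boundary handled by reflection.
    """
    # truncate chosen so the kernel radius is exactly 1 voxel
    out = ndimage.gaussian_filter(
        np.asarray(image.data, dtype=float), sigma=sigma, truncate=1.0 / sigma,
        mode="reflect",
    )
    return VoxelImage(out, image.spacing, image.value_kind)


def compute_threshold(image: VoxelImage, voi: np.ndarray | None = None,
                      bins: int = 256, smooth_window: int = 5,
                      return_peaks: bool = False):
    """Global threshold at the midpoint of the bone and background modes.

    A 256-bin histogram of the (optionally VOI-restricted) grey values is
    smoothed with a moving average and the two most prominent local maxima
    are taken as the background and bone peaks; the threshold is the mean of
    the two peak grey levels.

    Raises
    ------
    AmbiguityError
        If fewer than two modes are found; the caller may then supply a
        manual threshold.
    """
    from scipy.signal import find_peaks

    values = np.asarray(image.data, dtype=float)
    if voi is not None:
        values = values[np.asarray(voi, dtype=bool)]
    values = values.ravel()
    if values.size == 0:
        raise ValueError("empty VOI")
    hist, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(hist.astype(float), kernel, mode="same")
    # pad with -inf so modes at the histogram ends are detectable; a mode
    # must rise at least 5% of the tallest peak to count as a second phase
    padded = np.concatenate([[-np.inf], smoothed, [-np.inf]])
    peaks, props = find_peaks(padded, prominence=0.05 * smoothed.max())
    peaks -= 1
    if len(peaks) < 2:
        raise AmbiguityError(
            "histogram is not bimodal; supply a manual threshold"
        )
    order = np.argsort(props["prominences"])[::-1]
    two = np.sort(peaks[order[:2]])
    t = float(0.5 * (centers[two[0]] + centers[two[1]]))
    if return_peaks:
        return t, (float(centers[two[0]]), float(centers[two[1]]))
    return t


def segment(image: VoxelImage, threshold: float) -> BoneMask:
    """Single-level threshold; ``voxel >= threshold`` is bone (inclusive rule)."""
    return BoneMask(np.asarray(image.data) >= threshold, image.spacing, threshold)


def despeckle(mask: BoneMask, min_size: int = 10) -> BoneMask:
    """Remove 3-D bone volumes smaller than ``min_size`` voxels.

    Components are 26-connected; "smaller than" is strict, so a component of
    exactly ``min_size`` voxels is retained.
    """
    labels, n = ndimage.label(mask.data, structure=STRUCT_26)
    if n == 0:
        return mask.copy()
    counts = np.bincount(labels.ravel())
    keep = counts >= min_size
    keep[0] = False
    return BoneMask(keep[labels], mask.spacing, mask.threshold)


def largest_component(mask: BoneMask, connectivity: int = 6) -> BoneMask:
    """Keep only the largest connected component (6-connected by default).

    Ties are broken deterministically in favour of the component containing
    the lowest linear voxel index (labels are assigned in raster order).
    """
    if mask.count() == 0:
        raise ValueError("empty mask has no components")
    struct = STRUCT_6 if connectivity == 6 else STRUCT_26
    labels, n = ndimage.label(mask.data, structure=struct)
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1  # argmax returns first max: lowest label id
    return BoneMask(labels == best, mask.spacing, mask.threshold)


def close_cortical_pores(mask: BoneMask, radius_px: int = 10) -> BoneMask:
    """Per-slice (XY) morphological closing with a discrete disk.

    Fills intracortical pores so that cortical area and thickness are
    measured on the solid envelope of the cortex. Dilation and erosion with
    the Euclidean disk are computed through per-slice distance transforms
    (equivalent to the explicit structuring-element operations, but much
    faster on stacks).
    """
    out = _disk_closing(mask.data, radius_px)
    # closing is extensive; guard against border clipping
    out |= mask.data
    return BoneMask(out, mask.spacing, mask.threshold)


def _disk_closing(data: np.ndarray, radius_px: int) -> np.ndarray:
    """Slice-wise (XY) binary closing with a Euclidean disk of given radius."""
    if not data.any():
        return data.copy()
    pad = radius_px + 1  # border-safe: dilation may overrun the grid
    if data.ndim == 3:
        padded = np.pad(data, ((0, 0), (pad, pad), (pad, pad)))
        samp = (1e9, 1.0, 1.0)  # huge Z sampling: EDT acts per slice
        crop = (slice(None), slice(pad, -pad), slice(pad, -pad))
    else:
        padded = np.pad(data, pad)
        samp = (1.0, 1.0)
        crop = (slice(pad, -pad), slice(pad, -pad))
    dist_to_fg = ndimage.distance_transform_edt(~padded, sampling=samp)
    dilated = dist_to_fg <= radius_px
    dist_to_bg = ndimage.distance_transform_edt(dilated, sampling=samp)
    return (dist_to_bg > radius_px)[crop]


# ---------------------------------------------------------------------------
# Alignment and length
# ---------------------------------------------------------------------------

@dataclass
class AlignmentTransform:
    """Rigid rotation (about the grid centre) mapping the bone axis to Z."""

    rotation: np.ndarray  # 3x3, applied to (z, y, x) offsets from centre
    mirrored: bool = False


def align_principal_axis(mask: BoneMask, image: VoxelImage | None = None,
                         mirror: bool = False, min_anisotropy: float = 1.05):
    """Rotate so the first principal axis of the bone voxels lies along Z.

    This replaces image-to-image rigid registration for phantom data, which
    is generated in a known frame. Masks are resampled with nearest
    neighbour, greyscale images with trilinear interpolation. ``mirror``
    additionally flips the X axis (left limbs are mirrored so that left and
    right share an anatomical frame).

    Returns ``(aligned_mask, transform)`` or
    ``(aligned_mask, aligned_image, transform)`` when an image is supplied.
    """
    coords = np.argwhere(mask.data)
    if coords.shape[0] < 2:
        raise ValueError("mask too small to define an axis")
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] < min_anisotropy * evals[-2]:
        raise AmbiguityError("no dominant principal axis (isotropic blob)")
    axis = evecs[:, -1]
    if axis[0] < 0:
        axis = -axis
    rot = _rotation_to_z(axis)
    aligned_mask_data = _apply_rotation(mask.data.astype(float), rot, order=0) > 0.5
    if mirror:
        aligned_mask_data = aligned_mask_data[:, :, ::-1].copy()
    tr = AlignmentTransform(rotation=rot, mirrored=mirror)
    out_mask = BoneMask(aligned_mask_data, mask.spacing, mask.threshold)
    if image is None:
        return out_mask, tr
    img_data = _apply_rotation(np.asarray(image.data, dtype=float), rot, order=1)
    if mirror:
        img_data = img_data[:, :, ::-1].copy()
    return out_mask, VoxelImage(img_data, image.spacing, image.value_kind), tr


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix sending ``axis`` (unit, zyx order) to the Z unit vector."""
    z = np.array([1.0, 0.0, 0.0])  # axis 0 is Z in our (z, y, x) convention
    v = np.cross(axis, z)
    c = float(np.dot(axis, z))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _apply_rotation(data: np.ndarray, rot: np.ndarray, order: int) -> np.ndarray:
    center = (np.array(data.shape) - 1) / 2.0
    inv = rot.T  # inverse of a rotation
    offset = center - inv @ center
    return ndimage.affine_transform(data, inv, offset=offset, order=order,
                                    mode="constant", cval=0.0)


def tibia_length(mask: BoneMask) -> float:
    """Bone length in mm: proximal-to-distal slice extent (slab convention).

    ``(z_last - z_first + 1) * spacing`` so a single-slice object has one
    voxel spacing of length.
    """
    occ = np.flatnonzero(mask.data.any(axis=(1, 2)))
    if occ.size == 0:
        raise ValueError("empty mask has no length")
    return float((occ[-1] - occ[0] + 1) * mask.spacing / 1000.0)
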