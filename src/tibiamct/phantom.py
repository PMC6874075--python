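"""Synthetic left/right tibia-like voxel phantoms with known ground truth.

The phantom is deliberately simple rather than anatomically faithful: a
cortical shell (annulus with a longitudinally varying periosteal radius)
around a medullary canal, plus a proximal trabecular lattice of axis-aligned
rods placed on a jittered grid. This geometry gives analytic ground truth
for the quantities the analysis chain measures — cross-sectional areas, rod
count (trabecular number), rod diameter (trabecular thickness) and the
per-voxel mineral-density field — while still exercising every stage of the
pipeline (calibration, filtering, thresholding, despeckling, VOI logic,
partitioning, meshing).

Left/right pairs share geometry: the right image is the mirrored left with a
controlled "radiation" effect applied (fewer rods, thinner/thicker rods,
scaled periosteal area) and an independent noise realisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .imgproc import VoxelImage


class PhantomSizingError(ValueError):
    """Image too small to contain the requested geometry."""


@dataclass
class RadiationEffect:
    """Injectable right-side effect sizes, in percent change.

    ``delta_tb_n_pct`` changes the rod count, ``delta_tb_th_pct`` the rod
    diameter and ``delta_tt_ar_pct`` the periosteal cross-sectional area.
    The right limb is the irradiated one; zero effect makes the right
    phantom the mirrored left up to the noise realisation.
    """

    delta_tb_n_pct: float = 0.0
    delta_tb_th_pct: float = 0.0
    delta_tt_ar_pct: float = 0.0
    applies_to: str = "R"

    def __post_init__(self) -> None:
        for v in (self.delta_tb_n_pct, self.delta_tb_th_pct, self.delta_tt_ar_pct):
            if v <= -100:
                raise ValueError("percent changes must be > -100")


@dataclass
class PhantomSpec:
    """Geometry, density and noise description of one left/right pair.

    Lengths are in μm. The periosteal radius and cortical thickness hold
    their first profile value (a wide metaphysis with thin cortex) over the
    trabecular region and taper linearly to the second value at the distal
    end, emulating the metaphysis-to-shaft transition of a (scaled-down)
    tibia. Defaults give ~50 μm rods at 170 μm pitch inside a 390 μm
    medullary canal (Tb.Th ≈ 50 μm, Tb.N ≈ 1-1.5 /mm, Tb.BV/TV ≈ 5-8%,
    values typical of the mouse proximal tibia) and a bone tissue density
    of 720 mg HA/cc.
    """

    image_shape: tuple = (380, 104, 104)  # (nz, ny, nx)
    spacing: float = 10.4  # μm/voxel
    outer_radius_profile: tuple = (500.0, 300.0)  # periosteal radius μm (meta, dist)
    cortical_thickness_profile: tuple = (110.0, 250.0)  # μm (meta, dist)
    trabecular_region: tuple = (150.0, 1350.0)  # longitudinal extent μm
    rod_thickness: float = 50.0  # μm (rod diameter)
    rod_spacing: float = 170.0  # μm (lattice pitch)
    rod_margin: float = 30.0  # μm clearance from the endosteal wall
    tissue_density: float = 720.0  # mg HA/cc
    background_density: float = 0.0  # mg HA/cc
    noise_sd: float = 0.0  # grey units
    grey_slope: float = 0.7  # (mg HA/cc) per grey: TMD = intercept + slope*grey
    grey_intercept: float = -50.0  # mg HA/cc
    effect: RadiationEffect = field(default_factory=RadiationEffect)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.effect, dict):
            self.effect = RadiationEffect(**self.effect)
        ro = np.asarray(self.outer_radius_profile, dtype=float)
        ct = np.asarray(self.cortical_thickness_profile, dtype=float)
        if not np.all(ro > ct):
            raise ValueError("outer radius must exceed cortical thickness")
        if self.rod_thickness >= self.rod_spacing:
            raise ValueError("rod_thickness must be smaller than rod_spacing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.grey_slope == 0:
            raise ValueError("grey_slope must be non-zero")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        path.write_text(json.dumps(d, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        d = json.loads(Path(path).read_text())
        d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)


# label values of the noiseless field
BACKGROUND, CORTEX, ROD, FIBULA = 0, 1, 2, 3


@dataclass
class GroundTruth:
    """Exact description of the generated pair, before noise.

    ``labels_left`` / ``labels_right`` are the noiseless label fields
    (0 background, 1 cortex, 2 trabecular rod, 3 synthetic fibula) from
    which every ground-truth quantity is recomputable by direct counting.
    """

    rod_count_left: int
    rod_count_right: int
    rod_diameter_left_um: float
    rod_diameter_right_um: float
    outer_radius_left_um: tuple
    outer_radius_right_um: tuple
    cortical_thickness_um: tuple
    trabecular_slices: tuple  # (z0, z1) slice indices, half-open
    reference_slice: int  # proximal end of the trabecular region
    tissue_density: float
    spacing: float
    labels_left: np.ndarray = field(repr=False)
    labels_right: np.ndarray = field(repr=False)

    def tmd_field(self, side: str) -> np.ndarray:
        labels = self.labels_left if side == "L" else self.labels_right
        return (labels > 0) * self.tissue_density

    def tt_ar_analytic_mm2(self, side: str = "L") -> float:
        """Analytic periosteal area π·R² in the metaphyseal plateau, mm²."""
        r_um = (self.outer_radius_left_um if side == "L"
                else self.outer_radius_right_um)[0]
        return float(np.pi * (r_um / 1000.0) ** 2)

    def summary(self) -> dict:
        d = {k: v for k, v in asdict(self).items()
             if k not in ("labels_left", "labels_right")}
        return d

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.summary(), indent=2, default=_jsonify))
        return path


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _profiles(spec: PhantomSpec, outer_scale: float = 1.0):
    """Per-slice periosteal radius and cortical thickness (μm).

    Both hold their metaphyseal value over the trabecular region and taper
    linearly to the distal value at the end of the image.
    """
    ro = np.asarray(spec.outer_radius_profile, dtype=float) * outer_scale
    ct = np.asarray(spec.cortical_thickness_profile, dtype=float)
    nz = spec.image_shape[0]
    z_um = (np.arange(nz) + 0.5) * spec.spacing
    z1u = spec.trabecular_region[1]
    length = nz * spec.spacing
    t = np.clip((z_um - z1u) / max(length - z1u, 1e-9), 0.0, 1.0)
    r_out = ro[0] + (ro[1] - ro[0]) * t
    thick = ct[0] + (ct[1] - ct[0]) * t
    return z_um, r_out, thick


def _rod_centers(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid rod centre positions (μm, relative to the bone axis).

    Rods must fit inside the medullary canal over the whole trabecular
    region with ``rod_margin`` clearance from the endosteal wall.
    """
    z_um, r_out, thick = _profiles(spec)
    z0u, z1u = spec.trabecular_region
    in_trab = (z_um >= z0u) & (z_um < z1u)
    if not in_trab.any():
        raise PhantomSizingError("trabecular region contains no slice")
    r_inner = r_out - thick
    r_avail = float(r_inner[in_trab].min()) - spec.rod_margin - spec.rod_thickness / 2
    if r_avail <= spec.rod_thickness:
        raise PhantomSizingError("medullary canal too small for the rod lattice")
    s = spec.rod_spacing
    n_half = int(np.floor(r_avail / s)) + 1
    grid = np.arange(-n_half, n_half + 1) * s
    gy, gx = np.meshgrid(grid, grid, indexing="ij")
    jitter = rng.uniform(-0.15 * s, 0.15 * s, size=(2,) + gy.shape)
    cy = gy + jitter[0]
    cx = gx + jitter[1]
    keep = np.hypot(cy, cx) <= r_avail
    return np.stack([cy[keep], cx[keep]], axis=1)


def _build_labels(spec: PhantomSpec, centers: np.ndarray, rod_radius_um: float,
                  outer_scale: float, fibula: bool) -> np.ndarray:
    nz, ny, nx = spec.image_shape
    z_um, r_out, thick = _profiles(spec, outer_scale)
    c_y = (ny - 1) / 2.0 * spec.spacing
    c_x = (nx - 1) / 2.0 * spec.spacing
    yy = np.arange(ny) * spec.spacing - c_y
    xx = np.arange(nx) * spec.spacing - c_x
    Y, X = np.meshgrid(yy, xx, indexing="ij")
    R2 = Y * Y + X * X

    max_r = r_out.max() + (180.0 + 60.0 if fibula else 0.0)
    if max_r > min(c_y, c_x) - spec.spacing:
        raise PhantomSizingError(
            f"cross-section of {ny}x{nx} voxels cannot contain radius {max_r:.0f} um"
        )

    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    r_in = r_out - thick
    z0u, z1u = spec.trabecular_region
    if z1u > nz * spec.spacing:
        raise PhantomSizingError("trabecular region extends beyond the image")
    in_trab = (z_um >= z0u) & (z_um < z1u)

    rod_slice = np.zeros((ny, nx), dtype=bool)
    rr2 = rod_radius_um**2
    for cy, cx in centers:
        rod_slice |= (Y - cy) ** 2 + (X - cx) ** 2 <= rr2

    fib_slice = np.zeros((ny, nx), dtype=bool)
    if fibula:
        # small off-axis rod alongside the tibia, separated from the cortex
        fib_c = r_out.max() + 120.0
        fib_slice = (Y - fib_c) ** 2 + X**2 <= 60.0**2

    for z in range(nz):
        ring = (R2 <= r_out[z] ** 2) & (R2 >= r_in[z] ** 2)
        labels[z][ring] = CORTEX
        if in_trab[z]:
            labels[z][rod_slice & (labels[z] == 0)] = ROD
        if fibula:
            labels[z][fib_slice & (labels[z] == 0)] = FIBULA
    return labels


def generate_tibia_phantom(spec: PhantomSpec, fibula: bool = False):
    """Generate a matched left/right pair of greyscale tibia phantoms.

    Returns ``(left, right, ground_truth)``. The right image is the mirrored
    left (reflection of the X axis, i.e. across the sagittal plane) with the
    spec's :class:`RadiationEffect` applied and an independent noise draw.
    Identical ``spec`` (including seed) gives bit-identical output.

    ``fibula=True`` adds a small off-axis rod to both sides, used to test
    the fibula-exclusion rule of the densitometric VOI.
    """
    rng_geom = np.random.default_rng([spec.seed, 0])
    rng_noise_l = np.random.default_rng([spec.seed, 1])
    rng_noise_r = np.random.default_rng([spec.seed, 2])
    rng_drop = np.random.default_rng([spec.seed, 3])

    centers = _rod_centers(spec, rng_geom)
    n_left = centers.shape[0]
    eff = spec.effect
    n_right = int(round(n_left * (1.0 + eff.delta_tb_n_pct / 100.0)))
    n_right = max(n_right, 0)
    if n_right < n_left:
        keep = rng_drop.choice(n_left, size=n_right, replace=False)
        centers_r = centers[np.sort(keep)]
    else:
        centers_r = centers
    rod_r_l = spec.rod_thickness / 2.0
    rod_r_r = rod_r_l * (1.0 + eff.delta_tb_th_pct / 100.0)
    outer_scale_r = float(np.sqrt(1.0 + eff.delta_tt_ar_pct / 100.0))

    labels_l = _build_labels(spec, centers, rod_r_l, 1.0, fibula)
    labels_r_unmirrored = _build_labels(spec, centers_r, rod_r_r, outer_scale_r,
                                        fibula)
    labels_r = labels_r_unmirrored[:, :, ::-1].copy()

    def to_grey(labels, rng):
        tmd = np.where(labels > 0, spec.tissue_density, spec.background_density)
        grey = (tmd - spec.grey_intercept) / spec.grey_slope
        if spec.noise_sd > 0:
            grey = grey + rng.normal(0.0, spec.noise_sd, size=grey.shape)
        return grey

    left = VoxelImage(to_grey(labels_l, rng_noise_l), spec.spacing)
    right = VoxelImage(to_grey(labels_r, rng_noise_r), spec.spacing)

    z0 = int(np.ceil(spec.trabecular_region[0] / spec.spacing - 0.5))
    z1 = int(np.ceil(spec.trabecular_region[1] / spec.spacing - 0.5))
    ro = tuple(np.asarray(spec.outer_radius_profile, dtype=float))
    gt = GroundTruth(
        rod_count_left=int(n_left),
        rod_count_right=int(centers_r.shape[0]),
        rod_diameter_left_um=2 * rod_r_l,
        rod_diameter_right_um=2 * rod_r_r,
        outer_radius_left_um=ro,
        outer_radius_right_um=tuple(np.asarray(ro) * outer_scale_r),
        cortical_thickness_um=tuple(
            np.asarray(spec.cortical_thickness_profile, dtype=float)
        ),
        trabecular_slices=(z0, z1),
        reference_slice=z0,
        tissue_density=spec.tissue_density,
        spacing=spec.spacing,
        labels_left=labels_l,
        labels_right=labels_r,
    )
    return left, right, gt


def calibration_curve_of(spec: PhantomSpec):
    """The grey → TMD calibration curve a phantom was generated with."""
    from .imgproc import CalibrationCurve

    return CalibrationCurve(spec.grey_slope, spec.grey_intercept)


# ---------------------------------------------------------------------------
# densitometric calibration phantom
# ---------------------------------------------------------------------------

def generate_calibration_phantom(densities, grey_slope: float,
                                 grey_intercept: float, noise_sd: float = 0.0,
                                 seed: int = 0, insert_radius_px: int = 8,
                                 n_slices: int = 12):
    """Phantom with one homogeneous cylindrical insert per known density.

    Mimics the weekly quality-control phantom: each insert is a cylinder of
    uniform equivalent density (mg HA/cc) and the image grey values follow
    ``grey = grey_intercept + grey_slope * density`` plus Gaussian noise.

    Returns ``(image, insert_labels)`` where ``insert_labels`` is an integer
    field (0 = background, k = insert index k in ``densities`` order + 1).
    """
    densities = list(densities)
    if len(densities) < 2:
        raise ValueError("need at least two insert densities")
    if len(set(densities)) != len(densities):
        raise ValueError("insert densities must be distinct")
    pitch = 3 * insert_radius_px
    nx = pitch * len(densities)
    ny = pitch
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    labels2d = np.zeros((ny, nx), dtype=np.int32)
    for k in range(len(densities)):
        cy, cx = ny / 2.0 - 0.5, pitch * (k + 0.5) - 0.5
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= insert_radius_px**2
        labels2d[inside] = k + 1
    labels = np.broadcast_to(labels2d, (n_slices, ny, nx)).copy()
    dens_of = np.concatenate([[0.0], np.asarray(densities, dtype=float)])
    grey = grey_intercept + grey_slope * dens_of[labels]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        grey = grey + rng.normal(0.0, noise_sd, size=grey.shape)
    return VoxelImage(grey, spacing=10.4), labels
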