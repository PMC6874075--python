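"""End-to-end study runner: phantoms → preprocessing → measurements → stats.

A single :class:`RunConfig` drives the whole chain. For every mouse a
left/right phantom pair is generated (or images are loaded), preprocessed
(calibration, Gaussian filter, threshold, despeckle), measured
(morphometry, 40-partition densitometry, optional micro-FE) and the pooled
records are fed to the paired radiation-effect analysis. All outputs are
plain CSV/JSON/markdown with the config hash and seed embedded for
provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import densitometry, imgproc, microfe, morphometry, stats
from .imgproc import BoneMask, VoxelImage
from .morphometry import VOIConfig
from .microfe import FEModelSpec
from .phantom import PhantomSpec, RadiationEffect, generate_tibia_phantom

log = logging.getLogger("tibiamct")


class StageError(RuntimeError):
    """Error raised by a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Configuration of a full phantom study run."""

    n_mice: int = 4
    strains: tuple = ("B6", "BAL")  # assigned round-robin over mice
    interventions: tuple = ("WT",)
    phantom: PhantomSpec = field(
        default_factory=lambda: PhantomSpec(noise_sd=30.0))
    effect: RadiationEffect = field(default_factory=RadiationEffect)
    biological_cv: float = 0.03  # between-mouse geometry/density variation
    voi: VOIConfig = field(default_factory=VOIConfig)
    fe: FEModelSpec = field(default_factory=FEModelSpec)
    run_fe: bool = True
    fe_downsample: int = 4  # coarsen masks before meshing (whole-bone FE)
    run_partitions: bool = True
    stats_parameters: tuple = ("Tb.BV/TV", "Tb.Th", "Tb.Sp", "Tb.N")
    stats_split: str | None = None
    output_dir: str | Path = "tibiamct_out"
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths and logging excluded)."""
        d = _serializable(self)
        d.pop("output_dir", None)
        d.pop("log_level", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _serializable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _serializable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_serializable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


# ---------------------------------------------------------------------------
# specimen-level processing
# ---------------------------------------------------------------------------

def preprocess(image: VoxelImage, curve, despeckle_min: int = 10,
               threshold: float | None = None):
    """Filter, calibrate, segment and despeckle one greyscale image.

    Returns ``(tmd_image, bone_mask)``. The threshold is computed from the
    histogram of the filtered greyscale image unless supplied.
    """
    filtered = imgproc.gaussian_filter(image)
    if threshold is None:
        threshold = imgproc.compute_threshold(filtered)
    mask = imgproc.segment(filtered, threshold)
    mask = imgproc.despeckle(mask, min_size=despeckle_min)
    tmd = imgproc.to_tmd(filtered, curve)
    return tmd, mask


def run_specimen(config: RunConfig, image: VoxelImage, curve,
                 reference_slice: int) -> dict:
    """Process one specimen image into a dict of parameter values."""
    results: dict = {}
    try:
        tmd, mask = preprocess(image, curve)
    except Exception as e:  # noqa: BLE001
        raise StageError("preprocess", e) from e
    results["_mask"] = mask
    results["_tmd"] = tmd
    try:
        results["Length"] = imgproc.tibia_length(mask)
    except Exception as e:  # noqa: BLE001
        raise StageError("length", e) from e
    try:
        voi = VOIConfig(reference_slice=reference_slice,
                        trab_offset_mm=config.voi.trab_offset_mm,
                        trab_height_mm=config.voi.trab_height_mm,
                        cort_height_mm=config.voi.cort_height_mm)
        tm = morphometry.trabecular_metrics(mask, voi)
        results["Tb.BV/TV"] = tm.bvtv_pct
        results["Tb.Th"] = tm.tb_th_um
        results["Tb.Sp"] = tm.tb_sp_um
        results["Tb.N"] = tm.tb_n_per_mm
        cm = morphometry.cortical_metrics(mask, voi)
        results["Tt.Ar"] = cm.tt_ar_mm2
        results["Ct.Ar"] = cm.ct_ar_mm2
        results["Ct.Ar/Tt.Ar"] = cm.ct_ar_tt_ar_pct
        results["Ct.Th"] = cm.ct_th_um
    except Exception as e:  # noqa: BLE001
        raise StageError("morphometry", e) from e
    try:
        voi_mask, srange = densitometry.densitometric_voi(
            mask, start_slice=reference_slice)
        results["Total BMC"] = densitometry.total_bmc(tmd, voi_mask)
        if config.run_partitions:
            grid = densitometry.partition(voi_mask, srange)
            results["_partitions"] = densitometry.partition_metrics(
                tmd, voi_mask, grid)
    except Exception as e:  # noqa: BLE001
        raise StageError("densitometry", e) from e
    if config.run_fe:
        try:
            fe_mask = microfe.downsample_mask(voi_mask, config.fe_downsample)
            mesh = microfe.build_mesh(fe_mask)
            results["Stiffness"] = microfe.solve_stiffness(
                mesh, config.fe).stiffness_n_per_mm
            results["Strength"] = microfe.solve_strength(
                mesh, config.fe).strength_n
        except Exception as e:  # noqa: BLE001
            raise StageError("microfe", e) from e
    return results


# ---------------------------------------------------------------------------
# study-level orchestration
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    records: pd.DataFrame
    effects: pd.DataFrame
    partition_diffs: dict
    failures: list
    config_hash: str
    seed: int


def run_study(config: RunConfig) -> StudyResult:
    """Run the full paired study on a phantom cohort and write reports."""
    logging.basicConfig(level=config.log_level)
    if config.n_mice < 1:
        raise ValueError("cohort must contain at least one mouse")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    curve = imgproc.CalibrationCurve(config.phantom.grey_slope,
                                     config.phantom.grey_intercept)
    rows, failures = [], []
    partition_diffs: dict = {}
    for m in range(config.n_mice):
        strain = config.strains[m % len(config.strains)]
        interv = config.interventions[(m // len(config.strains))
                                      % len(config.interventions)]
        mouse_id = f"m{m + 1:03d}"
        kwargs = _phantom_kwargs(config.phantom)
        if config.biological_cv > 0:
            # per-mouse anatomy: mild multiplicative variation of geometry
            # and tissue density, shared by both limbs of the mouse
            brng = np.random.default_rng([config.seed, 7, m])
            cv = config.biological_cv
            kwargs["outer_radius_profile"] = tuple(
                np.asarray(kwargs["outer_radius_profile"])
                * brng.normal(1.0, cv))
            kwargs["cortical_thickness_profile"] = tuple(
                np.asarray(kwargs["cortical_thickness_profile"])
                * brng.normal(1.0, cv))
            kwargs["rod_thickness"] *= brng.normal(1.0, cv)
            kwargs["tissue_density"] *= brng.normal(1.0, cv)
        pspec = PhantomSpec(**kwargs, effect=config.effect,
                            seed=int(config.seed * 10_000 + m))
        left, right, gt = generate_tibia_phantom(pspec)
        per_side = {}
        # left tibiae are horizontally flipped into the right-limb frame so
        # paired comparisons (and quadrant labels) line up anatomically
        left_flipped = VoxelImage(left.data[:, :, ::-1].copy(), left.spacing,
                                  left.value_kind)
        for side, img in (("L", left_flipped), ("R", right)):
            log.info("processing %s side %s", mouse_id, side)
            try:
                res = run_specimen(config, img, curve, gt.reference_slice)
            except StageError as e:
                log.error("%s/%s: %s", mouse_id, side, e)
                failures.append((mouse_id, side, str(e)))
                continue
            per_side[side] = res
            for param, value in res.items():
                if param.startswith("_"):
                    continue
                rows.append({"mouse_id": mouse_id, "strain": strain,
                             "intervention": interv, "side": side,
                             "parameter": param, "value": value})
        if ("L" in per_side and "R" in per_side
                and "_partitions" in per_side["L"]):
            partition_diffs[mouse_id] = densitometry.paired_partition_difference(
                per_side["L"]["_partitions"], per_side["R"]["_partitions"])
            for side in ("L", "R"):
                _write_csv(per_side[side]["_partitions"],
                           outdir / f"partitions_{mouse_id}_{side}.csv",
                           chash, config.seed)
    records = pd.DataFrame(rows)
    if records.empty:
        raise RuntimeError("all specimens failed")
    _write_csv(records, outdir / "records.csv", chash, config.seed)

    estimates = []
    for param in config.stats_parameters:
        try:
            ests, _checks = stats.analyze_parameter(
                records, param, split=config.stats_split)
            estimates.extend(ests)
        except ValueError as e:
            failures.append(("stats", param, str(e)))
    effects = stats.effects_table(estimates) if estimates else pd.DataFrame()
    if not effects.empty:
        _write_csv(effects, outdir / "effects.csv", chash, config.seed)
    _write_report(outdir / "report.md", config, records, effects, failures)
    return StudyResult(records, effects, partition_diffs, failures,
                       chash, config.seed)


def _phantom_kwargs(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    d.pop("effect")
    d.pop("seed")
    d["image_shape"] = tuple(d["image_shape"])
    return d


def _write_csv(df: pd.DataFrame, path: Path, chash: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tibiamct config={chash} seed={seed}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_output_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _write_report(path: Path, config: RunConfig, records: pd.DataFrame,
                  effects: pd.DataFrame, failures: list) -> None:
    lines = ["# Paired radiation-effect study report", "",
             f"- config hash: `{config.config_hash()}`",
             f"- seed: {config.seed}",
             f"- mice: {records['mouse_id'].nunique()}",
             f"- specimens: {len(records.groupby(['mouse_id', 'side']))}",
             ""]
    if not effects.empty:
        lines += ["## Radiation & side effects", "",
                  effects.to_markdown(index=False), ""]
    if failures:
        lines += ["## Failures", ""] + [f"- {f}" for f in failures] + [""]
    path.write_text("\n".join(lines))
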