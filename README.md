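# tibiamct

Whole-tibia microCT analysis for paired left/right mouse studies:
standard trabecular and cortical morphometry, spatially resolved
densitometry (40-partition bone mineral maps), voxel-based
micro-finite-element mechanics, and the paired mixed-model statistics used
to quantify the effect of repeated *in vivo* irradiation on the scanned
(right) limb relative to its non-irradiated (left) control.

The package targets researchers running longitudinal *in vivo* microCT
studies in rodents who need a reproducible, fully scriptable re-implementation
of the usual commercial tool chain (scanner calibration → segmentation →
CTAn-style morphometry → partition densitometry → micro-FE → R-style mixed
models), plus a synthetic-phantom generator with exact ground truth to
validate every stage.

## What it computes

**Preprocessing** (`tibiamct.imgproc`): TIFF/MetaImage/NIfTI I/O at
isotropic spacing (nominally 10.4 μm), densitometric calibration
(TMD = intercept + slope·grey, fitted to hydroxyapatite insert phantoms),
3×3×3 Gaussian filtering (σ = 0.65), global thresholding at the midpoint of
the bone/background histogram modes, despeckling (3-D volumes < 10 voxels),
and principal-axis alignment.

**Morphometry** (`tibiamct.morphometry`): in a 1 mm trabecular VOI offset
0.2 mm below a reference slice — Tb.BV/TV, Tb.Th, Tb.Sp (model-independent
maximal-sphere local thickness of the bone/background phase) and
Tb.N = (BV/TV)/Tb.Th; in a 1 mm midshaft VOI after 2-D pore closing
(disk radius 10 px) — Tt.Ar, Ct.Ar, Ct.Ar/Tt.Ar, Ct.Th; tibia length.

**Densitometry** (`tibiamct.densitometry`): a VOI spanning 80% of the
tibia length below the growth plate, fibula excluded, divided into 10
longitudinal sections × 4 anatomical quadrants; per partition BMC (mg),
TMD, BMD and BV/TV, with exact conservation (Σ partition BMC = total BMC).

**Micro-FE** (`tibiamct.microfe`): each bone voxel becomes an 8-node
hexahedral element (E = 14.8 GPa, ν = 0.3). Apparent stiffness: proximal
face fixed, axial displacement prescribed on the distal face, stiffness =
Σ proximal axial reactions / displacement. Strength: unit distal load
equally distributed per node, failure when 2% of considered nodes exceed
−10300 με (third principal) or +8000 με (first principal), with 10% of the
length excluded at each end.

**Statistics** (`tibiamct.stats`): per parameter, a linear mixed-effects
ANOVA (fixed: Strain, Intervention, Side and two-way interactions; random
intercept per mouse), Shapiro–Wilk/Levene assumption gating with subgroup
splitting, pruning of non-significant interactions, and the Side effect as
a contrast of estimated marginal means with 95% CI, also expressed as a
percentage of the left (control) marginal mean.

**Phantoms** (`tibiamct.phantom`): mirrored left/right tibia-like voxel
pairs — cortical shell with a tapering shaft, medullary canal, jittered rod
lattice in the proximal metaphysis, linear grey↔density mapping, Gaussian
detector noise — with injectable right-side effects (e.g. −14% trabecular
number) and exact ground truth for every measured quantity.

## Worked example

```python
from tibiamct import stats

records = stats.simulate_study_records(side_effect_pct=-14.2, seed=42)
estimates, checks = stats.analyze_parameter(records, "Tb.N", split=None)
print(stats.effects_table(estimates).to_string(index=False))
```

```
parameter subgroup        L        R      diff    ci_low   ci_high       sd  pct_diff  pct_ci_low  pct_ci_high      p_value  n_mice
     Tb.N          1.432122 1.247501 -0.184621 -0.232646 -0.136596 0.102614     -12.9       -16.2         -9.5 1.538391e-07      20
```

A 20-mouse cohort with a −14.2% right-side trabecular-number effect
injected: the mixed model estimates left/right marginal means of 1.43 and
1.25 /mm, a paired difference of −0.185 /mm (95% CI −0.233 to −0.137), and
a percent difference of −12.9% (CI −16.2 to −9.5) — covering the injected
truth. The same estimate on real data is how a radiation-induced
trabecular loss would be reported.

The image-based chain runs the same way from the command line:

```bash
tibiamct phantom --out pair/ --seed 1
tibiamct preprocess --in pair/left.mhd --out left_mask.mhd \
    --calib-slope 0.7 --calib-intercept -50
tibiamct fe --mask left_mask.mhd --mode both --downsample 4
tibiamct run --out study/ --n-mice 4 --tb-n-effect -14.2
```

## Layout

```
src/tibiamct/
  phantom.py       synthetic left/right pairs + ground truth
  imgproc.py       I/O, calibration, filtering, segmentation, alignment
  morphometry.py   trabecular + cortical metrics, local thickness
  densitometry.py  80% VOI, fibula exclusion, 40-partition tables
  microfe.py       hexahedral micro-FE stiffness and strength
  stats.py         mixed-model paired-effect pipeline
  pipeline.py      end-to-end study runner
  cli.py           `tibiamct` subcommands
docs/methods.md    model assumptions, parameters, numerical choices
tests/             pytest suite with independent oracles
```
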