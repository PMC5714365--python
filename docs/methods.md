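# Methods

`protonmotion` studies how cranio-caudal breathing motion perturbs the dose of
passively scattered (double-scattering) proton plans for mobile liver-dome
tumors, and how a *field-specific distal proton margin* — the per-field range
difference between plans built on the maximum-intensity (MIP) and average
(AVG) 4D-CT reconstructions — compensates it.  Everything runs on synthetic
4D-CT series so the full pipeline is reproducible without patient data.

## The breathing phantom

Ten phase volumes (labels 0%…90%; 0% = end-inspiration, 50% = end-expiration)
of Hounsfield units on a 96³ grid at 2 mm isotropic spacing.  Anatomy, from
outside in:

* a 20 mm soft-tissue body wall (40 HU) around the axial periphery;
* a cylinder of motionless soft tissue (chest wall / mediastinum abstraction);
* inside it, a **conical diaphragm flank**: liver (100–130 HU) below the
  interface `z = z_base + d(phase) + h·(1 − ρ/r0)`, lung (−900…−300 HU) above
  it.  Defaults `z_base = 58 mm`, `h = 114 mm`, `r0 = 81.4 mm` put the cone
  apex at 172 mm with flank slope 1.4 (mm height per mm radius);
* a spherical gross tumor (30 mm diameter, 60 HU) riding rigidly on the
  liver, centred 67 mm below the apex on the cone axis;
* a narrow moving lung invagination (a recess-like notch, slope 4.5, tip 3 mm
  above the tumor top) that places a small part of the PTV into lung at
  inspiratory phases.

The displacement law is a sinusoid anchored to the 4D-CT phase convention,
`d(p) = A·(1 − cos 2πp/100)/2`, with peak-to-peak amplitude `A = 1.3 cm` by
default (the upper end of reported liver-dome motion; configurable down to
zero).  Liver, tumor and notch translate rigidly and together.

Two properties of this geometry are deliberate, because the compensation
method depends on them:

1. **Every beam's-eye ray through the PTV crosses the moving lung/liver
   wedge once, obliquely.**  The water-equivalent path length (WEPL) of each
   ray therefore swings by roughly the wedge path × the lung/liver stopping
   power difference — about 0.2–0.5 cm between the AVG reconstruction and the
   end-expiration phase — matching the 0.03–0.95 cm effective-depth changes
   reported clinically for 0.5–1.3 cm motion.
2. **The swing is fairly uniform across rays, including the deepest one.**
   The field-specific margin is a *single scalar per field* (the difference
   of the deepest-ray WEPL between MIP and AVG volumes), so it can only
   compensate per-ray swings comparable to the deepest ray's swing.  Early
   geometries in which the deepest ray crossed no moving tissue (a flat
   moving diaphragm base, or a dome apex far above a static liver column)
   make the margin collapse to ~0 while other rays swing by 1–2 cm; no
   field-level margin can rescue such anatomy, and the 4D verdicts of all
   strategies fail.  That regime is reachable through the config (it is
   physically meaningful), but it is not the study default.

Tissue texture is a seeded, spatially smoothed random field (≈6 mm
correlation length, standard deviation one-twelfth of the tissue interval,
clipped to the interval), plus seeded Gaussian noise (sd 10 HU).  Texture and
noise are drawn **once** and shared by all phases: phases differ only by the
motion, so a zero-amplitude series is bit-identical across phases and the
generator is fully deterministic per seed.  Per-voxel independent texture
spanning the full lung interval is *not* used: it adds ~0.1 cm of per-ray
WEPL noise, which is larger than the falloff tolerance of the margin test and
turns single-voxel D100% verdicts into coin flips.

What the phantom does **not** emulate: deformation (the liver translates
rigidly), hysteresis and irregular breathing, anterior–posterior/lateral
motion components, realistic CT texture and reconstruction artifacts, ribs,
and beam-hardening.  Passing tests therefore show that the planning and
evaluation machinery behaves as described for translation-dominated
liver-dome motion with sharp interfaces; they do not certify performance on
deforming patients.

## HU → stopping power

Piecewise-linear calibration with anchors
(−1000→0.001, −700→0.29, −300→0.71, 0→1.00, 60→1.04, 120→1.07, 1600→1.85),
clamped outside the domain, user-replaceable via a two-column CSV.  The
anchors put the liver/lung stopping-power ratio at representative HU
(115 vs −700) inside the 3–4× band characteristic of those tissues.

## Beam model

Pristine Bragg curves use a Bortfeld-style analytic form — a power-law
stopping term `17.93·u^(−0.435)` plus a fluence-loss term
`(0.444 + 3.17/R)·u^0.565` with `u = R − z` — convolved numerically with a
Gaussian range-straggling kernel `σ = 0.012·R^0.935` cm on a 0.1 mm grid,
then sampled on the working 0.5 mm WEPL grid and peak-normalized.

An SOBP for distal range `R` and modulation `M` (both defined on the 90%
dose levels: `R` = distal-90% depth, `M` = distal-90 − proximal-90) is a
nonnegative-least-squares superposition of pristine peaks spaced by
0.6 × the 80–20% distal falloff of the deepest peak.  Numerical details that
matter:

* the NNLS fit region extends a few straggling widths proximal of the
  shallowest peak; otherwise that peak's maximum sits just outside the
  penalized window and the optimizer grows an unconstrained "horn" there;
* a damped outer loop shifts the deepest/shallowest peak ranges until the
  *composed curve's own* 90% crossings land on `R` and `R − M` (within a
  quarter step), with a scalar polish of the proximal shift for stubborn
  combinations;
* the guaranteed-flat plateau is `[R − M + max(0.55, 0.1·M) cm, R − 3·spacing]`,
  normalized to dose 1 with ripple ≤ ±2%.  The proximal allowance is physics,
  not slack: pristine peaks have slow power-law proximal shoulders, so a
  curve whose 90% crossing sits exactly at `R − M` necessarily climbs to full
  plateau dose over a knee a few millimetres to ~1 cm wide.  The 90%-level
  identities (the quantities every plan metric uses) hold to half a depth
  step across `R ∈ [8, 20]`, `M ∈ [4, 15]` cm.

## Dose engine

Parallel broad beams along the four cardinal axial directions (no source
divergence; the aperture "cone" is a cylinder).  Per field: WEPL is the
cumulative stopping-power integral along each ray to the voxel centre;
the aperture is the PTV's beam's-eye projection dilated by a 1 cm Euclidean
margin; the range compensator gives every PTV-crossing ray thickness
`R − WEPL(distal PTV surface)`, so the compensated distal surface sits at
`R` exactly, with non-crossing rays filled from the nearest crossing ray and
a 1 cm border-smoothing ring mean-filtered.  No smearing margin is applied.
Voxel dose is the field's SOBP curve evaluated at `WEPL + compensator`,
times the field weight, zero outside the aperture; an optional Gaussian
penumbra (σ 3 mm) is off by default so range behaviour stays exact.

Field fitting sets `R` to the deepest distal-surface WEPL over PTV rays plus
half a depth step.  `M` is the **maximum per-ray WEPL chord** through the PTV
plus one step: with the compensator in place, ray `r`'s plateau must reach
back from `R` over exactly `chord(r)`, so the maximum chord is the minimal
modulation that bounds the PTV between the 90% surfaces.  (Setting
`M = R − min proximal WEPL` without accounting for the compensator degenerates
when the PTV extends into lung: the shallowest proximal WEPL is then the
chest-wall depth, the SOBP widens to near-full modulation, and the proximal
mechanism that distinguishes the MIP strategy at inspiration disappears.)

## Plans and evaluation

* AVG / MIP / OVR plans: two equally weighted orthogonal coplanar fields
  (posterior 180° + right-lateral 270° by default) fitted on the strategy's
  volume; the OVR volume is the AVG with all PTV voxels set to the mean AVG
  HU over the ITV.  Plan dose is normalized so the minimum PTV dose is
  exactly 95% of prescription (100% coverage at the 95% isodose).
* mAVG: per field, `R → R + ΔR` and `M → M + ΔR` with
  `ΔR = R(MIP) − R(AVG)` for that field, which holds the proximal-90 depth
  fixed (AVG-like proximal coverage) and moves the distal-90 to the MIP
  depth; compensators, apertures, angles and weights are inherited unchanged;
  dose is recomputed on the AVG volume and re-normalized (fresh normalization
  keeps the four strategies comparable at the same coverage level).
* Evaluation: each plan is recomputed on every phase CT with all hardware and
  the normalization factor frozen; D95%/D99%/D100% (sort-based order
  statistics with linear rank interpolation; D100% = minimum) and the
  conformity index (total volume ≥ level over target volume ≥ level, level
  95% by default — the normalization level, since that is where coverage is
  prescribed) are compared with the plan's own 3-D baseline.  A phase passes
  if all three indices change by at most 2 percentage points of prescription,
  inclusive.  The 4D dose is the equal-weighted voxel-wise mean of the ten
  phase doses on the common grid (rigid overlay, no deformable mapping) and
  is judged by the same rule.

## Problem sizes and defaults

The headline experiment runs on the default 96³ phantom (10 phases, 2 fields,
amplitude 1.3 cm) in a few seconds; unit and property tests use a 48³ version
of the same anatomy at 4 mm spacing.  `scripts/acceptance.py` reruns the
96³ experiment from scratch for any seed.

## Known limitations

* Broad-beam ray physics: no lateral scatter, nuclear halo or Monte Carlo
  fidelity; cold spots are sharper than a clinical engine would render them.
* Single-voxel D100% on a 2 mm grid is an unforgiving statistic; clinical
  systems evaluate finer grids with smoother dose.
* The density-override (OVR) strategy is faithful to its definition, but in
  this phantom its characteristic end-expiration D100% rescue does not
  reproduce: the end-expiration minimum lives at the PTV corner that is
  distal for *both* orthogonal fields, and overriding a ~99%-liver PTV to the
  (lower) mean gross-tumor HU slightly deflates the planning density there.
  The clinical rescues were reported for targets whose PTVs intersected lung
  by tens of cm³; embedding that much lung in this phantom's PTV drives
  apex-grazing ray swings past any field-level margin and destroys the mAVG
  4D identity, so the default anatomy prioritizes the margin mechanism.
* Rigid 4D composition over-credits all strategies equally; with deformable
  mapping the absolute composite indices would differ.
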