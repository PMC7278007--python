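# Methods

`sctdosim` implements a desk-scale, fully synthetic re-enactment of the
dosimetric evaluation workflow used to qualify segmentation-based synthetic
CT (sCT) for MRI-only radiotherapy planning of the brain: six-class
tissue segmentation with Hounsfield-unit (HU) assignment, bone-segmentation
metrics, plan-copy dose recalculation, DVH parameter comparison, and global
3-D gamma analysis, driven by a seeded head-phantom cohort generator.

## Synthetic head phantom

Real patient MR/CT pairs are not available, so the cohort is emulated by a
generator that produces co-registered CT and MR volumes from one shared
anatomy. The anatomy is a set of nested ellipsoidal shells — scalp/soft rim,
cortical-bone skull shell, CSF layer, grey-matter shell, white-matter core —
plus an anterior air sinus and an ellipsoidal contrast-enhancing lesion
placed uniformly at random inside the eroded brain. The lesion is voxelized
by thresholding its ellipsoidal coordinate at the value that yields exactly
the requested voxel count, so the gross tumor volume (GTV) is accurate to
half a voxel. The planning target volume (PTV) is the GTV expanded by a
group-specific margin (glioma 16 mm, metastasis 2.5 mm) and clipped to the
body.

Cohorts sample GTV volumes uniformly from group subranges (glioma
20–90 cm³, metastasis 1.0–16.4 cm³). These subranges sit inside the clinical
GTV ranges for the two tumor types and were chosen so that the PTVs produced
by the fixed margins also land inside the clinical PTV ranges (roughly
133–373 cm³ for glioma, 0.3–29 cm³ for metastasis), and so that metastasis
lesions remain resolvable on the coarse grids used for desk-scale runs.
Glioma cases default to 1×1×2 mm voxels and metastasis cases to 1×1×1 mm,
matching the acquisition convention of thinner slices for small lesions;
scaled-down runs override both with isotropic 3 mm, 64³ grids.

CT synthesis assigns each class its mean HU — air −1000, soft tissue 40,
cortical bone 942, grey matter 41, white matter 25, CSF 15 — deliberately
identical to the HU lookup table the sCT stage applies. This gives the
pipeline an exact fixed point: with all degradations disabled
(`PhantomConfig.noiseless()`), the sCT equals the CT voxel for voxel, so
DSC = 1, MAE = 0, every dose difference is 0 and both gamma criteria pass at
100%. The realistic regime (the default) breaks the fixed point with
Gaussian CT noise (sd 20 HU), a continuous skull HU gradient (1300 HU at
the outer table to 700 HU at the inner table — the sCT's single 942 HU bone
value cannot represent it, creating genuine bone MAE), and 0.5-voxel
partial-volume blurring.

MR synthesis is a single T1w-like channel with class means (air 2, bone 30,
CSF 70, GM 120, WM 170, soft 220 in arbitrary units), multiplied by a
smooth random bias field (amplitude 0.10), with the lesion boosted by a
contrast-enhancement factor (1.3, emulating gadolinium uptake) and Gaussian
noise (sd 8) added. The degradation parameters were fixed once at values
that produce segmentation accuracy in the mid-90% range — high enough that
the method works, low enough that bone delineation errors, body-outline
differences and nonzero MAE actually occur.

What the generator does **not** emulate: cortical folding and true brain
topology, MR sequence physics (Dixon fat/water separation, susceptibility),
thermoplastic-mask artifacts, CT beam hardening, and registration error
(pairs are generated co-registered; the analysis assumes resolution matching
only). Passing tests therefore demonstrate the correctness and internal
consistency of the evaluation machinery and the qualitative error
mechanisms, not clinical performance on patients.

## Tissue segmentation and sCT assembly

Air is assigned by body-outline thresholding: voxels outside the largest
above-threshold connected component (holes filled), or below the threshold
(8% of the 99th-percentile intensity), are air. The remaining five classes
are a 1-D Gaussian mixture fitted by EM (k-means++ initialization, three
restarts, `reg_covar` 10⁻³) to the body-voxel intensities. Bias-field
flattening is interleaved with the fit: the residual between log-intensity
and the posterior-predicted log class mean is fitted by a degree-2
polynomial in normalized coordinates and divided out, then the mixture is
refitted (two iterations). On a bias-free image the residual is identically
zero, so the correction is exactly the identity — this preserves the
noiseless fixed point, which a generic homomorphic or histogram-based
correction would not.

Mixture components are mapped to tissue classes by the rank of their fitted
means against the expected MR intensity ordering; an optional atlas label
map can override this by majority overlap. Posteriors are hardened by
argmax with a fixed tie priority (bone > CSF > GM > WM > soft > air), and
connected components of bone or air smaller than 0.05 cm³ are reassigned to
soft tissue. The sCT is the piecewise-constant HU lookup of the resulting
partition; resolution matching resamples the label image with
nearest-neighbor interpolation before the lookup so the output stays within
the six table values. The sixth class ("other soft tissue") is set to
40 HU — a standard literature soft-tissue value — and is configurable, as is
the whole table.

## Dose engine

The engine is a divergent exponential-attenuation pencil model for 6 MV
photons:

    dose_b(v) = w_b · exp(−μ_eff · d_rad(v)) · (SAD / r(v))² · P(v)

with μ_eff = 0.0049 mm⁻¹ (water-equivalent), SAD = 1000 mm, r the
source–voxel distance, d_rad the radiological depth (line integral of
relative electron density from the source), and P an error-function
penumbra (σ = 3 mm at the field edge, evaluated in the isocenter plane on
divergent coordinates). HU are converted to relative electron density by a
piecewise-linear calibration anchored at (−1000 → 0.001, 0 → 1.000,
942 → 1.512, 3071 → 2.2). There is no buildup region, scatter kernel or
electron transport: the model is a documented simplification whose only
requirements here are physical monotonicity (attenuation, inverse square,
penumbra) and strict identity of treatment between the CT and sCT arms,
which is what the plan-copy comparison methodology exercises.

`radiological_depth` is an exact Siddon-style voxel traversal and is kept
for single-ray queries and as the oracle anchor; `compute_dose` integrates
depth by fixed-count midpoint quadrature along each source–voxel ray
(clipped to the grid, step ≈ half the smallest voxel dimension, capped at
256 samples). The quadrature choice vectorizes over all voxels at once and
agrees with exact traversal far within the 1% tolerance the engine is
verified to.

Plans are equally weighted coplanar beams (default four, at evenly spaced
gantry angles in the axial plane) aimed at the PTV centroid, square fields
covering the PTV bounding box plus 5 mm. Dose is normalized so the CT-based
plan's PTV median equals the prescription (default 30 Gy; absolute level
cancels in all reported relative quantities), and the *same* constant is
reused for the sCT recalculation — true plan-copy semantics, so a
systematically more attenuating sCT shows up as PTV underdosage rather than
being renormalized away.

## Evaluation metrics

**Bone**: CT and sCT are thresholded at 300 HU (strict exceedance) into
skull masks; reported are the Dice coefficient 2|A∩B|/(|A|+|B|) (defined as
1 for two empty masks), bone volumes (per-slice voxel counts × voxel
volume), their relative difference 100·(V_sCT − V_CT)/V_CT, and the mean
absolute HU error. The MAE region is the body mask restricted to axial
slices from the superior-most body slice down through 55% of the head
height — a reproducible stand-in for "crown to cranial base", since no
landmark algorithm is defined for ellipsoid phantoms. DSC uses the
whole-scan masks.

**DVH**: curves are exact empirical distributions of member-voxel doses (no
binning). D_X% is read in the near-max/near-min convention — the minimum
dose received by the hottest X% of the structure volume — via interpolated
order statistics; D_0.1cc is the minimum of the ⌈0.1 cm³ / voxel volume⌉
hottest voxels (falling back to D_max with a warning for structures smaller
than 0.1 cm³); D_max is the voxel maximum, reported separately from D_0.1cc;
D_mean the arithmetic mean. The organ-at-risk structure is the geometric
ring of body tissue within 2 cm of the PTV outer edge, excluding the PTV.
Relative differences are 100·(D_sCT − D_CT)/D_CT per parameter.

**Statistics**: paired CT-vs-sCT differences use the two-sided Wilcoxon
signed-rank test (exact null for untied n ≤ 25, otherwise normal
approximation with Pratt zero handling and tie correction); between-group
comparisons use the two-sided Mann–Whitney U test (exact for pooled n ≤ 12
without ties, otherwise corrected normal approximation). Both wrap
scipy.stats and are cross-checked in the test suite against exhaustive
enumeration oracles.

**Gamma**: global 3-D gamma with dose differences normalized to the maximum
of the *reference* (CT-based) dose, a >10% low-dose threshold on the
reference, and a cap of 2. For each evaluated reference voxel the minimum
over positions of √((Δr/DTA)² + (ΔD/tol)²) is searched on a shift subgrid
of step DTA/10, refined to at most 0.1 mm so that steep dose gradients are
resolved identically across criteria, within a radius cap×DTA (farther
positions cannot score below the cap). The search is exact on that subgrid:
a voxel settles only when no remaining candidate — bounded below by its
distance term plus the gap between the reference dose and the local
evaluated dose range — can improve its cap-clamped γ. A deliberately
separate brute-force implementation (dense per-voxel exhaustive search at
0.1 mm) serves as the oracle in tests. Every criterion, threshold,
normalization choice and cap is embedded in the emitted reports, since
gamma results are not comparable without them.

## Scaled-down experiment and calibration

The cohort experiment that the acceptance script and the test suite run
uses 5 glioma + 5 metastasis phantoms on 64³ isotropic 3 mm grids — sizes
chosen so a full run completes in minutes on one CPU while every stage
operates on genuinely 3-D data. The between-group comparison is
null-calibrated: with both arms drawn from *matched* generator settings
(eight glioma-type phantoms split 4/4, tiny 32³ grids, 20 master seeds),
the Mann–Whitney test on PTV mean-dose differences must reject at α = 0.05
no more often than chance allows (≤ 3 of 20; Binomial(20, 0.05) puts
P(X ≥ 4) below 2%).

## Numerical and design choices

- Geometry is voxel-centered, 0-based, axis order (x, y, z) with z the
  axial (slice) axis; world coordinates in mm. Resampling is nearest or
  trilinear with out-of-extent fill (−1000 for HU, 0 otherwise); disjoint
  extents are an error, not silence.
- I/O uses NIfTI-1 and MetaImage via SimpleITK; masks are uint8 {0,1};
  float32 round trips are bitwise.
- Rigid/deformable registration is out of scope by design: phantom pairs
  are born co-registered, and registration error is a known limitation of
  the emulated workflow, not part of its method.
- Per-case seeds derive from the master seed as `seed·1000 + index`; every
  stochastic stage takes an explicit seed, and a fixed-seed rerun of a case
  reproduces its record byte for byte.
- Exact ties in posterior hardening go to the denser/more consequential
  class first (bone highest) so that HU assignment errs toward visible,
  testable behavior rather than platform-dependent argmax order.

## Known limitations

- The dose engine has no buildup or scatter; absolute depth-dose curves are
  not clinical, only comparisons between identically computed arms are
  meaningful.
- The phantom's six-class anatomy cannot produce partial-volume mixtures of
  bone/air/soft tissue like the real nasal sinus region beyond its single
  air cavity; MAE values are therefore not directly comparable to patient
  cohorts.
- The gamma search cost grows with the failing-voxel fraction (each failing
  voxel must be searched to radius γ·DTA); grossly disagreeing dose pairs
  are the slowest case even with the range-bound pruning.
- `D_max` is the voxel maximum, which is grid-resolution dependent;
  `D_0.1cc` is the stable near-max surrogate.
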