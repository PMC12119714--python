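# Methods

## The problem

A same-day dual-tracer PET protocol images a patient twice with two
fluorine-18 labelled tracers: a low-activity glucose scan
(0.5 MBq/kg [¹⁸F]FDG, 10 min acquisition at 60 min p.i.) and, at least
3.5 h after the first acquisition ends, a standard-activity
somatostatin-receptor scan (3.0 MBq/kg, 5 min acquisition at 90 min p.i.).
Since both tracers share the 109.8 min half-life of ¹⁸F, the second image
contains a decaying remnant of the first tracer. The package quantifies that
remnant and its effect on second-scan semi-quantification, and carries the
downstream lesion-level analysis (TLR classification, tumor volumes,
group statistics).

## Residual-activity model

The residual fraction after an interval Δt is `2^(−Δt/T½)`. Two conventions
matter:

* **Interval anchor.** Δt runs from the *end* of the first acquisition to
  the *start* of the second, because the protocol anchors its ≥ 3.5 h
  (mean 4.2 h) interval to completion of the first scan. With the default
  timing this gives (4.2·60 + 90)/109.8 ≈ 3.11 elapsed half-lives and a
  ~12 % mean residual; a start-to-start convention would give 3.2.
* **Scenarios.** Fixed fractions stand in for worst cases: R15 % is the
  decay fraction at the shortest observed interval (298 min,
  2^(−298/109.8) ≈ 0.152), and R20 % adds headroom for FDG uptake that keeps
  increasing between scans. Scenarios are multiplicative on the first-scan
  lesion ACT; no kinetic model is attempted (deliberately, matching how the
  quantity is defined).

Contamination is reported as 100 × residual ACT / *measured* second-scan
ACT. The measured denominator already contains the residual; a
residual-free denominator would change the percentages by at most a few
percent of themselves and is not what the quantity describes. Cohort
summaries are means ± standard error of the *per-lesion* percentages. The
distinction matters: with heterogeneous lesions the mean of ratios
(≈ 5 %) is much larger than the ratio of mean ACTs (≈ 2 %), because
FDG-avid/SSTR-negative lesions combine a large numerator with a small
denominator. A regression test pins this down.

## SUV and VOI statistics

SUV uses body-weight normalisation with tissue density 1 g/mL and the
injected dose decay-corrected to the acquisition start (single time point;
intra-acquisition decay over 5–10 min scans is ignored). `SUVSD` uses the
population (n) denominator so the CoV of a synthetic uniform region is
exactly the noise model's value. `SUVpeak` is the maximum over VOI voxels of
the mean in a 1 mL sphere centred at the voxel; the sphere may extend
beyond the VOI but is clipped at the image boundary. The sphere centre is
restricted to the VOI — the common convention where none is prescribed.

Fixed-geometry VOIs follow the protocol: a 3 cm³ cylinder in the descending
aorta (blood pool), a 1 cm³ cylinder in the posterior myocardial wall, and
a 14 mL liver background region. The liver VOI is realised as an
axis-aligned block (no shape is prescribed; its stated "14 m³" is read as
14 mL, the only physical possibility). Cylinder centres snap to the voxel
lattice so the voxelised volume does not depend on sub-voxel placement;
cylinder axes default to cranio-caudal (aorta orientation).

TLR divides lesion SUVmean (or SUVpeak) by liver SUVmean; the peak variant
also uses the liver *mean* in the denominator, the usual choice where the
reference is ambiguous.

## Segmentation

All thresholds are strict (`>`), matching the printed MTV definition; the
41 % isocontour keeps voxels at or above 41 % of the local maximum.
Connected components use 26-connectivity, and MTV components below 0.5 mL
are discarded as noise speckle (the minimum-lesion rule reused as a
component filter). The FDG-MTV physiological exclusions (brain, myocardium,
blood pool by default) are caller-supplied masks. The isocontour's
local-maximum search radius defaults to 15 mm and is configurable; the
pipeline, which seeds at known lesion centres, uses the lesion's own extent
instead so a hotter neighbour cannot capture the search.

A fixed-fraction isocontour *floods* into the host organ when lesion
contrast is below 1/0.41 ≈ 2.4 × background — at 41 % of such a maximum the
threshold is below the background level, so the connected component is the
organ, not the lesion. Readers avoid this by confining the isocontour to a
bounding region around the visible lesion; `isocontour_41` accepts an
optional bounding sphere with exactly that role, and the phantom pipeline
sets it to the lesion extent plus 4 mm. No background-corrected or adaptive
threshold is used.

## The digital phantom

The phantom emulates the *measured structure* the analysis rests on, not
acquisition physics:

* Piecewise-constant organs on a 96³ grid at 2 mm (the clinical 1.65 mm
  voxel is available through the grid config; the coarser default keeps the
  test suite fast). Organ SUVs are set to the measured levels: FDG scan —
  brain 6.0, myocardium 2.9, liver 2.0, blood 1.5, body 0.8; SSTR scan —
  liver 2.9, blood pool 1.1, no brain uptake. Myocardial SSTR-scan uptake is
  set to 1.0, the blood-pool level: in patients the myocardial wall signal
  on the SSTR scan is indistinguishable from blood, and a piecewise-constant
  phantom has no spill-over, so the blood-volume contribution is modelled as
  the organ's own level.
* Liver SUV anchors (FDG 2.0, SSTR 2.9) make the class-mean TLRs reproduce
  the observed lesion ACT scale at the protocol doses (≈ 340 Bq/mL per SUV
  on the low-activity scan, ≈ 1700 on the standard scan).
* The second scan is the pure second-tracer field plus the *noiseless*
  first-scan field times the decay fraction, then noise is applied once —
  residual signal and noise are never double-counted.
* Noise is Gaussian in image space with voxel SD = k·√(mean ACT), the
  simplest model that reproduces reconstructed-PET noise texture at the VOI
  level; the default k = 4.0 puts liver CoV at ≈ 15 % on the low-activity
  scan (the measured range is 13–18 % depending on reconstruction mode) and
  proportionally lower on the standard-activity scan. Negative voxels are
  clipped at zero with a warning count. Sinogram/Poisson simulation,
  attenuation, scatter, PSF and partial-volume effects are out of scope:
  the analysis consumes VOI means, not edge profiles.
* A voxel belongs to a shape iff its centre lies inside; world coordinates
  are voxel-centre based, axis-aligned, in mm.

The cohort generator plants lesion classes with probabilities 55/125,
25/125, 45/125 and per-lesion TLRs around the observed class means
(FDG+/SSTR+ 3.1/2.8, FDG+/SSTR− 3.4/0.7, FDG−/SSTR+ 0.9/2.8). The
distributions are a modelling choice, not data: lognormal (σ = 0.25,
truncated to [1.2, 6]) for positive TLRs, truncated normal below 1 for
negative TLRs. The negative-side upper bound (0.93) is derived from the
construction: residual first-tracer signal inflates second-scan TLRs by up
to ≈ 0.07 for the hottest FDG lesions, and the planted class must remain
consistent with the measured-TLR rule it defines. Patient weights vary
around 75 kg, the inter-scan interval around 4.2 h (SD 0.09 h); lesion
ellipsoid radii are 5–9 mm (0.5–3 mL), at most five per organ, placed by
rejection sampling with a keep-out zone around the liver background block
so the background VOI stays healthy tissue.

What passing tests on this phantom do **not** show: robustness to
partial-volume bias at lesion edges, to mis-registration between the two
scans beyond the provided integer-voxel shifts, to heterogeneous intra-
lesion uptake, or to organ-level kinetic differences. They do show that the
arithmetic, segmentation logic, scenario propagation and classification
rules are correct and identifiable from image data with realistic noise.

## Statistics

Paired organ comparisons use the Wilcoxon matched-pairs signed-rank test
(zero differences dropped; exact null for n ≤ 25 without ties, normal
approximation otherwise; an all-zero sample returns p = 1). Three or more
groups use Kruskal–Wallis with tie correction, followed by Dunn's pairwise
z tests; the multiplicity adjustment is Bonferroni over all pairs, the
usual default where the adjustment family is unspecified. Dunn's test is
implemented directly (standard rank-variance formula with tie term) and is
checked against closed-form hand computations.

## Numerical and interface choices

* TLR positivity is strict (> 1.0): negativity is defined as "equal to or
  below 1.0". Lesions negative on both tracers have no class in the
  three-class scheme; they are kept and flagged `double-negative` rather
  than dropped, so simulated truth is never silently lost.
* The per-patient discordant flag is any FDG+/SSTR− lesion or any FDG-MTV
  volume outside the SSTR-MTV mask (the "discordant MTV" concept made
  computable).
* Co-registration between the two scans is identity on the shared grid;
  a rigid integer-voxel shift hook exists for robustness experiments.
* Lesion filter tie-breaks: rank by SUVmax, then larger volume, then stable
  input order; the 0.5 mL volume bound is inclusive.
* Study directories store volumes as uncompressed NIfTI and metadata as
  JSON with sorted keys; together with fixed CSV float formatting this
  makes a fixed-seed run bit-reproducible.
* Simulation sizes used by the tests and the acceptance script: 96³ voxels
  at 2 mm, 20-patient cohorts (~125 lesions), chosen to exercise the full
  analysis at interactive runtimes.

## Known limitations

* The phantom's piecewise-constant lesions make 41 % isocontours recover
  planted volumes almost exactly; on real data partial-volume effects make
  the recovered volume threshold-sensitive.
* The contamination analysis quantifies, but does not correct, the residual
  signal; no dual-tracer unmixing is attempted.
* Reported class-mean TLR spreads are narrower than clinical cohorts, where
  heavy lesion-size and uptake tails dominate the means.
* The Fig.-style significance pattern between class groups depends on
  per-lesion data that only the generator provides; the statistical
  machinery is validated on oracles, not on the clinical dataset.
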