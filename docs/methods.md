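# Methods

## The analysis

scnkit implements seed-based structural covariance network (SCN) analysis
for voxel-based morphometry. The inputs are a cohort of spatially
normalized, modulated, smoothed gray-matter (GM) density maps sharing one
voxel-to-MNI affine, a phenotype table (genotype, demographics, cognitive
and neuropsychiatric scores), and a table of seed coordinates. The chain
is:

1. **Seed volume extraction.** For each seed, a sphere of radius
   `sphere_radius_mm` (default 4 mm) is placed at its MNI coordinate. A
   voxel belongs to the sphere when its center lies within the radius
   (boundary-closed); partial-volume weighting is deliberately not used,
   so the mask is exactly testable against an exhaustive distance scan.
   The extracted volume is the sum of GM density over sphere voxels times
   the voxel volume, reported in milliliters (voxel volume from the
   affine determinant; the unit choice is a convention, correlations and
   T statistics are invariant to it).

2. **Covariance mapping.** Per group, every voxel inside the analysis
   mask is regressed on the seed volume by OLS:
   `GM(v) = b0 + b1 * seed (+ nuisance)`. The SCN contrast is the
   one-sided positive T on `b1` ("voxels positively covarying with the
   seed"); the voxel-wise group comparison uses a two-sided T on a group
   indicator. The implementation is vectorized over voxels but
   numerically identical to per-voxel fits (asserted against independent
   closed-form and statsmodels fits to 1e-8). Voxels with zero residual
   variance receive a +inf T sentinel with p = 0 and a logged count.

3. **Thresholding.** Benjamini-Hochberg FDR at `scn_q` (default 0.01 for
   SCN and interaction maps, 0.05 for the group comparison), applied to
   voxel-level p-values *within the analysis mask only*, followed by a
   cluster-extent filter keeping connected components of at least
   `min_cluster_voxels` (default 100) under the configured neighborhood
   (default 18-connectivity; 6 and 26 selectable). The order —
   voxel-level FDR first, extent filter second — is one reading of the
   conventional "p < 0.01 FDR-corrected, cluster > 100 voxels"
   phrasing; a peak-FDR variant would be an alternative and is not
   implemented. A cluster's peak is its member voxel with maximal T,
   ties broken by lexicographic voxel index; records sort by descending
   peak T.

4. **Genotype interaction.** Slope differences between Met-carriers
   (Met/Met + Val/Met, pooled because Met/Met is rare) and
   Val-homozygotes are mapped with the pooled model
   `GM(v) = b0 + b1*seed + b2*group + b3*(seed x group)`, group coded
   Val = 0 / Met = 1, so `b3` is the Met-minus-Val slope difference and
   a one-sided positive T on `b3` gives the Met > Val map. The pooled
   formulation assumes equal residual variance across groups (the
   standard interaction-contrast idiom); a Welch-style slope contrast is
   a known alternative and a documented limitation. With no shared
   nuisance columns the pooled per-group slopes (`b1`, `b1 + b3`) are
   algebraically identical to separately fitted group slopes, which is
   asserted in the tests. The engine can compute both directions; the
   reporting default filters to Met > Val.

5. **Clinical statistics.** Spheres on interaction-cluster peaks yield
   per-subject peak volumes; seed and peak volumes are correlated with
   behavior scores per group (Pearson r, two-sided p, flags at raw
   p < 0.05 and p < 0.01 — the flag convention of printed correlation
   tables; optional BH adjustment is available but off by default).
   Group demographics use a pooled-variance Student t (Welch optional)
   and Pearson chi-square without continuity correction (Yates
   optional); genotype counts get a 1-df Hardy-Weinberg chi-square with
   the allele frequency estimated from the counts.

## Analysis mask and preprocessing options

Real SPM-style pipelines mask implicitly; here the mask is explicit and
configurable: voxels whose cohort-mean GM density is at least
`mask_threshold` (default 0.1, the conventional absolute threshold for
modulated GM). Re-smoothing of inputs and proportional scaling by total
GM are available but default to off, since the pipeline expects
already-smoothed maps and the reference design does not state global
scaling. Nuisance covariates (age, sex, ...) default to none and can be
added by column name.

Gaussian smoothing uses a per-axis sigma of
`fwhm / (voxel_size * 2*sqrt(2 ln 2))` voxels with zero-padded
boundaries and the kernel truncated at 3 sigma; truncation at 3 sigma
makes the convolution exactly mass-preserving for images whose content
keeps a 3-sigma zero margin, which the generator's fields do.

## The synthetic cohort generator

No patient data ship with the package; the generator produces cohorts
with exactly the statistical structure the analysis assumes, so every
stage can be validated against known ground truth.

* **Geometry.** Default 40 x 48 x 40 voxels at 4 mm isotropic with the
  MNI origin at the grid center — all ten default seeds fall inside the
  field of view while keeping full-cohort fits fast. This is a
  deliberately coarse desk-scale grid; consequently a "100-voxel"
  cluster is 6.4 mL here versus well under 1 mL on a 1.5-mm acquisition
  grid, and the planted blobs are correspondingly large (14 mm half-max
  radius) so that true clusters can clear the extent threshold.
* **Baseline.** An ellipsoidal brain-like GM compartment (semi-axes
  70 x 88 x 66 mm around MNI (0, -18, 5)) at density 0.6 with a soft
  taper in the outer 15%, or a uniform box for calibration studies
  where the mask must cover the whole grid.
* **Genotypes.** The default Met allele frequency is 111/384, the value
  implied by reference genotype counts 20/71/101. Unconditional draws
  follow Hardy-Weinberg proportions (p^2, 2pq, q^2); when fixed group
  sizes are requested (default 91 Met-carriers vs 101 Val-homozygotes),
  Val-homozygotes are VV and Met-carriers draw MM vs MV at the
  HWE-conditional odds p : 2q.
* **Planted networks.** Each template ties a latent score
  s_i ~ N(0, latent_sd) to the seed region and to remote target blobs
  with group-specific slopes. Blobs are compact raised-cosine profiles
  (1 at center, 1/2 at the nominal radius, exactly 0 beyond twice the
  radius), standing in for smoothed data while keeping the planted
  support unambiguous (ground-truth support = profile >= 5% of peak).
  The seed's own profile is scaled so the extracted 4-mm sphere volume
  equals a constant plus s_i — unit gain in mL per latent unit — which
  makes the voxel-on-seed-volume regression slope at a blob center
  numerically equal to the template's slope. White Gaussian voxel noise
  (default SD 0.015 GM units against latent SD 0.02 mL) is added and
  the image clamped at zero; at the default baseline the clamp is
  inactive inside the brain compartment.
* **Behavior.** Scores are `intercept + slope * seed_volume + noise`,
  continuous and unclipped so the linear ground truth stays exact;
  default couplings give MMSE/CASI-like ranges with weak-to-moderate
  correlations. Demographics (age, education, sex, ApoE4) are drawn
  at reference-cohort-like rates and are independent of the images.

What the generator does **not** emulate: spatially correlated noise,
subject misregistration, atrophy gradients, genotype effects on mean GM,
score floor/ceiling effects, or cross-network correlations (one
independent latent per template). Passing tests therefore demonstrate
correctness of the statistical machinery under the model's own
assumptions, not robustness to real-data artifacts.

## Validation studies

Two simulation studies ship in `scnkit.validation` and back the
acceptance checks:

* **Null FDR calibration.** 200 cohorts of 30 + 30 subjects on a 20^3
  uniform box whose seed carries a latent score but drives no target
  (slope 0 in both groups). The realized false-discovery proportion of
  the one-sided SCN selection at q = 0.01 — counting any selection
  outside the seed's own signal support as false — must stay within two
  Monte-Carlo SEs of q.
* **Interaction recovery.** 50 cohorts at the default study conditions
  (91 + 101 subjects, slopes 2 vs 1 on the dorsal caudal putamen
  template). The interaction coefficient at each planted blob-center
  voxel must lie within 3 SEs of the planted difference 1.0 (the exact
  generating value at a center voxel is the planted difference times the
  blob profile there, slightly below 1 because voxel centers do not sit
  exactly on blob centers), and the top cluster's peak must fall within
  one blob radius of a planted center in at least 90% of replicates.

Problem sizes (grid, replicate counts, group sizes) are chosen so the
full suite and the validation studies run in a few minutes on one core
while keeping Monte-Carlo error well inside the tested margins.

## Numerical and degenerate-input choices

* float32 on disk (NIfTI convention), float64 in computation.
* OLS via `numpy.linalg.lstsq`; rank-deficient designs and n <= k are
  rejected up front. Zero residual variance (relative tolerance 1e-14
  against the data's sum of squares) → +inf T, p = 0, logged.
* BH selection delegates to `statsmodels.stats.multitest.multipletests`
  and is verified against an independently coded textbook step-up rule
  on all 2^10 vectors from a two-level p-grid.
* Empty FDR selection, empty cluster lists, empty peak tables and empty
  correlation tables are all well-defined empty outputs, not errors; an
  empty analysis mask is an error with a pointer at `mask_threshold`.
* Sphere membership uses a 1e-9 slack on the squared distance so that
  integer-radius boundary cases (e.g. face neighbors at exactly the
  radius) are stable against floating-point rounding.
* Cluster peak ties break lexicographically on voxel index; cluster
  records with equal peak T order by peak index.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; rerunning any stage with the same inputs
  is bit-identical, which the pipeline asserts by checksumming outputs.

## Known limitations

* Voxel-level BH FDR is implemented; SPM's peak/cluster-FDR variants
  are not.
* The correlation tables flag raw p-values (matching printed-table
  conventions); family-wise or FDR adjustment across table cells is
  optional and off by default.
* The pooled interaction model shares one residual variance across
  groups.
* Listwise deletion for missing scores (with a logged count) is the
  only missing-data policy.
* No atlas labeling of clusters and no rendered figures; outputs are
  NIfTI statistic maps and TSV tables.
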