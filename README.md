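# scnkit

Seed-based **structural covariance network (SCN)** analysis for
voxel-based morphometry, with a synthetic-cohort simulator.

## Who this is for

Neuroimaging groups studying how a genetic polymorphism (the motivating
case: COMT Val158Met in Alzheimer's disease, Met-carriers vs
Val-homozygotes) reshapes gray-matter covariance networks. Given
spatially normalized, modulated GM density maps (NIfTI), a phenotype
table, and a set of seed coordinates, scnkit builds the per-group SCN
maps, finds voxels where the seed-to-voxel covariance *slope* differs
between groups, and correlates seed/cluster volumes with cognitive and
neuropsychiatric scores. Because such patient datasets are rarely
shareable, the package includes a first-class generator of synthetic
cohorts with planted covariance structure, so the entire chain is
verifiable against known ground truth.

## The model

For seed *s* with extracted sphere volume *x<sub>i</sub>* (4-mm radius,
mL) in subject *i*, each voxel *v* inside the analysis mask is fit per
group by OLS:

&nbsp;&nbsp;GM<sub>i</sub>(v) = β₀ + β₁ x<sub>i</sub> + ε,&nbsp;&nbsp;ε ~ N(0, σ²)

The SCN is the one-sided T map on β₁ > 0, thresholded by
Benjamini–Hochberg FDR at q = 0.01 within the mask plus a cluster extent
of ≥ 100 voxels. Group differences in covariance strength use the pooled
interaction model

&nbsp;&nbsp;GM<sub>i</sub>(v) = b₀ + b₁ x<sub>i</sub> + b₂ g<sub>i</sub> + b₃ x<sub>i</sub> g<sub>i</sub> + ε,&nbsp;&nbsp;g = 1 for Met-carriers

where b₃ is the Met-minus-Val slope difference; the reported contrast is
the one-sided T on b₃ (Met > Val), same FDR and extent rules. Spheres on
interaction-cluster peaks give per-subject cluster volumes for Pearson
correlation with behavior (flags at p < 0.05 / p < 0.01). Scalar
comparisons use pooled-variance Student t and Pearson χ²; genotype
counts get a 1-df Hardy–Weinberg χ². Ten literature seeds are built in:
six striatal subdivisions and four triple-network nodes (e.g. dorsal
caudal putamen (28, 1, 3), left PCC (−2, −36, 35)).

See `docs/methods.md` for assumptions, parameter defaults, and what the
simulator does and does not emulate.

## Worked example

Simulate the default study conditions — 91 Met-carriers vs 101
Val-homozygotes, one planted network on the dorsal caudal putamen (DCP)
seed whose covariance slope is 2 in Met-carriers vs 1 in Val-homozygotes
— then analyze three seeds:

```bash
scnkit simulate --seed 7 --out demo/cohort
printf 'seeds: [dorsal_caudal_putamen, dorsal_rostral_putamen, left_pcc]\n' > demo/analysis.yaml
scnkit run demo/cohort --config demo/analysis.yaml --out demo/results
scnkit report demo/results
```

prints:

```
scnkit 0.1.0 run: 192 subjects (91 Met / 101 Val)
HWE: chi2 = 0.018, p = 0.894 (in equilibrium)
group VBM difference: 0 cluster(s)
dorsal_caudal_putamen: 2 Met>Val interaction cluster(s): (-38, -50, 26) T=10.24 k=245; (22, -58, 10) T=9.96 k=239
dorsal_rostral_putamen: no Met>Val interaction clusters
left_pcc: no Met>Val interaction clusters
```

Reading this: the simulated genotypes pass the Hardy–Weinberg check
(p = 0.894); there is no voxel-wise mean GM difference between groups
(none was planted); and the Met > Val slope-interaction map is non-empty
*only* for the DCP seed — two clusters of 245 and 239 voxels whose MNI
peaks sit within a few millimeters of the planted target centers
(−32, −48, 28) and (24, −52, 8) — while the unplanted DRP and PCC seeds
correctly yield nothing. Per-seed outputs (T maps as NIfTI, cluster and
correlation tables as TSV, `manifest.json` with config, checksums and
thresholds) land under `demo/results/`.

The same machinery is available in Python:

```python
from scnkit import SimulationConfig, generate_cohort, SlopeInteraction

cohort, truth = generate_cohort(SimulationConfig(rng_seed=7))
model = SlopeInteraction(seed_name="dorsal_caudal_putamen").fit(cohort)
model.clusters_          # ClusterRecords: size, MNI peak, peak T
model.stat_map_.beta     # voxel-wise Met-minus-Val slope difference
```

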