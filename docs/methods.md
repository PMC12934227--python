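# Methods

## Measurement model

Skull thickness is defined operationally, not anatomically: it is the mean
distance from a point on the outer skull surface to its k = 30 nearest
neighbours among points sampled on the inner surface. This definition is
robust to sampling outliers (a single stray inner point moves the mean by
at most 1/k of its error) but carries a predictable positive bias. If the
inner cloud has surface density λ (points/mm²) and the true gap is t, the
30 nearest neighbours sit at tangential offsets s with
E[s²] ≈ (k+1)/(2πλ), so the per-point estimate is inflated by roughly

    bias ≈ E[s²] / (2 t).

At the default density (5·10⁵ points on a ~8·10⁴ mm² cranial surface,
λ ≈ 6.2/mm²) this is ≈ 0.13 mm for a 3 mm gap — measured as 0.129 mm on
the sphere phantom. The bias halves when the point count doubles; a
consequence is that the scan median is density-dependent at the 0.05 mm
level, so comparisons across scans must use the same `n_points` (all
defaults do). Within-subject *changes* in thickness are unaffected to
first order, because the bias cancels in differences at fixed density.

Per-point values outside 0.5–12 mm (inclusive at both ends — the less
destructive convention) are flagged out of bounds and excluded from the
median; the excluded fraction is reported and a warning is raised above
20 %, which in practice signals a failed surface segmentation. Bounds are
applied to the k-NN-averaged value, the only per-point quantity the
pipeline reports. The inner cloud must contain at least k points; smaller
clouds are an error rather than a silent reduction of k.

ICV is the signed-tetrahedron volume of the watertight inner surface
(divergence theorem), in mL. Orientation is auto-corrected (negative total
volume flips winding, with a log notice) because mesh sources differ in
winding convention. Non-watertight meshes are rejected with the boundary
edge count; volumes are translation-invariant by construction.

Surface sampling is area-weighted inverse-CDF face selection with a single
uniform draw per point, then uniform barycentric placement (reflected
(u, v)). Zero-area faces get zero probability but are retained for
topology. Identical (mesh, n, seed) gives identical clouds.

## Regional partition

The supratentorial restriction keeps points with world z at or above the
exclusion plane, computed from the atlas affine as the world z of axial
slice 28 on the 2 mm standard grid (−16 mm under the canonical affine).
The plane is derived from the affine rather than hard-coded because
coordinate conventions drift across atlas files; the header affine (sform
if valid, else qform) is authoritative.

Atlas "dilation" is per-label Gaussian smoothing (σ = 8 mm) followed by
argmax relabelling of originally unlabeled voxels. Each label's smoothed
response is normalized to its own peak, and voxels whose best response
falls below 1 % of that peak stay unlabeled — this bounds the spread at
roughly 3σ however thick the labelled slab is. Ties go to the lowest label
id. Originally labelled voxels are never changed. Point classification is
nearest-voxel lookup through the inverse affine; points outside the grid
are unlabeled and excluded from regional (but not global) medians.
Registration of atlas to subject space is out of scope: cloud and atlas
must share a world space (an upstream rigid/nonlinear registration step in
any real deployment).

Regions holding under 1 % of classified points are flagged unreliable and
excluded from slope analysis; on real skull masks this is the temporal
bone, whose share of the supratentorial surface is tiny.

## Longitudinal statistics

Scans are stratified at 20 years (boundary age assigned to the adult
stratum) because skull growth levels off around that age; slopes are
unweighted OLS per subject and stratum, requiring ≥ 2 scans at distinct
ages, with missing thickness dropped per-measure and never imputed.

The comparison design is chosen from the data: Shapiro–Wilk for groups of
≤ 50 slopes, Lilliefors-corrected Kolmogorov–Smirnov above (the KS null
parameters are estimated from the sample, so the standard KS p-value would
be anti-conservative), and Levene's test for variance homogeneity, all at
α = 0.05. Three groups fall back to Kruskal–Wallis when any assumption
fails; two groups use a t-test, Welch-corrected when Levene rejects.
Dunn's post-hoc z-tests use pooled mid-ranks with the tie correction
Σ(t³−t)/(12(N−1)) and Bonferroni multiplication by the number of pairs,
gated on omnibus p < α (a flag can force them). Constant data degenerate
to statistic 0, p = 1.

The ICV–thickness association is a REML random-intercept model
(statsmodels MixedLM), fitted within one group on scans at age ≥ 20, with
sex coded female = 0 / male = 1 so the sex coefficient is the male ICV
offset. p-values for fixed effects are Wald tests, not Satterthwaite — a
known mild anti-conservatism at small subject counts, accepted as a
limitation. Boundary fits (random-intercept variance pinned at 0) are
reported with a note rather than an error; at the boundary the fixed
effects coincide with pooled OLS.

## Synthetic data

The generator exists because the clinical cohorts this methodology targets
are not deposited. It emulates two things.

**Geometry.** Shell phantoms: the inner surface is a subdivided icosphere
(subdivision 4, ~5120 faces, volume accurate to 0.22 % for cranial radii),
optionally scaled to an ellipsoid or halved (hemisphere with a
fan-triangulated flat cap); the outer surface displaces the inner vertices
along exact analytic outward normals by a gap field (constant or angular),
plus optional Gaussian jitter emulating segmentation noise. True ICV and
the true thickness field are therefore known in closed form. The inward
remodeling simulator recedes the inner table along its normals with the
outer table fixed, so thickness gain is exact and volume loss follows the
thin-shell identity ΔV ≈ A·δ. What this does *not* emulate: real skull
topology (foramina, skull base), segmentation topology errors, or
spatially correlated segmentation noise — so passing phantom tests
validates the measurement chain, not the upstream segmentation.

**Cohorts.** Subjects draw sex, an entry age, ICV/thickness intercepts and
per-stratum slopes; scans evaluate a piecewise-linear latent trajectory
(break at 20 years) plus i.i.d. measurement noise. The default template
(`data/cohort_default.json`) encodes the group sizes (MLD 20/14, MS 199,
control 12/52 for the young/adult strata) and Gaussian slope mean ± sd per
group and stratum reported in published three-group longitudinal skull
morphometry, with measurement noise of 7 mL (ICV) and 0.05 mm (median
thickness) chosen to match typical scan–rescan repeatability of
segmentation-based measures; intercept distributions (~1350 ± 110 mL, men
≈ +130 mL; ~6.5 ± 0.9 mm, men ≈ −0.3 mm) reflect normative adult values.
Ages are uniform within the entry window, scan intervals fixed (3 scans,
2 years apart), with no dropout model. In `inward_remodeling` mode the
latent ICV slope is exactly −gain × thickness slope — the coupling is a
free parameter, not a mechanistic claim. A separate generator
(`generate_association_cohort`) draws directly from the random-intercept
association model for mixed-model parameter-recovery studies, and a mesh
cohort generator chains phantom evolution to scans for small end-to-end
runs (meshes are heavy; subdivision 3 and ~10⁴–10⁵ points keep those runs
in seconds).

Because the template slope distributions are Gaussians matched only to the
published mean ± sd, the generated fitted-slope distributions have
slightly larger spread than the printed sd (OLS estimation noise adds in
quadrature) and — more importantly — much weaker rank separation between
the small MLD group and controls than the real data evidently had (the
real slope distributions failed normality tests; their shape is not
recoverable from printed summaries). Simulation studies of the rank-based
post-hoc pattern on this template therefore measure the machinery's
behaviour under a moment-matched Gaussian stand-in, not the real cohort's
separability: the full published significance pattern reproduces in only
~10–20 % of template draws, driven almost entirely by the
MLD-versus-control ICV contrast at n = 14.

## Numerical and design choices

- Units: mm and mL throughout; conversions happen once, at volume
  computation.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); pipelines re-run byte-identically.
- `measure_skull` samples the outer cloud with `seed` and the inner with
  `seed + 1` so the two clouds are independent but jointly reproducible.
- Median of an even count is the midpoint of the central order statistics.
- Degenerate inputs fail loudly with typed exceptions (topology, empty
  filter, insufficient data, parameter) rather than returning NaNs;
  constant-data statistical comparisons degenerate to p = 1 with a logged
  note instead of erroring.
- Problem sizes in the test-suite simulations (e.g. 100-seed recovery
  studies, 1000-replicate calibration runs, 2·10⁵-point phantom scans in
  unit tests with the full 5·10⁵/10⁶ scans reserved for the acceptance
  checks) were chosen to give stable Monte-Carlo estimates at interactive
  runtimes.

## Known limitations

- The k-NN thickness bias makes absolute medians density- and k-dependent;
  only measurements at identical settings are comparable.
- Wald inference for mixed-model fixed effects; no Satterthwaite or
  Kenward–Roger correction.
- The exclusion-plane constant assumes the atlas shares the standard
  2 mm grid orientation up to its affine.
- The cohort generator's linear-plus-noise trajectories ignore pediatric
  growth curvature, dropout, and scanner effects.
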