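# cranioquant

Quantification of skull thickness and intracranial volume (ICV) from inner
and outer skull surface meshes, with the longitudinal statistics needed to
ask whether a skull is remodeling: per-subject rates of change, group
comparisons, and the mixed-effects association between skull thickening and
ICV loss.

The package is aimed at neuroimaging researchers studying disorders with
progressive brain atrophy (e.g. metachromatic leukodystrophy, multiple
sclerosis). In such disorders the skull may grow inward along its inner
table, thickening while the intracranial volume shrinks — a confound for
any analysis that normalizes brain volumes by ICV. Because clinical MRI
cohorts of this kind are rarely shareable, the package also ships a
synthetic-data module that generates skull phantoms and longitudinal
cohorts with known ground truth, so every stage of the pipeline is testable
end to end.

## Method

**Thickness.** Given inner and outer skull surfaces (PLY/STL/OFF triangle
meshes, mm), `n = 5·10⁵` points are sampled area-uniformly on each surface.
For each outer point `x_i`, thickness is the mean Euclidean distance to its
`k = 30` nearest neighbours among the inner points,

    t_i = (1/k) Σ_{j ∈ NN_k(x_i)} ‖x_i − y_j‖,

with physical bounds 0.5 mm ≤ t_i ≤ 12 mm (inclusive) flagging implausible
values. The scan statistic is the **median** over in-bounds points, since
per-skull thickness distributions are skewed.

**ICV.** The volume enclosed by the watertight inner surface, from the
divergence theorem: `V = (1/6) Σ_faces v0 · (v1 × v2)`, reported in mL.

**Regions.** Points are restricted to the supratentorial calvaria (world
z ≥ the z of axial slice 28 of the 2 mm MNI grid, −16 mm under the standard
affine) and partitioned into frontal/parietal/occipital/temporal territory
by a labelled atlas volume whose labels are first spread outward by an
8 mm-σ Gaussian dilation. Regions holding < 1 % of classified points
(typically the temporal bones) are flagged unreliable.

**Statistics.** Per subject and per age stratum (< 20 / ≥ 20 years), OLS
slopes ΔICV (mL/yr) and Δthickness (mm/yr) versus age (≥ 2 scans).
Group comparisons are assumption-gated: Shapiro–Wilk (n ≤ 50) or
Lilliefors/KS normality plus Levene's variance test select a t-test,
one-way ANOVA, or Kruskal–Wallis with Dunn's Bonferroni-corrected post-hoc
z-tests. The ICV–thickness association is a REML linear mixed model

    ICV_ij = β₀ + β_t · thickness_ij + β_sex · male_i + a_i + ε_ij,

with subject random intercepts `a_i`; `β_t` (mL/mm) is the volume lost per
millimetre of thickening.

## Worked example

```python
import cranioquant as cq

# a concentric-sphere skull phantom: inner radius 80 mm, true gap 3 mm
ph = cq.make_shell_phantom("sphere", 80.0, 3.0, subdivision=4)
print(round(cq.enclosed_volume(ph.inner_mesh), 1))   # 2140.0 (mL; analytic 2144.7)

cloud, summary = cq.measure_skull(ph.inner_mesh, ph.outer_mesh,
                                  n_points=500_000, k=30, seed=0)
print(round(summary.median_mm, 3))                   # 3.129 (mm; true gap 3.0)

# the skull remodels inward by 0.5 mm: thickness up, ICV down by ~A·δ
evolved = cq.evolve_inward(ph, 0.5, 1)[0]
print(round(cq.enclosed_volume(ph.inner_mesh)
            - cq.enclosed_volume(evolved.inner_mesh), 1))  # 39.9 (mL; 4πR²δ ≈ 40.2)
```

The measured median exceeds the true 3 mm gap by ≈ 0.13 mm: averaging the
30 nearest neighbours includes tangentially offset points, a bias of order
`E[s²]/2t` at the sampling density used (see `docs/methods.md`).

Cohort-level statistics run from a scan table (CSV: subject_id, group, sex,
age_years, icv_ml, thickness_mm):

```bash
cranioquant simulate-cohort --seed 0 --out cohort.csv
cranioquant slopes --scans cohort.csv --out slopes.csv
cranioquant compare --slopes slopes.csv --stratum over20 --measure d_icv
cranioquant lmm --scans cohort.csv --group MLD
```

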