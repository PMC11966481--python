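# corticalmark

Functional cortical deficit-pattern biomarkers from regional brain measures.

Case–control neuroimaging studies of major depressive disorder (and other
psychiatric conditions) report small, noisy regional differences — but the
*pattern* of those differences across cortical regions replicates across
cohorts and modalities far better than any single region does.  `corticalmark`
implements the full analysis chain for pattern-based biomarkers:

1. **ReHo** — voxelwise regional homogeneity of 4-D BOLD data, i.e. Kendall's
   coefficient of concordance *W* over each voxel's 3×3×3 neighborhood
   (27 series), reduced to bilateral regional means on a parcellation.
2. **Effect-size maps** — per-region case–control Cohen's *d* (pooled SD),
   after ordinary-least-squares adjustment for age and sex, with Bonferroni
   significance flags.  Deficits are negative (*case − control*).
3. **Spatial statistics** — Pearson correlation between regional maps,
   spin-permutation significance (random SO(3) rotations of spherical parcel
   centroids with nearest-centroid reassignment), and Fisher r-to-z
   comparison of correlations across cohort pairs.
4. **RVI** — the Regional Vulnerability Index: each subject's regional
   measures are z-scored against the control reference and correlated,
   across regions, with a template deficit pattern.  Subjects expressing the
   illness pattern score positively; RVI supports group contrasts and
   symptom-severity associations.
5. **Synthetic cohorts** — a generator for toy bilateral atlases, 4-D time
   series with controllable within-region temporal coherence, and two-group
   regional tables with planted effect patterns, covariate structure and
   severity ratings — so the whole pipeline runs end-to-end with no
   restricted data.

The statistics at the core are

```text
W  = 12 Σ_t (R_t − K(T+1)/2)² / (K²(T³−T) − K Σ_k C_k)        (ReHo / KCC)
d_j = (x̄_case,j − x̄_ctrl,j) / s_pooled,j                      (deficit map)
RVI_i = corr_j( z_ij , d_template,j )                          (vulnerability)
z  = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3))            (Fisher)
```

## Worked example

```python
import numpy as np, pandas as pd
from corticalmark import (SimulationConfig, simulate_regional_cohort,
                          DeficitPatternModel, RVIModel, TemplateVector,
                          spin_permutation_p)

rng = np.random.default_rng(7)
planted = rng.uniform(-0.5, 0.0, 34)              # a deficit pattern over 34 regions
cfg = SimulationConfig(n_cases=300, n_controls=300, planted_d=planted,
                       beta_age=0.002, beta_sex=0.05, seed=7)
cohort = simulate_regional_cohort(cfg)

res = DeficitPatternModel(cohort).fit()           # age/sex-adjusted Cohen's d map
s = res.summarize()
print(f"mean d = {s['mean_d']:+.3f} (SD {s['sd_d']:.3f}) over {s['n_regions']} regions")

centroids = rng.normal(size=(34, 3))
centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
spin = spin_permutation_p(res.d.to_numpy(), planted, centroids, n_perm=999, seed=7)
print(f"map correlation with planted pattern: r = {spin.r:.2f}, p_spin = {spin.p_spin:.3f}")

template = TemplateVector(pd.Series(planted, index=cfg.region_names), "planted")
print(RVIModel(cohort, template).fit().summary())
```

prints

```text
mean d = -0.258 (SD 0.173) over 34 regions
map correlation with planted pattern: r = 0.89, p_spin = 0.002
Regional Vulnerability Index
  template:  planted (34 regions, pearson)
  subjects:  600 scored (300 cases, 300 controls)
  contrast:  Cohen's d = +0.923, t = +11.30, p = 5.58e-27
  severity:  Pearson r = +0.233, p = 4.66e-05 (n = 300)
```

The adjusted map recovers the planted deficit pattern (mean *d* ≈ the planted
mean of −0.25), the spin test confirms the map–template agreement is far
beyond what random rotations produce, and cases score visibly higher than
controls on the RVI, with RVI tracking symptom severity among cases.

## Command line

Every stage is also a subcommand (`corticalmark simulate | reho | esmap |
spin-test | rvi | run | validate`); `run --config config.yaml` executes the
configured stages end-to-end into an output directory with a reproducibility
manifest.  Exit codes: 0 ok, 1 data error, 2 usage error.

```bash
corticalmark reho --bold sub01_bold.nii.gz --mask mask.nii.gz --out reho.nii.gz
corticalmark esmap --table regional.tsv --covars age,sex --out esmap.tsv
corticalmark spin-test --map-a esmap_a.tsv --map-b esmap_b.tsv \
    --centroids centroids.tsv --n-perm 999 --seed 7
corticalmark rvi --table regional.tsv --template template.tsv --out rvi.tsv
```

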