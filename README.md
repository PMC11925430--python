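# cranial-iip

Quantitative evaluation of cranial bone signs of increased intracranial
pressure (IIP) in craniosynostosis, from CT-like volumes.

Children with craniosynostosis — premature fusion of one or more cranial
sutures — are at risk of chronic IIP, which is hard to diagnose: invasive
pressure measurement is rarely performed and clinical signs are subtle. A
consistent radiological signature of chronic IIP is calvarial remodeling:
bone **density** drops by on the order of 100–250 HU while **thickness**
changes are smaller. This package implements the computational pipeline for
detecting that signature:

1. **Preprocessing** (`volume_io`) — NIfTI/NRRD input, exclusion of scans
   coarser than 0.5 mm in-plane / 1.5 mm slices, trilinear resampling to a
   uniform 0.5 × 0.5 × 1.5 mm grid.
2. **Quantification** (`calvaria_metrics`) — calvaria segmentation, labeling
   of the five calvarial bones (frontal L/R, parietal L/R, occipital) with
   canonical suture bands, and local thickness (mm) / density (HU) measured
   along centroid rays on a standardized 2562-direction surface grid that
   gives cross-subject correspondence.
3. **Normative modeling** (`normative_model`) — per-region linear model

   `Y = β₀ + β₁·Age + β₂·Sex + β₃·V + β₄·IIP + β₅·MC + β₆·SC + β₇·UCC + β₈·BCC + β₉·AS + ε`

   with mutually exclusive diagnostic indicators (metopic, sagittal,
   unicoronal, bicoronal, Apert); covariate-adjusted measurements and Welch
   t contrasts between phenotype groups.
4. **Risk screening** (`iip_risk`) — logistic classifier on adjusted
   densities (normative vs chronic IIP), Youden-index and ≥95%-specificity
   operating points selected on cross-validated scores, per-group prevalence,
   Mann-Whitney U comparisons with Bonferroni correction, Spearman risk–age
   correlation.
5. **Synthetic data** (`synthetic_data`) — ellipsoidal skull phantoms with
   analytic thickness/density ground truth, and simulated cohorts with the
   statistical structure and effect magnitudes of the published study, so
   the whole pipeline is testable without patient data.

## Worked example

```python
import numpy as np
from cranial_iip import (PhantomSpec, generate_skull_phantom, quantify_volume,
                         default_cohort_design, simulate_cohort,
                         fit_normative_regression)

# a spherical bone shell, inner 70 / outer 74 mm, 800 HU, CT-like voxels
spec = PhantomSpec(outer_radii=(74, 74, 74), thickness_field=4.0,
                   density_field=800.0, suture_gaps=[], spacing=(0.5, 0.5, 1.5))
vol, truth = generate_skull_phantom(spec)
maps, grid, summary = quantify_volume(vol)
print(f"mean thickness: {maps.thickness[maps.valid].mean():.3f} mm "
      f"(truth {truth.thickness_map.mean():.1f} mm)")
print(f"mean density:   {maps.density[maps.valid].mean():.1f} HU")

# a cohort at the published composition (1018 normative, 48 IIP, 403 CS, 19 AS)
cohort = simulate_cohort(default_cohort_design(rng_seed=1))
fit = fit_normative_regression(cohort, "global", "density")
print(f"IIP density effect: {fit.group_effect('IIP'):+.1f} "
      f"+/- {fit.se[4]:.1f} HU (designed -163.7)")
```

prints

```
mean thickness: 3.988 mm (truth 4.0 mm)
mean density:   800.0 HU
IIP density effect: -156.1 +/- 20.1 HU (designed -163.7)
```

The measured thickness agrees with the analytic shell to well under the
1.5 mm slice spacing; density is exact on a noiseless phantom; and the
global calvarial density deficit of the simulated chronic-IIP group is
recovered by the regression within one standard error of the designed
−163.7 HU.

## Command-line pipeline

```bash
cranial-iip all --seed 1 --out-dir pipeline_out          # simulate → quantify → analyze
cranial-iip simulate --config my_config.yaml --out-dir out
```

Each stage writes CSV/JSON reports (group-contrast tables, UCC side-resolved
contrasts, ROC, risk scores, prevalence per threshold, distribution
comparisons) and a manifest with the config hash, seed, package versions and
SHA-256 of every output, so runs are exactly reproducible.

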