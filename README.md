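# vortexlcs

Lagrangian-coherent-structure (LCS) analysis of the diastolic vortex ring in
the left ventricle, from time-resolved three-component (4D phase-contrast)
velocity fields.

During filling, blood entering through the mitral valve rolls up into a
vortex ring. The ring's outer boundary is a material surface — the interface
between inflowing and resident blood — and its size and position relative to
the chamber wall carry physiological information (filling efficiency,
vortex-wall coupling, formation reserve). `vortexlcs` is for researchers in
cardiac flow imaging who want a reproducible, scriptable version of this
analysis: from raw velocity volumes to vortex contours, volumetric metrics
and cohort statistics, with synthetic flows providing exact ground truth for
validation.

## Method

For each diastolic timeframe, particles seeded 0.8 mm apart on short-axis
planes are advected **backwards in time** (classic RK4, 5 ms step) to the
beginning of vortex ring formation (detected E-wave onset). The flow-map
gradient G over the seeding plane gives the Cauchy–Green tensor C = GᵀG and
the finite-time Lyapunov exponent

FTLE = ln √λ_max(C) / |T|   (1/s),

whose ridges mark attracting material boundaries. Per timeframe the FTLE
field is normalised to its 95th percentile; seeds above 50 % of that value
form the ridge, which is traced into closed contours (blind ridge ends
bridged with straight segments), cropped to the endocardium, and converted
to volumes by slice summation (Σ area × thickness). Derived metrics:

- **VV%** — vortex volume as a percentage of LV volume;
- **vortex–wall distance** — (3V_LV/4π)^⅓ − (3V_vortex/4π)^⅓ in mm;
- **effective diameters** — equal-area-circle diameters of the mitral flow
  profile and the largest LCS cross-section, and their ratio;
- **VFR** — vortex formation ratio L/D = 4V/(πD³);
- group comparisons (Mann-Whitney-Wilcoxon) and an OLS correlation battery
  with Bonferroni correction (α/32 = 0.0015625).

Preprocessing covers first-order background-phase correction against a
stationary-tissue mask and VENC phase unwrapping. The `synthetic_data`
module generates analytic benchmark flows (double gyre, Hill's spherical
vortex, planar strain, solid rotation) and a kinematic ventricle phantom
(3 mm isotropic, 40 timephases) with exact vortex ground truth. See
`docs/methods.md` for the full model description and limitations.

## Worked example

```python
import vortexlcs as v
from vortexlcs.synthetic_data import synthetic_ventricle

field, truth = synthetic_ventricle(seed=17)
lv = v.slice_summation_volume(truth.endo_contours)
vortex = v.slice_summation_volume(truth.vortex_contours).reindex(lv.index, fill_value=0.0)
ed = lv.index[-1]  # end-diastole

print(f"end-diastolic LV volume     : {lv[ed]:6.1f} ml")
print(f"end-diastolic vortex volume : {vortex[ed]:6.1f} ml")
print(f"vortex volume fraction VV%  : {v.vortex_volume_fraction(vortex[ed], lv[ed]):6.1f} %")
print(f"vortex-wall distance        : {v.vortex_wall_distance(lv[ed], vortex[ed]):6.2f} mm")
print(f"vortex formation ratio      : {v.vortex_formation_ratio(truth.inflow_volume_ml, truth.mitral_diameter_mm):6.2f}")
```

prints

```
end-diastolic LV volume     :  150.8 ml
end-diastolic vortex volume :   80.0 ml
vortex volume fraction VV%  :   53.1 %
vortex-wall distance        :   6.29 mm
vortex formation ratio      :   3.62
```

i.e. the phantom's vortex ring holds 53 % of a 151 ml ventricle at
end-diastole, its boundary sits ~6.3 mm inside the sphere-equivalent wall,
and the E-wave inflow column is 3.6 inlet diameters long. Running the full
pipeline instead of the ground-truth contours (`vortexlcs run --out rundir`)
recovers the same VV% curve from the velocity field alone to within a few
percentage points.

The same stages are scriptable from the shell:

```sh
vortexlcs synth --model synthetic_ventricle --seed 17 --out dataset/
vortexlcs ftle --field dataset/field.h5 --endo dataset/endo_contours.csv \
          --t-origin 375 --out lcs.csv
vortexlcs metrics --lcs lcs.csv --endo dataset/endo_contours.csv --out metrics.csv
vortexlcs stats --metrics cohort.csv --out report.csv
```

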