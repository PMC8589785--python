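# ventrimetry

Angular and linear radiological indices of lateral ventriculomegaly —
Evans' index (EI), the callosal angle (CA), and the splenial angle (SA), a
simple axial angular index measured on DTI directionally-encoded color FA
maps — together with:

- a DTI pipeline (log-linear tensor fit, FA, principal eigenvector, RGB
  directional encoding) for NIfTI volumes with FSL-style bval/bvec sidecars;
- a fully automated SA measurement: red-dominant commissural masking,
  caudocranial selection of the first axial slice with a complete callosal
  body, midline detection, and straight-ray fitting of the forceps-major
  limbs around a midline pivot;
- 3D digital head phantoms with analytically known ground-truth EI/CA/SA
  (wedge-roof ventricles, a draped callosal sheet, straight forceps limbs at
  a prescribed opening angle), plus a coronal-plane tilt/rotation experiment
  quantifying CA sensitivity to mal-angulation;
- synthetic four-group cohorts (HC/PD/AD/NPH, n = 19 each) and paired
  shunt/no-shunt follow-up tables drawn from canonical published group
  moments;
- the statistical evaluation harness: ICC(A,1) with F-based CIs, one-way
  ANOVA, pairwise t-tests with Benjamini–Hochberg adjustment, ROC screening
  analysis (empirical AUC, DeLong CIs, closest-to-top-left cutoffs),
  bidirectional-AIC stepwise logistic prediction, and between-arm Student's
  t-tests on follow-up changes.

## Command line

```sh
# fit tensors and write FA / e1 / RGB maps
ventrimetry tensor dwi.nii.gz dwi.bval dwi.bvec -o maps/

# generate a phantom with a ground-truth sidecar (ventriculomegaly factor 2)
ventrimetry phantom -o phantom/ -v 2.0

# automated splenial angle on a tensor volume
ventrimetry measure phantom/phantom_tensor.nii.gz --index sa -o sa.json

# EI / CA from landmark JSON files
ventrimetry measure flair.nii.gz --index ei --landmarks ei.json -o ei.json

# simulate the canonical 4 x 19 cohort (+ paired follow-up table)
ventrimetry cohort -o cohort.csv --seed 1 --followup followup.csv

# full statistical report bundle
ventrimetry evaluate cohort.csv -o report/ --followup followup.csv
```

Every artifact embeds the seed and a configuration hash; identical
invocations produce byte-identical outputs.

## Layout

| module | contents |
| --- | --- |
| `ventrimetry.dti` | DWI/tensor/FA/e1/RGB types and operations |
| `ventrimetry.geometry` | angle kernel, EI/BCI/CA/SA measurement, SA slice selection, tilt experiment |
| `ventrimetry.autosa` | automated SA landmarking chain with audit trail |
| `ventrimetry.simulate` | phantoms, cohort and follow-up simulation, canonical moments |
| `ventrimetry.stats` | ICC, ANOVA, BH pairwise tests, ROC, stepwise logistic, follow-up t-tests |
| `ventrimetry.nifti`, `ventrimetry.config`, `ventrimetry.cli` | I/O, run configuration, CLI |

Coordinates are millimetres in a canonical RAS frame (volumes are reoriented
on load); axial slices are ordered caudocranially, and the red channel of the
color map is tied to the left–right axis.
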