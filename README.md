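# petsubvol

Longitudinal ¹⁸F-FDG PET analysis of **where tumors recur** relative to
their baseline metabolic uptake, for head-and-neck squamous cell carcinoma
treated by radio-chemotherapy.

Dose-painting radiotherapy proposes boosting dose to the most FDG-avid
intra-tumor sub-volumes seen on the staging PET.  That strategy presumes
local failure arises *inside* those sub-volumes.  `petsubvol` implements
the analysis that tests the presumption on sequential PET/CT pairs:

1. **Rigid registration** of the follow-up scan pair onto the baseline pair
   (mutual-information maximization on the anatomical volumes, restricted
   to a region derived from the baseline PET high-uptake area; the rigid
   transform is then applied to the follow-up PET).
2. **Fixed-percentage SUVmax delineation**: seven baseline metabolic tumor
   sub-volumes I30 … I90 (thresholds 30–90% of SUVmax) and two
   post-treatment sub-volumes R40, R90 (whole recurrence / its hottest
   part), each the 26-connected component seeded at the SUVmax voxel, with
   MTV (cm³), SUVmean and TLG = MTV₄₀ × SUVmean₄₀.
3. **Five overlap indices** per (Ix, R) pair — Dice
   D = 2|I∩R|/(|I|+|R|), Jaccard J = |I∩R|/|I∪R|, overlap fraction
   OF = |I∩R|/min(|I|,|R|), VcI = |I∩R|/|I| and VcR = |I∩R|/|R| — plus a
   Cohen-kappa-style concordance grading.
4. **Cohort statistics**: Mann-Whitney U comparison of baseline MTV₄₀, TLG
   and SUVmax between complete responders (CR) and patients with local
   recurrence/residual disease (LRRD), with D'Agostino-Pearson
   normality-driven reporting.

Because clinical scan archives of this kind are not public, the package
includes a first-class **synthetic phantom generator** producing seeded,
ground-truthed baseline/follow-up PET + anatomical pairs and whole cohorts
with realistic clinical statistical structure (4 mm voxels, SUVmax ≈ 14 ± 4.5,
heterogeneous uptake, sub-volumes from ~40 cc at I30 down to sub-cc at I90,
known rigid repositioning transforms, edge-weighted recurrences, CR-vs-LRRD
volume separation).
See `docs/methods.md` for the model and every numerical choice.

## Worked example

```python
from petsubvol.cli_report import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(n_cr=3, n_lrrd=4, seed=7), "out/")
print(report.volume_summary.round(2))
for c in report.comparisons[:1]:
    print(f"{c.variable}: U={c.u_statistic:.1f} p={c.p_value:.3g}")
```

prints (run on this package, seed 7):

```
            scan  n  mean_cc  sd_cc
label
I30     baseline  4    41.63  11.18
I40     baseline  4    26.27   6.74
I50     baseline  4    15.87   4.17
I60     baseline  4     8.69   2.36
I70     baseline  4     4.59   1.23
I80     baseline  4     2.26   0.61
I90     baseline  4     0.77   0.16
R40    follow-up  4    38.82  14.08
R90    follow-up  4     0.75   0.31
MTV_I40_cc: U=1.0 p=0.114
```

Reading it: over the 4 simulated recurrence patients the baseline
sub-volumes shrink from ~42 cc at the 30% threshold to ~0.8 cc at 90%
(the hottest blob), the whole recurrence volume R40 is on the same scale
as the baseline volumes, and the recurrence hot spot R90 is sub-cc.  The
Mann-Whitney comparison of baseline MTV₄₀ between the 3 CR and 4 LRRD
patients gives p = 0.114 (exact path) — at these toy group sizes even a
near-complete separation (U = 1) is not significant; the full-size cohort
in the reproduction script below is.

The same pipeline is scriptable from the shell:

```bash
petsubvol run --outdir out --seed 7 --n-cr 35 --n-lrrd 38
petsubvol simulate --outdir phantoms --n-cr 1 --n-lrrd 1   # NIfTI + ground truth
petsubvol register --fixed-anat b_ct.nii.gz --moving-anat f_ct.nii.gz \
    --fixed-pet b_pet.nii.gz --moving-pet f_pet.nii.gz \
    --out-transform t.json --out-pet f_pet_aligned.nii.gz
petsubvol delineate --pet b_pet.nii.gz --voi -60 -40 -60 80 90 70 --outdir masks
```

`run` writes `patients.csv` (per-patient scalars and transforms),
`table1_volumes.csv` (per-threshold mean ± SD MTVs), `table2_presence.csv`
(patients with any Ix∩R90 overlap), `figure1_indices.csv` (per-threshold
overlap-index means), `group_comparisons.csv` and a consolidated
`report.json` with a provenance block (config digest, seed, version).

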