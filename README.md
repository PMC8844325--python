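# mbfvs

Vessel-specific myocardial blood flow (MBF) quantification from dynamic PET
fused with CT-derived cardiac anatomy, plus a digital biventricular phantom so
the whole pipeline can be exercised and stress-tested end to end without
patient data.

The pipeline:

1. **phantom** — synthetic short-axis anatomy (LV/RV blood pools, epicardial
   envelope), coronary centerlines for three territories (LAD / LCX / rPDA),
   a gamma-variate arterial input function, voxelwise 2-tissue-compartment
   kinetics, seeded dynamic-frame simulation, and segmentation-defect
   perturbations (apex truncation, RV encroachment, border jitter) emulating
   fully-automated ("FA") and briefly-corrected ("C") masks.
2. **imaging** — volume / dynamic-series data model with NIfTI + CSV I/O,
   short-axis reorientation, block resampling, and late-frame summation
   (`pet_sum`) for registration.
3. **fusion** — LV-guided rigid initialization plus mutual-information
   refinement mapping CT anatomy into PET space, and centerline transfer.
4. **vessel_roi** — discretization of the myocardium under a fused centerline
   into contiguous 4-mm cubic ROIs (base to apex), per-ROI TAC extraction,
   and the arterial input TAC from the eroded LV cavity.
5. **kinetics** — irreversible 2-tissue compartment model (frame-averaged),
   bounded weighted least-squares fitting, and per-vessel flow profiles
   (MBF = fitted K1) with monotone interpolation.
6. **classification** — normal/abnormal stratification against low-risk flow
   bands, Dice agreement between pipelines (matched-fraction and abnormal-set
   variants), pooled globally / per territory, and Student's t tests.
7. **experiment / cli** — the reproducible mask-robustness experiment:
   simulate phantoms, fuse with reference and perturbed anatomy, extract
   profiles, classify, and tabulate Dice agreement.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria (kinetic
recovery, registration recovery, Dice oracle equivalence, end-to-end identity,
perturbation monotonicity, lesion localization); the remaining files are unit
and property tests per module.

## CLI

```bash
mbfvs simulate --preset SNUH --state rest --seed 1 --out out/sim
mbfvs fuse --pet-series out/sim/dpet_rest.nii.gz --schedule out/sim/schedule.csv \
    --lv out/sim/lv.nii.gz --rv out/sim/rv.nii.gz --epi out/sim/epi.nii.gz --out out/fuse
mbfvs flow --pet-series ... --schedule ... --lv ... --rv ... --epi ... \
    --centerline LAD out/sim/centerline_LAD.csv --out out/flow
mbfvs classify --profile out/flow/profile_LAD_rest.csv --ranges ranges.csv --out out/cls.csv
mbfvs compare --a out/cls_a.csv --b out/cls_b.csv --vessel LAD --state rest
mbfvs experiment --config config.yaml --out out/experiment
```

`mbfvs experiment` consumes a YAML `ExperimentConfig` (see
`mbfvs.experiment.ExperimentConfig` for keys and defaults) and writes DC
record/pooled tables, t tests, a seed manifest, the resolved config, and
per-vessel profile plots — staged to a temporary directory and renamed
atomically on success.

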