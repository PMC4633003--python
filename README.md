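# fvri — coronary remodeling from IVUS pullbacks via inferred normal dimensions

`fvri` quantifies coronary artery remodeling from intravascular-ultrasound
(IVUS) pullback measurements. Classical remodeling assessment compares a
diseased cross-section with nearby "reference" segments, which are rarely
truly normal. This package instead infers each cross-section's *pre-disease*
vessel size from constitutional and anatomical covariates and scores the
vessel's response to its own plaque with the **fractional vessel remodeling
index (FVRI)**:

```
FVRI = EEM_actual / (EEM_predicted + P)
```

where `EEM_actual` is the measured external-elastic-membrane area (mm²),
`P` is the plaque + media area (EEM − lumen), and `EEM_predicted` is the
inferred normal vessel area from a bootstrap multivariable linear model

```
EEM_predicted = b0 + b_dom·dominance + b_ves·vessel + b_dist·ln(distance) + b_bsa·BSA
```

trained on near-normal frames (plaque burden < 20%, lumen area 3.1–19.6 mm²),
where lumen and vessel area coincide. FVRI = 1 is complete compensatory
(Glagov) enlargement; frames and lesions are classified as **ectatic**
(FVRI > 1.17), **complete compensatory** (0.83–1.17), **incomplete
compensatory** (< 0.83 with EEM ≥ predicted) or **negative** (< 0.83 with
EEM < predicted, i.e. absolute shrinkage). A published fitted model ships as
the built-in `falcao2015-default`, so pullbacks can be scored without
refitting; lesions (runs of ≥ 3 frames above 40% burden) are additionally
classified by the classical reference-based index (cutoffs 0.88 / 1.00) and
the two schemes are cross-tabulated with percent agreement and Cohen's kappa.

The package is aimed at quantitative-imaging researchers who have per-frame
IVUS planimetry (and optionally virtual-histology composition) as delimited
tables, and at methodologists who want a fully simulated test bed: the
synthetic-cohort generator produces pullbacks with known per-frame and
per-lesion remodeling ground truth.

## Worked example

Simulate a 12-patient three-vessel cohort and run the full pipeline with the
packaged model:

```bash
fvri simulate --out sim --seed 7 --n-patients 12
fvri run sim/frames.csv sim/patients.csv --outdir out --model-source packaged
```

which prints the stage-by-stage record counts

```
counts: {'frames_read': 7388, 'classified_frames': 6216, 'lesions': 135, 'lesions_with_references': 129}
```

— 7,388 frames were read, 6,216 carry established plaque (burden ≥ 20%) and
were classified, 135 lesions were detected, and 129 of them have both a
proximal and a distal reference and therefore also get a classical index.
`out/report.md` then tabulates, among other things, the frame-level
remodeling mix of this synthetic cohort:

```
| class | n | % |
|---|---|---|
| negative | 1602 | 25.8 |
| incomplete_compensatory | 1006 | 16.2 |
| complete_compensatory | 3171 | 51.0 |
| ectatic | 437 | 7.0 |
```

i.e. about half of the diseased cross-sections show complete compensatory
enlargement, ectasia is rare, and the remainder split between incomplete
compensation and true vessel shrinkage. `out/frames_scored.csv` holds the
per-frame geometry, `EEM_predicted`, FVRI and class; `out/lesions.csv` one
row per lesion with both classifications; `out/agreement.json` the 4×3
cross-tabulation with marginals, agreement and kappa.

The model can also be refitted to your own (or simulated) data instead of
using the packaged equation:

```bash
fvri fit sim/frames.csv sim/patients.csv --bootstrap 5000 --seed 1 --out model.json
fvri score sim/frames.csv sim/patients.csv --model model.json --out scored.csv
```

`fvri --version` prints the provenance of the packaged default model.

## Library use

Every CLI stage is a thin wrapper over `fvri`'s public API:

```python
from fvri import (SimulationConfig, simulate_cohort, score_frames,
                  assess_lesions, agreement_table, FALCAO2015_DEFAULT, FvriConfig)

sim = simulate_cohort(SimulationConfig(seed=7, n_patients=12))
scored = score_frames(sim.cohort, FALCAO2015_DEFAULT, FvriConfig())
lesions = assess_lesions(scored)
print(agreement_table(lesions).overall_agreement_pct)
```

See `docs/methods.md` for the model, the simulator's generative assumptions,
and numerical conventions.

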