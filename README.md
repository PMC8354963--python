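# sinusid

3D-3D superimposition of frontal-sinus surface models for forensic personal
identification, with a full replication of the four reference-model
protocol study on a calibrated synthetic cohort.

## The problem

The frontal sinuses are among the most individually distinctive anatomical
structures, which makes them a candidate for radiological identification:
an antemortem (AM) CT scan is compared with a postmortem (PM) one by
segmenting the sinus from each scan, superimposing the two 3D surface
models, and quantifying their difference. The standard workflow has two
steps, each of which needs a *reference* ("master") model:

1. **Registration** — the other ("slave") model is moved rigidly onto the
   reference, minimising the point-to-point distance over the whole
   surface (ICP);
2. **Distance calculation** — the RMS of closest-point distances from one
   model's vertices to the reference surface:

   RMS = sqrt( (1/n) Σᵢ d(vᵢ, S)² ),

   where d(v, S) is the Euclidean distance from vertex v to the nearest
   point of surface S. A pair is called a *match* when RMS falls below the
   0.96 mm literature threshold.

With two models there are four protocols, depending on which model is the
reference at each step:

| group | registration reference | distance reference |
|-------|------------------------|--------------------|
| A     | sample 1               | sample 2           |
| B     | sample 1               | sample 1           |
| C     | sample 2               | sample 1           |
| D     | sample 2               | sample 2           |

The scientific question this package replicates: **does the choice of
reference model change the outcome?** The study design is 50 subjects,
each segmented twice (samples 1 and 2), giving 50 same-subject (match)
superimpositions plus 50 random different-subject (mismatch) pairings,
each run under all four protocols, followed by paired Student's t-tests
between reference-swapped groups and Pearson correlations of the RMS
differences against sinus size differences (maximum breadth, maximum
height, volume).

Because no CT data accompany the design, the package ships a synthetic
frontal-sinus generator calibrated to the published population statistics
(breadth 56.9 ± 11.2 mm, height 32.0 ± 7.0 mm, volume ≈ 8.9 cm³) with a
repeated-segmentation noise model tuned so match superimpositions land in
the reported ≈ 0.18 mm RMS regime.

## Worked example

```python
from sinusid import SuperimpositionStudy

study = SuperimpositionStudy.simulate(n_subjects=50, master_seed=42)
results = study.fit()
print(results.summary())
```

prints (abridged):

```
3D-3D superimposition study (four reference-model protocols)
================================================================
pairs: 50 matches, 50 mismatches

RMS point-to-point distance (mm), mean +/- SD:
  matches     A=0.16+/-0.02 B=0.16+/-0.02 C=0.16+/-0.02 D=0.16+/-0.02
  mismatches  A=3.96+/-2.69 B=3.24+/-1.93 C=3.89+/-2.38 D=3.27+/-2.30

|RMS difference| between protocols (mm), mean:
  matches     |B-C|=0.00 |A-D|=0.00 |A-B|=0.00 |C-D|=0.00
  mismatches  |B-C|=0.65 |A-D|=0.69 |A-B|=2.47 |C-D|=2.61

paired t-test p-values (reference swaps):
  registration     B-C: matches p=0.376  mismatches p=4.94e-06
  registration     A-D: matches p=0.533  mismatches p=4.32e-06
  rms_calculation  A-B: matches p=0.569  mismatches p=1.71e-01
  rms_calculation  C-D: matches p=0.371  mismatches p=2.28e-01

separation at 0.96 mm threshold: max match RMS = 0.280 mm, min mismatch RMS = 0.970 mm
  overlap: no; classification accuracy 100.0%
```

Reading the output: match superimpositions are insensitive to every
reference choice (all four groups ≈ 0.16 mm, all swap differences ≈ 0.00,
all paired tests non-significant). In mismatches, swapping the
*registration* reference changes RMS systematically (p < 0.001) — the RMS
measured in the direction the ICP minimised is the smaller one — while
swapping the *distance* reference produces large but sign-random
differences (p > 0.05) that track how different the two sinuses are in
size. Match and mismatch RMS never overlap across the 0.96 mm threshold,
so identification is unaffected by the protocol choice.

`results.frame` holds the per-pair quartets as a DataFrame;
`results.tables.table1/2/3` are the summary, paired-t and correlation
tables; `results.plot_rms("rms.png")` draws the RMS distribution by group
and match status.

The same pipeline is scriptable from the shell:

```bash
sinusid replicate-study --quick --out study_out       # small fast profile
sinusid generate --n-subjects 50 --out cohort/        # meshes + manifest
sinusid superimpose cohort/sample1_subject000.ply cohort/sample2_subject000.ply \
    --out pair_out                                    # one pair + chromatic maps
```

`superimpose` prints the four RMS values, classifies the pair at the
threshold, and writes blue/green/red chromatic-map PLYs (green = surfaces
within the band, red/blue = outward/inward deviation).

## Layout

- `sinusid.mesh` — mesh I/O (PLY/STL/OBJ), validation, breadth/height/volume
- `sinusid.distance` — exact point-to-surface distance fields, chromatic maps
- `sinusid.registration` — whole-surface point-to-point ICP with PCA multi-start
- `sinusid.protocols` — the four reference-model protocols per pair
- `sinusid.stats` — paired t, Pearson r, the three study tables, separability
- `sinusid.synthetic` — sinus generator, re-segmentation noise, cohort builder
- `sinusid.study` — `SuperimpositionStudy` / `StudyResults` (model/results)
- `sinusid.cli` — `sinusid generate | superimpose | replicate-study`

See `docs/methods.md` for the model assumptions, calibration choices and
known limitations.
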