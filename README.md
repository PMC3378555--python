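# retinowm

Retinotopic mapping of spatial working-memory delay activity in early
visual cortex — a tested, reusable Python pipeline, exercised end-to-end on
synthetic BOLD data with known ground truth.

## The scientific problem

Spatial relations come in two flavors: *categorical* (region-based, e.g.
"the dot is in the opposite quadrant") and *coordinate* (metric, e.g. "the
dot is at the same distance from the center"). If the two are processed by
different mechanisms, the way attention is distributed over the visual
field during a memory delay should differ between them — and because
spatial attention modulates retinotopically organized activity in V1/V2/V3,
that difference is measurable as a redistribution of BOLD signal across the
retinotopic map during the retention interval of a delayed-comparison task.

The pipeline implements the full analysis chain for this question:

1. **Phase-encoded retinotopy.** A 45° wedge rotates clockwise (8 cycles of
   54 000 ms, one volume every 540 ms, 100 volumes per cycle) and a ring
   expands from 0.4° to 7.5° eccentricity. Each voxel's time course is
   Pearson-correlated with an HRF-convolved cyclic activation vector at
   every integer lag 0–99; the peak lag decodes the voxel's polar angle
   (wedge) or eccentricity (ring). Voxels pass a Bonferroni-corrected
   activation mask (p < .05 / n voxels).
2. **Visual-field segment ROIs.** Decoded polar angles are binned into the
   four quadrants (0–90°, …, 270–360°); eccentricities are binned around
   the four stimulus radii (1.875°, 3.75°, 5.625°, 7.5°). Per trial, the
   *matching* region is the diagonally opposite quadrant (categorical
   instruction) or the stimulus ring (coordinate instruction).
3. **Concatenated-segment GLM.** The four segment mean time courses of one
   area are concatenated (length 4 T) and fit jointly with one design:
   per-trial delay boxcars placed in the matching / mismatching segment
   blocks, S1/S2 impulse events in the blocks containing the stimulus, an
   eccentricity parametric modulator, and per-block constants plus an
   8-component discrete-cosine high-pass set. OLS yields delay-period
   betas per (area, instruction, region).
4. **Group statistics.** Three-way ROI × instruction × region
   repeated-measures ANOVA on the delay betas (univariate,
   Greenhouse–Geisser, and multivariate variants), per-ROI follow-ups with
   paired post-hocs, instruction × stimulus ANOVAs, behavioral paired
   t-tests, and a "contrast activation" ANOVA that checks the two ROI
   definitions discriminate visual-field locations equally well.

The synthetic-data module generates retinotopically organized voxel sheets
(ground-truth area / quadrant / ring per voxel), the mapping runs, 80-trial
cross-dot task sessions (40 match / 30 non-match / 10 catch, retention
jitter 3–8 s), behavioral responses, and noisy BOLD with injectable
delay-period effects — so every stage is testable without any download,
and parameter recovery can be verified against known truth.

## Worked example

Simulate a 10-subject cohort in which a delay-period match>mismatch effect
(amplitude 0.5 signal units) is confined to V3 under the categorical
instruction, run the full pipeline, and test the group pattern:

```python
from retinowm.pipeline import RunConfig, run_cohort, group_statistics

cfg = RunConfig(
    seed=42, n_subjects=10, n_per_area=32,
    delay_overrides={"categorical": {"V3": {"match": 0.5, "mismatch": 0.0}}},
    subject_amp_sd=0.05,
)
tables = run_cohort(cfg)
res = group_statistics(tables)

a = res["delay_anova"]
print(a[a["method"] == "univariate"][["effect", "F", "df_num", "df_den", "p"]])
fu = res["followups"]
print(fu[(fu["effect"] == "instruction*region") & (fu["method"] == "univariate")])
```

prints (abridged) a strongly significant three-way interaction,

```
                 effect          F  df_num  df_den            p
                   ...
area*instruction*region 602.747464     2.0    18.0 3.228739e-17
```

and per-ROI follow-up interactions that flag V3 and leave V1/V2 clean —
the injected effect is recovered where it was placed and nowhere else:

```
area           F  df_num  df_den            p
  V1    0.233497     1.0     9.0 6.404809e-01
  V2    0.207926     1.0     9.0 6.592012e-01
  V3 1698.948739     1.0     9.0 1.451017e-11
```

The recovered cell means confirm amplitude recovery: the V3
categorical-match cell averages 0.527 against a ~0.03 baseline elsewhere.

The same run is available from the shell:

```bash
retinowm run-all --config examples/config.yaml --seed 42 --out runs/demo/
```

which writes per-stage TSVs (events, retinotopy estimates, segment maps,
beta tables, ANOVA tables) plus `report.md` with mean ± SEM bar summaries
and a `manifest.json` recording config hash and seeds; reruns are
bit-identical.

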