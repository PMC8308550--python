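# celluscore

Photographic cellulite quantification and contralateral-trial analysis.

`celluscore` implements the measurement chain used in anti-cellulite
efficacy studies built around standardized oblique-light thigh
photography:

1. **Synthetic skin photographs** — height-field surfaces (flat,
   sinusoidal ridges, random dimple fields) rendered under a
   bottom-mounted divergent beam with Lambertian shading, sensor noise
   and 8-bit quantization, so every downstream stage can be exercised
   against images with a known ground truth.
2. **Undulation score** — the line-scan bandpass image score: vertical
   intensity profiles from twelve adjacent 4 × 60 mm regions of
   interest, smoothed at 1 mm and 20 mm, with the summed absolute
   deviation between the two smoothings quantifying cellulite-scale
   (millimetre-to-centimetre) relief. Smooth featureless skin scores
   exactly 0; visibly cellulitic skin scores in the hundreds to
   thousands.
3. **Visual grading** — the 0–15 Cellulite Severity Scale (CSS) with
   Mild/Moderate/Severe classes and the 0–3 dimpling grade, with
   multi-evaluator aggregation and percent-of-baseline normalization.
4. **Trial simulation** — a contralateral (within-participant
   left/right) placebo-controlled design: 20 enrolled, block-of-four
   side randomization, two mid-study withdrawals, 18 completers, seven
   instrumental outcomes plus evaluator grades, Likert questionnaires
   and diary comments, all driven by one seed.
5. **Statistics** — two-way within-subject repeated-measures ANOVA
   computed from first-principles sums of squares, Bonferroni-adjusted
   baseline contrasts on percent-of-baseline values, exact and
   normal-approximation Wilcoxon signed-rank tests, and summary/diary
   tabulation.
6. **IO, pipeline and CLI** — PNG/TIFF images with JSON calibration
   sidecars, CSV long-format tables, a YAML-configured five-stage
   pipeline and one `celluscore` executable with subcommands.

## The score in one formula

For each region of interest the column-averaged vertical profile
`p(y)` is smoothed twice with centred moving averages — `px1` with a
1 mm window (removes sub-millimetre texture and pixel noise) and `px2`
with a 20 mm window applied to `px1` (tracks the illumination trend) —
and scored on the range where the large window fits entirely:

```
score(ROI) = Σ_y |px1(y) − px2(y)|,   total = Σ over 12 adjacent ROIs
```

Window sizes are physical (mm), converted to odd pixel counts at the
image calibration (11 px and 201 px at 10 px/mm). Only features between
those two scales — precisely the scale of cellulite dimpling under
oblique light — survive the difference.

## Worked example

Render a dimpled thigh photograph, score it, then simulate and analyze
a full trial (python API; the CLI equivalents are shown after):

```python
from celluscore import (
    make_dimple_field, render_image, score_image,
    default_trial_config, simulate_trial, TrialDataset,
    summarize, rm_anova, baseline_contrasts,
)

# --- image branch ------------------------------------------------------
fld = make_dimple_field(n_dimples=40, extent_mm=(60, 70), seed=7)
img = render_image(fld, noise_sd=1.0, seed=7)       # 600x700 px, 10 px/mm
result = score_image(img, (4.0, 4.0))               # 12-ROI strip
print(round(result.total, 1))                       # 10755.3

# --- trial branch ------------------------------------------------------
ds = simulate_trial(default_trial_config(seed=42))  # 20 enrolled, 18 complete
complete = TrialDataset(ds.complete_cases(), ds.ledger)

table = summarize(complete)
css = table[(table.outcome == "css") & (table.thigh == "herbal")]
print(css[["week", "n", "mean", "sem"]].round(2).to_string(index=False))

res = rm_anova(complete, "css")
for s in ("treatment", "time", "treatment x time"):
    e = res.effect(s)
    print(f"{s:18s} F = {e['F']:.2f}  p = {e['p']:.3g}")
```

Output:

```
10755.3
 week  n  mean  sem
    0 18 13.49 0.21
    2 18 12.63 0.21
    4 18 12.24 0.32
    8 18 10.34 0.37
   12 18  9.86 0.43
   14 18  9.77 0.52
treatment          F = 66.11  p = 2.92e-07
time               F = 14.44  p = 3.17e-10
treatment x time   F = 6.62  p = 2.99e-05
```

The herbal-thigh severity scale falls from 13.49 (Severe) at baseline
to 9.86 (Moderate) at week 12 with a partial rebound after treatment
stops, and both the treatment main effect and the treatment-by-time
interaction are strongly significant — each participant's placebo
thigh serves as her own control.

The same flow from the command line:

```console
$ celluscore simulate-images --surface dimples --n-dimples 40 \
      --noise-sd 1 --seed 7 --out dimples.png
wrote dimples.png (600x700 px)
$ celluscore score --image dimples.png --origin-mm 4 4
total undulation score: 10755.279
$ celluscore simulate-trial --seed 42 --out trial/
wrote trial tables to trial (18 completers)
$ celluscore analyze --data trial/ --out out/
wrote out/results/results.json
$ celluscore report --out out/
wrote out/results/report.md
```

or in one shot with a YAML config: `celluscore run --seed 42 --out out/`.

## Layout

```
src/celluscore/
  synthetic_skin.py    surface fields, illumination, rendering, ink marks
  undulation_score.py  profiles, moving averages, bandpass score, ROIs
  grading.py           CSS classes, grade aggregation, baseline normalization
  trial_sim.py         trial configuration and simulation
  trial_stats.py       RM-ANOVA, contrasts, Wilcoxon, summaries, tabulation
  io.py                image IO with calibration sidecars
  pipeline.py          YAML-configured five-stage pipeline
  cli.py               `celluscore` command-line entry point
docs/methods.md        model, parameters and numerical choices
scripts/acceptance.py  from-scratch anchor-value computation
```
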