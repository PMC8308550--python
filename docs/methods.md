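# Methods

Model, parameter and numerical choices behind `celluscore`. Defaults
throughout reproduce the standardized study conditions the package
targets; they are fixed design choices, not tuning knobs.

## 1. Surface model

Skin is a height field `h(x, y)` in millimetres over a rectangular
patch, sampled on a 0.1 mm grid by default. `y` increases **upward**
(matching tape-measure positions above the knee); image row 0 is the
top of the raster, and the conversion between the two conventions is
centralized and tested.

- `make_flat_field` — `h ≡ 0`, the scorer's zero reference.
- `make_undulation_field` — `h = A sin(2π (x sinθ + y cosθ)/λ + φ)`.
  θ = 0 gives horizontal ridges (relief varies vertically, the
  direction the line scan reads); θ = 90° gives vertical ridges, which
  bottom lighting cannot reveal and the scorer must ignore.
- `make_dimple_field` — `n` Gaussian depressions with seeded random
  centres, depths 0.1–0.5 mm and radii 3–8 mm (σ = radius/2),
  approximating the dimple population of cellulitic skin.

## 2. Illumination and rendering

The light is a platform-level divergent beam aimed up the thigh,
i.e. from **below** the frame, at elevation `e = 70°` from the
participant's vertical axis, with `±7.5°` of divergence (the 15°
dispersion) spread linearly across the frame height and an ambient
fraction `a = 0.2`. The per-row unit light direction is
`l = (0, −cos e_r, sin e_r)` with `e_r` interpolated from
`e − 7.5°` at the bottom row to `e + 7.5°` at the top.

Lambertian shading, normalized so flat skin renders at exactly the
base level (180 by default) in every row:

```
I(r, c) = base · [ a + (1 − a) · max(0, n·l) / (n₀·l) ] + N(0, noise_sd²)
```

where `n` is the unit surface normal from central differences
(`np.gradient`) and `n₀·l = sin e_r` is the flat-surface factor. The
normalization matters: without it the divergent beam would paint a
vertical brightness gradient on flat skin and the flat-skin score
would not be exactly 0. With it, the gradient appears only where the
surface actually tilts — which is also why the 20 mm smoothing exists
in the scorer: on real photographs the illumination trend survives.

Intensities are rounded half-away-from-zero, clipped to [0, 255] and
stored as 8-bit grayscale at 10 px/mm. If the surface grid and pixel
grid differ, heights are resampled bilinearly at pixel centres.

Small-slope analysis used for calibration: for `h = A sin(ky)` the
rendered intensity is `base·[1 + (1−a)·h′·cot e]`, so the peak-to-peak
contrast is `2Ak·base·(1−a)·cot e`, maximal at the lowest beam
elevation `e = 62.5°`. `ridge_amplitude_for_contrast` inverts this to
pick the amplitude producing a requested grey-level span; at λ = 10 mm,
A ≈ 0.021 mm gives ≈2 levels and A ≈ 0.042 mm gives ≈4 levels.

### Generator realism and limits

The generator reproduces what the score actually measures — oriented,
band-limited relief under oblique light, sensor noise, quantization,
ink marks — but it is not a skin simulator: no pores, hair, specular
highlights, perspective or curvature of the thigh, and shading is
single-bounce Lambertian with no shadowing (valid for the ≤0.5 mm
relief slopes used, where `n·l` never approaches 0). Conclusions
about the scorer's band selectivity transfer to real photographs;
absolute score magnitudes do so only approximately.

## 3. Undulation score

Per image: twelve adjacent 4 × 60 mm regions of interest starting at a
configurable origin (default 4 mm in from the bottom-left). Per ROI:

1. average the pixel rows across the 4 mm width → vertical profile
   `p(y)`, one sample per pixel row;
2. `px1 = MA(p, 1 mm)` — small moving average;
3. `px2 = MA(px1, 20 mm)` — large moving average **of px1**;
4. `score = Σ |px1 − px2|` over the rows where the large window fits
   entirely (the central `L − 2·⌊w_large/2⌋` samples);
5. total = sum over the 12 ROIs.

Numerical choices:

- **Window sizes are physical** (mm) and converted at the image's
  calibration: `w = round(mm · px/mm)`, bumped **up** to the next odd
  integer so windows are centred (10 → 11 px, 200 → 201 px at
  10 px/mm). Rounding down instead (9 px) measurably weakens the
  sub-millimetre suppression, so the upward rule is load-bearing.
- Moving averages use a cumulative-sum implementation with
  symmetric shrinking windows at the edges
  (`k_i = min(k, i, n−1−i)`), verified against an explicit-loop oracle
  at 1e−9 relative tolerance. Edge behaviour never reaches the score:
  the deviation sum is restricted to the interior valid range.
- The deviation is the plain absolute sum (no normalization), making
  the score linear in contrast and exactly 0 for constant or linear
  profiles.
- Felt-pen measurement marks can be removed before scoring with
  `oblate_marks`, which linearly interpolates each profile column
  across the marked rows.

### Band selectivity, and one documented shortfall

With 1 mm and 20 mm windows the response to a sinusoid of wavelength λ
is `|B_small(λ) − B_small(λ)·B_large(λ)|` where `B_w(λ) = sinc(πw/λ)`
is the boxcar response. Measured against the λ = 10 mm band centre:

| λ | residual response | suppression |
|---|---|---|
| 0.4 mm | ≈7% | ≈93% ✓ |
| 80 mm | ≈10.1–11.2% | ≈89–90% ✗ |

The 80 mm case cannot reach 90% suppression with a 20 mm large
window: the boxcar leaves `1 − sinc(π·20/80) ≈ 9.97%` of an 80 mm
sinusoid in the continuous limit, and the 10 mm reference is itself
slightly attenuated (≈2.5%), so the ratio is ≥10.1% at every
resolution and profile length. The corresponding acceptance test is
left failing rather than widening the window (which would change the
published measurement) or weakening the test.

## 4. Grading

The Cellulite Severity Scale (CSS) is a 0–15 composite;
`classify_css` maps it to Mild (≤5) / Moderate (≤10) / Severe (≤15),
half-open upward. Evaluator dimpling grades are 0–3;
`aggregate_grades` averages over evaluators with SEM.
`normalize_to_baseline` expresses each participant-thigh series as
percent of its own week-0 value, excluding (with a logged warning)
series with a zero or missing baseline — the scale on which the
baseline contrasts are run.

## 5. Trial simulation

Contralateral placebo-controlled design: each participant treats one
thigh with active product and the other with placebo. Defaults encode
the study conditions: 20 enrolled, block-of-four side randomization
(each consecutive block of four participants contains two left- and
two right-active assignments), withdrawals at weeks 7 and 8 (one
participant each, chosen by seed), 18 completers, visits at weeks 0,
2, 4, 8, 12 and a follow-up at 14 (treatment stops at 12).

Outcome values are generated as

```
value = trajectory(thigh, week) + u_participant + ε,
u ~ N(0, participant_sd²) shared across both thighs and all weeks,
ε ~ N(0, residual_sd(week)²) independent per record.
```

The shared participant effect produces the contralateral correlation
that gives the paired design its power. For the CSS the herbal anchors
are 13.4 (wk 0), 12.1 (wk 2), 9.9 (wk 12) with linear interpolation
between anchors and a rebound to 10.9 at week 14; placebo declines
12.9 → 12.4. With `participant_sd = 1.0`, the week-resolved residual
sds (0.78 at baseline rising to 2.34 at week 12) are chosen so the
cross-sectional SEM at n = 18 is 0.30 at baseline and 0.60 at week 12
— the dispersion actually reported for the cohort. Secondary outcomes
(image score, circumferences, firmness, blood flow) follow the same
law with their own reported baselines.

Evaluator grades discretize the latent CSS
(`grade = clip(⌊css/5 + bias + noise + 0.5⌋, 0, 3)`, three
evaluators), and Likert answers discretize per-question normal means
to the 1–5 scale. Everything derives from `TrialConfig.seed`; equal
seeds give byte-identical CSV output.

## 6. Statistics

- **Repeated-measures ANOVA** (`rm_anova`): two-way within-subject
  decomposition computed from first-principles sums of squares on the
  balanced completer cube (subjects × thighs × weeks). Each
  within-subject effect is tested against its own effect-by-subject
  interaction: `F = MS_effect / MS_(effect×subject)`. Unbalanced input
  is rejected with instructions to filter to complete cases. Sums of
  squares below a size-scaled `eps²` tolerance are snapped to exactly
  0 (all-identical data otherwise reports SS ≈ 1e−29 from float
  accumulation) and degenerate effects report `F = p = NaN`. Verified
  against an independent loop oracle and against `pingouin.rm_anova`.
- **Baseline contrasts** (`baseline_contrasts`): per arm, each
  post-baseline week vs week 0 as a paired one-sample t-test, by
  default on percent-of-baseline values, Bonferroni-adjusted over the
  family of post-baseline weeks (`p_adj = min(1, m·p)`).
- **Wilcoxon signed-rank** (`wilcoxon_signed_rank`): zero differences
  dropped, mid-ranks for ties, `W = min(W⁺, W⁻)`. For ≤12 non-zero
  pairs the exact two-sided p is computed by convolution over the
  doubled (integer-lattice) ranks; otherwise a normal approximation
  with tie correction `Σ(t³−t)/48` and 0.5 continuity correction.
  Verified against full 2ⁿ enumeration and `scipy.stats.wilcoxon`.
- **Tabulation**: diary-comment counts per category and thigh with
  percentages of completers (nearest integer) and per-thigh totals.

## 7. Problem sizes and runtime

Default images are 600 × 700 px (60 × 70 mm at 10 px/mm); rendering
and scoring one image each take well under a second. A full trial
simulation plus two-way ANOVA on 18 × 2 × 6 completer records runs in
tens of milliseconds, which is what makes the 1000-replicate type-I
error check in the acceptance suite affordable. The entire test suite
runs in a few minutes on one CPU; `scripts/acceptance.py` in a few
seconds.
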