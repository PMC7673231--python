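# tonespace

Acoustic assessment of Mandarin lexical tone production, designed for
comparing pediatric cochlear-implant (CI) users with normal-hearing (NH)
peers. Clinicians and speech scientists who record monosyllabic word
productions can use it to quantify, per speaker, how well the four Mandarin
tones are separated in fundamental-frequency (F0) space — without listener
judgments.

## The method

Each produced word is reduced to an F0 contour (short-time autocorrelation
tracking with automatic doubling/halving repair) and summarized by three
landmarks: the F0 at the onset, midpoint, and offset of the voiced span.
Landmarks are normalized per speaker to semitones relative to *M*, the mean
F0 of the speaker's tone-1 (high-flat) tokens:

    semitone = 12 · log₂(F0 / M)

Each tone's token scatter is then summarized by a **tone ellipse** in
(onset, offset) space — the *2D method* — or a **tone ellipsoid** in
(onset, mid, offset) space — the *3D method* — centered on the scatter mean
with principal semiaxes of two standard deviations along the covariance
eigenvectors. Two scores follow:

- **Tone differentiability** of a contrast (i, j):
  `[(1 − Aᵢ/A₁) + (1 − Aᵢ/A₂)] / 2`, where `Aᵢ` is the intersection
  area/volume of the two tone regions (seeded Monte-Carlo estimate,
  validated against the closed-form circle-lens area) and `A₁, A₂` their
  measures. 0 = identical regions, 1 = disjoint. The speaker's score
  averages the six contrasts.
- **Tone hit rate**: cell (i, j) of a 4×4 confusion matrix is the proportion
  of target-tone-i tokens among all tokens inside tone region j; the
  diagonal average is the speaker's score.

Group statistics mirror standard practice for proportion scores: arcsine
square-root transform, two-way ANOVA (hearing group × method), one-way
repeated-measures ANOVA over contrasts/tones with Bonferroni post hocs,
Pearson correlations, and OLS of scores on age at implantation, duration of
device use, and their interaction.

Because no recordings ship with the package, a synthetic cohort generator
produces landmark-level (optionally audio-level) productions of a balanced
36-word list (18 syllables × 2 tones; 9 words per tone): NH-like subjects
with well-separated canonical contours, CI-like subjects with flattened,
noisier contours.

## Worked example

```python
from tonespace import CohortSpec, generate_cohort
from tonespace.pipeline import compute_features, tokens_from_features
from tonespace.tone_metrics import cohort_scores
from tonespace.tone_geometry import GeometryParams

cohort = generate_cohort(CohortSpec(n_nh=10, n_ci=10, seed=42))
feats = compute_features(cohort.manifest, precomputed=cohort.features)
scores = cohort_scores(tokens_from_features(feats),
                       params=GeometryParams(n_samples=50_000), seed=42)
print(scores["summary"].groupby(["group", "method", "measure"])["value"]
      .mean().round(3))
```

prints

```
group  method  measure
CI     2D      differentiability    0.768
               hit_rate             0.593
       3D      differentiability    0.904
               hit_rate             0.754
NH     2D      differentiability    0.950
               hit_rate             0.892
       3D      differentiability    0.989
               hit_rate             0.969
```

i.e. simulated NH speakers separate the four tones almost perfectly (2D
differentiability 0.95), simulated CI speakers are markedly worse (0.77 and
a hit rate near 0.59), and the 3D method scores higher than the 2D method
for every group × measure cell.

The same pipeline runs from the shell:

```bash
tonespace simulate --n-nh 10 --n-ci 10 --seed 42 --out-dir cohort
tonespace run --manifest cohort/manifest.csv \
              --features cohort/landmarks_hz.csv --out-dir results
```

which writes `features.csv`, `scores*.csv`, `stats.json`/`stats.txt`, and a
`figures/` directory (per-subject ellipse plots, contrast bar charts,
confusion heatmaps, correlation scatters). `tonespace features` accepts a
manifest pointing at WAV recordings to run the acoustic front end on real
audio.

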