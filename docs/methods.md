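# Methods

## The discrimination model

The pipeline asks a per-electrode question: does the distribution of gamma
band (70–170 Hz) log power around phoneme onset differ between phonemes
that carry a segmental feature ("+") and those that do not ("−")?  The
test statistic is the cross-validated ROC AUC of a linear decoder, so the
procedure makes no assumption about *which* latency bins carry the
difference, only that it is expressible as a linear boundary in binned
log-power space.  Key modeling assumptions:

* Cortical activation is monotonically reflected in gamma-band power;
  epochs are exchangeable given their label (no session drift model).
* The decoder's CV AUC, under the null, is approximately normal around
  0.5 with the Hanley–McNeil standard error computed from the total class
  counts.  This is the one deliberately rough approximation in the chain
  (see *Limitations*).
* Feature dimensions are analyzed independently; phonological overlap
  between dimensions (e.g., all vowels are voiced) is interpreted, not
  modeled.

## Phoneme feature coding

The compiled inventory is General American ARPAbet: 24 consonants and 15
vowels.  Coding follows standard English phonology, with two conventions
made explicit because top-level feature charts often leave the symbols
out: /h/ is obstruent, voiceless, and carries no oral place feature
(glottal); /ŋ/ is sonorant, voiced and dorsal.  All vowels are sonorant,
voiced and placeless; /w/ is the one doubly-placed consonant (labial and
dorsal).  Every phoneme is exactly one of obstruent/sonorant, and exactly
one of consonant/vowel.  For the phonological contrast the positive class
is the **vowel** ("+" = vowel); for all others "+" marks the named
feature.

## Signal chain parameters

| stage | parameter | default | rationale |
|---|---|---|---|
| high-pass | cutoff, order | 0.5 Hz, 4 (zero-phase) | drift/DC removal far below the band of interest |
| notch | f₀, Q | 120 Hz, 35 (bw ≈ 3.4 Hz) | only line harmonic inside 70–170 Hz; 60/180 Hz are left untouched as they cannot alias into the band |
| reference | — | CAR per grid | removes the shared reference/common-mode within each implant |
| band power | band, order | 70–170 Hz, 4 | squared + natural log; power floor ε = 1e−12 (signal units²) keeps exact zeros finite |
| epochs | window | −350…+350 ms, half-open | phoneme-onset locked; edge-overrunning epochs dropped, never padded |
| bins | width/step | 50/25 ms (27 bins) spatial; 50/10 ms (66 bins) temporal | bin value = mean log power; centers at bin midpoints, so the fine grid reports latencies on a 10 ms grid (−325…+325 ms) |

Filters use second-order sections: an order-4 Butterworth at a normalized
cutoff of 0.5/600 is numerically fragile in transfer-function form.

## Decoder

* **mRMR**, difference (MID) form: greedily add the feature maximizing
  MI(feature; label) − mean MI(feature; already selected).  Mutual
  information is computed on 3-level quantile-discretized features
  (discretization edges from the training fold only).  Ties break to the
  lowest feature index for determinism.  k = 50 for screening (pooled
  electrodes), k = 10 per electrode for the spatial analysis, none for
  the single-feature temporal analysis.
* **Shrinkage LDA**: pooled within-class covariance, centered per class,
  one Ledoit–Wolf intensity for the pooled matrix (scikit-learn's
  estimator); `shrinkage=0` recovers the plug-in discriminant exactly and
  is used for the one-dimensional temporal fits, where regularization is
  unnecessary.  The bias uses empirical class priors; AUC is
  threshold-free so the bias affects nothing reported.
* **Cross-validation**: stratified 5-fold with a seeded shuffle.
  Stratification protects the rarer classes (dorsal is ~12% of
  consonants).  Selection and fitting never see held-out data; the test
  verifying this rebuilds a fold by hand and checks score equality.

## Statistics

Hanley–McNeil SE with Q₁ = A/(2−A), Q₂ = 2A²/(1+A); one-sided normal test
of A > 0.5 (the analyses only interpret above-chance discrimination; a
two-sided option exists).  Benjamini–Hochberg step-up with an explicit
family size m, so a family can span subjects × electrodes (spatial) or
subjects × electrodes × bins (temporal) even when computed blockwise.
The activation index applies a strict threshold to the *corrected* p:
ψ(p) = −ln p for p < 0.01, else 0.  Before the log, p is floored at the
smallest positive normal double, capping AI near 708 instead of producing
infinities when the normal tail underflows.

Local maxima of temporal AI profiles are strict peaks of the 3-bin
moving-average series with minimum prominence 0.5 AI units; the global
peak is taken on the raw series.

## Screening

700 ms epochs centered on each word's midpoint versus 700 ms windows
tiled into silent gaps (gaps shrunk by a 150 ms guard so speech-locked
activity cannot bleed in).  Counts are matched by seeded subsampling of
whichever side is larger; fewer than 10 available silence windows is an
error.  A subject passes at CV AUC > 0.8 — far above chance, because a
subject whose recording cannot even separate speech from silence cannot
support feature-level contrasts.

## The simulator

What it emulates, per channel: 1/f^α Gaussian background (α = 1,
SD 15 a.u.), a shared per-grid common mode (SD 10), line sinusoids at
60/120/180 Hz (amplitudes 4/1.5/0.8, random phases, ±20% amplitude
jitter), and, per configured effect, band-limited 70–170 Hz noise bursts
with a Tukey taper, *centered* at onset + latency, at the effect's
electrodes, for phonemes positive on the effect's dimension.  Burst SD is
`gain` × the channel's baseline gamma-band SD; the default gain 1.5
roughly triples gamma power during the burst, in the range of speech
high-gamma responses, and bursts are broadband noise rather than added
sinusoids because the analysis measures band power.  Overlapping bursts
from adjacent positive phonemes merge (envelope maximum) rather than
stack.

Alignments: words of 2–8 phonemes at ~10 phonemes/s (±20% duration
jitter); half the inter-word pauses are long (1.5–2.5 s) so enough
silence windows exist for screening, the rest 150–350 ms.  Phoneme draws
are i.i.d. with vowel probability 0.392; consonant probabilities are
chosen so conditional place frequencies are labial 0.229, dorsal 0.124
and coronal 0.761 — 0.78 coronal is jointly infeasible with the other two
targets because /w/ is the only consonant carrying two place features, so
coronal absorbs the (small) feasibility gap.

What it does **not** emulate: coarticulation dynamics (labels are
i.i.d.; effect windows merely overlap), epileptiform or movement
artifacts, spatial correlation of background noise between neighboring
electrodes, session nonstationarity, or real cortical geometry (the
montage is a flat 8-column grid at 10 mm pitch).  Passing tests therefore
demonstrate that the *pipeline* is correct and calibrated under its own
assumptions — not that those assumptions hold in clinical recordings.

## Problem sizes

The shipped study runs 48-electrode subjects of 120 s (~350 phoneme
epochs, ~70 words); null calibration uses 20 replicates of 400 epochs ×
48 electrodes (the test suite uses 16-electrode replicates for the same
check).  These sizes give the decoder class counts comparable to a short
clinical run while keeping every analysis reproducible on a laptop.

## Limitations

* **Overlapping epochs vs Hanley–McNeil.**  At 10 phonemes/s, adjacent
  700 ms epochs share most of their samples.  Measured null CV-AUC
  spread is ≈1.4× the Hanley–McNeil SE, so raw p-values are mildly
  anti-conservative.  The strict AI threshold (corrected p < 0.01) plus
  BH absorbs this in practice — zero-effect runs yield empty significant
  sets in the seeded calibration tests — but p-values near the threshold
  should not be over-read.
* **CAR leakage.**  Common-average referencing subtracts 1/C of every
  effect burst from all channels of a grid, injecting a faint
  anti-correlated copy of the signal at non-effect electrodes.  With the
  default montage and gains this stays below the significance threshold,
  but it grows with the fraction of electrodes carrying effects.
* **Cross-dimension coupling.**  Because feature dimensions share
  phonemes (all vowels are voiced and sonorant), an effect injected on
  one dimension is genuinely discriminable along others.  Recovery
  reports therefore score recall per dimension but count false positives
  only outside the union of all injected effects.
* The AI ceiling (~708) is a numerical cap, not a measurement; AI values
  at the cap mean only "p underflowed".
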