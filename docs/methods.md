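# Methods

## Study design being modeled

The pipeline analyses three linked experiments on DGRP inbred lines of
*D. melanogaster*:

1. **Cold-tolerance assay.** Vials of 10 flies receive either a basal
   treatment (60 min at −6 °C) or an acclimated treatment (120 min at 4 °C,
   then 60 min at −6 °C); survival is scored after 24 h recovery at 25 °C.
   Design: 19 lines × 2 sexes × 2 treatments × 4 replicate vials (304 vials).
   The protocol is encoded as ordered (temperature, duration) steps in
   `cold_tolerance.TREATMENT_PROTOCOL`.
2. **Mating screen.** Virgin pairs in all four male × female acclimation
   combinations are watched for 4 h (14,400 s). Latency is censored at the
   screen length for non-courting males; duration exists only for pairs that
   mated.
3. **Song assay.** One pair per recording, up to 15 min; ambient temperature
   is logged at start and end and the recording temperature is their mean.

## Models and statistics

* **RCH capacity** is a difference of unweighted means of vial proportions
  (the vial, not the fly, is the replicate). Its standard error combines the
  vial-to-vial variances of the two independent arms:
  `SE² = s²_acc/n_acc + s²_bas/n_bas`.
* **Survival / behavior mixed models** are fit by maximum likelihood with
  statsmodels `MixedLM`: fixed effects treatment × sex (survival) or male ×
  female treatment (behavior), a random line intercept, and a line ×
  treatment variance component tested by likelihood ratio against the
  intercept-only random structure (χ², 1 df; conservative for a boundary
  hypothesis). Proportions are analysed directly, not on the logit scale —
  the replicate-vial proportions are approximately normal at n = 10 and the
  effect of interest is an additive shift in survival probability.
* **Mating contingency** is a Pearson χ² on the 2×2 male-treatment × mated
  table; Yates continuity correction defaults **on**, matching R's
  `chisq.test` default for 2×2 tables, with a flag to disable it (the
  original analysis environment's setting is not knowable, so reports include
  both).
* **Physiology–behavior regressions** use line means (latency and duration
  for the control pair and the acclimated-male pair, and plasticity) against
  male basal cold tolerance and RCH capacity; each fit is simple OLS
  (slope, F = t², R², p from `scipy.stats.linregress`).

## Song processing

* **Band-pass:** 4th-order Butterworth, 100–1000 Hz, applied
  forward–backward (`sosfiltfilt`) so pulse peak times are not delayed.
* **Pulse detection:** Hilbert envelope, lightly smoothed (0.5 ms Gaussian),
  peaks above `median + k·(1.4826·MAD)` of the envelope with `k = 8`, and a
  15 ms refractory window. MAD-based thresholding is robust because pulses
  occupy a tiny fraction of the recording, so the envelope's median and MAD
  estimate the noise floor. Two true pulses closer than the refractory
  window merge into one detection — a known limitation, irrelevant at
  *D. melanogaster* IPIs (~35 ms). The detector stands in for the study's
  manual oscillogram scoring and is validated against synthetic ground truth
  only; IPIs are peak-to-peak.
* **Bursts:** maximal runs with consecutive gaps ≤ 100 ms (≈ 3× a typical
  IPI). The burst definition in the source protocol is only "≥ 3 pulses";
  the gap threshold is the main free parameter affecting IPI counts and is
  configurable. Only bursts of ≥ 3 pulses contribute IPIs.
* **Temperature correction** is linear to 25 °C with default slope
  −1.0437 ms/°C; `estimate_ipi_temperature_slope` re-derives the slope from
  any song set. Because the correction is affine, correcting the mean equals
  the mean of corrected IPIs.
* **Retention:** mean IPI is reported only for songs with ≥ 15 IPIs
  (boundary inclusive); excluded songs keep their indices and duration.

## Bootstrap

Per selected song and sample size n, 10,000 subsample means are drawn, with
replacement by default (a without-replacement mode exists since the original
wording is just "randomly sampled"; both the mode and the percentile-CI
choice are recorded in output metadata). Stabilization is made quantitative,
replacing a visual read-out: the smallest n at which, for **every** selected
song, (a) the SD of subsample means dropped < 20% relative to the previous
size (the smallest size counts as zero decrease) and (b) the CI half-width
is < 5% of the full-song mean. Under the CLT (SD ≈ σ/√n, σ ≈ 3 ms, mean
≈ 35 ms) this rule lands at 15 IPIs, consistent with the retention filter.

## Synthetic-data generator

The generator reproduces the **structure** of the study, with effect sizes
chosen to be biologically plausible rather than fitted (per-line effects
were never published):

* Survival: binomial vials; per-line basal survival and additive RCH effects
  (defaults: basal ~ U(0.2, 0.8), RCH effect ~ U(0, 0.4) in the pipeline's
  simulate stage); an additive female survival shift is available.
* Courtship: log-normal latency (median 600 s, log-SD 0.9) and duration
  (median 900 s, log-SD 0.6) — right-skewed and positive, as the real
  behavioral data were reported to be; a multiplicative duration effect
  (default ×1.3) for acclimated males; mating probabilities 0.725 (control)
  vs 0.513 (acclimated male), the proportions reported for the song assay.
  The mated flag is independent of the sampled duration (a hook allows
  dependence).
* Song: within-burst IPIs ~ N(35 + slope·(T − 25), 3²) ms truncated
  positive; bursts of 3–10 pulses, 1–10 bursts per song (so IPI counts vary
  realistically around the ≥ 15 retention boundary); pulses are
  Gaussian-enveloped 250 Hz sinusoids (σ = 2 ms) with unit peak amplitude in
  Gaussian noise (SD 0.05, keeping peaks ≥ 5× the noise scale);
  148 recordings over 5 lines × 2 male treatments at temperatures
  U(23.5, 26.5) °C with a small start–end difference.

What the generator does **not** emulate: sine song, female acoustic
response, amplitude variation across pulses, non-stationary noise,
transcoding artifacts of the original MP4→MP3→WAV chain, and any dependence
of IPI variance on temperature. Passing tests therefore demonstrate that the
pipeline's measurement chain is correct and well calibrated, not that the
detector would match manual scoring on field-quality recordings.

## Numerical choices and problem sizes

All randomness flows through seeded `numpy.random.Generator`s (per-song
bootstrap seeds are spawned from one `SeedSequence`), so identical
configuration and seed reproduce outputs byte-for-byte; every output file
carries a hash of the scientific parameters. Ties in top-song selection
break by song id. Degenerate inputs (zero margins, constant predictors,
missing treatment arms, empty audio) raise informative errors rather than
returning zeros, except empty song inputs, which produce empty outputs with
a warning so a batch run can continue.

Test and acceptance runs use deliberately modest problem sizes — e.g. 25
songs for the audio round trip, 200 songs × 100 seeds for slope-recovery
coverage, 1000 seeds for the regression null calibration, 200 vials/arm for
capacity recovery — sizes at which the checked tolerances are comfortably
binding for a correct implementation.
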