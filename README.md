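# coldsong

Analysis pipeline for the costs and benefits of **rapid cold-hardening
(RCH)** in *Drosophila melanogaster*. RCH is a short acclimation (2 h at
4 °C) that raises survival of a subsequent severe cold shock (1 h at −6 °C).
The physiological benefit, however, may carry a reproductive cost: acclimated
males can court less efficiently. This package implements the full analysis
chain used to ask that question across DGRP (Drosophila Genetic Reference
Panel) inbred lines, together with a synthetic-data generator so every stage
runs end to end with no external data.

## What it computes

**Cold tolerance.** Each replicate vial of 10 flies yields a survival
proportion. For line *i*,

> RCH capacity_i = mean(acclimated vial proportions) − mean(basal vial proportions),

so positive capacity means acclimation improved survival. A mixed model
(treatment × sex fixed; line and line × treatment random) summarizes
genotype-by-environment structure.

**Mating behavior.** Courtship latency (censored at the 14,400 s screen for
non-courting males), courtship duration (mated pairs only), a 2×2 χ² test of
mating against male treatment, per-line behavioral plasticity

> plasticity_i = mean control-male duration − mean acclimated-male duration (control females only),

and OLS regressions of line-level behavior on basal cold tolerance and RCH
capacity.

**Courtship song.** 100–1000 Hz zero-phase band-pass; envelope-threshold
pulse detection; bursts of ≥ 3 pulses yield interpulse intervals (IPIs, ms);
per-song mean IPI is corrected to 25 °C via

> corrected IPI = −1.0437 · (25 °C − recording temperature) + measured IPI,

where the slope can also be re-estimated from the data by OLS of per-song
mean IPI on recording temperature. Song index (singing time / courtship
duration), courtship index, and a ≥ 15-IPI retention filter complete the
per-song metrics.

**IPI bootstrap.** For the songs with the most IPIs (top 5%), subsamples of
{3, 5, 10, 15, 20, 25, 30} IPIs are drawn 10,000 times each; the mean, SD and
percentile 95% CI of the subsample means determine the smallest sample size
at which the estimate of a song's mean IPI has stabilized.

## Worked example

Run the numbered drivers from any working directory (they write `data/` and
`results/` there), or use the `coldsong` CLI (`coldsong simulate`,
`coldsong survival`, `coldsong mating`, `coldsong song`, `coldsong report`):

```bash
python analysis/01_simulate.py --seed 3        # synthetic dataset + WAVs
python analysis/02_cold_tolerance.py --seed 3
python analysis/03_mating_behavior.py --seed 3
python analysis/04_song_metrics.py --seed 3
python analysis/05_report.py --seed 3
```

prints (seed 3):

```
RCH capacity across 19 lines: mean +0.203, range [+0.000, +0.463]
18/19 lines show positive capacity (acclimation improves cold survival)
mating vs male treatment: chi2 = 9.15 (df 1, p = 0.0025, continuity=on)
processed 148/148 songs; 117 retained (>= 15 IPIs)
IPI temperature slope: estimated -1.0229 ms/degC (configured -1.0437)
bootstrap: subsample-mean variation stabilizes at 15 IPIs (with replacement, percentile CI)
```

Reading: most simulated genotypes gain cold survival from acclimation, but
acclimated males are significantly less likely to mate (the χ² line). The
song pipeline recovers the generating IPI–temperature slope from the audio
alone, and the bootstrap confirms that ~15 IPIs per song suffice to estimate
its mean IPI — the basis of the ≥ 15-IPI retention rule.

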