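# circatemp

Quantitative analysis of **temperature encoding in the *Drosophila* circadian
circuit**: how heating and cooling reshape fly sleep/locomotion through clock
neurons such as DN1a, the evening cells (LNds), and sleep-promoting DN3s.

The package is a reusable, tested implementation of the analysis pipeline such
studies run between raw recordings and figures, for chronobiologists and
neuroscientists working with:

* **video locomotion monitors** — movement counts per 10-s epoch per fly;
* **two-photon calcium imaging** — two-channel (GCaMP + tdTomato) ROI time
  series under a Peltier temperature-step protocol;
* **connectome exports** — neuPrint-style synaptic connection tables.

Because such datasets are rarely deposited, a first-class synthetic-data
generator (`circatemp.synth`) emulates all three modalities with *planted,
recoverable* ground truth, so every downstream stage is testable end to end.

## What it computes

**Sleep and behavior indices** (`circatemp.sleep`). Sleep is scored with the
field-standard rule — any run of ≥ 5 min of immobility is a sleep bout —
and activity is summed in 30-min bins. Four indices quantify
temperature-driven re-shaping of the diurnal pattern, each a per-fly relative
change of a Zeitgeber-time window mean (ZT0 = lights-on):

| index | formula (per fly) |
|---|---|
| E-peak advance (cold) | (ZT6–12 activity at 18 °C − at 24 °C) / at 24 °C |
| E-peak offset delay (hot) | (ZT12–18 activity at 30 °C − at 22 °C) / at 22 °C |
| Night-sleep reduction (hot) | (ZT12–24 sleep at 22 °C − at 30 °C) / at 22 °C |
| E-peak sleep reduction | cold: (ZT6–12 sleep at 18 °C − at 24 °C)/at 24 °C; hot: ZT12–18 analogue at 30 vs 22 °C |

Group comparisons use one-way ANOVA with Tukey HSD and a compact letter
display (groups share a letter iff not significantly different).

**Calcium quantification** (`circatemp.calcium`). ΔF/F₀ = (F_t − F₀)/F₀ × 100 %
and ΔF_max/F₀; pre/post window fold change of a temperature step with
responder classification (±2 baseline SD); saturation analysis across step
amplitudes (the planted response clamps at −6 °C cooling / +8 °C heating);
Pearson correlation + average-linkage clustering of traces; paired pre/post
locomotion comparison.

**Diurnal curve stitching** (`circatemp.diurnal`). Long-term imaging covers
only ~6 h per fly, so four groups entrained on 6-h-shifted light cycles are
mapped through ZT = (local time + shift) mod 24 and pooled into a 30-min-binned
24-h GCaMP/tdTomato curve (ratiometry cancels common-mode drift exactly), with
double-plot export and estimation of the circadian gating of the temperature
response (night:day gain ratio).

**Connectome summary** (`circatemp.connectome`). Type-level partner ranking of
a cell type (downstream/upstream, weight-thresholded, conservation-checked)
and Sankey node/link JSON export.

## Worked example

```bash
python examples/01_sleep_and_indices.py
```

```
control flies sleep 715 +- 65 min/day (5-min immobility rule)
E-peak advance index: 0.314 +- 0.044 (n=32)
generator expectation: 0.300
```

The generator planted a +30 % evening (ZT6–12) locomotion effect under
cooling; 32 paired synthetic flies recover an index of 0.314 ± 0.044 against
the analytic expectation 0.300 — the estimate sits well within one standard
error of the truth. The other examples cover step-response quantification
(`02`), the saturation scan recovering the −6/+8 °C clamps (`03`), the
stitched diurnal curve peaking at ZT12 (`04`), circadian gating recovering
the planted 4:1 night:day ratio (`05`), and DN1a partner ranking (`06`).

A thin CLI wraps the same library:

```bash
circatemp report --seed 7 --out demo/     # full synthetic end-to-end run
circatemp simulate --seed 1 --out data/   # write synthetic tables
circatemp indices --activity data/activity.csv --out indices.csv
```

Every run writes a manifest (seed, parameters, output checksums) sufficient to
reproduce its outputs bit for bit.

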