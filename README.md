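# mesovasc

Quantification pipeline for awake-mouse mesoscopic cerebrovascular imaging:
widefield neurovascular coupling and CO₂ reactivity, single-vessel FWHM
diametry, two-photon amyloid pathology, and cohort-level mixed-model
statistics — with seeded synthetic-data generators that record ground truth
for every planted observable.

## The scientific problem

Vascular dysfunction appears early in Alzheimer's disease, and cerebral
amyloid angiopathy (CAA — amyloid-β deposited in artery walls) couples it to
amyloid pathology. Longitudinal widefield optical imaging of head-fixed mice
lets both arms be measured through a cranial window across most of the
lifespan:

- **Neurovascular coupling** — whisker stimulation drives barrel-cortex
  neurons (GCaMP6f fluorescence, 470 nm excitation) and an accompanying
  haemodynamic response read out as optical intrinsic signal (OIS)
  reflectance: deoxyhaemoglobin-weighted at 620 nm ("OIS BOLD"), total
  haemoglobin at the 570-nm isosbestic point ("OIS CBV").
- **CO₂ reactivity** — a hypercapnic challenge (30 s baseline, 90 s CO₂,
  270 s recovery, twice) probes vasodilation independent of neuronal drive,
  both globally (tissue ΔR/R₀) and per vessel (FWHM diametry).
- **Amyloid burden** — in-vivo two-photon z-stacks (methoxy-X04 for Aβ,
  SR101 for vessels) quantify CAA vessel coverage and tissue-plaque volume.
- **Cohort inference** — session- and vessel-level metrics from a
  genotype × sex × age design are modelled with linear mixed-effects
  regression (random intercept per mouse), Johnson–Neyman conditional-effect
  regions, and Holm-adjusted median-split contrasts.

## Core quantities

For a pixel/ROI intensity F with pre-stimulus baseline F₀ (2 s before each
whisker onset, 30 s before each CO₂ onset):

- evoked response: ΔF/F₀ = (F − F₀)/F₀; the barrel ROI is the top-100
  8-connected activation pixels grown greedily from the activation peak, and
  the session readouts are the ROI-mean trial-averaged peak GCaMP and
  OIS-BOLD responses and their ratio.
- reactivity: peak tissue ΔR/R₀ during the CO₂ window, repeats averaged at
  the epoch level, after K-means (k = 2) removal of the dark large-vessel
  cluster from the brain ROI.
- vessel diameter: full width at half maximum of the cross-sectional
  intensity profile; percent dilation = 100·max|D(t) − D₀|/D₀ over the CO₂
  window (sign attached).
- CAA coverage: percent of manually outlined vessel area on the methoxy MIP
  strictly above mean + 1.5 SD of that vessel's intensity; plaques:
  26-connected components strictly above 0.6 × the volume maximum with
  > 15 voxels, after CAA removal.
- Johnson–Neyman: for a fit y ~ b₀ + b₁·x + b₂·m + b₃·x·m, the conditional
  slope θ(m) = b₁ + b₃·m crosses significance where
  θ(m)² = t²crit·[var(b₁) + m²·var(b₃) + 2m·cov(b₁,b₃)], a quadratic solved
  in closed form.

## Worked example

```bash
python examples/02_whisker_evoked_coupling.py
```

```
peak GCaMP dF/F0 :  3.051 %  (planted 3.000 %)
peak OIS-BOLD    :  1.000 %  (planted 0.999 %)
BOLD:GCaMP ratio :  0.328
barrel ROI       : 100 connected pixels at the activation peak
```

A synthetic session plants a 3% GCaMP and ~1% OIS-BOLD response in the
barrel cortex over 8 stimulus trials at per-pixel SNR 10 with illumination
drift; the pipeline recovers both peaks within ~2% and forms the
neurovascular-coupling ratio. The other examples cover demux/preprocessing,
CO₂ reactivity (`03`, recovers a 2% plateau to 0.005 pp), diametry (`04`),
two-photon pathology (`05`), and cohort statistics with the Johnson–Neyman
boundary (`06`).

A thin CLI mirrors the per-session stages:

```bash
mesovasc demux --layout blue,green,red session.tif out/
mesovasc stats --model "peak_bold ~ age * genotype + sex" cohort.csv
mesovasc synth cohort --seed 7 --out data/
```

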