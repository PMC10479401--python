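# Methods

This note records the models, estimators, synthetic-data assumptions and
numerical choices behind `hcloop`, in the order of the analysis drivers.

## Feedback-loop plasticity model (`loop_model`)

A rate model with two binary sensory channels s, weights w onto an EC_L2/3
read-out `ro = wᵀs`, hippocampal rate `h`, and Hebbian update
`w ← w + α·h·s` (α = 0.005, 100 pairings, all rates and weights
initialised to 1; the read-out→hippocampus feedback weight g = 1 is fixed —
the feedback synapse itself is not plastic).

Two choices were genuinely open and are fixed as follows:

* **Additive feedback.** In the intact loop the hippocampal rate is
  `h = h₀ + g·ro`, i.e. the feedback adds to the baseline rather than
  replacing it. Only the additive form yields the compounded ≈2.29-fold
  potentiation together with the severed-loop 1.5-fold; replacement
  (`h = g·ro`) gives ≈1.65.
* **Update order.** Within a step: read-out from the incoming weights →
  hippocampal rate → weight increment (one synchronous read-out per
  pairing). The read-out is not recomputed after the increment; at these
  parameters doing so would not change the reported folds, but it would at
  high α, so the order is fixed and documented.

Weights are unbounded (no saturation); over 100 small steps the trajectories
stay far from any physiological ceiling. Closed forms: severed
`w_N = w₀ + Nαh₀`; intact (g > 0) `w_N = (w₀ + h₀/g)(1+αg)^N − h₀/g`;
silenced `w_N = w₀`. They hold for constant s₁ = 1 and are used as oracles
at tolerance 1e-9.

## Sweep feature extraction (`ephys`)

* **Peak amplitude.** Baseline = mean over the 100 ms before stimulus
  onset; peak = extremum in a 100-ms post-onset search window (maximum for
  PSPs/IPSCs, minimum for EPSCs); amplitude = peak − baseline, signed. The
  search-window length is a package default (the convention only fixes the
  baseline window); both windows are configurable.
* **Extremum bias and smoothing.** The raw extremum of a noisy trace is
  biased upward by the expected maximum of the noise in the window (~1 mV
  at 0.5 mV white noise and 2,000 samples), which would drag ratio
  estimates such as the ITDP fold toward 1. `measure_peak_amplitude`
  therefore accepts a boxcar pre-smoothing width; it is **off by default**
  (so noise-free measurements are exact) and **2 ms inside
  `compute_itdp`**, reducing the residual bias to ~0.2 mV, which largely
  cancels in the pre/post ratio.
* **Spike detection** is an upward crossing of 0 mV with a 2-ms refractory
  period — the convention only reports AP occurrence, so the detector is a
  package choice; both parameters are configurable.
* **ITDP.** The pre-induction steady state is the mean amplitude of the
  last 10 pre-induction sweeps (sweeps every 15 s ⇒ 3 min); the
  potentiation fold is the mean of the sub-threshold amplitudes among the
  last 10 post-induction sweeps over that denominator; spike probability is
  the spiking fraction of the same last-10 windows. If every late post
  sweep spikes, the fold is flagged undefined rather than guessed.
* **Photocurrent screen.** Functional-opsin screening asks for a sustained
  photocurrent under a 500-ms pulse; "sustained" is implemented as the mean
  over the final 50 % of the pulse exceeding 20 pA above baseline (both
  configurable) — a package criterion, since only the qualitative screen is
  specified.
* **Monosynaptic classification** under TTX/4-AP: |amplitude| strictly
  greater than 3× the baseline noise SD (k configurable). The persistence
  criterion itself is qualitative in the source protocol.
* **E/I ratio** is per-cell |EPSC|/|IPSC|; cohort values average per-cell
  ratios (a ratio of cohort means is *not* the same number and does not
  reproduce the reported cohort values).
* **Connectivity summaries** carry a per-(layer, category) tested
  denominator, because different cell subsets enter the response, spiking
  and TTX/4-AP assays (e.g. 60/61, 13/47 and 18/22 in the same layer).

## Behavior scoring (`behavior`)

Exploration of an object = head within 2 cm of the object **boundary**
(centre distance − radius; the common edge-wise reading of "within 2 cm of
the object", switchable to centre distance) *and* heading within ±45° of
the bearing to the object centre. Head positions inside the footprint count
as exploring (climbing is not excluded). Consecutive qualifying frames form
bouts; gaps ≤ 0.25 s are merged and bouts < 0.2 s (4 frames at 20 Hz)
dropped. The angular tolerance, minimum bout and merge gap are package
defaults standing in for an unquantified "head directed and sniffing"
criterion; all are configurable and the recovery tests are insensitive to
them at the ±0.05 level.

Novelty index = novel/(novel+familiar) exploration time; discrimination
index = (novel−familiar)/(novel+familiar) = 2·index − 1. Barnes-maze errors
count every hole-visit event without entry (escape hole included, repeat
visits counted separately); latency is the entry time, capped at the 180-s
trial limit (flagged) when the animal never enters. "Reaching" the escape
hole is implemented as entry into the escape box.

## Anatomy quantification (`anatomy`)

* **ROI integration** sums pixels whose centres fall inside the polygon
  (pixel-centre membership, even-odd rule — the standard rasterisation
  choice; membership is delegated to `matplotlib.path`, and the tests carry
  an independent ray-casting oracle). ROI drawing itself is manual in the
  source workflow; polygons are consumed from JSON.
* **Layer ratio** = mean over slices of integrated EC_L5 intensity ÷ mean
  over slices of integrated EC_L2/3 intensity.
* **Depth profiles** are linearly resampled onto a common pia-anchored grid
  (default 5 µm), averaged across slices, and max-normalised to 1 per
  animal (the published axis is "normalized fluorescence intensity" with an
  unstated constant; area-normalisation would be an alternative).
* **Input contributions** = 100 × count/total over all counted presynaptic
  cells. Starter cells are never in the counts; a flag additionally
  excludes the starter region's local cells from the denominator (whether
  local cells belong in the denominator is unstated; the default keeps
  them).

## Synthetic data (`synth`)

The generators emulate the statistical structure the analyses assume — not
the biophysics:

* **Sweeps**: rest −70 mV + dual-exponential PSP kernel (rise 2 ms, decay
  20 ms — typical cortical PSP scales, configurable), unit-normalised on
  the sampled grid so noise-free round trips are exact; amplitude follows a
  saturating LED-intensity curve (half-max at 20 %); white Gaussian sample
  noise (default 0.5 mV) plus optional sweep-to-sweep amplitude jitter.
  Stereotyped APs are inserted when the noiseless depolarisation crosses a
  threshold (default 20 mV above rest, i.e. sub-threshold for all default
  amplitudes); lowering the threshold with jitter makes post-induction
  spike probability a monotone function of potentiation, emulating the
  EC_L2/3 sensory pathway.
* **ITDP experiments**: 12 pre / 12 post sweeps at baseline 4 mV and
  baseline × fold.
* **Trajectories**: a bounded random walk at 20 Hz alternating roaming
  epochs (AR(1) velocity noise, wall reflection) with object-directed
  epochs (approach at 8 cm/s, exponential dwell ~2.5 s hovering ~1 cm off
  the edge, heading at the object). Epoch targets are drawn proportionally
  to per-object attraction biases, so the novelty index tracks the novel
  object's share of attraction mass, slightly compressed toward 0.5 by
  incidental symmetric passes. The control-like share (0.61) and
  silenced-like share (0.33) were calibrated once against the generator so
  the 50-animal cohort means land at 0.60 and 0.35; the constants are
  stored in the package (`CONTROL_BIAS`, `SILENCED_BIAS`).
* **Barnes logs** place exactly the configured number of non-entry visits
  before the configured entry latency.
* **Axon images**: two equal-area horizontal bands (EC_L2/3 nearer the pia
  at intensity I/2.5, EC_L5 at I) on a zero background with Gaussian noise,
  matching rectangular ROIs and a column-averaged pia-anchored profile;
  stacks default to 6 slices.
* **Rabies counts**: one multinomial draw per animal. Only the three
  largest region shares (26.7 %, 22.5 %, 11.9 %) are reported values; the
  remaining proportions are plausible order-of-magnitude choices. Reported
  cohort SEMs constrain between-animal variance only loosely, so generator
  variances throughout are order-of-magnitude defaults, documented as such.

What passing recovery tests show: the estimators are unbiased enough to
recover their generative parameters under realistic noise levels and sample
sizes. What they do not show: robustness to features of real recordings the
generators omit — electrode drift and access-resistance changes, correlated
membrane noise, non-stationary behavior (habituation within a session),
tissue autofluorescence gradients, or miscounted/missed cells.

## Problem sizes and tolerances

Validation and acceptance runs use 20 seeded ITDP experiments per fold,
50 animals per behavioral cohort (10-min sessions), 6-slice image stacks
and 10,000-cell count tables — cohort scales chosen to make sampling error
comfortably smaller than each check's tolerance (ITDP fold ±0.1, novelty
index ±0.05, intensity ratio ±5 %, CA1 share ±1 point, Barnes scores and
model folds exact/analytic). The full validation completes in seconds.

## Known limitations

* The loop model is a two-channel rate abstraction: no spiking, dendritic
  nonlinearity, inhibition, depression or weight bounds.
* The ITDP estimator excludes spiking sweeps, so under heavy post-induction
  spiking the sub-threshold fold underestimates the true potentiation —
  matching the convention it implements, not correcting it.
* Acquisition-vendor sweep formats are not parsed; sweeps enter as neutral
  CSV + JSON sidecars.
* No atlas registration, automatic layer delineation or cell detection;
  anatomical inputs are ROI polygons and count tables.
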