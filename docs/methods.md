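# Methods

`cardiossm` implements a shallow diagonal state-space (S4D) sequence
classifier for multi-label abnormality detection on raw multi-lead ECG,
together with everything needed to study it at desk scale: a
class-conditioned synthetic ECG generator, a classical denoising pipeline
(to demonstrate its dispensability), a metric suite, and the lead-ablation
robustness protocol.  This note records the model, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic experiments do and do not show.

## The diagonal state-space layer

Each channel of a layer carries an independent continuous-time linear
state-space model

    x'(t) = A x(t) + B u(t)
    y(t)  = C x(t) + D u(t)

with **diagonal complex** A, so the modes decouple.  For a real system the
spectrum is closed under conjugation; we store only the N/2 modes with
non-negative imaginary part and recover real outputs as `y = 2·Re(C x) + D u`.
Zero-order-hold discretization at step size Δ gives, per mode `a`:

    ā = exp(Δa),       b̄ = (exp(Δa) − 1)/a · b     (b̄ = Δ·b as a → 0)

with C and D unchanged.  The discrete system is equivalently a linear
recurrence `x_n = ā x_{n−1} + b̄ u_n` or a causal convolution with the
length-L impulse response

    K[n] = 2·Re( Σ_m c_m b̄_m ā_m^n ),   n = 0..L−1,

evaluated through a Vandermonde-style power table `V[m,n] = ā_m^n` (built by
cumulative products; `|ā| ≤ 1` keeps this stable) rather than a sequential
loop.  Convolution uses FFTs of length `next_fast_len(2L) ≥ 2L−1`, so the
circular wrap-around falls entirely in the discarded tail and the result is
the exact linear causal convolution.  The recurrent scan is kept as a slow,
independent oracle; tests require the two routes to agree to < 1e-5 relative
over hundreds of random configurations, and ZOH to match per-mode closed
forms evaluated with `cmath` to 1e-12.

**Initialization** is the linear diagonal scheme: `a_n = −1/2 + iπn`,
`b = 1`, `c` standard complex normal, `log Δ` log-uniform on `[1e-3, 1e-1]`
(seconds per sample; at 500 Hz this spans memory from a few samples to the
whole record).  Stability is structural: the real part of every pole is
parameterized as `−exp(ρ)`, so `|ā| ≤ 1` for any parameter value.

**Trainable tensors.** All SSM dynamics are trained: `log(−Re a)`, `Im a`,
`log Δ`, the complex output map `c` and the feedthrough `d`; the input map
`b` stays fixed at 1 (it is redundant against `c` in a diagonal system).
Gradients are derived analytically: with `gK = ∂L/∂K` and the moments
`S0 = Σ_n gK[n] ā^n`, `S1 = Σ_n gK[n] n ā^n`, the chain rule through the ZOH
formulas gives closed forms for every parameter (e.g.
`∂b̄/∂a = (Δā·a − ā + 1)/a²`, with the limit `Δ²/2` at `a = 0`).  An earlier
revision froze the poles and timescales; it trained but could not learn the
PR-interval (timing) class within the 30-epoch budget — adapting Δ turned
out to be what timing discrimination needs, which is consistent with the
reference treatment of these models.  The weight-decay term is not applied
to the dynamics parameters.

## The classifier

    lead→channel linear projection (n_leads → H)
    n_layers × [ pre-norm → per-channel S4D convolution → GELU
                 → position-wise linear (H → 2H) → GLU gate
                 → dropout → residual add ]
    mean pooling over time → LayerNorm → dense (H → n_classes) → sigmoid

Defaults follow the study configuration: 4 layers, model dimension H = 128,
state size N = 64, 12 leads, 8 classes, dropout 0.1.  The forward pass
recomputes kernels at whatever input length it receives, so the model is
length-agnostic.  Classes are predicted independently (multi-hot); the
binarization threshold for F1/accuracy is 0.5.

Open architectural choices, and what drove them:

* **Normalization axis.** The pre-norm standardizes each channel *over
  time* (instance norm) rather than across channels per time step.  With a
  small channel count and near-rank-3 projected ECG input, per-time-step
  normalization destroys the temporal amplitude envelope (every sample is
  forced to unit variance across 16 channels, amplifying baseline noise to
  QRS scale); normalizing along time preserves it.  Per-time-step LayerNorm
  remains available (`ModelConfig.norm="channel"`).
* **GLU gate.** The position-wise mixing maps H → 2H and gates the value
  half with the sigmoid of the gate half.  The multiplicative interaction
  ("P-wave detected AND QRS delayed") is what lets a convolution-plus-
  pointwise stack express interval logic; without it the PR-interval class
  plateaued near chance.
* **Pooling.** Mean over time.  A mean+max concatenation was evaluated and
  performed worse at this scale (the max path is noise-prone); it remains
  available as `pooling="meanmax"`.
* **Decoder conditioning.** A final LayerNorm on the pooled features gives
  the decoder unit-scale inputs, and the trainer initializes the decoder
  bias at the per-class prior log-odds, so the short training budget is
  spent on features rather than on learning base rates.
* **Lead dropout.** During training each whole input lead is zeroed with
  probability 0.05 (`ModelConfig.lead_dropout`), mirroring clinically
  dropped electrodes.  This is what gives the trained model the distributed
  lead usage that the lead-ablation protocol probes; without it a model
  trained on a homogeneous cohort is free to rely on a few leads and
  collapses when they are emptied.  Higher rates (0.1) buy more ablation
  robustness at a visible cost in clean accuracy under the short training
  budget.  Disabled automatically for single-lead models.
* **Input centering.** The forward pass subtracts each lead's mean before
  anything else.  Absolute DC on an ECG lead is electrode half-cell
  potential — an acquisition artifact, not physiology — yet it would
  otherwise ride the residual stream past every normalization into the
  temporal mean-pool and become a (spurious, fragile) feature; a 0.1 Hz
  baseline high-pass at evaluation time then shifts logits for no
  physiological reason.  Centering removes the channel by construction.
* **Numerics.** float32 by default (float64 via `dtype=`); every layer's
  hand-derived backward is finite-difference-checked in float64 in the test
  suite.  The GELU uses the tanh form and the sigmoid the tanh half-angle
  form — both dtype-preserving.

## Training recipe

AdamW (betas 0.9/0.999, eps 1e-8, decoupled weight decay 0.01), peak
learning rate 1e-3 annealed to 0 by the closed-form cosine
`lr(e) = lr_min + (lr_max − lr_min)(1 + cos(πe/E))/2`, batch size 32,
unweighted mean BCE with probabilities clamped to `[1e-7, 1−1e-7]`, exactly
E epochs — no early stopping.  The recorded learning-rate trace equals the
closed form exactly, by contract.  Validation is a stratified 15% split by
label combination (the study design reserves a test subset but defines no
validation rule).  "Accuracy" in the history is per-entry accuracy of the
thresholded multi-hot output; per-record exact match would be an equally
defensible reading for multi-label data, and is not what is recorded.

## Synthetic cohorts

Each record is a train of PQRST complexes built from Gaussian bumps (plus a
raised-cosine ST plateau) placed on a shared time axis; three source trains
(P, QRS, ST/T) are projected to the 12 standard leads through a fixed
full-column-rank 12×3 matrix, then per-lead white noise (default SD
0.05 mV, ordinary clinical noise floor) and a slow sinusoidal baseline
wander (0.15–0.35 Hz, 0.02–0.05 mV) are added.  Defaults: 500 Hz, 4096
samples, heart rate 60–90 bpm, four-class mix at 0.2 marginal prevalence
each with independent draws (so label co-occurrence happens at product
rate).  Label combinations that contradict each other's defining
measurements (AF∧1dAVb, AF∧PAC, LBBB∧RBBB, STD∧STE) are redrawn.

Class conditioning targets the defining measurement of each class: PR drawn
from 0.26–0.32 s for first-degree AV block (criterion > 0.2 s); absent P
waves, 100–140 bpm and RR jitter redrawn until the scheduled RR series has
CV ≥ 0.18 for atrial fibrillation (criterion ≥ 0.15 measured); QRS duration
0.13–0.16 s with V1-dominant (RBBB) or V6-dominant (LBBB) precordial weight
vectors; premature narrow (PAC) or wide (PVC) beats at rate 0.18 with one
guaranteed; ST offsets of −0.15…−0.25 / +0.25…+0.35 mV (criterion ∓0.1 mV).
The bundle-branch blocks additionally carry their canonical *intra-lead*
QRS shapes — a deep-S/late-tall-R' (rSR'-type) complex for RBBB and a
broad notched R for LBBB — not just per-lead amplitude asymmetry.  Without
a shape difference the two classes are identical up to scale on any single
lead, which would make a single-lead (Lead II) protocol ill-posed by
construction.  Likewise, every record receives its own electrical axis:
each entry of the lead-projection matrix is jittered multiplicatively
(uniform 0.88–1.15, sign-preserving, bounded so the class-defining V1/V6
asymmetry cannot flip).  Omitting inter-patient axis variability lets a
model bind to a single fixed lead mixture, which degenerates the
lead-ablation protocol.
Soundness is checked by *independent* fiducial estimators
(`cardiossm.measurements`) that share nothing with the generator: smoothed
R-peak detection, P-peak search windows, a QRS extent rule on the smoothed
energy envelope (2.5% of local peak energy inside ±120 ms), ST level
0.10–0.15 s after R against the median baseline.

What the generator does **not** emulate: real P/QRS/T morphology variation,
inter-patient covariance structure, electrode artifacts, muscle noise,
drift non-stationarity, or realistic class overlap rates.  Passing the
scaled-down study therefore shows the pipeline is correct and the
architecture can learn exactly the morphology/timing/rhythm signatures the
labels encode — it says nothing quantitative about clinical data.

## Evaluation conventions

AUROC is the rank (Mann–Whitney) statistic with ties credited 1/2; AUPRC is
average precision (the step-wise integral, equal to the mean of precision
at each positive's rank); both are verified against exhaustive enumeration
to 1e-12 in the tests.  Per-class accuracy is one-vs-rest at the threshold.
"Weighted average" weights classes by positive-label support.  Classes that
are single-valued in a dataset get NaN for the ranking metrics and are
excluded from the weighted averages.  Degenerate 0/0 precision/recall/F1
ratios are defined as 0.  "Emptying" a lead means setting it to zeros —
the only fill value carrying no information; masks are re-drawn per record
by default (`per_record=False` masks the whole pass identically).

## The denoising pipeline

4th-order Butterworth 0.5–40 Hz bandpass, then `db4` level-8 wavelet
shrinkage (universal soft threshold with MAD noise estimate from the finest
detail level), then a 6th-order 0.1 Hz high-pass, all zero-phase
(forward–backward) and lead-wise.  Whether the "0.1 Hz, 6th order" setting
belongs to the wavelet step or is a separate filter is ambiguous in the
source description; it is implemented as a separate high-pass, applied last
by default and switchable (`highpass_last`).  Forward–backward IIR
filtering at sub-hertz corners needs edge padding on the scale of the
corner's settling time; the default padding of the library routine is far
too short for 8 s records, so it is set explicitly from the corner
frequency.  The pipeline is nearly idempotent (< 5% RMS change on a reuse)
for passband content; broadband QRS energy in the transition bands is
attenuated on each pass, which bounds how idempotent any such cascade can be.

## Problem sizes

The scaled-down study trains the 4-layer, dim-16, state-32 model for 30
epochs on 600 records (12 × 4096 at 500 Hz) and evaluates on a held-out
150; the lead-ablation curve uses 3 mask redraws per level; the single-lead
arm repeats training on Lead II alone.  These sizes make the full study
reproducible in minutes on a single CPU while leaving the learning problem
non-trivial (the PR-interval class is only solved late in training).
Examples use further-reduced sizes and say so.

## Known limitations

* The NumPy implementation is single-threaded and trains small models only;
  it is a faithful, testable reference, not a GPU training stack.
* Frozen `b = 1` removes one redundant degree of freedom; models whose
  input map matters per-mode would need it released.
* The generator's conflict rules exclude clinically possible but
  measurement-contradictory label pairs, so co-occurrence statistics are
  only approximately the product of marginals.
* Wavelet shrinkage uses the universal threshold; no translation-invariant
  cycle spinning.
* AUPRC with tied scores depends on the stable sort order within a tied
  block, as average precision does in common library implementations.
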