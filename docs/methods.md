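# Methods

`flexb2b` re-implements, end to end and on synthetic inputs, the
computational pipeline of a flexible-electrode brain-to-brain interface:
SSVEP decoding of human EEG into eight two-mouse turning commands,
charge-balanced stimulation synthesis, behavioral quantification of the
evoked turning, and a quasi-static field model comparing neuron
activation by flexible and glial-encapsulated rigid electrodes.  This
note records the models, the defaults that matter, and the design
choices made where the protocol left the design open.

## Synthetic SSVEP EEG

No recordings from the original experiments are public, so the decoder
is developed and validated on a generative stand-in.  Each 1-s trial at
1000 samples/s on the 8-channel occipital montage (O1, POz, PO3, PO5,
Oz, PO6, PO4, O2) contains

- a steady-state response at one of eight joint frequency-phase targets:
  frequencies 8-15 Hz at 1 Hz spacing, phase offsets cycling 0, π/2, π,
  3π/2.  The response is a harmonic series: the k-th harmonic has
  amplitude k^(-harmonic_decay) (default decay 1.0, i.e. 1/k — harmonic
  amplitudes are visible but unreported in occipital recordings) and
  phase k·φ, i.e. a periodic non-sinusoidal waveform;
- channel mixing by a fixed all-positive random gain vector (0.5-1.5),
  since every occipital channel sees the response at some amplitude;
- background noise, by default an equal-power mixture of white and 1/f
  (pink) noise — the standard first-order description of resting EEG —
  scaled so that the ratio of response power to noise power in the
  4-100 Hz band equals `snr_db`.

The default `snr_db` of +10 dB makes the decoding problem comfortably
learnable while leaving the untrained network at chance; the generator
exposes the full range so that difficulty sweeps remain meaningful.
Every trial is a pure function of its seed; dataset seeds are spawned
from one master seed.

What the generator does **not** model: volume conduction and realistic
channel covariance, alpha-band structure, eye/muscle artifacts,
inter-subject and inter-session variability.  Passing the learnability
bar on this data shows the architecture and training loop work, not that
the published human accuracies (92.5-98.75%) are reproduced; those
require the original recordings.

## Preprocessing

Second-order Butterworth band-stops at 48-52 Hz and 98-102 Hz (the union
of the two stated power-line treatments: a 48-52 Hz notch and 50/100 Hz
band-stops) followed by a second-order 4-100 Hz band-pass.  Filters are
applied forward-backward (`sosfiltfilt`, even-reflection padding), i.e.
zero-phase: the decoder consumes waveform shape, and the protocol never
specifies causal filtering; a causal flag (`zero_phase=False`) is
available.  Trials are stacked into (batch, 1, channels, time) tensors.

## Dual-branch decoder

Implemented as a from-scratch numpy engine (`flexb2b.nn`) with explicit
forward/backward passes; every layer's gradient is verified against
numerical differentiation in the test suite.  Convolutions are stride-1
and evaluated via FFT products (fast lengths, frequency-domain channel
contraction), which keeps the broad dilated kernels cheap on CPU;
full-height valid kernels collapse to 1-D convolutions over time.

Architecture (smallest arrangement containing every named component):

- **time branch** on (batch, 1, 8, 1000): three blocks of 2-D conv →
  batch norm → ReLU → max pool, kernels (1,25), (8,11), (1,11), pools
  (1,4); then flatten → dropout 0.5 → linear → ReLU to 32 features.
- **frequency branch**: per-channel magnitude STFT, Hann window of 250
  samples (4 Hz bins, ≥2 cycles of 8 Hz), hop 62 (13 frames per 1-s
  trial), bins cropped at 100 Hz to match the band-pass (26 bins);
  log1p compression; a 1×1 entry conv; two residual blocks with dilated
  (9,13) kernels at dilation (2,2), each conv followed by batch norm;
  then flatten → dropout → linear → ReLU to 32 features.
- concatenation of the two 32-vectors forms the 64-d embedding (the
  vectors inspected with t-SNE); one fully connected layer maps it to
  the 8 class logits.

Training: plain SGD, batch 32, initial rate 0.2, cosine annealing with
warm restarts (initial period 50 epochs, multiplier 2; the original
study does not state the schedule, so both are exposed in config), 500
epochs by default; analyses here use a reduced 100 epochs, which is
already far past convergence on the synthetic task.  Augmentation adds
white Gaussian noise at 10% of per-batch RMS to a Bernoulli(0.5)-chosen
subset of each batch (the original study adds unspecified random noise to half of the
samples; additive Gaussian is the natural choice).  Cross-entropy on
the one-hot target.  All randomness (shuffling, dropout, augmentation,
init) is seeded; evaluation mode is deterministic.

Problem sizes for the headline check — 640 training / 320 test trials,
100 epochs — mirror the single-participant protocol and train in a few
minutes on one CPU core.

## Evaluation

Confusion matrices carry counts (rows true, columns predicted), exact
conservation, and pooled accuracy.  Parameter sweeps re-train from
scratch per grid point and average over seeds; single-seed sweeps are
flagged because they carry no dispersion.  t-SNE uses scikit-learn with
perplexity 30 (capped at (n−1)/3) and a recorded seed.

## Stimulation synthesis

Commands are two letters, one per mouse: L = left turn via right-M2
stimulation, R = right turn via left-M2 stimulation, X = none.  The
stimulation waveform is a cathodic-leading biphasic train: 200 µs at −I,
a 100 µs interphase gap, 400 µs at +I/2, repeated at 100 Hz, so each
pulse carries exactly zero net charge (200·I = 400·I/2).  The default
output rate of 1 MHz makes every phase width an integer sample count and
charge balance bit-exact; incommensurate rates are rejected with a
suggested alternative.  The accelerated-aging utility implements the
ASTM-style equivalence t_real = t_test · Q10^((T_test−T_real)/10) with
Q10 = 2, the conventional constant of the guideline.

## Behavior quantification

Heading is the direction of the velocity vector, unwrapped; steps
shorter than 1 mm (tracking noise scale) do not update it, and samples
before the first supra-threshold step inherit the first defined heading.
Counterclockwise is positive.  Angular displacement over a window is the
cumulative heading change; "maximum angular change" per phase is the
extremum (largest |change| from phase start) within the phase, so a
transient turn counts even if the animal turns back — an endpoint
variant is exposed.  Linear displacement is accumulated path length, not
net displacement: published baseline values (~100 mm during a
pre-stimulation phase) are consistent with accumulated path of a
near-stationary animal, and path length better reflects evoked motion.
A valid turn requires |angle| strictly greater than 20°; the pair label
"XX" (neither mouse turned) can be observed but never commanded.  Phase
comparisons use the two-tailed unpaired Student's t-test (pooled
variance, Welch by flag) with the conventional star coding.

The trajectory generator emulates video-tracked positions at 30
samples/s: near-stationary jittering rest (sub-threshold step lengths)
before and after stimulation, and constant-speed motion (45 mm/s) with
heading drift at ±25°/s during stimulation, plus seeded heading/position
jitter.  At zero jitter the during-phase heading change is exactly
rate × duration to within one sample step.

## Spike metrics

Peak-to-peak amplitude is max − min of the mean waveform.  Spike SNR has
no single field convention and the original study does not define its formula;
the default here is p2p / (2 · noise SD) with the factor k exposed and
reported alongside values.  Firing rates are histogram counts per bin
divided by the bin width (the series integrates back to the spike
count); the rate-velocity correlation is Pearson's r against
max-normalized velocity.  Spike sorting itself is out of scope — the
module consumes sorted trains (CSV: time, neuron, channel).

## Activation-field model

Electrostatics of stimulation in tissue: ∇·(σ∇V) = 0 in a 3 mm cube,
σ_brain = 0.2 S/m, with the electrode surfaces on the bottom face as
constant-current sources (uniform current density over each surface,
equal current per site), the remaining bottom face insulating, and the
five far faces grounded (return-electrode-at-infinity approximation;
the original boundary choice is unstated).  Relative permittivity (88.9)
is stored but unused — the solve is DC and the activation criterion is
on conduction current density.

Geometries: the flexible and rigid arrays share eight 16 µm × 12 µm
sites in a single column at 30 µm center-to-center pitch (the 16-site
shank covers 450 µm at the same pitch); the microwire is a 100-µm
diameter disc.  Rigid geometries are wrapped conformally by a 40-µm
glial scar (σ = 0.166 S/m) — every point within 40 µm of the
electrode-bearing footprint.

Discretization: cell-centered finite volumes on a graded tensor grid —
uniform 3-4 µm cells over the region where |J| can exceed threshold,
geometric growth (ratio 1.35, capped at 250 µm) to the boundary;
harmonic-mean face conductivities; Jacobi-preconditioned conjugate
gradients to 1e-8 relative tolerance.  |J| is evaluated at cell centers
from averaged face fluxes.  The scheme is validated against the closed
form for a uniform-current disc on an insulating plane (on-axis |J|
within 10%, observed ~1%), exact discrete current conservation, and
linearity in the injected current.  Refining the default grids changes
activated volumes and matched currents by well under 10% (observed
≤2.6% between the 2.5×-coarser test grids and the defaults, and ≤0.5%
under further refinement).

Activation: neurons are counted where |J| strictly exceeds 1000 A/m²,
excluding the glial volume (scar tissue contains no countable neurons —
this exclusion, not the modest σ contrast, is what penalizes the rigid
geometries).  The neuron count multiplies this volume by the density
constant, kept exactly as printed (135,801 m⁻³) although the magnitude
suggests mm⁻³ was meant; matched-current comparisons equate counts, so
the density cancels and all reported currents are density-independent.

`current_uA` throughout is the output of **one electrode site** (the
scanned "electrode's current output"); the array total is 8×.  Under
this reading the model reproduces the published comparison: the rigid
array matches the flexible array's 5 µA activation at ≈7.4 µA
(published 8.9, ratio 1.48 vs 1.78) and the microwire at ≈54.8 µA
(published 62.5, ratio 11.0 vs 12.5).  Under the alternative reading
(5 µA total split across sites) the rigid array activates no tissue at
all beyond the 40 µm standoff until ~30 µA — inconsistent with the
published 8.9 µA by an order of magnitude — which is why the per-site
convention was adopted.  Matching currents are found by bisection on the
linearly rescaled activation curve to 0.1 µA; currents beyond 100 µA are
reported as out of range.

Non-goals: no cable or compartment neuron models and no
activating-function criterion — activation is the threshold-on-|J| rule
above; no general unstructured meshing.

## Known limitations

- Synthetic EEG omits the structured non-stationarities that make real
  SSVEP decoding hard; accuracy bars here certify the pipeline, not
  human-data performance.
- The field model's absolute activation volumes depend on the open
  boundary/partition choices; the matched-current *ratios* are the
  robust quantity, and they land within ~20% of the published values.
- The trajectory generator's turning statistics are stylized (constant
  turn rate); it reproduces the analysis-relevant structure (signed
  drift, rest phases, valid-turn threshold), not full rodent kinematics.
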