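# Methods

## The task

The checkerboard task decouples a perceptual color decision from the motor
direction report. On each trial two targets appear, one red and one green,
with their left/right placement ("target configuration") randomized; a
red/green checkerboard then provides color evidence summarized by the signed
color coherence (R − G)/(R + G), drawn from 14 values placed symmetrically in
(−1, 1) (defaults ±{0.05, 0.15, 0.30, 0.45, 0.60, 0.75, 0.90}, configurable).
The correct color is red iff the coherence is positive; the correct direction
is the side holding the matching target, i.e. direction = color XOR
configuration. Because any color maps to either direction with equal
probability, a representation that is *minimal and sufficient* for the motor
report keeps direction and discards color and configuration — the
information-bottleneck prediction this package quantifies.

Simulated trials unfold on a 10 ms grid in four epochs: Center Hold
(duration ~ Normal(200 ms, 50 ms SD), truncated at one step; all inputs
zero), Targets (Uniform[600, 1000] ms; channels 1–2 carry the left/right
target colors, −1 red / +1 green, noiselessly), Decision (1500 ms; channels
3–4 carry the signed red and green coherences, which sum to zero before
noise, plus independent Gaussian noise of SD 0.1 per time step), and
Stimulus Off (300 ms; all inputs zero — its only role is the
return-to-baseline penalty, and its duration is a free choice here). The
desired output is a pair of decision variables (DVs): zero everywhere except
a unit step on the correct side during Decision. The first 200 ms of
Decision are excluded from the output loss so a gradual DV rise is not
penalized. Training streams include 10% catch trials (half no-input, half
targets-only, desired output zero throughout, full loss mask); validation
and test sets contain none.

## The network

A continuous-time rate network, tau x' = −x + W_rec r + W_in u + b_rec + eps
with r = relu(x) and readout z = W_out r, is integrated by forward Euler
with alpha = dt/tau = 0.2 (tau 50 ms, dt 10 ms). Recurrent noise is i.i.d.
Gaussian per unit and step with SD 0.05 as stated; we treat that as the
per-step discrete SD (a sqrt(2/alpha) continuous-time scaling is available
as `noise_scaling="sqrt2_alpha"`).

Areas are equal blocks of units (exemplar: 3 areas; 80% excitatory / 20%
inhibitory per area under Dale's law). Within-area connectivity is dense
(no self-connections). Only adjacent areas connect: feedforward E→E at 10%
Bernoulli density, feedback E→E at 5%, feedforward E→I at 0% by default —
all configurable. Task inputs drive area 1 only; the readout taps the last
area's excitatory units with nonnegative weights.

Initialization proved to be the one genuinely load-bearing free choice.
Recurrent magnitudes are folded Gaussians; under Dale's law the inhibitory
columns are scaled by n_E/n_I (4× at the 80/20 split) so expected row sums
vanish, and the signed matrix is rescaled to spectral radius 1.5. Without
the excitation/inhibition balance, multi-area Dale networks reliably
stalled at the condition-independent solution (both DVs rising identically,
no stimulus dependence); with it they train from most seeds. Input weights
are Gaussian with 1/sqrt(fan-in) scale; readout weights are folded Gaussians
scaled by 1/fan-in (all-positive weights sum coherently); biases start at
zero; x(0) = 0.

## Training

The loss is the masked mean squared DV error plus Frobenius penalties
lambda_in ||W_in||²/(N·N_in) + lambda_rec ||W_rec||²/N² +
lambda_out ||W_out||²/(N·N_out) with lambda = 1 each, an optional rate
penalty (coefficient 0 by default), and a vanishing-gradient penalty with
coefficient 2. The latter is the Pascanu norm-ratio regularizer
sum_t (||delta_t|| / ||delta_{t+1}|| − 1)² on the backpropagated errors,
differentiated under the standard first-order approximation (the incoming
error is treated as a constant); it is averaged over batch and time.

Optimization is Adam at learning rate 5e-5 with global gradient-norm
clipping at 1.0 (the clipping threshold and minibatch size, 64 fresh trials
per update, are unspecified upstream and fixed here). After every update the
parameters are projected onto the constraint set: masked entries zeroed,
wrong-signed entries clipped to zero. Every 200 updates a balanced
validation set is simulated and the run stops when, 500 ms before
checkerboard offset, the correct DV exceeds both the other DV and the 0.6
threshold on at least 65% of leftward and 65% of rightward trials; a trial
that is correct but sub-threshold does not count. The best checkpoint by the
smaller of the two directional fractions is returned, with a convergence
flag.

BPTT is implemented directly in numpy (verified against central finite
differences of the simulated loss on small networks, the suite's gradient
oracle); float32 forward/backward with float64 accumulation.

## Problem sizes

The exemplar protocol of record uses 300 units (100 per area) at learning
rate 5e-5. The analyses in this repository run reduced exemplars of 150
units (50 per area, 40 E + 10 I; the pipeline default is 90 units for even
faster iteration), a 560-trial validation set (20 per condition rather
than 100), learning rate 2e-4 (the bottleneck is robust across learning
rates in the full-scale protocol's own sweeps, and the smaller problem
supports larger steps — criterion in ~600–800 updates instead of ~7000),
and 1600 further updates past the first criterion pass. The continued
optimization matters: networks stopped at the bare 65% criterion have ~10%
endpoint-criterion decisions, an unshaped first inter-areal matrix, and no
bottleneck geometry; after the post-criterion phase the endpoint rate
drops below 0.5%, the direction axis locks onto the top potent dimension
of W21, and the output area's color-axis variance collapses. The
acceptance tests train one such seed (the epoch budget is capped at 3400
updates); the acceptance script uses the same configuration. Reported RNN quantities scale accordingly: the
potent/null analyses operate on 24×24 feedforward E→E blocks (chance line
m/24) instead of 80×80. All other protocol numbers follow the full-scale
recipe: 2800-trial behavioral evaluation at 200 trials per condition for
behavior curves, decode datasets of 700 training and 2100 test trials
simulated at recurrent noise SD 0.1 with features averaged in [−300, +100]
ms around each trial's threshold-crossing RT, and dPCA on condition
averages over whole trials.

## Analyses

**dPCA.** Condition-averaged tensors X[unit, color, direction, time] are
built from fixed-timing trials (center hold at its mean, targets interval
at its midpoint) so trials share a time base without restretching. The
2×2 color-by-direction grid is in bijection with (color, configuration), so
marginalization yields condition-independent (time), color, direction, and
the color×direction interaction — which *is* the target-configuration
signal. The four marginalized tensors sum exactly to the centered tensor.
Per marginal, encoder/decoder pairs minimize ||X_c − P D X||² by
reduced-rank ridge regression (rank-k SVD truncation of the ridge
prediction); the ridge is a fixed small fraction (1e-6) of mean per-unit
signal power rather than cross-validated — on condition averages of ≥25
trials per cell the cross-validated optimum is indistinguishable from 0,
and the parameter is exposed for callers who want to select it. Axis
overlap is the absolute dot product (dPCA axis signs are arbitrary).
k = 1 per marginal for network activity; restretched neural-style data use
k = 5.

**Restretching** (for neural-style sessions): each trial's
target-to-checkerboard interval and RT are piecewise-linearly mapped onto
their medians (defaults 735 ms and 527 ms); DLPFC-style uses one
target-aligned window [−100, 1200] ms, PMd-style concatenates target-aligned
[−100, 367] ms with checkerboard-aligned [−368, 465] ms. Trials too short
for the window are dropped.

**Decoding / usable information.** Usable information is the variational
bound max(0, H(Y) − L_CE) with L_CE the held-out cross-entropy in bits of a
trained decoder. The network decoder is an MLP (three hidden layers of 64
leaky-rectified units, slope 0.2, dropout 0.5; the linear variant drops the
nonlinearity and raises dropout to 0.8), Adam at 1e-3, minibatch 64, 200
epochs, parameters taken from the epoch with the best validation
cross-entropy (15% of the training split). Session-level decoding uses an
RBF-kernel support-vector classifier (kernel configurable) on
movement-aligned 400 ms window averages with an 80/20 split, and a
100-permutation trial-shuffle null; significance means exceeding the null's
99th percentile.

**Potent/null projections.** For each area's recurrent block and each
feedforward E→E block (W21, W32), the m-dimensional potent space is the span
of the top-m right singular vectors; a task axis (restricted to the source
units — excitatory only for the inter-areal blocks — and renormalized) is
scored by its squared projection, compared against a per-matrix 100-draw
random-vector baseline whose expectation is m/d.

**CCA.** Populations are compared on matched condition×time samples (10 ms
bins, [−400, 400] ms around checkerboard onset, condition-independent
signal removed), PCA-denoised (4 dims for DLPFC-like, 2 for PMd-like
comparisons), with a 2-dimensional CCA; the mean canonical correlation is
reported. Since the monkey recordings are not distributed, the reference
populations are the synthetic presets below — CCA similarity orderings
against them are a qualitative, not quantitative, stand-in.

## Synthetic sessions

`interareal.synth` generates small sessions (default 24 units) emulating the
recorded populations' structure: rates are a shared sigmoidal
condition-independent time course (80% of variance by default), plus
per-variable coding axes with configurable pairwise cosines (built by a
Gram-factor construction on a random orthonormal frame), each gated by a
sigmoidal post-checkerboard envelope so choice information appears only
after the stimulus, plus noise. Noise is half fast (i.i.d. per 10 ms bin)
and half slow (a per-trial constant per unit) by default; the slow share is
what keeps window-averaged features from becoming noiseless, mimicking
trial-to-trial state fluctuations in real data. Amplitudes are calibrated
against the empirically realized component variances, so requested variance
fractions hold exactly. Trial timing: uniform target-to-checkerboard
interval (500–1000 ms) and lognormal RT whose median scales as
1 + 0.35·(1 − |coherence|), median 450 ms at full coherence — qualitatively
matching slower responses to ambiguous stimuli.

Ground truth includes each variable's Bayes decode accuracy. Because
direction = color XOR configuration, the labels are pairwise independent
but jointly deterministic, and a variable can be decodable through the other
two axes; the oracle therefore enumerates the four (color, configuration)
combinations. When each class collapses to a single Gaussian the accuracy
is Phi(d/2σ) averaged over per-trial envelopes, and the exact channel
information is computed by quadrature; the general mixture case is evaluated
by a seeded Monte-Carlo likelihood-ratio test. The `dlpfc_like` preset
plants direction ≫ configuration ≥ color variance with configuration–color
cosine 0.5 and direction–color cosine 0.2; `pmd_like` plants direction only.

What the generator does *not* emulate: spiking statistics beyond an optional
Poisson mode, correlated noise structure beyond the isotropic slow
component, heterogeneous single-unit tuning shapes, and cross-session unit
identity. Passing tests on synthetic sessions therefore validate the
analysis machinery and its calibration, not claims about the monkey data.

## Numerical choices and degenerate inputs

Ties in the DV threshold crossing go to the larger DV, exact ties to left.
Trials that never cross threshold contribute to psychometric curves (by the
endpoint DV comparison) but not to RT, and are excluded (counted) from
decode datasets. Zero-rate units pass through normalization unchanged.
Degenerate dPCA marginals return zero-variance axes. The shuffle null with
100 permutations uses the interpolated 99th percentile, giving a ~1%
empirical false-positive rate (verified on null sessions). All randomness
flows through explicit numpy Generators; identical manifests reproduce
byte-identical reports.

## Known limitations

Training at the full 300-unit scale is supported but takes hours on one
CPU in this numpy implementation. The information-bottleneck checks run on
reduced networks, and one aspect of the full-scale phenomenon does not
carry down: although the condition-averaged bottleneck and the propagation
mechanism reproduce cleanly (output-area direction/color variance ratios in
the hundreds, direction axis on the top potent dimension of the inter-areal
matrix, color axis at the random baseline), a powerful single-trial decoder
still extracts residual color/configuration information from the reduced
output area (roughly 75–96% accuracy, versus ~51–54% at the full scale).
Longer training does not remove it at these sizes. Claims about
single-trial nuisance suppression therefore hold only at the full scale.
Occasional seeds fail the bilateral training criterion within the reduced
epoch budget; they are reported with the non-convergence flag rather than
silently retried. Monkey-data numbers
(e.g., DLPFC/PMd dPCA variances and session decoding percentages) are not
reproducible without the unreleased recordings; the synthetic presets cover
those stages qualitatively.
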