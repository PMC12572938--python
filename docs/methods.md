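# Methods

`spikewav` implements a spiking transformer for EEG decoding whose encoder
blocks fuse a softmax-free spiking self-attention path with a learned,
orthonormal Haar wavelet sub-band path. This note documents the model, the
numerical choices, the synthetic data world the tests run in, and what a
green test does and does not establish.

## Neuron model

All nonlinearities are leaky integrate-and-fire (LIF) neurons with hard
reset:

```
H[t] = V[t-1] + (X[t] - (V[t-1] - V_reset)) / tau
S[t] = Theta(H[t] - V_th)          Theta(u) = 1 for u >= 0
V[t] = H[t] (1 - S[t]) + V_reset S[t]
```

Defaults: `V_th = 0.5`, `V_reset = 0`, initial membrane potential 0, and a
simulation window of `T = 4` steps. The membrane time constant `tau` is
dimensionless (units of simulation steps); it is not pinned by the reference
setup, so we use the common surrogate-gradient default `tau = 2`
(configurable). Membrane state persists across the T steps of one forward
pass and is re-created on every call, so repeated forward passes are
bit-identical.

Training backpropagates through the Heaviside using the derivative of a
sharpened sigmoid, `d/du sigmoid(alpha u) = alpha s (1 - s)` with
`alpha = 4` (value 1 at the threshold). The forward pass stays exactly
binary; only the backward kernel is relaxed. Two conventions we fix
explicitly:

- *Derivative, not the sigmoid itself*: "sigmoid surrogate" is read as the
  sigmoid's derivative standing in for Theta' — the universal convention.
- *Detached reset*: gradients do not flow through the reset term
  `H (1 - S)`'s spike factor; this avoids a second, ill-behaved surrogate
  path and matches standard practice.

## Wavelet stage

The single-level 2D Haar transform uses the orthonormal normalisation: on
each 2x2 block `[[a, b], [c, d]]`, `LL = (a+b+c+d)/2` and the three details
likewise with gain 1/2. With this gain the analysis operator is an isometry
(`||W x|| = ||x||`, Lipschitz constant 1) and the synthesis operator is both
its inverse and its adjoint; perfect reconstruction holds to machine
precision. The "integer Haar" convention (gains 1 and 1/2) would break the
isometry and is deliberately not used.

The learned branch decomposes each block's token grid (tokens reshaped to
their `sqrt(N) x sqrt(N)` spatial layout), concatenates the LL, LH and HL
sub-bands channel-wise, applies a 3x3 convolution + batch norm + LIF
producing 4C spike-valued sub-bands, and reconstructs by the inverse
transform. Two open points resolved here:

- *The diagonal band*: the filtering stage's input list omits HH (the
  noisiest spatial frequencies). We honour that omission by default and map
  3C -> 4C channels, whose quarters are read as (LL, LH, HL, HH) for the
  inverse transform — this keeps the reconstruction well-defined while
  consuming exactly the listed bands. `include_hh=True` feeds all four
  bands (4C -> 4C) for the alternative reading.
- *Initialisation*: the convolution starts as an identity pass-through of
  the LL quarter and zeros elsewhere, so an untrained branch reconstructs a
  smoothed version of its input instead of injecting noise.

## Attention and fusion

Q, K and V are binary spike tensors (`Linear + BatchNorm + LIF` each, with
stateful LIF across the T steps). The attention current is `(Q K^T) V * s`
with no softmax; since Q, K, V are 0/1-valued the pre-scaling entries are
non-negative integers. We evaluate it as `Q (K^T V)` — associativity avoids
the N x N score matrix, and because all intermediate values are small
integers the two orders are bit-identical in float32. The scale `s = 0.125`
and `heads = 8` follow the spikformer conventions the architecture
otherwise defers to. A LIF re-binarises the attention output, followed by
`Linear + BN + LIF`.

Fusion concatenates the attention output with the wavelet reconstruction
along features (2d), then applies `Linear(2d -> d) + BN + LIF`. Folding the
linear projection *before* the BN+LIF (rather than after) keeps the block
output binary, which the residual stream requires; the projection is needed
at all because the residual add `X' = SWSA(X) + X` must be shape-legal.
Residual adds operate on spike values, so the stream carries small
non-negative integers; no LIF is applied after a residual add.

## Model assembly

`SPS` (spiking patch splitting) is two conv + BN + LIF stages with stride-2
downsampling as needed (32x32 maps -> 8x8 = 64 tokens of dimension d = 32
at desk scale). Because the input is replicated across time steps (direct
encoding), the first pre-spike conv stage computes one step and broadcasts
— detected at runtime by an equality check, bit-identical to the generic
path. Each of the L = 2 encoder blocks is `X' = SWSA(X) + X` then
`X = MLP(X') + X'` with the MLP `Linear(d -> 4d) + BN + LIF` twice.
Classification pools over tokens, then averages over time steps, then a
real-valued linear head (no LIF — cross-entropy needs real logits).
Desk-scale defaults: T=4, L=2, d=32, patch grid 8, heads 8, mlp ratio 4,
~258k parameters.

## Training

Adam at the stated initial learning rate 1e-4, no schedule, cross-entropy
on logits; 200 epochs is the reference setting, 30 the desk-scale default.
Batch size 16. An optional L1 penalty on the Haar analysis coefficients
(`lambda_l1`, default 0) implements the sparsity regularisation that
appears only in the convergence argument, never in the experimental setup —
hence off by default. Reproducibility: parameter init, the stratified
80/20 split, and per-epoch shuffling each use dedicated streams derived
from the configured seed; single-threaded runs are bit-reproducible.

Everything runs on a small in-repo reverse-mode autodiff engine (NumPy
arrays, tape-based), written because no autodiff framework is available in
the target environment. Every hand-written backward (conv im2col, fused
batch norm, fused LIF BPTT, Haar analysis/synthesis) is verified against
central finite differences or an op-by-op composite in the test suite.

## Preprocessing

Fixed order: common-average re-reference -> 1–32 Hz band-pass (6th-order
Chebyshev-II, i.e. prototype order 3 before the band-pass transform) ->
polyphase resample to 128 Hz -> per-channel, per-trial standardisation.
Choices the reference setup leaves open:

- Zero-phase (forward–backward) filtering: offline decoding favours no
  phase distortion; quoted stopband attenuation (default 40 dB) is
  effectively doubled.
- Chebyshev-II critical frequencies are *stopband* edges. For the 1–32 Hz
  chain filter this matches the stated design. For rhythm *extraction*
  (alpha, 8–13 Hz) the requested band must bound the *passband*, so
  `extract_band` uses a Butterworth design instead — a Chebyshev-II with
  8/13 Hz stopband edges would attenuate genuine alpha activity near the
  band edges.
- Sliding-window stride is unstated; default is the window length
  (non-overlapping), overridable.
- Fractional window lengths round to the nearest sample
  (0.1 s x 128 Hz = 12.8 -> 13 samples).
- Resampling rescales trial starts by floor and ends by ceil.

## Topographic encoding

Per decision window, the alpha-band signal is reduced to mean squared
amplitude per channel and interpolated onto a 32x32 head-plane grid
(power of two, required by Haar halving) by inverse-distance weighting
(power 2, 4 nearest electrodes). IDW is linear in the channel values and
yields convex combinations only, so maps never overshoot the electrode
values; pixels outside the unit disc are 0. The map is replicated across
the T simulation steps (direct encoding); the first spiking layer performs
the rate conversion implicitly. Whether to map amplitude or power, the
grid size, and the interpolation scheme are all unstated upstream; power +
32x32 + IDW is our documented choice.

## Energy model

`energy_rate = (E_AC / E_MAC) * spiking_rate * T` compares the SNN against
an equivalent ANN; the efficiency factor is its reciprocal. The
per-operation ratio is fixed at `1/17` (an accumulate is ~17x cheaper than
a multiply-accumulate) — the only reading of the stated 17:1 relation under
which spiking saves energy. At the reference operating point (spiking rate
12.3%, T=4) the formula yields ~34.6x, which clears the quoted "over 7x"
bound; the 7x figure itself cannot be re-derived from those inputs, a
discrepancy we report rather than hide. Spike rates are measured by
instrumentation hooks on every LIF output (fraction of entries equal to 1
over a full evaluation pass).

## Synthetic data: the stated world

The generator emulates the statistical shape of benchmark scalp EEG:
labelled trials of band-limited oscillations (delta 0.5–4, theta 4–8,
alpha 8–13, beta 13–30, gamma 30–45 Hz) over 1/f pink noise, on
10-20-style montages of 8, 32 (DEAP-like) or 64 (BioSemi-like) channels
with left/right mirror symmetry. Class structure is a hemispheric alpha
amplitude ratio (left:right 1.5 for class 0, 0.67 for class 1), applied by
the sign of the montage x-coordinate; midline channels get the mean gain.

Each rhythm is a superposition of 3 independently amplitude-modulated
sinusoids (random frequency in band, random phase, AM depth 0.2 at
0.2–0.8 Hz), normalised so band variance equals `amp^2/2` regardless of
the oscillator count. Default amplitudes: delta 1.0, theta 0.8, alpha 1.2,
beta 0.5; pink noise standard deviation 1.0 (`noise_scale`, a knob the
band-power map needs to be meaningful against). These values were fixed
against an independent linear probe so that the *windowed* dataset is
approximately linearly separable — the property the desk-scale learning
experiment asserts. Two interactions make this non-trivial: per-trial
unit-variance normalisation converts the alpha power ratio into an
alpha-fraction-of-variance contrast (so an alpha-dominated signal would
*lose* contrast), and 1 s windows make per-window power estimates noisy
(so a single deeply-modulated oscillator per band would bury the
contrast in estimator variance).

Bursts and noise draw from independent seed streams keyed by
`(seed, stage, class, trial)`, so changing the noise level never changes
the oscillatory content, and identical specs reproduce bit-identical data.

What the synthetic world does **not** contain: volume conduction /
leadfield mixing, ocular or muscular artifacts, bad channels,
non-stationary drift, or inter-subject variability. A green
synthetic-learning test establishes that the architecture, gradients and
pipeline work end to end on a spatially lateralised alpha signal at desk
scale; it says nothing about accuracy on real DEAP/KUL recordings.

## Known limitations

- CPU-only NumPy training: practical up to desk scale (hundreds of
  windows, minutes per run), not benchmark scale.
- Single-level Haar only; no other wavelet bases (a deliberate scope
  choice, matching the architecture's design rationale).
- EDF I/O is not implemented (no EDF library in the target environment);
  the HDF5 container is the interchange format.
- The energy model is the AC/MAC abstraction only — no FLOP counting of a
  concrete ANN twin and no joule-level hardware estimates.
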