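# Methods

## Synthetic iEMG model

Each recording is a superposition of `n_motor_units` (default 15)
independent motor units. A unit fires as a renewal process with
Gamma-distributed inter-spike intervals (mean rate 10 Hz, CV 0.15 —
the weak, constant voluntary contraction typical of diagnostic needle
examinations), and every discharge contributes the unit's fixed MUAP
kernel. Channel noise is additive white Gaussian with SD 20 µV (5 % of
the healthy amplitude midpoint).

A MUAP kernel is a train of `n_phases` alternating-sign Gaussian lobes
spread uniformly over the drawn duration (lobe width σ = duration /
(3·n_phases)), rebalanced so the kernel integrates to zero, normalized to
unit energy and scaled to the drawn amplitude. Class-conditional
parameter ranges:

| class      | amplitude (µV) | duration (ms) | phases |
|------------|----------------|---------------|--------|
| healthy    | 200–600        | 6–12          | 2–4    |
| myopathy   | 50–200         | 2–6           | 5–8    |
| neuropathy | 600–1500       | 12–25         | 5–8    |

The ranges are deliberately disjoint: they encode the qualitative
clinical contrasts (myopathic MUAPs small/short/polyphasic with a
high-frequency spectral shift; neurogenic MUAPs large/long/polyphasic
with a low-frequency shift) without claiming clinical calibration.
Defaults: fs = 10 kHz, 5 s records, so one recording yields nine
downsampled signals of ≥ 5000 samples.

What the simulator does **not** model: volume conduction and needle
geometry, motor-unit recruitment/rate modulation, inter-subject
variability, non-stationary contraction levels, line interference, or
amplitude/duration overlap between classes. Passing tests on this data
therefore demonstrate that the pipeline recovers class structure whose
separability is guaranteed by construction; they say nothing about
accuracy on clinical recordings, where class distributions overlap.

## Preprocessing and decimation

Default preprocessing is per-signal z-scoring only (an optional
zero-phase Butterworth band-pass is available). The subsequent features
are largely amplitude-invariant anyway — the LBP depends only on sample
comparisons — so normalization is the conservative choice. Decimation by
M is pure polyphase sample selection: child m holds x[m], x[m+M], …, so
the M children partition the parent's samples exactly (lengths
⌈(N−m)/M⌉) and interleaving them reconstructs the parent bit-exactly.
No anti-alias filter is applied; filtering would mix information across
children and destroy the partition. M defaults to 9 and is configurable.

## Lifting wavelet transform

Analysis follows split / predict / update / normalize. The lifting steps
for a wavelet are computed at run time by the Euclidean algorithm on the
analysis polyphase matrix, expressed over Laurent polynomials in the
delay operator: repeated division of the low-pass row's polyphase pair
yields alternating predict/update factors, and one exact division by the
resulting monomial clears the high-pass row. The normalization is a
monomial — a scale *and* an integer delay per lane (k_e = 0.4714,
shift 3 and k_o = −2.1213, shift 4 for rbio3.7 under the PyWavelets
filter alignment). Every constructed scheme is verified on a random
vector against direct polyphase filtering with the original filters
(tolerance 1e−8); construction fails loudly on disagreement, so a wrong
factorization cannot propagate. The test suite additionally compares
against an independently written convolution DWT.

Boundary handling defaults to periodization, under the convention
a[n] = Σ_k h[k] y[(2n+1−k) mod N]: coefficient counts halve exactly per
level, which keeps the bookkeeping and the convolution-oracle comparison
simple. Odd lengths are padded by repeating the last sample and the
pre-padding length recorded, so reconstruction is still exact
(downsampled-signal lengths differ by one across offsets). A symmetric
extension mode is available; lifting steps are invertible under any
extension rule, so perfect reconstruction holds there too, but the
convolution-equivalence statement is specific to periodization. Level 5
requires ≥ 32 samples.

## Features

*Higuchi fractal dimension* (per subband, coefficient vectors in the
fixed order a₅, d₁ … d₅): for stride k = 1 … k_max and phase m = 1 … k,

L_m(k) = [(N−1)/(⌊(N−m)/k⌋·k)] · (1/k) · Σᵢ |X(m+ik) − X(m+(i−1)k)|,

L(k) is the mean over m, and the dimension is the unweighted
least-squares slope of ln L(k) on ln(1/k) — Higuchi's original
prescription. Default k_max = 8: small enough for the shortest subband
of a length-5000 downsample (a₅ ≈ 157 coefficients) and standard in the
EMG/EEG fractal literature. A subband shorter than 2·k_max gets k_max
reduced to ⌊len/2⌋ with a warning (at least 4 coefficients are
required); a constant series is assigned dimension 1 by convention, with
a warning. A smooth curve scores ≈ 1, white noise ≈ 2.

*1-D local binary pattern*: each interior sample is compared with its 4
preceding and 4 following neighbors (neighbor ≥ center sets the bit —
ties count as 1; bit 0 is the farthest-left neighbor, bit 7 the
farthest-right). The 256-bin code histogram is normalized to relative
frequencies by default so that the ±1-sample length differences between
sibling downsamples do not leak into the features; raw counts are
available by flag. The histogram is exactly invariant to constant
offsets and positive rescaling. These conventions (neighborhood, tie
rule, bit order) are fixed, documented constants; any consistent choice
preserves the histogram's discriminative role.

The fused vector is the 6 fractal dimensions followed by the 256 LBP
bins (length 262); the order is pinned and tested. The LBP is computed
on the (preprocessed) downsampled signal itself, the fractal dimensions
on the subband coefficients.

## Classifier

A 262 → N_h → 3 perceptron with tanh hidden units, logistic-sigmoid
outputs, and sum-of-squares loss against one-hot targets ([1 0 0],
[0 1 0], [0 0 1] for healthy, myopathy, neuropathy). Features are
standardized with training-set statistics only (zero-variance features
keep scale 1, with a warning). Weights start uniform in ±1/√fan_in,
seeded. Training is full-batch nonlinear conjugate gradient with the
PR+ (non-negative Polak–Ribière) direction update and an Armijo
backtracking line search; one epoch = one CG iteration, so the loss is
non-increasing across accepted steps and the whole procedure is
deterministic given the seed. Defaults N_h = 25, N_e = 300; a hold-out
grid search (single stratified 70/30 split reused for all cells,
N_h ∈ {5,…,50} step 5 × N_e ∈ {50,…,500} step 50; ties resolve to the
smallest N_h then N_e) is provided for retuning. Prediction is the
argmax of the three outputs, ties broken by the fixed class order.

SSE with sigmoid outputs mirrors the classic least-squares
backpropagation formulation; loss/activation/init details beyond that
are this package's documented choices.

## Vote and evaluation

The M per-downsample labels of a recording are reduced by the
Boyer–Moore majority vote: one candidate-selection pass (O(1) state),
one verification pass, and a decision only if the candidate occurs
strictly more than M/2 times — otherwise the recording is
*indeterminate*. There is no plurality fallback; with three classes even
odd M can be indeterminate (e.g. 4/4/1).

Cross-validation stratifies folds over the downsampled signals, so
siblings of one recording typically span several folds — this reproduces
the within-recording protocol of the original study design. A
`group_by_parent` mode confines all M siblings to one fold for
across-recording generalization; the default remains the protocol mode
so the difference is measurable rather than hidden. Each repetition
draws fresh folds from a derived seed; per-fold classifiers get derived
seeds too. Metrics: Ac counts indeterminate as misclassification;
one-vs-rest Se/Sp treat an indeterminate decision as a negative
prediction for every class; the confusion table is row-normalized (rows
= true classes, sum to 100 %) with an explicit indeterminate column.
Aggregation over R repetitions reports mean ± SD (population SD, so
R = 1 gives SD 0). Hyperparameters are fixed once, not retuned per
repetition.

## Problem sizes and determinism

The shipped study configuration is 250 recordings (150/50/50) of 5 s at
10 kHz, M = 9 (2250 downsampled signals, 10-fold stratified CV with
folds of 225), three repetitions — about a minute end to end on one
CPU core. Unit and property tests use shorter records (0.5–1 s) of the
same generator. A single master seed spawns per-stage seeds via
`SeedSequence([master, stage])`, so the full pipeline is bit-reproducible
and every stage can be re-run independently from the logged provenance
block.

## Known limitations

- Synthetic separability is by construction; measured accuracies do not
  transfer to clinical data (see the simulator section).
- The default CV granularity shares recordings between train and test
  folds (protocol fidelity); use `group_by_parent` for subject-style
  generalization claims.
- The lifting factorization is computed in floating point; filters far
  longer than rbio3.7's 16 taps may need looser verification tolerances.
- The Higuchi estimator's value depends mildly on k_max; comparisons
  across datasets should hold it fixed.
- Class labels are per recording; no mixed-pathology or artifact classes
  are modeled.
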