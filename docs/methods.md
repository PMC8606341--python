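# Methods

This note records the models, numerical choices and design decisions behind
`hnntm`, and what the synthetic testbeds do and do not demonstrate.

## Class HMM and the two phases

A model is a labeled-state HMM: states `k` with begin distribution a_{Bk},
row-stochastic transitions a_{kl}, a hard label map δ_k (one label per
state; soft label probabilities are not supported), and either a per-state
emission table over the residue alphabet or a per-state emission network.
Structural zeros — transitions or begin states absent from the grammar — are
captured as boolean masks at construction and are never re-estimated away
from zero.

The free-running phase sums path scores over all paths (forward/backward);
the clamped phase masks the emission column at position i to the states
whose label equals yᵢ and is otherwise the identical recursion. The CML loss
is ℓ = ℓc − ℓf. In table mode P(x,y) ≤ P(x) guarantees ℓ ≥ 0; in HNN mode
the two quantities are path *scores* (networks are not normalized over
symbols), but their ratio is still a probability P(y|x) ∈ (0,1], so ℓ ≥ 0
there too.

### Numerics

Forward/backward use per-position scaling, with the log-likelihood
accumulated from log scale factors; the enumeration oracle in the test suite
pins this to exact path sums at 1e-9 (and to a direct log-space recursion at
1e-8 on L = 200). Posteriors and expected transition counts are normalized
*per position*, which cancels the (independent) forward and backward
scalings exactly and avoids coupling the two passes. An input admitting no
(label-consistent) path yields log-likelihood −inf with the first blocked
position recorded, never an exception. Unknown residues (index −1) emit the
uninformative constant 1/A in every state — they contribute nothing to state
discrimination and cancel in ℓ — and encode as all-zero blocks in context
windows.

Labeled Baum–Welch floors re-estimated probabilities at 1e-10 on allowed
entries (structural zeros stay exactly 0) and stops when |Δ log P(x,y|θ)| <
1e-6 or after 200 iterations. For gradient training, transitions are
reparameterized as masked row-softmaxes of unconstrained reals; the gradient
of ℓ in those coordinates is the difference of clamped and free expected
counts, centered within each row. Forbidden entries are not parameterized
and report exact-zero gradients.

## Emission networks

One hidden layer; hidden activations sigmoid (default), tanh, or a symmetric
sigmoid 2σ(z)−1; a single sigmoid output. Outputs are clamped to
[1e-6, 1−1e-6] before logs, so every log score is finite; the derivative
through an active clamp is zero, and the analytic gradients respect that.
The error signal at the output pre-activation is
ε_k(xᵢ) = (γ_free(k,i) − γ_clamped(k,i))·(1 − e_k(sᵢ)); its only contract is
agreement with central differences of ℓ, which the suite enforces at
relative 1e-4 over random tiny models (every weight, bias and transition
parameter).

A K=1 "saturated" construction (hidden units with gain-500 weights turning
the one-hot input into an indicator, output weights logit(p)) embeds any
emission table into an HNN; free and clamped log-likelihoods agree with the
table model to ~1e-15, which anchors the HNN recursions to the CHMM ones.

## Training

Per-label initialization trains one network per label (target 1 when the
window center carries the label, else 0) by full-batch RPROP for 100 epochs,
minimizing cross-entropy by default (summed squared error is available);
each state then receives a copy of its label's network, or a shared object
per label when hard tying is requested. Untied-after-initialization is the
default, so states of one label may diverge during joint training.

Joint CML training is full-batch (RPROP's sign logic needs consistent
gradients; mini-batching is deliberately excluded) with iRPROP−:
e_a = 1.2, e_d = 0.5, Δ₀ = 0.01, Δ ∈ [1e-8, 1.0], stored derivative zeroed
on a sign flip. The printed update rule in the literature this follows is
dimensionally ambiguous (it can be read as scaling the weight rather than
the step); the standard step-size reading is implemented. Weight decay
(default 0) adds λw to network gradients; momentum exists only in the
optional plain-gradient optimizer. Training runs at most 50 epochs with a
seeded by-sequence holdout (fraction 0.1) and patience 10; the returned
model is the parameter snapshot at the held-out minimum. Per-epoch train
loss is recorded at the pre-update parameters (it is the gradient pass) and
holdout loss at the post-update parameters. Everything is deterministic
given seed and config, down to the archived bytes.

## Decoding

The Optimal Accuracy Posterior Decoder maximizes the *sum* (equivalently
mean) of per-position label posteriors — free-phase state posteriors
aggregated by label — over grammar-valid label sequences. Validity,
including minimum segment lengths imposed by chained states, is enforced by
running the dynamic program on the state graph itself; ties break toward the
lowest state index, as in Viterbi. Three prediction summaries are this
package's explicit definitions (the literature names but does not define
them): *decoder score* = the maximized mean posterior, *reliability* = mean
chosen-label posterior (identical to the decoder score under posterior
decoding, distinct under Viterbi), *max probability* = maximum chosen-label
posterior.

## Metrics

Q2 is residue accuracy on a two-state projection (a configurable set of
labels counts as TM). SOV follows the 1999 revision — length-weighted, with
the δ allowance term, reference segments without overlap counted in the
normalizer — computed on both projected classes and pooled into a single
normalization. Topology correctness requires equal TM-segment counts,
in-order pairwise overlap of at least 1 residue (configurable), and in alpha
mode matching sidedness of every loop, termini included; loop sidedness is
the majority label of the loop segment. Beta mode skips the sidedness check.
MCC is 0 by convention when a denominator factor vanishes.

## Discrimination

The log-odds null is a single state with self-transition 1 and emissions
estimated (+1 smoothing) from training residues; log-probability is
per-residue (raw log P would be collinear with the separate length feature).
Features are standardized to zero mean/unit variance and fit with logistic
regression under an L2 ridge of 1e-6 — enough to stabilize small-n fits
without noticeably biasing coefficients. Decision threshold 0.5,
configurable.

## Synthetic testbeds and their limits

The **toy topology grammar** (labels i/M/o; one state per loop label, a
5-state chain with tied emissions for M; begin 0.5/0.5, loop
self-transitions 0.92, M5 self-transition 0.75) has hydrophobicity-flavored
emissions with a positive-inside skew, chosen so that labeled training and
decoding face a realistic-shaped but fully known target. With n = 300
sequences of length 60–120, labeled Baum–Welch recovers transitions and
emissions to well under 0.02 absolute error; the begin distribution is
estimated from only n draws (standard error ≈ 0.03 at n = 300) and is
therefore not held to that bound.

The **context generator** produces labels from a two-state chain (stay
probability 0.88) and residues from a 4-letter alphabet split into two
parity classes: state M emits in the previous residue's class with
probability 0.8, state i in the opposite class with probability 0.8, and
within the chosen class each label weakly prefers a different letter
(0.7/0.3). The parity rule is invisible to any first-order CHMM (its
per-state marginals are nearly flat over classes), while the within-class
tilt gives the CHMM a genuine signal above the majority baseline — so the
benchmark separates three performance tiers by construction: majority ≈
0.50, CHMM ≈ 0.77, HNN (window 5, 5 hidden units) ≈ 0.88 held-out Q2,
with correspondingly lower held-out conditional NLL for the HNN. The
4-letter alphabet keeps the Bayes structure of the testbed transparent and
the experiment fast; it exercises exactly the same code paths as the
20-letter protein alphabet.

What passing these tests shows: the likelihoods, gradients, optimizer,
decoder and metrics are correct, and joint CML training does extract context
information a CHMM cannot. What they do not show: performance on real
membrane proteins, whose hydrophobicity profiles, length distributions and
evolutionary signal (profiles/MSAs) the generators do not emulate. Profile
fixtures written by `make_fixture_suite` are synthetic stand-ins
(state-emission rows mixed with 30% uniform noise), not alignment-derived
PSSMs.

## Problem sizes

The shipped experiments run at desk scale by choice: 30 training / 15 test
sequences per seed (5 seeds) for the HNN-vs-CHMM comparison, 300 sequences
for parameter recovery, 25+25 for discrimination, and exhaustive-enumeration
checks restricted to ≤ 3 states, alphabet ≤ 4, length ≤ 6 where brute force
is exact and instant.

## Known limitations

No higher-order or partial HMMs; no unsupervised Baum–Welch beyond what
labeled training degenerates to; no transition networks (only emission
networks); no recurrent/convolutional architectures; nucleotide alphabets
work through `Alphabet` but carry no tested presets beyond the 4-letter
testbed; the PSI-BLAST PSSM converter is documented as an optional reader
but profiles are consumed as TSV only.
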