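# hnntm — hidden neural networks for transmembrane topology prediction

`hnntm` implements **Class Hidden Markov Models (CHMMs)** and their hybrid
extension, **Hidden Neural Networks (HNNs)**, for labeled biological sequence
analysis, with a working application to transmembrane-protein topology
prediction (alpha-helical membrane proteins and beta-barrel outer-membrane
proteins). It is aimed at researchers who want a transparent, fully tested
reference implementation of discriminative HMM training — not a pre-trained
production predictor.

## The model

A CHMM pairs each observation sequence **x** = x₁…x_L with a label sequence
**y** = y₁…y_L; every state *k* carries exactly one label through a
delta-function map δ_k. Two likelihoods drive everything:

* **free-running phase**: P(**x**|θ) = Σ_π a_{Bπ₁} ∏ᵢ e_{πᵢ}(xᵢ) a_{πᵢπᵢ₊₁},
  the forward/backward sum over *all* state paths;
* **clamped phase**: P(**x**,**y**|θ), the same sum restricted to paths whose
  state labels agree with **y**.

Supervised maximum-likelihood training (labeled Baum–Welch) maximizes the
clamped likelihood. **Conditional Maximum Likelihood (CML)** training instead
maximizes P(**y**|**x**,θ) by minimizing

    ℓ = ℓc − ℓf,   ℓc = −log P(x,y|θ),   ℓf = −log P(x|θ),

which requires gradients: each sequence costs two forward–backward passes,
one per phase.

The **HNN** replaces each state's emission probability e_k(xᵢ) with the
output of a one-hidden-layer perceptron e_k(sᵢ; w_k) applied to the encoded
context window sᵢ around position i (one-hot blocks of 20·K inputs for a
window of K residues, or stacked profile/PSSM rows; zero-padded at the
boundaries). Because the networks see neighboring residues, the HNN captures
context dependence that no first-order CHMM can represent. All parameters —
network weights and (reparameterized) transitions — are trained jointly on ℓ
by backpropagation through the per-position error signal
ε_k(xᵢ) = (γ_free − γ_clamped)·∂e/∂h, using the RPROP optimizer (iRPROP−;
sign-based per-weight step sizes). Networks are first initialized per label
as window classifiers (cross-entropy by default), then trained jointly for
up to 50 epochs with early stopping at the minimum of the held-back loss.

Decoding uses the **Optimal Accuracy Posterior Decoder**: the grammar-valid
label sequence maximizing the mean per-position label posterior (Viterbi is
also provided). Evaluation covers **Q2** (two-state residue accuracy),
**SOV** (segment overlap, 1999 definition), whole-protein topology
correctness and TM-segment counts; a logistic-regression stage discriminates
membrane from non-membrane proteins using model-derived features (sequence
length, log-odds against a background model, per-residue log-probability,
decoder/reliability scores, TM segment count and TM fraction).

## Worked example

Everything below runs in seconds from the shipped synthetic generators (a
documented toy topology grammar with labels `i` = inside loop, `M` =
membrane, `o` = outside loop, and a minimum TM segment length of 5 enforced
by chained states):

    $ hnntm simulate --kind fixtures --n 20 --seed 11 --out sim
    fixture suite written: ['profiles', 'toy_sequences.fasta', 'toy_sequences.labels'] + toy_grammar.txt

    $ hnntm train --labels sim/toy_sequences.labels --grammar sim/toy_grammar.txt --mode chmm --out chmm_run
    loaded 20 labeled sequences; grammar with 7 states / 3 labels
    labeled Baum-Welch: 3 iterations, final log P(x,y) = -5140.7868
    model archived to chmm_run/model.txt

    $ hnntm predict --model chmm_run/model.txt --fasta sim/toy_sequences.fasta --out pred
    decoded 20/20 sequences with the posterior decoder

    $ hnntm evaluate --ref sim/toy_sequences.labels --pred pred/predictions.labels --tm-labels M --out eval
    evaluated 20 proteins: mean Q2 0.9582, mean SOV 0.9731, 10 correct topologies

Mean Q2 0.958 says 95.8% of residues land on the correct side of the
TM/non-TM projection; SOV 0.973 says the predicted segments overlap the true
ones almost perfectly; 10/20 proteins have every TM segment and every loop
side exactly right. An HNN trained on the same data fits the training set
perfectly (expected for a discriminative model at this scale — evaluate on
held-out data for honest numbers):

    $ hnntm train --labels sim/toy_sequences.labels --grammar sim/toy_grammar.txt \
          --mode hnn --window 7 --hidden 5 --epochs 50 --seed 2 --out hnn_run
    HNN CML training: 21 epochs run, held-out minimum 0.0124 at epoch 11

Predictions are written in the 3-line label format (header, sequence,
per-residue labels; wrapped lines are concatenated and split in half):

    >chmm11_000
    PEAYIPCQWYNHGTMDKQTCHTHELAWFACMQDTSDGNFGYKVAFVPVCCVVKYHDQNPD
    ooMMMMMMMMooooooooooooooMMMMMMMoooooooooMMMMMMMMMMMMiiiiiiii

`hnntm crossval` runs strict sequence-level k-fold cross-validation, and
`hnntm discriminate` trains and cross-validates the logistic discrimination
stage. All file formats (FASTA, 3-line labels, profile TSV with the alphabet
`ACDEFGHIKLMNPQRSTVWY` as header, flat `key = value` model archives) are
plain text; reported intervals are 1-based and closed.

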