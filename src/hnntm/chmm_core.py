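"""Class HMM core: model structure, likelihoods, labeled training, CML.

A Class HMM (CHMM) is an HMM trained with per-residue labels: every state
``k`` carries exactly one label through a delta-function map δ_k.  Two
quantities drive everything here:

* the *free-running* likelihood  P(x|θ)  — forward/backward over all paths;
* the *clamped* likelihood  P(x,y|θ)  — the same recursion restricted to
  paths whose state labels agree with the observed labels y.

Conditional Maximum Likelihood (CML) training minimizes
``ℓ = ℓc − ℓf = −log P(x,y|θ) + log P(x|θ) = −log P(y|x,θ)``.

Numerics: forward/backward use per-position scaling; log-likelihoods are
accumulated from the log scale factors.  An input that admits no (label-
consistent) path yields ``log_likelihood = −inf`` with the first blocked
position recorded — never an exception.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .seqdata import Alphabet, LabeledSequence, Profile, WindowSpec, encode_windows

_TINY = 1e-300


# ---------------------------------------------------------------------------
# model structure
# ---------------------------------------------------------------------------

@dataclass
class EmissionTable:
    """Per-state emission probability vectors over the alphabet.

    ``tie_ids[k]`` assigns state ``k`` to a tying group; states in one group
    share a single emission vector (rows are kept identical).
    """

    probs: np.ndarray                      # (S, A), rows sum to 1
    tie_ids: Optional[np.ndarray] = None   # (S,) ints; default: each state its own

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.tie_ids is None:
            self.tie_ids = np.arange(self.probs.shape[0])
        self.tie_ids = np.asarray(self.tie_ids, dtype=int)

    def validate(self) -> None:
        if (self.probs < 0).any():
            raise ValueError("negative emission probability")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-10):
            raise ValueError(f"emission rows must sum to 1 (got {sums})")
        for g in np.unique(self.tie_ids):
            rows = self.probs[self.tie_ids == g]
            if not np.allclose(rows, rows[0], atol=1e-12):
                raise ValueError(f"tied states in group {g} have differing emissions")


@dataclass
class TopologyModel:
    """CHMM / HNN topology grammar with parameters.

    ``emissions`` is either an :class:`EmissionTable` (CHMM mode) or a dict
    mapping state id to an emission network object exposing
    ``batch_output(X) -> scores`` (HNN mode; see :mod:`hnntm.hnn`).
    Structural zeros (forbidden transitions / begin states) are fixed by the
    masks captured at construction and never re-estimated away from zero.
    """

    states: list[str]
    label_set: list[str]
    state_labels: list[str]                 # δ_k, one label per state
    begin: np.ndarray                       # (S,)
    trans: np.ndarray                       # (S, S), row-stochastic on mask
    emissions: Union[EmissionTable, dict]
    alphabet: Alphabet = field(default_factory=Alphabet)
    end_states: Optional[list[str]] = None  # None => free end
    window: Optional[WindowSpec] = None     # HNN mode
    encoding: str = "onehot"                # "onehot" | "profile"
    trans_mask: Optional[np.ndarray] = None
    begin_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.begin = np.asarray(self.begin, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        if self.trans_mask is None:
            self.trans_mask = self.trans > 0
        if self.begin_mask is None:
            self.begin_mask = self.begin > 0
        self.trans_mask = np.asarray(self.trans_mask, dtype=bool)
        self.begin_mask = np.asarray(self.begin_mask, dtype=bool)

    # -- structure helpers ---------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def is_hnn(self) -> bool:
        return not isinstance(self.emissions, EmissionTable)

    def state_index(self, name: str) -> int:
        return self.states.index(name)

    def states_for_label(self, label: str) -> list[int]:
        return [k for k, lab in enumerate(self.state_labels) if lab == label]

    @property
    def end_vec(self) -> Optional[np.ndarray]:
        if self.end_states is None:
            return None
        v = np.zeros(self.n_states)
        for s in self.end_states:
            v[self.state_index(s)] = 1.0
        return v

    def validate(self) -> None:
        S = self.n_states
        if len(self.state_labels) != S or len(self.begin) != S:
            raise ValueError("state/label/begin dimensions disagree")
        if set(self.state_labels) - set(self.label_set):
            raise ValueError("state label outside declared label set")
        if abs(self.begin.sum() - 1.0) > 1e-10:
            raise ValueError("begin distribution must sum to 1")
        if (self.begin[~self.begin_mask] != 0).any():
            raise ValueError("begin mass on a forbidden begin state")
        if (self.trans[~self.trans_mask] != 0).any():
            raise ValueError("transition mass on a structural zero")
        rows = self.trans.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-10):
            raise ValueError(f"transition rows must sum to 1 (got {rows})")
        if not self.is_hnn:
            self.emissions.validate()

    def copy(self) -> "TopologyModel":
        return copy.deepcopy(self)

    # -- emission scores -----------------------------------------------------

    def emission_matrix(
        self, seq: LabeledSequence, profile: Optional[Profile] = None
    ) -> np.ndarray:
        """Per-state, per-position emission scores, shape ``(S, L)``.

        CHMM mode returns probabilities e_k(x_i); unknown residues emit the
        uninformative constant 1/A in every state.  HNN mode returns the
        per-state network outputs e_k(s_i; w_k) — path *scores*, not a
        normalized sequence probability.
        """
        L = len(seq)
        if not self.is_hnn:
            x = seq.residues
            E = np.empty((self.n_states, L))
            known = x >= 0
            E[:, known] = self.emissions.probs[:, x[known]]
            E[:, ~known] = 1.0 / self.alphabet.size
            return E
        if self.window is None:
            raise ValueError("HNN model has no window specification")
        prof = profile if self.encoding == "profile" else None
        if self.encoding == "profile" and profile is None:
            raise ValueError(f"profile encoding requires a profile for {seq.id!r}")
        X = encode_windows(seq, self.window, prof)
        E = np.empty((self.n_states, L))
        for k, name in enumerate(self.states):
            E[k] = self.emissions[name].batch_output(X)
        return E

    def label_mask(self, labels: str) -> np.ndarray:
        """Boolean ``(S, L)`` mask: state k allowed at i iff δ_k == y_i."""
        lab = np.array(list(labels))
        delta = np.array(self.state_labels)
        return delta[:, None] == lab[None, :]


# ---------------------------------------------------------------------------
# trellises
# ---------------------------------------------------------------------------

@dataclass
class Trellis:
    """Scaled forward or backward matrix with its log-likelihood.

    ``matrix`` rows are positions; forward rows are normalized to sum 1,
    backward rows carry their own per-position scaling.  ``ok`` is False when
    no (label-consistent) path exists; ``blocked_pos`` then records the first
    0-based position at which all mass vanished.
    """

    phase: str            # "free" | "clamped"
    direction: str        # "forward" | "backward"
    matrix: np.ndarray    # (L, S)
    scales: np.ndarray    # (L,)
    log_likelihood: float
    ok: bool = True
    blocked_pos: Optional[int] = None


def _masked_E(E: np.ndarray, mask: Optional[np.ndarray]) -> np.ndarray:
    return E if mask is None else E * mask


def _forward_pass(E, begin, trans, end_vec):
    S, L = E.shape
    f = np.zeros((L, S))
    scales = np.zeros(L)
    v = begin * E[:, 0]
    for i in range(L):
        if i > 0:
            v = (f[i - 1] @ trans) * E[:, i]
        s = v.sum()
        if not np.isfinite(s) or s <= 0.0:
            return f, scales, -np.inf, i
        f[i] = v / s
        scales[i] = s
    ll = float(np.log(scales).sum())
    if end_vec is not None:
        w = float(f[L - 1] @ end_vec)
        if w <= 0.0:
            return f, scales, -np.inf, L - 1
        ll += np.log(w)
    return f, scales, ll, None


def _backward_pass(E, begin, trans, end_vec):
    S, L = E.shape
    b = np.zeros((L, S))
    scales = np.ones(L)
    v = np.ones(S) if end_vec is None else end_vec.astype(float)
    s = v.sum()
    if s <= 0.0:
        return b, scales, -np.inf, L - 1
    b[L - 1] = v / s
    scales[L - 1] = s
    for i in range(L - 2, -1, -1):
        v = trans @ (E[:, i + 1] * b[i + 1])
        s = v.sum()
        if not np.isfinite(s) or s <= 0.0:
            return b, scales, -np.inf, i
        b[i] = v / s
        scales[i] = s
    w = float(begin @ (E[:, 0] * b[0]))
    if w <= 0.0:
        return b, scales, -np.inf, 0
    ll = float(np.log(scales).sum() + np.log(w))
    return b, scales, ll, None


def forward(
    model: TopologyModel,
    seq: LabeledSequence,
    labels: Optional[str] = None,
    profile: Optional[Profile] = None,
) -> Trellis:
    """Free (or, with ``labels``, clamped) scaled forward pass."""
    E = model.emission_matrix(seq, profile)
    mask = model.label_mask(labels) if labels is not None else None
    f, scales, ll, blocked = _forward_pass(
        _masked_E(E, mask), model.begin, model.trans, model.end_vec
    )
    phase = "clamped" if labels is not None else "free"
    return Trellis(phase, "forward", f, scales, ll, blocked is None, blocked)


def backward(
    model: TopologyModel,
    seq: LabeledSequence,
    labels: Optional[str] = None,
    profile: Optional[Profile] = None,
) -> Trellis:
    """Free (or clamped) scaled backward pass; same log-likelihood as forward."""
    E = model.emission_matrix(seq, profile)
    mask = model.label_mask(labels) if labels is not None else None
    b, scales, ll, blocked = _backward_pass(
        _masked_E(E, mask), model.begin, model.trans, model.end_vec
    )
    phase = "clamped" if labels is not None else "free"
    return Trellis(phase, "backward", b, scales, ll, blocked is None, blocked)


def clamped_forward(model, seq, labels, profile=None) -> Trellis:
    """Forward pass restricted to paths agreeing with the label sequence."""
    return forward(model, seq, labels=labels, profile=profile)


def posteriors(fwd: Trellis, bwd: Trellis) -> np.ndarray:
    """Per-position state posteriors γ, shape ``(S, L)``, columns summing to 1.

    Per-position normalization cancels the (independent) scalings of the two
    trellises exactly, so mixing forward- and backward-scaled matrices is safe.
    """
    if fwd.phase != bwd.phase:
        raise ValueError(f"phase mismatch: {fwd.phase} vs {bwd.phase}")
    if not (fwd.ok and bwd.ok):
        raise ValueError("cannot form posteriors from a blocked trellis")
    raw = fwd.matrix * bwd.matrix          # (L, S)
    tot = raw.sum(axis=1, keepdims=True)
    return (raw / tot).T


# ---------------------------------------------------------------------------
# expected counts (shared by Baum-Welch and CML gradients)
# ---------------------------------------------------------------------------

def _counts_one_phase(E, begin, trans, end_vec):
    """gamma (S,L), begin counts (S,), transition counts (S,S), ll."""
    f, _, llf, blocked = _forward_pass(E, begin, trans, end_vec)
    if blocked is not None:
        return None, None, None, -np.inf
    b, _, _, blocked_b = _backward_pass(E, begin, trans, end_vec)
    if blocked_b is not None:
        return None, None, None, -np.inf
    raw = f * b
    gamma = (raw / raw.sum(axis=1, keepdims=True)).T
    S, L = E.shape
    xi = np.zeros((S, S))
    for i in range(L - 1):
        M = (f[i][:, None] * trans) * (E[:, i + 1] * b[i + 1])[None, :]
        xi += M / M.sum()
    return gamma, gamma[:, 0].copy(), xi, llf


def expected_counts(
    model: TopologyModel,
    seq: LabeledSequence,
    labels: Optional[str] = None,
    profile: Optional[Profile] = None,
):
    """Posterior expectations for one sequence in one phase.

    Returns ``(gamma, begin_counts, transition_counts, log_likelihood)``;
    the phase is clamped when ``labels`` is given, free otherwise.
    """
    E = model.emission_matrix(seq, profile)
    mask = model.label_mask(labels) if labels is not None else None
    return _counts_one_phase(_masked_E(E, mask), model.begin, model.trans, model.end_vec)


# ---------------------------------------------------------------------------
# labeled Baum-Welch (supervised ML)
# ---------------------------------------------------------------------------

def baum_welch_labeled(
    model: TopologyModel,
    data: Sequence[LabeledSequence],
    tol: float = 1e-6,
    max_iter: int = 200,
    pseudocount: float = 1e-10,
    update_transitions: bool = True,
    update_emissions: bool = True,
):
    """Supervised ML re-estimation from labeled data (CHMM mode).

    Iterates the clamped expected-count E-step and the row-normalizing M-step
    until ``|Δ log P(x,y|θ)| < tol`` or ``max_iter``.  Re-estimated
    probabilities are floored at ``pseudocount`` on structurally allowed
    entries; structural zeros stay exactly 0.

    Returns ``(trained_model, history)`` where ``history`` is the list of
    total clamped log-likelihoods, one per iteration (non-decreasing).
    """
    if model.is_hnn:
        raise ValueError("baum_welch_labeled requires an EmissionTable model")
    model = model.copy()
    A = model.alphabet.size
    S = model.n_states
    history: list[float] = []
    prev_ll = None
    for _ in range(max_iter):
        trans_c = np.zeros((S, S))
        begin_c = np.zeros(S)
        emis_c = np.zeros((S, A))
        total_ll = 0.0
        for seq in data:
            if seq.labels is None:
                raise ValueError(f"sequence {seq.id!r} has no labels")
            gamma, bc, xi, ll = expected_counts(model, seq, labels=seq.labels)
            if not np.isfinite(ll):
                raise ValueError(
                    f"sequence {seq.id!r} admits no label-consistent path"
                )
            total_ll += ll
            begin_c += bc
            trans_c += xi
            known = seq.residues >= 0
            np.add.at(emis_c.T, seq.residues[known], gamma[:, known].T)
        history.append(total_ll)
        if update_transitions:
            t = np.where(model.trans_mask, trans_c + pseudocount, 0.0)
            rows = t.sum(axis=1)
            rows[rows == 0] = 1.0
            model.trans = t / rows[:, None]
            bg = np.where(model.begin_mask, begin_c + pseudocount, 0.0)
            model.begin = bg / bg.sum()
        if update_emissions:
            tie = model.emissions.tie_ids
            probs = model.emissions.probs
            for g in np.unique(tie):
                members = tie == g
                row = emis_c[members].sum(axis=0) + pseudocount
                probs[members] = row / row.sum()
        if prev_ll is not None and abs(total_ll - prev_ll) < tol:
            break
        prev_ll = total_ll
    return model, history


# ---------------------------------------------------------------------------
# CML loss and transition gradients
# ---------------------------------------------------------------------------

@dataclass
class CMLLoss:
    """Negative conditional log-likelihood ℓ = ℓc − ℓf = −log P(y|x,θ)."""

    lc: float            # −log P(x,y|θ)
    lf: float            # −log P(x|θ)
    ok: bool = True
    blocked_pos: Optional[int] = None

    @property
    def loss(self) -> float:
        return self.lc - self.lf


def cml_loss(
    model: TopologyModel,
    seq: LabeledSequence,
    labels: Optional[str] = None,
    profile: Optional[Profile] = None,
) -> CMLLoss:
    """CML loss for one labeled sequence; ``ℓ = +inf`` (flagged) when the
    labeling is impossible under the grammar."""
    labels = labels if labels is not None else seq.labels
    if labels is None:
        raise ValueError(f"sequence {seq.id!r} has no labels")
    ft = forward(model, seq, profile=profile)
    ct = forward(model, seq, labels=labels, profile=profile)
    if not ct.ok:
        return CMLLoss(np.inf, -ft.log_likelihood, ok=False, blocked_pos=ct.blocked_pos)
    return CMLLoss(-ct.log_likelihood, -ft.log_likelihood)


def _logit_gradient_from_counts(counts_c, counts_f, probs, mask):
    """∂ℓ/∂z for row-softmax reparameterized probabilities.

    ∂log P/∂z_kl = E[n_kl] − a_kl Σ_l' E[n_kl'];  ℓ = −log Pc + log Pf.
    Forbidden entries are not parameterized: gradient exactly 0 there.
    """
    diff = counts_f - counts_c                     # (…,)
    if diff.ndim == 1:
        g = diff - probs * diff.sum()
        g[~mask] = 0.0
        return g
    g = diff - probs * diff.sum(axis=1, keepdims=True)
    g[~mask] = 0.0
    return g


def cml_transition_gradients(
    model: TopologyModel,
    data: Sequence[LabeledSequence],
    profiles: Optional[Sequence[Optional[Profile]]] = None,
):
    """Analytic gradient of Σ ℓ over unconstrained transition parameters.

    Transitions are reparameterized per row as normalized exponentials of
    unconstrained reals (softmax over the structurally allowed successors);
    the begin distribution is treated as one more softmax row.  Returns
    ``(grad_trans, grad_begin)`` shaped like ``model.trans`` / ``model.begin``
    with exact zeros at structural zeros.
    """
    profiles = profiles or [None] * len(data)
    S = model.n_states
    trans_f = np.zeros((S, S))
    trans_c = np.zeros((S, S))
    begin_f = np.zeros(S)
    begin_c = np.zeros(S)
    for seq, prof in zip(data, profiles):
        if seq.labels is None:
            raise ValueError(f"sequence {seq.id!r} has no labels")
        _, bc, xc, llc = expected_counts(model, seq, labels=seq.labels, profile=prof)
        _, bf, xf, llf = expected_counts(model, seq, profile=prof)
        if not (np.isfinite(llc) and np.isfinite(llf)):
            raise ValueError(f"sequence {seq.id!r}: infinite CML loss")
        trans_c += xc
        trans_f += xf
        begin_c += bc
        begin_f += bf
    g_trans = _logit_gradient_from_counts(trans_c, trans_f, model.trans, model.trans_mask)
    g_begin = _logit_gradient_from_counts(begin_c, begin_f, model.begin, model.begin_mask)
    return g_trans, g_begin


def transition_logits(model: TopologyModel):
    """Current unconstrained transition/begin parameters (log probabilities on
    allowed entries, 0 elsewhere)."""
    zt = np.where(model.trans_mask, np.log(np.maximum(model.trans, _TINY)), 0.0)
    zb = np.where(model.begin_mask, np.log(np.maximum(model.begin, _TINY)), 0.0)
    return zt, zb


def set_transition_logits(model: TopologyModel, z_trans, z_begin) -> None:
    """Set transitions/begin from unconstrained reals via masked row-softmax."""
    t = np.where(model.trans_mask, np.exp(z_trans - z_trans.max(axis=1, keepdims=True)), 0.0)
    rows = t.sum(axis=1)
    rows[rows == 0] = 1.0
    model.trans = t / rows[:, None]
    b = np.where(model.begin_mask, np.exp(z_begin - z_begin.max()), 0.0)
    model.begin = b / b.sum()
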