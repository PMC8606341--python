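"""Hidden Neural Network layer: MLP emissions, RPROP, CML training.

An HNN is a CHMM whose per-state emission probabilities e_k(x_i) are replaced
by the output of a small one-hidden-layer perceptron e_k(s_i; w_k) applied to
the encoded context window s_i around position i.  The forward/backward
recursions are unchanged; the result is a path *score* rather than a
normalized sequence probability, but the conditional probability
P(y|x) = P(x,y)/P(x) remains well defined and is what CML training optimizes.

Training: the loss ℓ = ℓc − ℓf is differentiated by two forward–backward
passes per sequence (free and clamped).  The per-position error signal at the
output pre-activation h of state k's network is

    ε_k(x_i) = ∂ℓ/∂h_{k,i} = (γ_free(k,i) − γ_clamped(k,i)) · (1 − e_k(s_i))

(for the sigmoid output; zero where the output sits on its clamp).  Standard
backpropagation pushes ε through each network; transition parameters are
updated jointly through their softmax reparameterization.  The optimizer is
iRPROP−: per-weight step sizes grow by e_a on consistent gradient signs and
shrink by e_d on sign flips, with the stored derivative zeroed on a flip.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from . import chmm_core
from .chmm_core import (
    EmissionTable,
    TopologyModel,
    Trellis,
    _counts_one_phase,
    _logit_gradient_from_counts,
    set_transition_logits,
    transition_logits,
)
from .seqdata import LabeledSequence, Profile, WindowSpec, encode_windows


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "sigmoid":
        return expit(z)
    if name == "tanh":
        return np.tanh(z)
    if name == "msigmoid":           # symmetric sigmoid 2σ(z) − 1
        return 2.0 * expit(z) - 1.0
    raise ValueError(f"unknown activation {name!r}")


def _act_deriv(name: str, h: np.ndarray) -> np.ndarray:
    """Derivative expressed through the activation value h."""
    if name == "sigmoid":
        return h * (1.0 - h)
    if name == "tanh":
        return 1.0 - h * h
    if name == "msigmoid":
        return 0.5 * (1.0 + h) * (1.0 - h)
    raise ValueError(f"unknown activation {name!r}")


# ---------------------------------------------------------------------------
# emission network
# ---------------------------------------------------------------------------

@dataclass
class EmissionNetwork:
    """One-hidden-layer MLP with a single sigmoid output in (0, 1).

    The output is clamped to ``[clamp, 1 − clamp]`` before use so that log
    scores stay finite; the gradient through a clamped output is zero.
    """

    W1: np.ndarray                    # (H, D)
    b1: np.ndarray                    # (H,)
    w2: np.ndarray                    # (H,)
    b2: float
    hidden_activation: str = "sigmoid"
    clamp: float = 1e-6

    @property
    def input_dim(self) -> int:
        return self.W1.shape[1]

    @property
    def hidden_units(self) -> int:
        return self.W1.shape[0]

    @property
    def n_parameters(self) -> int:
        return self.W1.size + self.b1.size + self.w2.size + 1

    @classmethod
    def random(
        cls,
        input_dim: int,
        hidden_units: int,
        rng: np.random.Generator,
        hidden_activation: str = "sigmoid",
        clamp: float = 1e-6,
        scale: float = 0.1,
    ) -> "EmissionNetwork":
        """Weights drawn uniform in [−scale, scale]."""
        return cls(
            W1=rng.uniform(-scale, scale, size=(hidden_units, input_dim)),
            b1=rng.uniform(-scale, scale, size=hidden_units),
            w2=rng.uniform(-scale, scale, size=hidden_units),
            b2=float(rng.uniform(-scale, scale)),
            hidden_activation=hidden_activation,
            clamp=clamp,
        )

    @classmethod
    def from_emission_row(
        cls, probs: np.ndarray, gain: float = 500.0, clamp: float = 1e-6
    ) -> "EmissionNetwork":
        """K=1 saturated network reproducing an emission probability row.

        One hidden unit per alphabet symbol with huge input weights turns the
        one-hot input into a (numerically exact) hidden indicator; the output
        weight of unit a is logit(p_a), so the output equals p_a.
        """
        probs = np.asarray(probs, dtype=float)
        A = probs.size
        p = np.clip(probs, clamp, 1.0 - clamp)
        return cls(
            W1=np.eye(A) * gain,
            b1=np.full(A, -gain / 2.0),
            w2=logit(p),
            b2=0.0,
            hidden_activation="sigmoid",
            clamp=clamp,
        )

    # -- forward / backward --------------------------------------------------

    def batch_output(self, X: np.ndarray) -> np.ndarray:
        """Clamped outputs for a batch of context vectors, shape ``(N,)``."""
        return self._forward_cache(X)[0]

    def _forward_cache(self, X: np.ndarray):
        if X.shape[-1] != self.input_dim:
            raise ValueError(
                f"input dimension {X.shape[-1]} != network input_dim {self.input_dim}"
            )
        hidden = _act(self.hidden_activation, X @ self.W1.T + self.b1)  # (N, H)
        h = hidden @ self.w2 + self.b2                                   # (N,)
        raw = expit(h)
        out = np.clip(raw, self.clamp, 1.0 - self.clamp)
        cache = {"X": X, "hidden": hidden, "raw": raw, "out": out}
        return out, cache

    def backprop(self, cache: dict, g_h: np.ndarray) -> dict:
        """Parameter gradients given ∂E/∂h per example (h = output pre-activation)."""
        hidden, X = cache["hidden"], cache["X"]
        g_w2 = hidden.T @ g_h
        g_b2 = float(g_h.sum())
        g_hidden = np.outer(g_h, self.w2) * _act_deriv(self.hidden_activation, hidden)
        g_W1 = g_hidden.T @ X
        g_b1 = g_hidden.sum(axis=0)
        return {"W1": g_W1, "b1": g_b1, "w2": g_w2, "b2": g_b2}


def network_emit(net: EmissionNetwork, s: np.ndarray) -> float:
    """Score of a single context vector (clamped to the open unit interval)."""
    return float(net.batch_output(np.asarray(s, dtype=float)[None, :])[0])


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def attach_networks(
    model: TopologyModel,
    window: WindowSpec,
    hidden_units: int,
    seed: int = 0,
    hidden_activation: str = "sigmoid",
    clamp: float = 1e-6,
    encoding: str = "onehot",
) -> TopologyModel:
    """Return an HNN copy of ``model`` with fresh random emission networks."""
    hnn = model.copy()
    rng = np.random.default_rng(seed)
    D = model.alphabet.size * window.K
    hnn.emissions = {
        name: EmissionNetwork.random(D, hidden_units, rng, hidden_activation, clamp)
        for name in model.states
    }
    hnn.window = window
    hnn.encoding = encoding
    return hnn


def embed_emission_table(model: TopologyModel, gain: float = 500.0) -> TopologyModel:
    """HNN with K=1 saturated networks replicating a CHMM's emission table.

    The resulting free and clamped log scores agree with the CHMM
    log-likelihoods to the saturation error (≈ e^{−gain/2}).
    """
    if model.is_hnn:
        raise ValueError("expected an EmissionTable model")
    hnn = model.copy()
    hnn.emissions = {
        name: EmissionNetwork.from_emission_row(model.emissions.probs[k], gain=gain)
        for k, name in enumerate(model.states)
    }
    hnn.window = WindowSpec(0, 0)
    hnn.encoding = "onehot"
    return hnn


# thin aliases: the recursions are shared with chmm_core, dispatched on the
# emission parameterization.

def hnn_forward(model: TopologyModel, seq, profile=None) -> Trellis:
    return chmm_core.forward(model, seq, profile=profile)


def hnn_clamped_forward(model: TopologyModel, seq, labels, profile=None) -> Trellis:
    return chmm_core.forward(model, seq, labels=labels, profile=profile)


# ---------------------------------------------------------------------------
# error signal and gradients
# ---------------------------------------------------------------------------

def _unique_networks(model: TopologyModel):
    """Unique network objects with the states that share them (order stable)."""
    seen: dict[int, list[int]] = {}
    order: list[EmissionNetwork] = []
    for k, name in enumerate(model.states):
        net = model.emissions[name]
        if id(net) not in seen:
            seen[id(net)] = []
            order.append(net)
        seen[id(net)].append(k)
    return [(net, seen[id(net)]) for net in order]


def _hnn_scores(model: TopologyModel, seq: LabeledSequence, profile=None):
    """Emission score matrix (S, L) plus per-unique-network caches."""
    prof = profile if model.encoding == "profile" else None
    X = encode_windows(seq, model.window, prof)
    S, L = model.n_states, len(seq)
    E = np.empty((S, L))
    caches = []
    for net, states in _unique_networks(model):
        out, cache = net._forward_cache(X)
        caches.append((net, states, cache))
        for k in states:
            E[k] = out
    return E, caches


def _sequence_error_signal(model, seq, labels, profile=None):
    """(ε, E, caches, ℓc, ℓf, free counts, clamped counts) for one sequence."""
    E, caches = _hnn_scores(model, seq, profile)
    mask = model.label_mask(labels)
    g_f, bc_f, xi_f, llf = _counts_one_phase(E, model.begin, model.trans, model.end_vec)
    g_c, bc_c, xi_c, llc = _counts_one_phase(
        E * mask, model.begin, model.trans, model.end_vec
    )
    if not (np.isfinite(llf) and np.isfinite(llc)):
        raise ValueError(f"sequence {seq.id!r}: infinite CML loss")
    # derivative through the output sigmoid; zero where the clamp is active
    eps = (g_f - g_c) * (1.0 - E)
    for net, states, cache in caches:
        active = (cache["raw"] >= net.clamp) & (cache["raw"] <= 1.0 - net.clamp)
        for k in states:
            eps[k] = np.where(active, eps[k], 0.0)
    return eps, E, caches, -llc, -llf, (g_f, bc_f, xi_f), (g_c, bc_c, xi_c)


def error_signal(
    model: TopologyModel,
    seq: LabeledSequence,
    labels: Optional[str] = None,
    profile: Optional[Profile] = None,
) -> np.ndarray:
    """Per-state, per-position loss derivative at the output pre-activation.

    Zero wherever free and clamped posteriors coincide; raises when either
    phase has infinite loss.
    """
    labels = labels if labels is not None else seq.labels
    if labels is None:
        raise ValueError(f"sequence {seq.id!r} has no labels")
    eps, *_ = _sequence_error_signal(model, seq, labels, profile)
    return eps


def backprop_gradients(
    model: TopologyModel,
    data: Sequence[LabeledSequence],
    profiles: Optional[Sequence[Optional[Profile]]] = None,
    weight_decay: float = 0.0,
    joint_transitions: bool = True,
):
    """Total CML loss and its gradients over a batch.

    Returns ``(loss, net_grads, g_trans, g_begin)`` where ``net_grads`` is a
    list aligned with the model's unique networks, each a dict of arrays, and
    the transition gradients are matrix-shaped with zeros at structural zeros
    (``None`` when ``joint_transitions`` is off).  The weight-decay term
    ``λ·w`` is added to every network parameter gradient and ``λ/2·‖w‖²`` to
    the loss.
    """
    profiles = profiles or [None] * len(data)
    uniq = _unique_networks(model)
    net_grads = [
        {
            "W1": np.zeros_like(net.W1),
            "b1": np.zeros_like(net.b1),
            "w2": np.zeros_like(net.w2),
            "b2": 0.0,
        }
        for net, _ in uniq
    ]
    S = model.n_states
    trans_f = np.zeros((S, S))
    trans_c = np.zeros((S, S))
    begin_f = np.zeros(S)
    begin_c = np.zeros(S)
    total = 0.0
    for seq, prof in zip(data, profiles):
        if seq.labels is None:
            raise ValueError(f"sequence {seq.id!r} has no labels")
        eps, E, caches, lc, lf, free_cts, clamp_cts = _sequence_error_signal(
            model, seq, seq.labels, prof
        )
        total += lc - lf
        for acc, (net, states, cache) in zip(net_grads, caches):
            g_h = eps[states].sum(axis=0)
            g = net.backprop(cache, g_h)
            for key in ("W1", "b1", "w2"):
                acc[key] += g[key]
            acc["b2"] += g["b2"]
        if joint_transitions:
            trans_f += free_cts[2]
            trans_c += clamp_cts[2]
            begin_f += free_cts[1]
            begin_c += clamp_cts[1]
    if weight_decay:
        for acc, (net, _) in zip(net_grads, uniq):
            acc["W1"] += weight_decay * net.W1
            acc["b1"] += weight_decay * net.b1
            acc["w2"] += weight_decay * net.w2
            acc["b2"] += weight_decay * net.b2
            total += 0.5 * weight_decay * (
                np.sum(net.W1**2) + np.sum(net.b1**2) + np.sum(net.w2**2) + net.b2**2
            )
    if joint_transitions:
        g_trans = _logit_gradient_from_counts(trans_c, trans_f, model.trans, model.trans_mask)
        g_begin = _logit_gradient_from_counts(begin_c, begin_f, model.begin, model.begin_mask)
    else:
        g_trans = g_begin = None
    return total, net_grads, g_trans, g_begin


# ---------------------------------------------------------------------------
# flat parameter view (shared by the trainer and the gradient checks)
# ---------------------------------------------------------------------------

class HNNParameters:
    """Flat vector view over all trainable parameters of an HNN model.

    Layout: per unique network (W1, b1, w2, b2 in order), then the allowed
    transition logits (row-major over the structural mask), then the allowed
    begin logits.  The softmax reparameterization makes the transition block
    shift-invariant; gradients and packed values use the same layout.
    """

    def __init__(self, model: TopologyModel, train_transitions: bool = True):
        self.model = model
        self.train_transitions = train_transitions
        self.uniq = _unique_networks(model)
        self.trans_idx = np.argwhere(model.trans_mask)
        self.begin_idx = np.flatnonzero(model.begin_mask)
        n = sum(net.n_parameters for net, _ in self.uniq)
        if train_transitions:
            n += len(self.trans_idx) + len(self.begin_idx)
        self.size = n

    def pack(self) -> np.ndarray:
        parts = []
        for net, _ in self.uniq:
            parts += [net.W1.ravel(), net.b1, net.w2, [net.b2]]
        if self.train_transitions:
            zt, zb = transition_logits(self.model)
            parts.append(zt[self.trans_idx[:, 0], self.trans_idx[:, 1]])
            parts.append(zb[self.begin_idx])
        return np.concatenate([np.asarray(p, dtype=float) for p in parts])

    def unpack(self, vec: np.ndarray) -> None:
        pos = 0
        for net, _ in self.uniq:
            n = net.W1.size
            net.W1[...] = vec[pos : pos + n].reshape(net.W1.shape)
            pos += n
            n = net.b1.size
            net.b1[...] = vec[pos : pos + n]
            pos += n
            n = net.w2.size
            net.w2[...] = vec[pos : pos + n]
            pos += n
            net.b2 = float(vec[pos])
            pos += 1
        if self.train_transitions:
            zt = np.zeros_like(self.model.trans)
            n = len(self.trans_idx)
            zt[self.trans_idx[:, 0], self.trans_idx[:, 1]] = vec[pos : pos + n]
            pos += n
            zb = np.zeros_like(self.model.begin)
            # keep forbidden entries harmless: softmax is masked anyway
            zb[self.begin_idx] = vec[pos : pos + len(self.begin_idx)]
            pos += len(self.begin_idx)
            set_transition_logits(self.model, zt, zb)
        assert pos == self.size

    def pack_gradients(self, net_grads, g_trans, g_begin) -> np.ndarray:
        parts = []
        for acc in net_grads:
            parts += [acc["W1"].ravel(), acc["b1"], acc["w2"], [acc["b2"]]]
        if self.train_transitions:
            parts.append(g_trans[self.trans_idx[:, 0], self.trans_idx[:, 1]])
            parts.append(g_begin[self.begin_idx])
        return np.concatenate([np.asarray(p, dtype=float) for p in parts])


def batch_loss(
    model: TopologyModel,
    data: Sequence[LabeledSequence],
    profiles=None,
    weight_decay: float = 0.0,
) -> float:
    """Total CML loss Σ ℓ over a batch (plus the weight-decay penalty)."""
    profiles = profiles or [None] * len(data)
    total = 0.0
    for seq, prof in zip(data, profiles):
        c = chmm_core.cml_loss(model, seq, profile=prof)
        if not c.ok:
            return np.inf
        total += c.loss
    if weight_decay and model.is_hnn:
        for net, _ in _unique_networks(model):
            total += 0.5 * weight_decay * (
                np.sum(net.W1**2) + np.sum(net.b1**2) + np.sum(net.w2**2) + net.b2**2
            )
    return total


# ---------------------------------------------------------------------------
# RPROP (iRPROP− variant)
# ---------------------------------------------------------------------------

@dataclass
class RPROPState:
    """Per-weight step sizes and previous derivatives for iRPROP−.

    On a sign change of the partial derivative the step shrinks by ``e_d``
    and the stored derivative is zeroed; on a consistent sign it grows by
    ``e_a``.  Steps are kept inside ``[step_min, step_max]`` at all times.
    """

    step: np.ndarray
    prev_grad: np.ndarray
    e_a: float = 1.2
    e_d: float = 0.5
    step_min: float = 1e-8
    step_max: float = 1.0

    @classmethod
    def init(
        cls,
        n: int,
        step0: float = 0.01,
        e_a: float = 1.2,
        e_d: float = 0.5,
        step_min: float = 1e-8,
        step_max: float = 1.0,
    ) -> "RPROPState":
        return cls(np.full(n, step0), np.zeros(n), e_a, e_d, step_min, step_max)


def rprop_step(state: RPROPState, grad: np.ndarray) -> np.ndarray:
    """One iRPROP− update; returns the weight increment Δw (state mutated)."""
    sign = state.prev_grad * grad
    state.step = np.where(
        sign > 0,
        np.minimum(state.step * state.e_a, state.step_max),
        np.where(sign < 0, np.maximum(state.step * state.e_d, state.step_min), state.step),
    )
    g_eff = np.where(sign < 0, 0.0, grad)
    state.prev_grad = g_eff
    return -np.sign(g_eff) * state.step


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Knobs for network initialization and joint CML training.

    ``max_epochs`` defaults to 50 with early stopping at the minimum of the
    held-back loss (``patience`` epochs without improvement).  ``init_loss``
    selects the per-label pre-training criterion (cross-entropy by default).
    """

    max_epochs: int = 50
    holdout_fraction: float = 0.1
    weight_decay: float = 0.0
    momentum: float = 0.0
    init_loss: str = "ce"            # "ce" | "rmse"
    seed: int = 0
    clamp: float = 1e-6
    patience: int = 10
    init_epochs: int = 100
    joint_transitions: bool = True
    tie_networks: bool = False
    optimizer: str = "rprop"         # "rprop" | "sgd"
    learning_rate: float = 0.05      # sgd only

    def __post_init__(self) -> None:
        if not 0.0 < self.holdout_fraction < 0.5:
            raise ValueError("holdout_fraction must be in (0, 0.5)")
        if not 0.0 < self.clamp <= 1e-3:
            raise ValueError("output clamp must be in (0, 1e-3]")
        if self.init_loss not in ("ce", "rmse"):
            raise ValueError(f"init_loss {self.init_loss!r}")


def _init_targets(data, label, model, profiles):
    Xs, ts = [], []
    prof_list = profiles or [None] * len(data)
    for seq, prof in zip(data, prof_list):
        p = prof if model.encoding == "profile" else None
        Xs.append(encode_windows(seq, model.window, p))
        ts.append(np.array([c == label for c in seq.labels], dtype=float))
    return np.vstack(Xs), np.concatenate(ts)


def init_networks(
    data: Sequence[LabeledSequence],
    model: TopologyModel,
    config: TrainConfig,
    profiles=None,
) -> dict:
    """Per-label network pre-training (RPROP on CE or summed squared error).

    One network is created and trained per label to output 1 on windows whose
    center carries that label and 0 otherwise; every state then receives a
    copy of its label's network (a shared object per label when
    ``config.tie_networks``).  A label absent from the data leaves its network
    at the random initialization with a warning.
    """
    if model.window is None:
        raise ValueError("model has no window specification; use attach_networks first")
    rng = np.random.default_rng(config.seed)
    D = model.alphabet.size * model.window.K
    hidden = next(iter(model.emissions.values())).hidden_units if model.is_hnn else 5
    activation = (
        next(iter(model.emissions.values())).hidden_activation if model.is_hnn else "sigmoid"
    )
    label_nets: dict[str, EmissionNetwork] = {}
    for label in model.label_set:
        net = EmissionNetwork.random(D, hidden, rng, activation, config.clamp)
        X, t = _init_targets(data, label, model, profiles)
        if t.sum() == 0:
            warnings.warn(f"label {label!r} absent from training data; "
                          f"network left at random initialization")
            label_nets[label] = net
            continue
        state = RPROPState.init(net.n_parameters)

        def pack(g):
            return np.concatenate([g["W1"].ravel(), g["b1"], g["w2"], [g["b2"]]])

        vec = np.concatenate([net.W1.ravel(), net.b1, net.w2, [net.b2]])

        def unpack(v):
            p = 0
            net.W1[...] = v[p : p + net.W1.size].reshape(net.W1.shape)
            p += net.W1.size
            net.b1[...] = v[p : p + net.b1.size]
            p += net.b1.size
            net.w2[...] = v[p : p + net.w2.size]
            p += net.w2.size
            net.b2 = float(v[p])

        for _ in range(config.init_epochs):
            out, cache = net._forward_cache(X)
            raw = cache["raw"]
            if config.init_loss == "ce":
                g_h = raw - t
            else:                     # squared error through the sigmoid
                g_h = (raw - t) * raw * (1.0 - raw)
            grad = pack(net.backprop(cache, g_h))
            vec = vec + rprop_step(state, grad)
            unpack(vec)
        label_nets[label] = net
    out: dict[str, EmissionNetwork] = {}
    for k, name in enumerate(model.states):
        lab = model.state_labels[k]
        out[name] = label_nets[lab] if config.tie_networks else copy.deepcopy(label_nets[lab])
    return out


def train_hnn(
    model: TopologyModel,
    data: Sequence[LabeledSequence],
    config: TrainConfig,
    profiles=None,
):
    """Joint CML training of emission networks (and transitions) by RPROP.

    Full-batch gradients (RPROP needs consistent sign information); a seeded
    by-sequence holdout split tracks the early-stopping loss.  Returns
    ``(best_model, log)`` where ``best_model`` is the parameter snapshot at
    the held-out minimum and ``log`` lists per-epoch train/holdout losses.
    """
    if not model.is_hnn:
        raise ValueError("train_hnn requires an HNN model (see attach_networks)")
    model = model.copy()
    profiles = list(profiles) if profiles is not None else [None] * len(data)
    bad = []
    for i, s in enumerate(data):
        prof = profiles[i] if model.encoding == "profile" else None
        if not chmm_core.forward(model, s, labels=s.labels, profile=prof).ok:
            bad.append(s.id)
    if bad:
        raise ValueError(f"label-inconsistent sequences (no clamped path): {bad}")

    rng = np.random.default_rng(config.seed)
    idx = rng.permutation(len(data))
    n_hold = int(round(config.holdout_fraction * len(data))) if len(data) >= 2 else 0
    hold_idx, train_idx = idx[:n_hold], idx[n_hold:]
    train = [data[i] for i in train_idx]
    train_prof = [profiles[i] for i in train_idx]
    hold = [data[i] for i in hold_idx]
    hold_prof = [profiles[i] for i in hold_idx]

    params = HNNParameters(model, train_transitions=config.joint_transitions)
    vec = params.pack()
    rprop = RPROPState.init(params.size)
    velocity = np.zeros(params.size)

    hold_loss = batch_loss(model, hold or train, hold_prof or train_prof,
                           config.weight_decay)
    best_vec = vec.copy()
    best_epoch = 0
    best_hold = hold_loss
    log = [{"epoch": 0, "train_loss": None, "holdout_loss": hold_loss}]
    for epoch in range(1, config.max_epochs + 1):
        loss, net_grads, g_t, g_b = backprop_gradients(
            model, train, train_prof, config.weight_decay, config.joint_transitions
        )
        grad = params.pack_gradients(net_grads, g_t, g_b)
        if config.optimizer == "rprop":
            vec = vec + rprop_step(rprop, grad)
        else:
            velocity = config.momentum * velocity - config.learning_rate * grad
            vec = vec + velocity
        params.unpack(vec)
        hold_loss = batch_loss(model, hold or train, hold_prof or train_prof,
                               config.weight_decay)
        log.append({"epoch": epoch, "train_loss": loss, "holdout_loss": hold_loss})
        if hold_loss < best_hold - 1e-12:
            best_hold = hold_loss
            best_vec = vec.copy()
            best_epoch = epoch
        if epoch - best_epoch >= config.patience:
            break
    params.unpack(best_vec)
    return model, log
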