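"""Label decoding: Viterbi and the Optimal Accuracy Posterior Decoder.

For discriminatively trained models the Viterbi path (the single most likely
state path) is a poor label predictor; the posterior decoder instead returns
the grammar-valid label sequence that maximizes the sum of per-position label
posteriors, where the label posterior aggregates the free-phase state
posteriors over all states carrying that label.  Grammar validity (allowed
label adjacencies and minimum segment lengths imposed by chained states) is
enforced by running the dynamic program over the state graph itself: every
state path realizes a valid label sequence and every valid label sequence is
realized by some state path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .chmm_core import TopologyModel, backward, forward, posteriors
from .seqdata import LabeledSequence, Profile


@dataclass
class Prediction:
    """A decoded labeling with its per-position posterior support."""

    id: str
    labels: str                     # decoded label sequence, length L
    label_list: list[str]           # row order of label_posteriors
    label_posteriors: np.ndarray    # (C, L), columns sum to 1
    chosen_posterior: np.ndarray    # (L,) posterior of the decoded label
    decoder: str                    # "posterior" | "viterbi"
    score: float                    # decoding objective value
    log_likelihood: float           # free-phase log score of the sequence

    @property
    def reliability(self) -> float:
        """Mean over positions of the chosen-label posterior, in [0, 1]."""
        return float(self.chosen_posterior.mean())

    @property
    def max_probability(self) -> float:
        """Maximum over positions of the chosen-label posterior."""
        return float(self.chosen_posterior.max())


def segments(labels: str) -> list[tuple[int, int, str]]:
    """Maximal constant-label runs as 1-based closed intervals ``(start, end, label)``."""
    if not labels:
        raise ValueError("empty labeling")
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start + 1, i, labels[start]))
            start = i
    return out


def reliability(prediction: Prediction) -> float:
    return prediction.reliability


def _label_posterior_matrix(model: TopologyModel, gamma: np.ndarray) -> np.ndarray:
    C = len(model.label_set)
    P = np.zeros((C, gamma.shape[1]))
    for c, lab in enumerate(model.label_set):
        for k in model.states_for_label(lab):
            P[c] += gamma[k]
    return P


def viterbi(model: TopologyModel, seq: LabeledSequence, profile: Optional[Profile] = None):
    """Most probable state path.

    Returns ``(path, log_score, labels)``; ties at a backtrack step are broken
    toward the lowest state index.  A sequence with no positive-score path
    yields ``(None, -inf, None)``.
    """
    E = model.emission_matrix(seq, profile)
    with np.errstate(divide="ignore"):
        logE = np.log(E)
        logT = np.where(model.trans_mask, np.log(np.maximum(model.trans, 1e-300)), -np.inf)
        logB = np.where(model.begin_mask, np.log(np.maximum(model.begin, 1e-300)), -np.inf)
    S, L = E.shape
    V = np.full((L, S), -np.inf)
    ptr = np.zeros((L, S), dtype=int)
    V[0] = logB + logE[:, 0]
    for i in range(1, L):
        cand = V[i - 1][:, None] + logT          # (from, to)
        ptr[i] = np.argmax(cand, axis=0)         # argmax picks lowest index on ties
        V[i] = cand[ptr[i], np.arange(S)] + logE[:, i]
    last = V[L - 1].copy()
    if model.end_vec is not None:
        last[model.end_vec == 0] = -np.inf
    k = int(np.argmax(last))
    if not np.isfinite(last[k]):
        return None, -np.inf, None
    path = [k]
    for i in range(L - 1, 0, -1):
        path.append(int(ptr[i, path[-1]]))
    path.reverse()
    labels = "".join(model.state_labels[k] for k in path)
    return path, float(last[k]), labels


def posterior_label_decode(
    model: TopologyModel, seq: LabeledSequence, profile: Optional[Profile] = None
) -> Prediction:
    """Optimal Accuracy Posterior Decoder.

    Maximizes the mean per-position label posterior over all grammar-valid
    label sequences (dynamic program over the state graph; posterior of a
    state's label is credited at each position).  The decoder score is the
    maximized mean.
    """
    ft = forward(model, seq, profile=profile)
    bt = backward(model, seq, profile=profile)
    if not (ft.ok and bt.ok):
        raise ValueError(f"sequence {seq.id!r}: free phase has no path")
    gamma = posteriors(ft, bt)
    P = _label_posterior_matrix(model, gamma)                    # (C, L)
    lab_of_state = np.array(
        [model.label_set.index(lab) for lab in model.state_labels]
    )
    S, L = gamma.shape
    reward = P[lab_of_state]                                     # (S, L)
    V = np.full((L, S), -np.inf)
    ptr = np.zeros((L, S), dtype=int)
    V[0] = np.where(model.begin_mask, reward[:, 0], -np.inf)
    neg = np.where(model.trans_mask.T, 0.0, -np.inf)             # (to, from)
    for i in range(1, L):
        cand = V[i - 1][None, :] + neg                           # (to, from)
        ptr[i] = np.argmax(cand, axis=1)
        V[i] = cand[np.arange(S), ptr[i]] + reward[:, i]
    last = V[L - 1].copy()
    if model.end_vec is not None:
        last[model.end_vec == 0] = -np.inf
    k = int(np.argmax(last))
    if not np.isfinite(last[k]):
        raise ValueError("grammar admits no valid label sequence for this length")
    path = [k]
    for i in range(L - 1, 0, -1):
        path.append(int(ptr[i, path[-1]]))
    path.reverse()
    labels = "".join(model.state_labels[s] for s in path)
    chosen = P[[model.label_set.index(c) for c in labels], np.arange(L)]
    return Prediction(
        id=seq.id,
        labels=labels,
        label_list=list(model.label_set),
        label_posteriors=P,
        chosen_posterior=chosen,
        decoder="posterior",
        score=float(last[k]) / L,
        log_likelihood=ft.log_likelihood,
    )


def viterbi_decode(
    model: TopologyModel, seq: LabeledSequence, profile: Optional[Profile] = None
) -> Prediction:
    """Viterbi decoding wrapped in a :class:`Prediction` (posteriors attached)."""
    path, score, labels = viterbi(model, seq, profile)
    ft = forward(model, seq, profile=profile)
    if labels is None or not ft.ok:
        raise ValueError(f"sequence {seq.id!r}: no positive-score path")
    bt = backward(model, seq, profile=profile)
    gamma = posteriors(ft, bt)
    P = _label_posterior_matrix(model, gamma)
    L = len(labels)
    chosen = P[[model.label_set.index(c) for c in labels], np.arange(L)]
    return Prediction(
        id=seq.id,
        labels=labels,
        label_list=list(model.label_set),
        label_posteriors=P,
        chosen_posterior=chosen,
        decoder="viterbi",
        score=score,
        log_likelihood=ft.log_likelihood,
    )
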