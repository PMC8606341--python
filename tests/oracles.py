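"""Independent brute-force oracles: exhaustive path and label enumeration.

Everything here works with plain Python loops over all state paths, entirely
independent of the scaled dynamic-programming implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def _path_score(E, begin, trans, path, end_vec=None):
    p = begin[path[0]] * E[path[0], 0]
    for i in range(1, len(path)):
        p *= trans[path[i - 1], path[i]] * E[path[i], i]
    if end_vec is not None:
        p *= end_vec[path[-1]]
    return p


def enum_log_likelihood(E, begin, trans, mask=None, end_vec=None) -> float:
    """log Σ_paths (score), optionally restricted by a label-consistency mask."""
    S, L = E.shape
    Em = E if mask is None else E * mask
    tot = 0.0
    for path in itertools.product(range(S), repeat=L):
        tot += _path_score(Em, begin, trans, path, end_vec)
    return math.log(tot) if tot > 0 else -math.inf


def enum_posteriors(E, begin, trans, mask=None, end_vec=None) -> np.ndarray:
    """Per-position state posteriors, shape (S, L), by path enumeration."""
    S, L = E.shape
    Em = E if mask is None else E * mask
    acc = np.zeros((S, L))
    tot = 0.0
    for path in itertools.product(range(S), repeat=L):
        p = _path_score(Em, begin, trans, path, end_vec)
        tot += p
        for i, k in enumerate(path):
            acc[k, i] += p
    return acc / tot


def enum_viterbi_logscore(E, begin, trans, end_vec=None) -> float:
    S, L = E.shape
    best = 0.0
    for path in itertools.product(range(S), repeat=L):
        best = max(best, _path_score(E, begin, trans, path, end_vec))
    return math.log(best) if best > 0 else -math.inf


def enum_best_labeling(model, E) -> tuple[float, set]:
    """Optimal-accuracy objective by brute force.

    Enumerates all structurally valid state paths, maps each to its label
    sequence, scores a label sequence by the sum of per-position label
    posteriors (computed here by enumeration as well), and returns the
    maximum objective together with the set of optimal label sequences.
    """
    S, L = E.shape
    gamma = enum_posteriors(E, model.begin, model.trans, end_vec=model.end_vec)
    P = np.zeros((len(model.label_set), L))
    for k, lab in enumerate(model.state_labels):
        P[model.label_set.index(lab)] += gamma[k]
    end_ok = (
        (lambda k: True)
        if model.end_states is None
        else (lambda k: model.states[k] in model.end_states)
    )
    best = -math.inf
    argbest: set[str] = set()
    for path in itertools.product(range(S), repeat=L):
        if not model.begin_mask[path[0]] or not end_ok(path[-1]):
            continue
        if any(not model.trans_mask[path[i - 1], path[i]] for i in range(1, L)):
            continue
        labels = "".join(model.state_labels[k] for k in path)
        obj = sum(P[model.label_set.index(c), i] for i, c in enumerate(labels))
        if obj > best + 1e-12:
            best = obj
            argbest = {labels}
        elif abs(obj - best) <= 1e-12:
            argbest.add(labels)
    return best, argbest


def logspace_forward(E, begin, trans, mask=None, end_vec=None) -> float:
    """Direct log-space forward recursion (logsumexp), no per-position scaling."""
    from scipy.special import logsumexp

    S, L = E.shape
    Em = E if mask is None else E * mask
    with np.errstate(divide="ignore"):
        logE = np.log(Em)
        logT = np.log(trans)
        logB = np.log(begin)
    v = logB + logE[:, 0]
    for i in range(1, L):
        v = logsumexp(v[:, None] + logT, axis=0) + logE[:, i]
    if end_vec is not None:
        with np.errstate(divide="ignore"):
            v = v + np.log(end_vec)
    return float(logsumexp(v))
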