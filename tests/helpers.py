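"""Shared builders for random tiny model instances used across the suite."""

from __future__ import annotations

import numpy as np

from hnntm.chmm_core import EmissionTable, TopologyModel
from hnntm.hnn import attach_networks
from hnntm.seqdata import Alphabet, LabeledSequence, WindowSpec

ALPHABETS = {2: Alphabet("AB"), 3: Alphabet("ABC"), 4: Alphabet("ACGT")}


def random_chmm(
    rng: np.random.Generator,
    n_states: int = 3,
    alphabet_size: int = 4,
    n_labels: int = 2,
    min_emission: float = 1e-3,
) -> TopologyModel:
    """Fully connected random CHMM with Dirichlet parameters.

    Emissions are floored at ``min_emission`` (then renormalized) so that
    saturated-network embeddings stay inside the output clamp.
    """
    alphabet = ALPHABETS[alphabet_size]
    S, A = n_states, alphabet_size
    labels = [chr(ord("a") + i) for i in range(min(n_labels, S))]
    state_labels = [labels[k % len(labels)] for k in range(S)]
    probs = rng.dirichlet(np.ones(A) * 2.0, size=S)
    probs = np.clip(probs, min_emission, None)
    probs /= probs.sum(axis=1, keepdims=True)
    model = TopologyModel(
        states=[f"s{k}" for k in range(S)],
        label_set=sorted(set(state_labels)),
        state_labels=state_labels,
        begin=rng.dirichlet(np.ones(S)),
        trans=rng.dirichlet(np.ones(S), size=S),
        emissions=EmissionTable(probs),
        alphabet=alphabet,
    )
    model.validate()
    return model


def random_hnn(
    rng: np.random.Generator,
    n_states: int = 3,
    alphabet_size: int = 4,
    n_labels: int = 2,
    window: WindowSpec = WindowSpec(1, 1),
    hidden: int = 3,
) -> TopologyModel:
    base = random_chmm(rng, n_states, alphabet_size, n_labels)
    return attach_networks(base, window, hidden, seed=int(rng.integers(2**31)))


def sampled_labels(rng: np.random.Generator, model: TopologyModel, L: int) -> str:
    """Label sequence of a state path sampled from the model (always feasible)."""
    k = int(rng.choice(model.n_states, p=model.begin))
    labs = [model.state_labels[k]]
    for _ in range(L - 1):
        k = int(rng.choice(model.n_states, p=model.trans[k]))
        labs.append(model.state_labels[k])
    return "".join(labs)


def random_instance(rng: np.random.Generator, model: TopologyModel, L: int) -> LabeledSequence:
    """Uniform random residues paired with grammar-feasible labels."""
    x = rng.integers(0, model.alphabet.size, size=L)
    return LabeledSequence(f"r{L}", x, sampled_labels(rng, model, L), model.alphabet)
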