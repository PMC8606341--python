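"""Seeded generators of labeled sequences with known structure.

Two generative processes cover the training regimes the package targets:

* ``chmm`` — sequences sampled from a fully specified first-order CHMM (the
  documented toy transmembrane grammar below), the regime a table-emission
  CHMM can fit exactly;
* ``context`` — labels follow a first-order chain but each residue's
  distribution depends on the *previous residue* as well as the label.  A
  first-order CHMM cannot represent that dependence, while an emission
  network over a window of width ≥ 3 sees both residues — this is the
  testbed for the discriminative advantage of the HNN.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .chmm_core import EmissionTable, TopologyModel
from .seqdata import (
    AMINO_ACIDS,
    Alphabet,
    LabeledSequence,
    Profile,
    write_fasta,
    write_labels,
    write_profile,
)

_HYDROPHOBIC = set("ACFILMVWY")
_POSITIVE = set("KR")
_POLAR = set("DEHKNPQRSTG")


def _toy_emissions(alphabet: Alphabet) -> dict[str, np.ndarray]:
    """Hydrophobicity-flavored emission rows for the toy grammar.

    TM states favor hydrophobic residues; loop states favor polar residues,
    with the inside loop additionally enriched in K/R (positive-inside rule)
    so that the two loop labels are distinguishable.
    """
    rows = {}
    for name in ("M", "i", "o"):
        w = np.empty(alphabet.size)
        for a, ch in enumerate(alphabet.symbols):
            if name == "M":
                w[a] = 5.0 if ch in _HYDROPHOBIC else 0.5
            else:
                w[a] = 3.0 if ch in _POLAR else 0.6
                if ch in _POSITIVE:
                    w[a] = 8.0 if name == "i" else 1.0
        rows[name] = w / w.sum()
    return rows


def toy_topology_model(alphabet: Optional[Alphabet] = None) -> TopologyModel:
    """The documented toy transmembrane grammar.

    Labels {i, M, o}; one inside-loop state I, one outside-loop state O and a
    chain M1→…→M5 (tied emissions) enforcing a minimum TM segment length of
    5.  All probabilities are fixed:

    * begin: I 0.5, O 0.5
    * I → I 0.92, I → M1 0.08;  O → O 0.92, O → M1 0.08
    * M1…M4 advance with probability 1; M5 → M5 0.75, M5 → I 0.125,
      M5 → O 0.125 (mean TM length 8)
    """
    alphabet = alphabet or Alphabet()
    states = ["I", "O", "M1", "M2", "M3", "M4", "M5"]
    labels = ["i", "o", "M", "M", "M", "M", "M"]
    S = len(states)
    trans = np.zeros((S, S))
    ix = {s: k for k, s in enumerate(states)}
    trans[ix["I"], ix["I"]] = 0.92
    trans[ix["I"], ix["M1"]] = 0.08
    trans[ix["O"], ix["O"]] = 0.92
    trans[ix["O"], ix["M1"]] = 0.08
    for a, b in (("M1", "M2"), ("M2", "M3"), ("M3", "M4"), ("M4", "M5")):
        trans[ix[a], ix[b]] = 1.0
    trans[ix["M5"], ix["M5"]] = 0.75
    trans[ix["M5"], ix["I"]] = 0.125
    trans[ix["M5"], ix["O"]] = 0.125
    begin = np.zeros(S)
    begin[ix["I"]] = begin[ix["O"]] = 0.5
    rows = _toy_emissions(alphabet)
    probs = np.vstack([rows[lab] for lab in labels])
    tie = np.array([0, 1, 2, 2, 2, 2, 2])
    model = TopologyModel(
        states=states,
        label_set=["i", "M", "o"],
        state_labels=labels,
        begin=begin,
        trans=trans,
        emissions=EmissionTable(probs=probs, tie_ids=tie),
        alphabet=alphabet,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# context-dependent generator
# ---------------------------------------------------------------------------

@dataclass
class ContextTables:
    """Emission distributions conditioned on (label, previous residue)."""

    alphabet: Alphabet
    label_set: list[str]
    begin: np.ndarray            # (C,)
    trans: np.ndarray            # (C, C) label chain
    first: np.ndarray            # (C, A) emission at position 0
    cond: np.ndarray             # (C, A, A): [label, prev residue, residue]

    def validate(self) -> None:
        for arr, axis in ((self.begin, None), (self.trans, 1), (self.first, 1)):
            s = arr.sum() if axis is None else arr.sum(axis=axis)
            if np.any(np.abs(s - 1.0) > 1e-10):
                raise ValueError("context tables must be row-stochastic")
        if np.any(np.abs(self.cond.sum(axis=2) - 1.0) > 1e-10):
            raise ValueError("conditional emissions must be row-stochastic")


def default_context_tables() -> ContextTables:
    """The fixed context testbed (4-letter alphabet, labels {i, M}).

    Residues split into two parity classes {A, C} and {G, T}.  State M emits
    in the *same* class as the previous residue with probability 0.8; state i
    emits in the *opposite* class with probability 0.8 — information only a
    context window can see.  Within the chosen class each label weakly favors
    a different letter (0.7/0.3), giving a first-order CHMM a real but weaker
    signal, so both model families beat the majority baseline while only the
    window-based model captures the pairing rule.
    """
    alphabet = Alphabet("ACGT")
    labels = ["i", "M"]
    begin = np.array([0.5, 0.5])
    trans = np.array([[0.88, 0.12], [0.12, 0.88]])
    first = np.full((2, 4), 0.25)
    # class membership: A,C -> class 0; G,T -> class 1
    klass = np.array([0, 0, 1, 1])
    # within-class letter preference: M favors (A, G), i favors (C, T)
    within = {
        "M": {0: np.array([0.7, 0.3]), 1: np.array([0.7, 0.3])},
        "i": {0: np.array([0.3, 0.7]), 1: np.array([0.3, 0.7])},
    }
    cond = np.zeros((2, 4, 4))
    for c, lab in enumerate(labels):
        match = 0.8 if lab == "M" else 0.2
        for prev in range(4):
            for kc in (0, 1):
                mass = match if kc == klass[prev] else 1.0 - match
                members = np.flatnonzero(klass == kc)
                cond[c, prev, members] = mass * within[lab][kc]
    tables = ContextTables(alphabet, labels, begin, trans, first, cond)
    tables.validate()
    return tables


@dataclass
class GeneratorSpec:
    """Specification of one synthetic dataset draw."""

    kind: str = "chmm"                        # "chmm" | "context"
    model: Optional[TopologyModel] = None     # chmm kind
    context: Optional[ContextTables] = None   # context kind
    min_len: int = 60
    max_len: int = 120
    n: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("chmm", "context"):
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if self.min_len < 2 or self.max_len < self.min_len:
            raise ValueError("need max_len >= min_len >= 2")


def sample(spec: GeneratorSpec) -> list[LabeledSequence]:
    """Draw labeled sequences from the specified process (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "chmm":
        model = spec.model or toy_topology_model()
        return _sample_chmm(model, spec, rng)
    tables = spec.context or default_context_tables()
    return _sample_context(tables, spec, rng)


def _sample_chmm(model: TopologyModel, spec: GeneratorSpec, rng) -> list[LabeledSequence]:
    probs = model.emissions.probs
    out = []
    S = model.n_states
    for j in range(spec.n):
        L = int(rng.integers(spec.min_len, spec.max_len + 1))
        x = np.empty(L, dtype=np.int64)
        labs = []
        k = int(rng.choice(S, p=model.begin))
        for i in range(L):
            if i > 0:
                k = int(rng.choice(S, p=model.trans[k]))
            x[i] = rng.choice(model.alphabet.size, p=probs[k])
            labs.append(model.state_labels[k])
        out.append(
            LabeledSequence(f"chmm{spec.seed}_{j:03d}", x, "".join(labs), model.alphabet)
        )
    return out


def _sample_context(tables: ContextTables, spec: GeneratorSpec, rng) -> list[LabeledSequence]:
    C = len(tables.label_set)
    A = tables.alphabet.size
    out = []
    for j in range(spec.n):
        L = int(rng.integers(spec.min_len, spec.max_len + 1))
        x = np.empty(L, dtype=np.int64)
        labs = []
        c = int(rng.choice(C, p=tables.begin))
        for i in range(L):
            if i > 0:
                c = int(rng.choice(C, p=tables.trans[c]))
            if i == 0:
                x[i] = rng.choice(A, p=tables.first[c])
            else:
                x[i] = rng.choice(A, p=tables.cond[c, x[i - 1]])
            labs.append(tables.label_set[c])
        out.append(
            LabeledSequence(f"ctx{spec.seed}_{j:03d}", x, "".join(labs), tables.alphabet)
        )
    return out


def make_fixture_suite(outdir, seed: int = 0, n: int = 20) -> dict[str, Path]:
    """Write a small FASTA + label + profile fixture set (n ≤ 50, L ≤ 120).

    Profiles are synthetic stand-ins for alignment-derived PSSMs: the true
    state's emission row mixed with 30% uniform noise.  Returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = min(n, 50)
    model = toy_topology_model()
    data = sample(GeneratorSpec(kind="chmm", model=model, n=n, seed=seed))
    paths = {
        "fasta": outdir / "toy_sequences.fasta",
        "labels": outdir / "toy_sequences.labels",
        "profiles": outdir / "profiles",
    }
    write_fasta(data, paths["fasta"])
    write_labels(data, paths["labels"])
    paths["profiles"].mkdir(exist_ok=True)
    rows = _toy_emissions(model.alphabet)
    uniform = np.full(model.alphabet.size, 1.0 / model.alphabet.size)
    for seq in data:
        mat = np.vstack([0.7 * rows[c] + 0.3 * uniform for c in seq.labels])
        write_profile(
            Profile(seq.id, mat), paths["profiles"] / f"{seq.id}.profile.tsv",
            model.alphabet,
        )
    return paths
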