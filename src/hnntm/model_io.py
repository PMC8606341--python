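"""Flat-text model/grammar files and trained-model archives.

A model file is a sequence of ``key = value`` lines (``#`` comments allowed).
Structure keys declare the grammar — states, labels, the δ map, allowed
transitions, tying, begin/end policy; declared transitions define the
structural mask (anything undeclared is a structural zero).  Parameter keys
(emission rows or network weight tables) make the file a trained archive.
Floats are written with ``repr`` so that save → load round-trips bitwise.

Example (the toy grammar, table mode)::

    alphabet = ACDEFGHIKLMNPQRSTVWY
    labels = i M o
    states = I O M1 M2 M3 M4 M5
    label.I = i
    begin = I:0.5 O:0.5
    trans.I = I:0.92 M1:0.08
    tie = M1 M2 M3 M4 M5
    end = free
    emission.I = 0.0123 ...
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .chmm_core import EmissionTable, TopologyModel
from .hnn import EmissionNetwork
from .seqdata import Alphabet, WindowSpec


def _fmt(x: float) -> str:
    return repr(float(x))


def _fmt_vec(v) -> str:
    return " ".join(_fmt(x) for x in v)


def save_model(model: TopologyModel, path) -> None:
    """Write a model (structure + parameters) as a flat-text archive."""
    lines = ["# hnntm model file (positions in reports are 1-based closed intervals)"]
    lines.append(f"alphabet = {model.alphabet.symbols}")
    lines.append(f"labels = {' '.join(model.label_set)}")
    lines.append(f"states = {' '.join(model.states)}")
    for name, lab in zip(model.states, model.state_labels):
        lines.append(f"label.{name} = {lab}")
    lines.append(
        "begin = "
        + " ".join(
            f"{model.states[k]}:{_fmt(model.begin[k])}"
            for k in np.flatnonzero(model.begin_mask)
        )
    )
    for k, name in enumerate(model.states):
        succ = np.flatnonzero(model.trans_mask[k])
        if len(succ):
            lines.append(
                f"trans.{name} = "
                + " ".join(f"{model.states[l]}:{_fmt(model.trans[k, l])}" for l in succ)
            )
    lines.append(
        "end = free" if model.end_states is None else "end = " + " ".join(model.end_states)
    )
    lines.append(f"encoding = {model.encoding}")
    if not model.is_hnn:
        tie = model.emissions.tie_ids
        for g in np.unique(tie):
            members = [model.states[k] for k in np.flatnonzero(tie == g)]
            if len(members) > 1:
                lines.append(f"tie = {' '.join(members)}")
        for k, name in enumerate(model.states):
            lines.append(f"emission.{name} = {_fmt_vec(model.emissions.probs[k])}")
    else:
        lines.append(f"window = {model.window.left} {model.window.right}")
        written: dict[int, str] = {}
        for name in model.states:
            net = model.emissions[name]
            if id(net) in written:
                lines.append(f"network.{name}.same_as = {written[id(net)]}")
                continue
            written[id(net)] = name
            lines.append(f"network.{name}.activation = {net.hidden_activation}")
            lines.append(f"network.{name}.clamp = {_fmt(net.clamp)}")
            lines.append(f"network.{name}.shape = {net.hidden_units} {net.input_dim}")
            for r in range(net.hidden_units):
                lines.append(f"network.{name}.W1.{r} = {_fmt_vec(net.W1[r])}")
            lines.append(f"network.{name}.b1 = {_fmt_vec(net.b1)}")
            lines.append(f"network.{name}.w2 = {_fmt_vec(net.w2)}")
            lines.append(f"network.{name}.b2 = {_fmt(net.b2)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_kv(path) -> list[tuple[str, str]]:
    pairs = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: malformed line {raw!r}")
        key, val = line.split("=", 1)
        pairs.append((key.strip(), val.strip()))
    return pairs


def load_model(path, unknown_policy: str = "zero") -> TopologyModel:
    """Read a model/grammar file; parameters default to uniform when absent."""
    dict_multi: dict[str, list[str]] = {}
    for k, v in _parse_kv(path):
        dict_multi.setdefault(k, []).append(v)

    def one(key, default=None):
        vals = dict_multi.get(key)
        if vals is None:
            if default is None:
                raise ValueError(f"{path}: missing required key {key!r}")
            return default
        return vals[-1]

    alphabet = Alphabet(one("alphabet"), unknown_policy)
    label_set = one("labels").split()
    states = one("states").split()
    ix = {s: k for k, s in enumerate(states)}
    S = len(states)
    state_labels = []
    for name in states:
        lab = one(f"label.{name}")
        if lab not in label_set:
            raise ValueError(f"{path}: state {name} has undeclared label {lab!r}")
        state_labels.append(lab)

    begin = np.zeros(S)
    begin_mask = np.zeros(S, dtype=bool)
    for tok in one("begin").split():
        name, p = tok.split(":")
        begin[ix[name]] = float(p)
        begin_mask[ix[name]] = True
    trans = np.zeros((S, S))
    trans_mask = np.zeros((S, S), dtype=bool)
    for name in states:
        vals = dict_multi.get(f"trans.{name}")
        if not vals:
            continue
        for tok in vals[-1].split():
            dest, p = tok.split(":")
            trans[ix[name], ix[dest]] = float(p)
            trans_mask[ix[name], ix[dest]] = True

    end_val = one("end", "free")
    end_states = None if end_val == "free" else end_val.split()
    encoding = one("encoding", "onehot")

    is_hnn = any(k.startswith("network.") for k in dict_multi)
    if is_hnn:
        window = one("window").split()
        wspec = WindowSpec(int(window[0]), int(window[1]))
        nets: dict[str, EmissionNetwork] = {}
        for name in states:
            same = dict_multi.get(f"network.{name}.same_as")
            if same:
                nets[name] = nets[same[-1]]
                continue
            H, D = (int(t) for t in one(f"network.{name}.shape").split())
            W1 = np.vstack(
                [
                    np.fromstring(one(f"network.{name}.W1.{r}"), sep=" ")
                    for r in range(H)
                ]
            ).reshape(H, D)
            nets[name] = EmissionNetwork(
                W1=W1,
                b1=np.fromstring(one(f"network.{name}.b1"), sep=" "),
                w2=np.fromstring(one(f"network.{name}.w2"), sep=" "),
                b2=float(one(f"network.{name}.b2")),
                hidden_activation=one(f"network.{name}.activation", "sigmoid"),
                clamp=float(one(f"network.{name}.clamp", "1e-06")),
            )
        emissions = nets
    else:
        wspec = None
        A = alphabet.size
        probs = np.full((S, A), 1.0 / A)
        for k, name in enumerate(states):
            row = dict_multi.get(f"emission.{name}")
            if row:
                v = np.fromstring(row[-1], sep=" ")
                if v.size != A:
                    raise ValueError(f"{path}: emission.{name} has {v.size} values")
                probs[k] = v
        tie_ids = np.arange(S)
        for group in dict_multi.get("tie", []):
            members = [ix[m] for m in group.split()]
            tie_ids[members] = members[0]
        # renumber groups densely
        _, tie_ids = np.unique(tie_ids, return_inverse=True)
        emissions = EmissionTable(probs=probs, tie_ids=tie_ids)

    model = TopologyModel(
        states=states,
        label_set=label_set,
        state_labels=state_labels,
        begin=begin,
        trans=trans,
        emissions=emissions,
        alphabet=alphabet,
        end_states=end_states,
        window=wspec,
        encoding=encoding,
        trans_mask=trans_mask,
        begin_mask=begin_mask,
    )
    return model


def save_grammar(model: TopologyModel, path) -> None:
    """Write structure only (no emission parameters): a grammar file."""
    bare = model.copy()
    A = model.alphabet.size
    if bare.is_hnn:
        bare.emissions = EmissionTable(probs=np.full((model.n_states, A), 1.0 / A))
        bare.window = None
    else:
        tie = bare.emissions.tie_ids
        bare.emissions = EmissionTable(
            probs=np.full((model.n_states, A), 1.0 / A), tie_ids=tie
        )
    save_model(bare, path)
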