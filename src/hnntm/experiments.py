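"""Self-contained benchmark experiments on the synthetic generators.

These drive the package end to end at desk scale: supervised CHMM training,
HNN initialization + CML training, decoding, topology metrics and the
discrimination stage, all on seeded synthetic data.  Both the test suite and
the reproduction script call into these functions so that every reported
number is recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from .chmm_core import EmissionTable, TopologyModel, baum_welch_labeled, cml_loss
from .decoding import posterior_label_decode
from .discrimination import (
    cross_validated_stats,
    extract_features,
    null_model_from_data,
)
from .hnn import TrainConfig, attach_networks, init_networks, train_hnn
from .metrics import q2
from .seqdata import LabeledSequence, WindowSpec
from .synthetic import (
    GeneratorSpec,
    default_context_tables,
    sample,
    toy_topology_model,
)


def context_chmm_grammar() -> TopologyModel:
    """Two-state first-order grammar matching the context generator's labels."""
    tables = default_context_tables()
    return TopologyModel(
        states=["Si", "Sm"],
        label_set=["i", "M"],
        state_labels=["i", "M"],
        begin=np.array([0.5, 0.5]),
        trans=np.array([[0.88, 0.12], [0.12, 0.88]]),
        emissions=EmissionTable(np.full((2, 4), 0.25)),
        alphabet=tables.alphabet,
    )


def discriminative_advantage_experiment(
    seeds=range(5),
    n_train: int = 30,
    n_test: int = 15,
    window: WindowSpec = WindowSpec(2, 2),
    hidden: int = 5,
    max_epochs: int = 50,
    base_seed: int = 0,
) -> dict:
    """HNN vs CHMM on the context-dependent generator.

    For each seed: draw train/test sets, fit the CHMM by labeled Baum-Welch
    and the HNN by per-label initialization + joint CML (early stopping on a
    held-back split), then compare held-out Q2 and per-residue conditional
    negative log-likelihood.  Returns per-seed values and medians.
    """
    tables = default_context_tables()
    rows = []
    for seed in seeds:
        train = sample(GeneratorSpec(kind="context", context=tables, n=n_train,
                                     seed=base_seed + 100 + seed))
        test = sample(GeneratorSpec(kind="context", context=tables, n=n_test,
                                    seed=base_seed + 200 + seed))
        labels_train = "".join(s.labels for s in train)
        majority = max(tables.label_set, key=labels_train.count)
        maj_q2 = float(np.mean([c == majority for s in test for c in s.labels]))

        chmm, _ = baum_welch_labeled(context_chmm_grammar(), train)
        cfg = TrainConfig(max_epochs=max_epochs, seed=base_seed + seed)
        hnn_model = attach_networks(context_chmm_grammar(), window, hidden,
                                    seed=base_seed + seed)
        hnn_model.emissions = init_networks(train, hnn_model, cfg)
        hnn_model, log = train_hnn(hnn_model, train, cfg)

        n_res = sum(len(s) for s in test)
        row = {"seed": seed, "majority_q2": maj_q2, "epochs_run": len(log) - 1}
        for name, model in (("chmm", chmm), ("hnn", hnn_model)):
            q2s = [q2(s.labels, posterior_label_decode(model, s).labels, "M")
                   for s in test]
            row[f"{name}_q2"] = float(np.mean(q2s))
            row[f"{name}_nll_per_residue"] = float(
                sum(cml_loss(model, s).loss for s in test) / n_res
            )
        rows.append(row)
    out = {"per_seed": rows}
    for key in ("majority_q2", "chmm_q2", "hnn_q2",
                "chmm_nll_per_residue", "hnn_nll_per_residue"):
        out[f"median_{key}"] = float(np.median([r[key] for r in rows]))
    return out


def baum_welch_recovery_experiment(seed: int = 42, n: int = 300) -> dict:
    """Parameter recovery of the toy grammar from its own samples.

    Starts labeled Baum-Welch from uniform allowed parameters and reports the
    maximum absolute error of the recovered transitions and (tied) emissions
    against the generating values, plus the per-iteration log-joint history.
    """
    truth = toy_topology_model()
    data = sample(GeneratorSpec(kind="chmm", model=truth, n=n,
                                min_len=60, max_len=120, seed=seed))
    init = truth.copy()
    init.trans = np.where(truth.trans_mask, 1.0, 0.0)
    init.trans /= init.trans.sum(axis=1, keepdims=True)
    init.begin = np.where(truth.begin_mask, 1.0, 0.0)
    init.begin /= init.begin.sum()
    init.emissions.probs[:] = 1.0 / truth.alphabet.size
    fit, history = baum_welch_labeled(init, data)
    return {
        "history": history,
        "max_abs_error_transitions": float(np.abs(fit.trans - truth.trans).max()),
        "max_abs_error_emissions": float(
            np.abs(fit.emissions.probs - truth.emissions.probs).max()
        ),
        "n_iterations": len(history),
    }


def discrimination_experiment(seed: int = 0, n_pos: int = 25, n_neg: int = 25) -> dict:
    """Membrane-vs-globular discrimination on separable synthetic generators.

    Positives come from the toy transmembrane grammar; negatives from a
    single-state background with a blended (membrane-free) composition.
    Reports cross-validated sensitivity/specificity/MCC of the six-feature
    logistic classifier.
    """
    model = toy_topology_model()
    alpha = model.alphabet
    pos = sample(GeneratorSpec(kind="chmm", model=model, n=n_pos,
                               min_len=60, max_len=120, seed=seed + 21))
    rows = model.emissions.probs
    blend = 0.55 * rows[0] + 0.25 * rows[1] + 0.20 * rows[2]
    neg_model = TopologyModel(
        states=["g"], label_set=["i"], state_labels=["i"],
        begin=np.array([1.0]), trans=np.array([[1.0]]),
        emissions=EmissionTable(blend[None, :]), alphabet=alpha,
    )
    neg = sample(GeneratorSpec(kind="chmm", model=neg_model, n=n_neg,
                               min_len=60, max_len=120, seed=seed + 22))
    trained, _ = baum_welch_labeled(model, pos)
    null = null_model_from_data(pos + neg, alpha)
    feats, ys = [], []
    for seq, y in [(s, 1) for s in pos] + [(s, 0) for s in neg]:
        plain = LabeledSequence(seq.id, seq.residues, None, alpha)
        pred = posterior_label_decode(trained, plain)
        fv = extract_features(trained, null, plain, pred, ["M"], "beta-six")
        if fv is not None:
            feats.append(fv)
            ys.append(y)
    return cross_validated_stats(feats, ys, n_folds=5, seed=seed)
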