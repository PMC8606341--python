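"""Membrane-vs-non-membrane discrimination from model-derived features.

A topology model scores every sequence; a handful of summary features of the
score and the decoded prediction feed a regularized logistic regression.
Two documented feature subsets exist: ``beta-six`` (sequence length, log-odds,
per-residue log-probability, reliability, number of TM segments, TM ratio)
and ``alpha-seven`` (length, log-odds, max probability, decoder score,
reliability, number of TM segments, TM ratio).

The log-odds null is a single-state background model whose emissions are the
residue frequencies of the training data (self-transition 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .chmm_core import EmissionTable, TopologyModel, forward
from .decoding import Prediction, segments
from .metrics import binary_stats
from .seqdata import Alphabet, LabeledSequence, Profile

FEATURES_BETA = [
    "sequence_length", "log_odds", "log_probability",
    "reliability", "n_tm_segments", "tm_ratio",
]
FEATURES_ALPHA = [
    "sequence_length", "log_odds", "max_probability", "decoder_score",
    "reliability", "n_tm_segments", "tm_ratio",
]
_SUBSETS = {"beta-six": FEATURES_BETA, "alpha-seven": FEATURES_ALPHA}


@dataclass
class FeatureVector:
    """Model-derived summary features for one sequence."""

    id: str
    sequence_length: int
    log_odds: float          # log P_model(x) − log P_null(x), natural log
    log_probability: float   # log P_model(x) / L (per-residue)
    max_probability: float
    decoder_score: float
    reliability: float
    n_tm_segments: int
    tm_ratio: float
    subset: str = "beta-six"

    def values(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _SUBSETS[self.subset]], dtype=float)


def null_model_from_data(
    data: Sequence[LabeledSequence], alphabet: Optional[Alphabet] = None
) -> TopologyModel:
    """Single-state background model with training-set residue frequencies."""
    alphabet = alphabet or (data[0].alphabet if data else Alphabet())
    counts = np.ones(alphabet.size)  # +1 smoothing keeps every symbol scoreable
    for seq in data:
        known = seq.residues >= 0
        np.add.at(counts, seq.residues[known], 1.0)
    return TopologyModel(
        states=["bg"],
        label_set=["."],
        state_labels=["."],
        begin=np.array([1.0]),
        trans=np.array([[1.0]]),
        emissions=EmissionTable(probs=(counts / counts.sum())[None, :]),
        alphabet=alphabet,
    )


def extract_features(
    model: TopologyModel,
    null_model: TopologyModel,
    seq: LabeledSequence,
    prediction: Prediction,
    tm_labels: Iterable[str],
    subset: str = "beta-six",
    profile: Optional[Profile] = None,
) -> Optional[FeatureVector]:
    """Feature vector for one sequence, or ``None`` (with a warning) when the
    model assigns the sequence a −inf score."""
    if subset not in _SUBSETS:
        raise ValueError(f"unknown feature subset {subset!r}")
    lp = prediction.log_likelihood
    ft_null = forward(null_model, seq)
    if not np.isfinite(lp) or not ft_null.ok:
        warnings.warn(f"sequence {seq.id!r} excluded: infinite model score")
        return None
    tm = set(tm_labels)
    L = len(seq)
    segs = [s for s in segments(prediction.labels) if s[2] in tm]
    n_tm_res = sum(e - s + 1 for s, e, _ in segs)
    return FeatureVector(
        id=seq.id,
        sequence_length=L,
        log_odds=lp - ft_null.log_likelihood,
        log_probability=lp / L,
        max_probability=prediction.max_probability,
        decoder_score=prediction.score,
        reliability=prediction.reliability,
        n_tm_segments=len(segs),
        tm_ratio=n_tm_res / L,
        subset=subset,
    )


@dataclass
class Classifier:
    """Standardized logistic regression with its scaling parameters."""

    subset: str
    mean: np.ndarray
    std: np.ndarray
    coef: np.ndarray
    intercept: float

    def probability(self, fv: FeatureVector) -> float:
        if fv.subset != self.subset:
            raise ValueError(f"feature subset mismatch: {fv.subset} vs {self.subset}")
        z = (fv.values() - self.mean) / self.std
        t = float(z @ self.coef + self.intercept)
        return float(1.0 / (1.0 + np.exp(-t)))


def fit_logistic(
    features: Sequence[FeatureVector],
    class_labels: Sequence[int],
    ridge: float = 1e-6,
) -> Classifier:
    """Maximum-likelihood logistic fit on standardized features (L2 ridge for
    stability).  Raises on single-class input."""
    y = np.asarray(class_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to fit a classifier")
    subset = features[0].subset
    X = np.vstack([f.values() for f in features])
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Z = (X - mean) / std
    lr = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=2000, tol=1e-10)
    lr.fit(Z, y)
    return Classifier(subset, mean, std, lr.coef_[0].copy(), float(lr.intercept_[0]))


def classify(
    classifier: Classifier, fv: FeatureVector, threshold: float = 0.5
) -> tuple[float, int]:
    """Membership probability and thresholded decision for one feature vector."""
    p = classifier.probability(fv)
    return p, int(p >= threshold)


def cross_validated_stats(
    features: Sequence[FeatureVector],
    class_labels: Sequence[int],
    n_folds: int = 5,
    seed: int = 0,
    ridge: float = 1e-6,
) -> dict:
    """Stratification-free k-fold CV returning pooled sensitivity/specificity/MCC."""
    y = np.asarray(class_labels, dtype=int)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    folds = np.array_split(idx, n_folds)
    tp = fp = tn = fn = 0
    for i in range(n_folds):
        test = folds[i]
        train = np.concatenate([folds[j] for j in range(n_folds) if j != i])
        clf = fit_logistic([features[j] for j in train], y[train], ridge)
        for j in test:
            _, pred = classify(clf, features[j])
            if y[j] == 1 and pred == 1:
                tp += 1
            elif y[j] == 1:
                fn += 1
            elif pred == 1:
                fp += 1
            else:
                tn += 1
    out = binary_stats(tp, fp, tn, fn)
    out.update({"tp": tp, "fp": fp, "tn": tn, "fn": fn})
    return out
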