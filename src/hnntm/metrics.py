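"""Topology evaluation metrics: Q2, SOV, topology correctness, MCC.

All segment metrics operate on a two-state projection of the label alphabet:
a set of labels counts as "membrane" (TM) and everything else as non-TM.
SOV follows the 1999 revision (length-weighted, with the δ allowance term),
computed over both projected classes and normalized jointly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .decoding import segments


def _project(labels: str, tm_labels: Iterable[str]) -> np.ndarray:
    tm = set(tm_labels)
    return np.array([c in tm for c in labels], dtype=bool)


def _check_lengths(ref: str, pred: str) -> None:
    if len(ref) != len(pred):
        raise ValueError(f"length mismatch: reference {len(ref)} vs predicted {len(pred)}")


def q2(ref: str, pred: str, tm_labels: Iterable[str]) -> float:
    """Fraction of residues agreeing in the two-state (TM / non-TM) projection."""
    _check_lengths(ref, pred)
    return float(np.mean(_project(ref, tm_labels) == _project(pred, tm_labels)))


def _binary_segments(mask: np.ndarray, value: bool) -> list[tuple[int, int]]:
    segs = []
    start = None
    for i, v in enumerate(mask):
        if (v == value) and start is None:
            start = i
        elif (v != value) and start is not None:
            segs.append((start + 1, i))
            start = None
    if start is not None:
        segs.append((start + 1, len(mask)))
    return segs


def sov(ref: str, pred: str, tm_labels: Iterable[str]) -> float:
    """Segment overlap score (1999 definition) on the two-state projection.

    For each projected class, reference segments s1 are paired with every
    overlapping predicted segment s2 and contribute
    ``len(s1)·(minov + δ)/maxov`` with
    ``δ = min(maxov − minov, minov, ⌊len(s1)/2⌋, ⌊len(s2)/2⌋)``;
    reference segments with no overlap contribute only to the normalizer.
    Both classes are pooled into a single length-weighted normalization.
    """
    _check_lengths(ref, pred)
    rmask = _project(ref, tm_labels)
    pmask = _project(pred, tm_labels)
    num = 0.0
    denom = 0.0
    for value in (True, False):
        rsegs = _binary_segments(rmask, value)
        psegs = _binary_segments(pmask, value)
        for r1, r2 in rsegs:
            len1 = r2 - r1 + 1
            overlaps = [(p1, p2) for p1, p2 in psegs if p1 <= r2 and p2 >= r1]
            if not overlaps:
                denom += len1
                continue
            denom += len1 * len(overlaps)
            for p1, p2 in overlaps:
                len2 = p2 - p1 + 1
                minov = min(r2, p2) - max(r1, p1) + 1
                maxov = max(r2, p2) - min(r1, p1) + 1
                delta = min(maxov - minov, minov, len1 // 2, len2 // 2)
                num += len1 * (minov + delta) / maxov
    if denom == 0:
        return 0.0
    return float(min(1.0, num / denom))


def _loop_side(labels: str, start: int, end: int) -> str:
    """Majority label of a loop segment (1-based closed interval); ties break
    toward the earlier-appearing label."""
    counts = Counter(labels[start - 1 : end])
    top = max(counts.values())
    for c in labels[start - 1 : end]:
        if counts[c] == top:
            return c
    return labels[start - 1]


def topology_correct(
    ref: str,
    pred: str,
    tm_labels: Iterable[str],
    mode: str = "alpha",
    min_overlap: int = 1,
) -> bool:
    """Whole-protein topology criterion.

    True iff the number of TM segments matches, the k-th predicted TM segment
    overlaps the k-th reference TM segment by at least ``min_overlap``
    residues, and (``mode="alpha"``) the sidedness label of every connecting
    loop — termini included — matches.  ``mode="beta"`` checks counts and
    in-order overlaps only.
    """
    _check_lengths(ref, pred)
    rmask = _project(ref, tm_labels)
    pmask = _project(pred, tm_labels)
    rsegs = _binary_segments(rmask, True)
    psegs = _binary_segments(pmask, True)
    if len(rsegs) != len(psegs):
        return False
    for (r1, r2), (p1, p2) in zip(rsegs, psegs):
        ov = min(r2, p2) - max(r1, p1) + 1
        if ov < min_overlap:
            return False
    if mode == "alpha":
        rloops = _binary_segments(rmask, False)
        ploops = _binary_segments(pmask, False)
        if len(rloops) != len(ploops):
            return False
        for (r1, r2), (p1, p2) in zip(rloops, ploops):
            if _loop_side(ref, r1, r2) != _loop_side(pred, p1, p2):
                return False
    return True


def strand_count_correct(ref: str, pred: str, tm_labels: Iterable[str]) -> bool:
    """True iff reference and prediction have the same number of TM segments."""
    _check_lengths(ref, pred)
    n_ref = len(_binary_segments(_project(ref, tm_labels), True))
    n_pred = len(_binary_segments(_project(pred, tm_labels), True))
    return n_ref == n_pred


def binary_stats(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Sensitivity, specificity and MCC; MCC is 0 when a denominator factor is 0."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be nonnegative")
    if tp + fp + tn + fn == 0:
        raise ValueError("all counts are zero")
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return {"sensitivity": float(sens), "specificity": float(spec), "mcc": float(mcc)}


@dataclass
class EvalReport:
    """Per-protein metrics table plus aggregate summary.

    ``table`` columns: id, length, q2, sov, topology_correct,
    segment_count_correct, n_tm_ref, n_tm_pred.
    """

    table: pd.DataFrame
    tm_labels: list[str]
    mode: str

    @property
    def aggregate(self) -> dict:
        t = self.table
        return {
            "n_proteins": int(len(t)),
            "mean_q2": float(t["q2"].mean()),
            "mean_sov": float(t["sov"].mean()),
            "residue_weighted_q2": float(
                (t["q2"] * t["length"]).sum() / t["length"].sum()
            ),
            "n_topology_correct": int(t["topology_correct"].sum()),
            "n_segment_count_correct": int(t["segment_count_correct"].sum()),
        }

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# per-protein topology metrics (positions are 1-based closed intervals)\n")
            fh.write(f"# projection: TM labels = {','.join(self.tm_labels)}; mode = {self.mode}\n")
            self.table.to_csv(fh, sep="\t", index=False)
            fh.write("#\n# aggregate\n")
            for k, v in self.aggregate.items():
                fh.write(f"# {k}\t{v}\n")


def evaluate_dataset(
    refs: Sequence,
    pred_labels: Sequence[str],
    tm_labels: Iterable[str],
    mode: str = "alpha",
) -> EvalReport:
    """Evaluate predicted labelings against labeled reference sequences."""
    rows = []
    tm = list(tm_labels)
    for ref_seq, pred in zip(refs, pred_labels):
        ref = ref_seq.labels
        rows.append(
            {
                "id": ref_seq.id,
                "length": len(ref),
                "q2": q2(ref, pred, tm),
                "sov": sov(ref, pred, tm),
                "topology_correct": topology_correct(ref, pred, tm, mode),
                "segment_count_correct": strand_count_correct(ref, pred, tm),
                "n_tm_ref": len(_binary_segments(_project(ref, tm), True)),
                "n_tm_pred": len(_binary_segments(_project(pred, tm), True)),
            }
        )
    return EvalReport(pd.DataFrame(rows), tm, mode)
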