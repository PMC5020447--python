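"""Evaluation statistics for 3-state secondary-structure predictions.

Residue-level scores (Q3, per-class Q, per-class one-vs-rest Matthews
correlation, helix/strand confusion rate) are derived from a 3x3
confusion matrix with observed states in rows and predicted states in
columns, both ordered H, E, C.  Segment-level agreement uses the 1999
revision of the segment-overlap (SOV) score: maximal same-state runs
are matched between observed and predicted strings and each
overlapping pair is credited with an allowance term delta that rewards
approximately-placed segments without ever exceeding the exact-match
credit.  Multi-chain scoring pools residues across chains for the
residue-level scores and accumulates per-chain SOV numerators and
normalizers — segments never merge across chain boundaries.

Percentages are held at full precision; rounding to the customary two
decimals is display-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chains import SS3_STATES

__all__ = [
    "ConfusionMatrix3",
    "confusion",
    "q3",
    "q_class",
    "mcc_class",
    "q_he_error",
    "sov",
    "MetricsReport",
    "score_chains",
]

_IDX = {s: i for i, s in enumerate(SS3_STATES)}


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 observed-vs-predicted counts, rows/columns ordered H, E, C."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (3, 3):
            raise ValueError(f"confusion matrix must be 3x3, got {c.shape}")
        if (c < 0).any():
            raise ValueError("confusion matrix cells must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, key: tuple[str, str]) -> int:
        obs, pred = key
        return int(self.counts[_IDX[obs], _IDX[pred]])

    def __add__(self, other: "ConfusionMatrix3") -> "ConfusionMatrix3":
        return ConfusionMatrix3(self.counts + other.counts)


def _as_counts(cm) -> np.ndarray:
    if isinstance(cm, ConfusionMatrix3):
        return cm.counts
    return ConfusionMatrix3(np.asarray(cm)).counts


def confusion(observed: str, predicted: str) -> ConfusionMatrix3:
    """Count (observed, predicted) state pairs position by position."""
    if len(observed) != len(predicted):
        raise ValueError(
            f"length mismatch: observed {len(observed)} vs predicted {len(predicted)}"
        )
    counts = np.zeros((3, 3), dtype=np.int64)
    for o, p in zip(observed, predicted):
        try:
            counts[_IDX[o], _IDX[p]] += 1
        except KeyError:
            bad = o if o not in _IDX else p
            raise ValueError(f"symbol {bad!r} outside the HEC alphabet") from None
    return ConfusionMatrix3(counts)


def q3(cm) -> float:
    """Overall residue accuracy: 100 * trace / total."""
    c = _as_counts(cm)
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * np.trace(c) / total


def q_class(cm, j: str) -> float | None:
    """Per-class accuracy 100 * cm[j, j] / row_sum(j); None if class absent."""
    c = _as_counts(cm)
    row = c[_IDX[j]]
    if row.sum() == 0:
        return None
    return 100.0 * row[_IDX[j]] / row.sum()


def mcc_class(cm, j: str) -> float:
    """One-vs-rest Matthews correlation for state j.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); the value is
    0 by convention whenever a denominator factor vanishes.
    """
    c = _as_counts(cm).astype(float)
    i = _IDX[j]
    tp = c[i, i]
    fn = c[i].sum() - tp
    fp = c[:, i].sum() - tp
    tn = c.sum() - tp - fn - fp
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def q_he_error(cm) -> float:
    """Helix/strand cross-misprediction rate: 100*(cm[H,E]+cm[E,H])/total."""
    c = _as_counts(cm)
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * (c[_IDX["H"], _IDX["E"]] + c[_IDX["E"], _IDX["H"]]) / total


# ----------------------------------------------------------------------
# Segment overlap (SOV), 1999 revision


def _segments(s: str, state: str) -> list[tuple[int, int]]:
    """Maximal runs of ``state`` in ``s`` as (start, end) inclusive."""
    segs = []
    start = None
    for i, sym in enumerate(s):
        if sym == state and start is None:
            start = i
        elif sym != state and start is not None:
            segs.append((start, i - 1))
            start = None
    if start is not None:
        segs.append((start, len(s) - 1))
    return segs


def _sov_parts(observed: str, predicted: str, state: str) -> tuple[float, float]:
    """(numerator, normalizer) of the SOV sum for one state in one chain."""
    if len(observed) != len(predicted):
        raise ValueError(
            f"length mismatch: observed {len(observed)} vs predicted {len(predicted)}"
        )
    num = 0.0
    norm = 0.0
    pred_segs = _segments(predicted, state)
    for b1, e1 in _segments(observed, state):
        len1 = e1 - b1 + 1
        overlapped = False
        for b2, e2 in pred_segs:
            minov = min(e1, e2) - max(b1, b2) + 1
            if minov <= 0:
                continue
            overlapped = True
            maxov = max(e1, e2) - min(b1, b2) + 1
            len2 = e2 - b2 + 1
            delta = min(maxov - minov, minov, len1 // 2, len2 // 2)
            num += len1 * (minov + delta) / maxov
            norm += len1
        if not overlapped:
            norm += len1
    return num, norm


def sov(
    observed: str | Sequence[str],
    predicted: str | Sequence[str],
    states: Iterable[str] = SS3_STATES,
) -> float | None:
    """Segment-overlap score over the given states, in percent.

    ``observed``/``predicted`` may be single strings or parallel
    sequences of per-chain strings; chains are scored independently
    (segments never span a chain boundary) and their numerators and
    normalizers pooled.  Returns None when no observed segment of any
    requested state exists.
    """
    if isinstance(observed, str):
        observed, predicted = [observed], [predicted]  # type: ignore[list-item]
    if len(observed) != len(predicted):
        raise ValueError("observed and predicted chain counts differ")
    num = 0.0
    norm = 0.0
    for obs, pred in zip(observed, predicted):
        for state in states:
            n, d = _sov_parts(obs, pred, state)
            num += n
            norm += d
    if norm == 0:
        return None
    return 100.0 * num / norm


# ----------------------------------------------------------------------


@dataclass(frozen=True)
class MetricsReport:
    """Full score panel for one evaluation; per-class values may be None
    when the class is absent from the observed strings."""

    q3: float
    q_H: float | None
    q_E: float | None
    q_C: float | None
    sov: float | None
    sov_H: float | None
    sov_E: float | None
    sov_C: float | None
    mcc_H: float
    mcc_E: float
    mcc_C: float
    q_he_error: float
    confusion: ConfusionMatrix3

    def as_dict(self) -> dict:
        out = {}
        for key in (
            "q3", "q_H", "q_E", "q_C", "sov", "sov_H", "sov_E", "sov_C",
            "mcc_H", "mcc_E", "mcc_C", "q_he_error",
        ):
            out[key] = getattr(self, key)
        return out

    def __str__(self) -> str:
        def fmt(v):
            return "  --" if v is None else f"{v:.2f}"

        return (
            f"Q3 {fmt(self.q3)}  QH {fmt(self.q_H)}  QE {fmt(self.q_E)}  "
            f"QC {fmt(self.q_C)}\n"
            f"SOV {fmt(self.sov)}  SOVH {fmt(self.sov_H)}  "
            f"SOVE {fmt(self.sov_E)}  SOVC {fmt(self.sov_C)}\n"
            f"MCCH {self.mcc_H:.2f}  MCCE {self.mcc_E:.2f}  "
            f"MCCC {self.mcc_C:.2f}  QHEerr {fmt(self.q_he_error)}"
        )


def score_chains(
    pairs: Sequence[tuple[str, str]] | Mapping[str, tuple[str, str]],
) -> MetricsReport:
    """Score a set of (observed, predicted) chain pairs.

    Residues are pooled across chains for the confusion-matrix scores;
    SOV accumulates per-chain segment sums.  ``pairs`` is a sequence of
    (observed, predicted) tuples or a mapping chain_id -> pair.
    """
    if isinstance(pairs, Mapping):
        items = list(pairs.items())
    else:
        items = [(str(i), p) for i, p in enumerate(pairs)]
    if not items:
        raise ValueError("no chain pairs to score")

    counts = np.zeros((3, 3), dtype=np.int64)
    obs_list, pred_list = [], []
    for cid, (obs, pred) in items:
        if len(obs) != len(pred):
            raise ValueError(
                f"chain {cid!r}: observed length {len(obs)} != "
                f"predicted length {len(pred)}"
            )
        counts += confusion(obs, pred).counts
        obs_list.append(obs)
        pred_list.append(pred)
    cm = ConfusionMatrix3(counts)
    return MetricsReport(
        q3=q3(cm),
        q_H=q_class(cm, "H"),
        q_E=q_class(cm, "E"),
        q_C=q_class(cm, "C"),
        sov=sov(obs_list, pred_list),
        sov_H=sov(obs_list, pred_list, states=["H"]),
        sov_E=sov(obs_list, pred_list, states=["E"]),
        sov_C=sov(obs_list, pred_list, states=["C"]),
        mcc_H=mcc_class(cm, "H"),
        mcc_E=mcc_class(cm, "E"),
        mcc_C=mcc_class(cm, "C"),
        q_he_error=q_he_error(cm),
        confusion=cm,
    )
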