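"""Threshold-conditioned recognizer metrics.

Implements the detection confusion outcomes, precision/sensitivity,
ROC/AUROC with Youden's J threshold selection, and the multi-syllable
subsampling penalty.

Two deliberately different denominators are in play: ROC positives and
negatives are *verified matches* (TP vs FP), while conditional sensitivity
divides retained TP matches by the number of *true calls* — so sensitivity
can exceed 1 when several syllable-level hits land on one multi-syllable
call.  True negatives are uncountable in open audio; they are
operationalized as verified-FP matches scoring below the threshold (the
discrimination task over scored candidates).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .recognizer import Match
from .scenes import TrueCall

__all__ = [
    "ConfusionCounts",
    "ROCCurve",
    "ConditionalMetrics",
    "label_matches",
    "confusion_at_threshold",
    "point_metrics",
    "roc_and_threshold",
    "conditional_metrics",
    "subsample_penalty",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray  # descending unique observed scores
    tpr: np.ndarray
    tnr: np.ndarray
    auroc: float
    youden_j: np.ndarray
    optimal_threshold: float


@dataclass(frozen=True)
class ConditionalMetrics:
    threshold: float
    precision: float | None
    sensitivity: float | None
    penalized_precision: float | None = None
    penalized_sensitivity: float | None = None
    n_reps: int | None = None

    @property
    def type1_error(self) -> float | None:
        return None if self.precision is None else 1.0 - self.precision

    @property
    def type2_error(self) -> float | None:
        return None if self.sensitivity is None else 1.0 - self.sensitivity


def _overlaps(m: Match, c: TrueCall) -> bool:
    return (
        m.recording_id == c.recording_id
        and m.start_s < c.end_s
        and m.end_s > c.start_s
    )


def label_matches(
    matches: list[Match],
    annotations: list[TrueCall],
    matching_mode: str = "per-match",
    recording_ids: set[str] | None = None,
) -> list[Match]:
    """Verify matches against ground truth by temporal overlap.

    ``per-match`` (default): every match overlapping any true call is a TP —
    many-to-one, reproducing sensitivity > 1 on multi-syllable calls.
    ``per-call``: greedy one-to-one by descending score; surplus matches on an
    already-claimed call become FPs.  When ``recording_ids`` gives the
    recording universe, matches outside it are rejected (a match in a known
    but call-free recording is simply an FP).
    """
    if matching_mode not in ("per-match", "per-call"):
        raise ValueError("matching_mode must be 'per-match' or 'per-call'")
    if recording_ids is not None:
        for m in matches:
            if m.recording_id not in recording_ids:
                raise ValueError(
                    f"match references unknown recording {m.recording_id!r}"
                )

    if matching_mode == "per-match":
        return [
            dataclasses.replace(
                m, label="TP" if any(_overlaps(m, c) for c in annotations) else "FP"
            )
            for m in matches
        ]

    # per-call: greedy by score, each call claimable once
    order = sorted(range(len(matches)), key=lambda i: -matches[i].score)
    claimed: set[int] = set()
    labels = ["FP"] * len(matches)
    for i in order:
        for j, c in enumerate(annotations):
            if j not in claimed and _overlaps(matches[i], c):
                claimed.add(j)
                labels[i] = "TP"
                break
    return [dataclasses.replace(m, label=lab) for m, lab in zip(matches, labels)]


def _require_verified(matches: list[Match]) -> None:
    for m in matches:
        if m.label not in ("TP", "FP"):
            raise ValueError("matches must be verified (label TP or FP)")


def confusion_at_threshold(
    labeled: list[Match], annotations: list[TrueCall], t: float
) -> ConfusionCounts:
    """Confusion counts at score threshold ``t``.

    fn counts annotated calls not overlapped by any retained TP; tn counts
    verified-FP matches scoring below the threshold.
    """
    _require_verified(labeled)
    tp = sum(1 for m in labeled if m.label == "TP" and m.score >= t)
    fp = sum(1 for m in labeled if m.label == "FP" and m.score >= t)
    tn = sum(1 for m in labeled if m.label == "FP" and m.score < t)
    retained_tp = [m for m in labeled if m.label == "TP" and m.score >= t]
    n_hit = sum(1 for c in annotations if any(_overlaps(m, c) for m in retained_tp))
    fn = max(0, len(annotations) - n_hit)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def point_metrics(
    counts: ConfusionCounts, n_calls: int
) -> tuple[float | None, float | None]:
    """(precision, sensitivity); ``None`` marks an undefined metric.

    Sensitivity divides retained TP matches by ALL true calls, so it can
    exceed 1 under per-match labeling.
    """
    precision = None if counts.tp + counts.fp == 0 else counts.tp / (counts.tp + counts.fp)
    sensitivity = None if n_calls <= 0 else counts.tp / n_calls
    return precision, sensitivity


def _roc_arrays(tp_scores: np.ndarray, fp_scores: np.ndarray, tie_break: str = "highest"):
    thresholds = np.unique(np.concatenate([tp_scores, fp_scores]))[::-1]
    tp_sorted = np.sort(tp_scores)
    fp_sorted = np.sort(fp_scores)
    n_tp, n_fp = len(tp_scores), len(fp_scores)
    tpr = (n_tp - np.searchsorted(tp_sorted, thresholds, side="left")) / n_tp
    tnr = np.searchsorted(fp_sorted, thresholds, side="left") / n_fp
    j = tpr + tnr - 1.0
    best = np.flatnonzero(j == j.max())
    # thresholds are descending, so index 0 of the maximizers is the highest
    opt = float(thresholds[best[0]] if tie_break == "highest" else thresholds[best[-1]])
    fpr = 1.0 - tnr
    auroc = float(np.trapezoid(np.concatenate([[0.0], tpr]), np.concatenate([[0.0], fpr])))
    return thresholds, tpr, tnr, j, opt, auroc


def roc_and_threshold(labeled: list[Match], tie_break: str = "highest") -> ROCCurve:
    """ROC over verified match scores; optimal threshold by Youden's J.

    Candidate thresholds are the unique observed scores; J = tpr + tnr - 1.
    Ties in J resolve to the highest threshold by default (favors precision).
    """
    if tie_break not in ("highest", "lowest"):
        raise ValueError("tie_break must be 'highest' or 'lowest'")
    _require_verified(labeled)
    tp_scores = np.array([m.score for m in labeled if m.label == "TP"], dtype=float)
    fp_scores = np.array([m.score for m in labeled if m.label == "FP"], dtype=float)
    if len(tp_scores) == 0 or len(fp_scores) == 0:
        raise ValueError("ROC requires at least one TP and one FP match")
    thresholds, tpr, tnr, j, opt, auroc = _roc_arrays(tp_scores, fp_scores, tie_break)
    return ROCCurve(
        thresholds=thresholds,
        tpr=tpr,
        tnr=tnr,
        auroc=auroc,
        youden_j=j,
        optimal_threshold=opt,
    )


def conditional_metrics(
    labeled: list[Match], annotations: list[TrueCall], t_star: float
) -> ConditionalMetrics:
    """Precision and sensitivity conditioned on the ROC-chosen threshold."""
    counts = confusion_at_threshold(labeled, annotations, t_star)
    precision, sensitivity = point_metrics(counts, len(annotations))
    return ConditionalMetrics(threshold=t_star, precision=precision, sensitivity=sensitivity)


def _youden_threshold_or_fallback(tp_scores: np.ndarray, fp_scores: np.ndarray) -> float:
    """Youden threshold; with no FPs fall back to keeping every TP."""
    if len(fp_scores) == 0:
        return float(tp_scores.min()) if len(tp_scores) else 0.0
    if len(tp_scores) == 0:
        return float(fp_scores.max()) + 1.0
    return _roc_arrays(tp_scores, fp_scores)[4]


def subsample_penalty(
    labeled: list[Match],
    annotations: list[TrueCall],
    n_reps: int = 1000,
    seed: int | None = None,
    *,
    recompute_threshold: bool = True,
) -> ConditionalMetrics:
    """Multi-syllable subsampling penalty.

    Per repetition, at most N TP matches are retained (N = number of true
    calls; uniform sample without replacement when there are more), all FPs
    are kept, the ROC threshold is recomputed on the reduced set, and the
    conditional metrics are recomputed; the reported penalized metrics are
    means over repetitions.  Per-repetition sensitivity is <= 1 by
    construction.  With ``recompute_threshold=False`` the threshold from the
    full set is frozen across repetitions.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n_calls = len(annotations)
    if n_calls == 0:
        raise ValueError("subsample penalty undefined with zero true calls")
    _require_verified(labeled)
    tp_scores = np.array([m.score for m in labeled if m.label == "TP"], dtype=float)
    fp_scores = np.array([m.score for m in labeled if m.label == "FP"], dtype=float)

    full_t = _youden_threshold_or_fallback(tp_scores, fp_scores)
    base = conditional_metrics(labeled, annotations, full_t)

    if len(tp_scores) <= n_calls:
        # no subsampling branch: penalized metrics equal the unpenalized ones
        return dataclasses.replace(
            base,
            penalized_precision=base.precision,
            penalized_sensitivity=base.sensitivity,
            n_reps=n_reps,
        )

    rng = np.random.default_rng(seed)
    n_fp = len(fp_scores)
    prec_sum, prec_n = 0.0, 0
    sens_sum = 0.0
    thr_sum = 0.0
    for _ in range(n_reps):
        sub = rng.choice(tp_scores, size=n_calls, replace=False)
        t = (
            _youden_threshold_or_fallback(sub, fp_scores)
            if recompute_threshold
            else full_t
        )
        tp_ret = int(np.sum(sub >= t))
        fp_ret = int(np.sum(fp_scores >= t)) if n_fp else 0
        if tp_ret + fp_ret > 0:
            prec_sum += tp_ret / (tp_ret + fp_ret)
            prec_n += 1
        sens_sum += tp_ret / n_calls
        thr_sum += t
    return ConditionalMetrics(
        threshold=thr_sum / n_reps,
        precision=base.precision,
        sensitivity=base.sensitivity,
        penalized_precision=(prec_sum / prec_n) if prec_n else None,
        penalized_sensitivity=sens_sum / n_reps,
        n_reps=n_reps,
    )
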