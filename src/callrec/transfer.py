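"""Out-of-sample recognizer evaluation with frozen training thresholds.

Selected recognizers are applied to dataset groups whose provenance differs
from training (same sites/different year, different sites/same year, both
different, disjoint region) using the score thresholds determined on the
training data — never re-thresholded on test data.  Includes the
segment-based SNR estimator, BCa bootstrap confidence intervals and the
cumulative detection probability utility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .evaluation import conditional_metrics, label_matches
from .recognizer import RecognizerSettings, Template, detect
from .scenes import DatasetGroup, Recording, TrueCall

__all__ = [
    "SNREstimate",
    "BootstrapCI",
    "estimate_snr",
    "bootstrap_ci",
    "evaluate_transfer",
    "cumulative_detection",
]


@dataclass(frozen=True)
class SNREstimate:
    mean_signal_db: float
    mean_noise_db: float
    snr_db: float
    n_segments_per_group: int
    segment_s: float


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    lower: float
    upper: float
    n_reps: int
    method: str
    seed: int | None


def _segment_db(x: np.ndarray) -> float:
    return 20.0 * np.log10(np.sqrt(np.mean(x**2)) + 1e-30)


def estimate_snr(
    recording: Recording,
    annotations: list[TrueCall],
    n: int = 10,
    segment_s: float = 1.0,
    seed: int | None = None,
) -> SNREstimate:
    """Segment-based SNR: mean dB of n call-containing segments minus mean dB
    of n call-free segments, segments drawn without replacement from a
    disjoint grid."""
    fs = recording.sample_rate_hz
    x = recording.samples
    if x is None:
        raise ValueError("symbolic recording has no samples")
    seg_len = int(round(segment_s * fs))
    n_seg = len(x) // seg_len
    calls = [c for c in annotations if c.recording_id == recording.recording_id]
    has_call = np.zeros(n_seg, dtype=bool)
    for c in calls:
        lo = max(int(np.floor(c.start_s / segment_s)), 0)
        hi = min(int(np.ceil(c.end_s / segment_s)), n_seg)
        has_call[lo:hi] = True
    signal_idx = np.flatnonzero(has_call)
    noise_idx = np.flatnonzero(~has_call)
    if len(signal_idx) < n:
        raise ValueError(f"only {len(signal_idx)} call-containing segments, need {n}")
    if len(noise_idx) < n:
        raise ValueError(f"only {len(noise_idx)} call-free segments, need {n}")
    rng = np.random.default_rng(seed)
    sig_pick = rng.choice(signal_idx, size=n, replace=False)
    noi_pick = rng.choice(noise_idx, size=n, replace=False)
    sig_db = [_segment_db(x[i * seg_len : (i + 1) * seg_len]) for i in sig_pick]
    noi_db = [_segment_db(x[i * seg_len : (i + 1) * seg_len]) for i in noi_pick]
    ms, mn = float(np.mean(sig_db)), float(np.mean(noi_db))
    return SNREstimate(
        mean_signal_db=ms,
        mean_noise_db=mn,
        snr_db=ms - mn,
        n_segments_per_group=n,
        segment_s=segment_s,
    )


def bootstrap_ci(
    values,
    n_reps: int = 2000,
    method: str = "bca",
    seed: int | None = None,
    confidence_level: float = 0.95,
) -> BootstrapCI:
    """Bootstrap CI of the mean (BCa by default, percentile fallback)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("bootstrap requires at least 2 values")
    if method not in ("bca", "percentile"):
        raise ValueError("method must be 'bca' or 'percentile'")
    point = float(values.mean())
    if np.ptp(values) == 0.0:
        # degenerate sample: acceleration undefined, interval collapses
        return BootstrapCI(point, point, point, n_reps, "degenerate", seed)
    rng = np.random.default_rng(seed)
    scipy_method = "BCa" if method == "bca" else "percentile"
    res = _st.bootstrap(
        (values,),
        np.mean,
        n_resamples=n_reps,
        confidence_level=confidence_level,
        method=scipy_method,
        random_state=rng,
    )
    lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    if not np.isfinite(lo) or not np.isfinite(hi):
        res = _st.bootstrap(
            (values,),
            np.mean,
            n_resamples=n_reps,
            confidence_level=confidence_level,
            method="percentile",
            random_state=np.random.default_rng(seed),
        )
        lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
        method = "percentile"
    return BootstrapCI(point, lo, hi, n_reps, method, seed)


def _recording_metrics(
    rec: Recording,
    calls: list[TrueCall],
    template: Template,
    settings: RecognizerSettings,
    threshold: float,
    matching_mode: str,
):
    matches = detect(rec, template, settings)
    if not calls:
        n_ret = sum(1 for m in matches if m.score >= threshold)
        # no calls: every retained match is an FP; sensitivity undefined
        return (0.0 if n_ret else None), None
    labeled = label_matches(matches, calls, matching_mode)
    cm = conditional_metrics(labeled, calls, threshold)
    return cm.precision, cm.sensitivity


def evaluate_transfer(
    recognizers,
    groups: list[DatasetGroup],
    *,
    n_boot: int = 2000,
    seed: int = 0,
    matching_mode: str = "per-match",
) -> pd.DataFrame:
    """Evaluate selected recognizers on dataset groups at frozen thresholds.

    ``recognizers`` is a list of (name, settings, template, threshold)
    tuples; the thresholds must come from the training data (they are never
    recomputed here).  Returns one row per recognizer x group with group-mean
    precision/sensitivity over recording-level metrics plus BCa bootstrap
    CIs (the bootstrap unit is the recording).
    """
    rows = []
    for rec_idx, (name, settings, template, threshold) in enumerate(recognizers):
        if threshold is None:
            raise ValueError(f"recognizer {name!r} has no training-derived threshold")
        for grp in groups:
            by_rec: dict[str, list[TrueCall]] = {}
            for c in grp.calls:
                by_rec.setdefault(c.recording_id, []).append(c)
            precs, senss = [], []
            for rec in grp.recordings:
                p, s = _recording_metrics(
                    rec, by_rec.get(rec.recording_id, []), template, settings,
                    threshold, matching_mode,
                )
                if p is not None:
                    precs.append(p)
                if s is not None:
                    senss.append(s)
            row = {
                "recognizer": name,
                "group": grp.label,
                "threshold": threshold,
                "n_recordings": len(grp.recordings),
                "precision": float(np.mean(precs)) if precs else None,
                "sensitivity": float(np.mean(senss)) if senss else None,
            }
            for key, vals in (("precision", precs), ("sensitivity", senss)):
                if len(vals) >= 2:
                    ci = bootstrap_ci(
                        vals, n_reps=n_boot, seed=seed * 7919 + rec_idx * 13 + len(rows)
                    )
                    row[f"{key}_lo"], row[f"{key}_hi"] = ci.lower, ci.upper
                else:
                    row[f"{key}_lo"] = row[f"{key}_hi"] = None
            rows.append(row)
    return pd.DataFrame(rows)


def cumulative_detection(p: float, n_surveys: int) -> float:
    """Probability of at least one detection in N surveys: 1 - (1-p)^N."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if n_surveys < 0 or int(n_surveys) != n_surveys:
        raise ValueError("N must be a non-negative integer")
    return 1.0 - (1.0 - p) ** int(n_surveys)
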