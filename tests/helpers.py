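"""Shared oracles and builders for the test suite."""

from __future__ import annotations

import numpy as np

from callrec import Match, RecognizerSettings, Recording, TrueCall, train_recognizer
from callrec.scenes import SceneConfig, _render_call


def brute_force_youden(tp_scores, fp_scores):
    """Exhaustive Youden sweep over unique observed scores.

    Returns (max_j, optimal_threshold) with the highest-threshold tie-break.
    """
    thresholds = sorted(set(tp_scores) | set(fp_scores), reverse=True)
    best_j, best_t = -2.0, None
    for t in thresholds:
        tpr = sum(s >= t for s in tp_scores) / len(tp_scores)
        tnr = sum(s < t for s in fp_scores) / len(fp_scores)
        j = tpr + tnr - 1.0
        if j > best_j:
            best_j, best_t = j, t
    return best_j, best_t


def make_matches(tp_scores, fp_scores, recording_id="r0"):
    """Verified match list with the given scores (intervals are arbitrary)."""
    out = []
    t = 0.0
    for s in tp_scores:
        out.append(Match(recording_id, t, t + 0.1, float(s), "TP"))
        t += 1.0
    for s in fp_scores:
        out.append(Match(recording_id, t, t + 0.1, float(s), "FP"))
        t += 1.0
    return out


def make_call_recording(
    n_syllables=3,
    freq_hz=1200.0,
    noise_rms=0.002,
    duration_s=10.0,
    call_start_s=4.0,
    amplitude=0.05,
    seed=0,
    recording_id="r0",
):
    """One recording containing a single known call over (optional) noise."""
    cfg = SceneConfig()
    rng = np.random.default_rng(seed)
    fs = cfg.sample_rate_hz
    wave = _render_call(freq_hz, n_syllables, cfg, rng)
    buf = noise_rms * rng.standard_normal(int(duration_s * fs)) if noise_rms else np.zeros(
        int(duration_s * fs)
    )
    i0 = int(call_start_s * fs)
    buf[i0 : i0 + len(wave)] += amplitude * wave
    rec = Recording(recording_id, "s0", "Y1", "train", fs, buf)
    ann = TrueCall(recording_id, i0 / fs, (i0 + len(wave)) / fs, n_syllables, "s0", "Y1")
    return rec, ann


def overlaps(m: Match, c: TrueCall) -> bool:
    return (
        m.recording_id == c.recording_id and m.start_s < c.end_s and m.end_s > c.start_s
    )


def make_call_library(n_sites=4, recs_per_site=3, calls_per_rec=4):
    """Symbolic annotation library (no audio) with full site/recording depth."""
    calls = []
    for s in range(n_sites):
        for r in range(recs_per_site):
            rid = f"S{s:02d}_r{r:02d}"
            for k in range(calls_per_rec):
                calls.append(
                    TrueCall(rid, 2.0 * k, 2.0 * k + 0.3, 1 + k % 4, f"S{s:02d}", "Y1")
                )
    return calls
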