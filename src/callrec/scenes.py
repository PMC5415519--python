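"""Synthetic chorus scenes with hierarchical call variability.

Emulates field recordings for recognizer design experiments: each recording
contains a background noise floor, a Poisson number of multi-syllable calls
whose dominant frequency is drawn hierarchically (site effect + recording
effect + call effect), and occasional non-target interfering chirps that give
the detector false-positive opportunities.  The signal gain in every recording
is calibrated so that the segment-based SNR estimator (mean dB of 1-s
call-containing segments minus mean dB of call-free segments) recovers the
configured target SNR.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

__all__ = [
    "SceneConfig",
    "TrueCall",
    "Recording",
    "DatasetGroup",
    "SymbolicMatchConfig",
    "synth_scene",
    "synth_match_table",
    "build_dataset_groups",
]

#: Linear RMS of the background noise floor (relative to full scale); signals
#: are scaled relative to this to reach the configured SNR.
NOISE_RMS = 0.01


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic chorus scene.

    Durations are in the units of their suffix; ``syllable_count_probs`` is a
    probability vector over 1-4 syllables per call; the three ``sd_*_hz``
    values are the standard deviations of the hierarchical frequency effects
    (among sites, among recordings within a site, among calls within a
    recording).
    """

    n_sites: int = 8
    recordings_per_site: int = 1
    duration_s: float = 30.0
    sample_rate_hz: int = 8000
    calls_per_recording: float = 5.0
    syllable_count_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    dominant_freq_hz: float = 1200.0
    sd_site_hz: float = 60.0
    sd_recording_hz: float = 25.0
    sd_call_hz: float = 10.0
    syllable_dur_ms: float = 40.0
    syllable_gap_ms: float = 30.0
    snr_db: float = 13.0
    interferer_rate_per_min: float = 2.0
    noise_color: str = "white"  # "white" or "pink"
    seed: int = 0

    def validate(self) -> None:
        probs = np.asarray(self.syllable_count_probs, dtype=float)
        if probs.shape != (4,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("syllable_count_probs must be 4 non-negative values summing to 1")
        for name in ("duration_s", "sample_rate_hz", "syllable_dur_ms", "syllable_gap_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "calls_per_recording",
            "sd_site_hz",
            "sd_recording_hz",
            "sd_call_hz",
            "interferer_rate_per_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_sites < 1 or self.recordings_per_site < 1:
            raise ValueError("n_sites and recordings_per_site must be >= 1")
        if self.sample_rate_hz <= 2 * (self.dominant_freq_hz + 3 * self.sd_site_hz):
            raise ValueError("sample_rate_hz must exceed 2*(dominant_freq_hz + 3*sd_site_hz)")
        if self.noise_color not in ("white", "pink"):
            raise ValueError("noise_color must be 'white' or 'pink'")
        if self.calls_per_recording * self.mean_call_duration_s > self.duration_s:
            raise ValueError("expected total call time exceeds recording duration")
        if self.max_call_duration_s >= self.duration_s:
            raise ValueError("a maximal call does not fit in the recording")

    @property
    def mean_call_duration_s(self) -> float:
        probs = np.asarray(self.syllable_count_probs, dtype=float)
        mean_n = float(np.dot(probs, np.arange(1, 5)))
        return (
            mean_n * self.syllable_dur_ms + max(mean_n - 1.0, 0.0) * self.syllable_gap_ms
        ) / 1000.0

    @property
    def max_call_duration_s(self) -> float:
        return (4 * self.syllable_dur_ms + 3 * self.syllable_gap_ms) / 1000.0


@dataclass(frozen=True)
class TrueCall:
    """Ground-truth annotation of one call (half-open interval in seconds).

    ``freq_hz`` is a synthesis diagnostic (the call's dominant frequency); it
    is not part of the on-disk annotation format.
    """

    recording_id: str
    start_s: float
    end_s: float
    n_syllables: int
    site_id: str
    year_label: str
    freq_hz: float | None = None

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("end_s must exceed start_s")
        if not 1 <= self.n_syllables <= 4:
            raise ValueError("n_syllables must be in 1..4")


@dataclass
class Recording:
    recording_id: str
    site_id: str
    year_label: str
    group_label: str
    sample_rate_hz: int
    samples: np.ndarray | None = None

    @property
    def duration_s(self) -> float:
        if self.samples is None:
            raise ValueError("symbolic recording has no samples")
        return len(self.samples) / self.sample_rate_hz


@dataclass(frozen=True)
class DatasetGroup:
    """A labelled set of recordings with site/year provenance flags."""

    label: str
    recordings: list[Recording]
    calls: list[TrueCall]
    same_sites: bool
    same_year: bool
    same_region: bool


@dataclass(frozen=True)
class SymbolicMatchConfig:
    """Fast-path generator of verified match tables without audio synthesis."""

    tp_score_mean: float = 70.0
    tp_score_sd: float = 10.0
    fp_per_min: float = 2.0
    fp_score_mean: float = 30.0
    fp_score_sd: float = 10.0
    extra_hit_prob: float = 0.0
    miss_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("extra_hit_prob", "miss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fp_per_min < 0:
            raise ValueError("fp_per_min must be >= 0")
        for name in ("tp_score_sd", "fp_score_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------


def _syllable_wave(freq_hz: float, dur_s: float, fs: int, phase: float) -> np.ndarray:
    n = max(int(round(dur_s * fs)), 2)
    t = np.arange(n) / fs
    env = 0.5 * (1.0 - np.cos(2 * np.pi * np.arange(n) / (n - 1)))  # raised cosine
    return env * np.sin(2 * np.pi * freq_hz * t + phase)


def _render_call(freq_hz: float, n_syllables: int, cfg: SceneConfig, rng) -> np.ndarray:
    fs = cfg.sample_rate_hz
    dur = cfg.syllable_dur_ms / 1000.0
    gap = cfg.syllable_gap_ms / 1000.0
    parts = []
    for k in range(n_syllables):
        parts.append(_syllable_wave(freq_hz, dur, fs, rng.uniform(0, 2 * np.pi)))
        if k < n_syllables - 1:
            parts.append(np.zeros(int(round(gap * fs))))
    return np.concatenate(parts)


def _render_interferer(cfg: SceneConfig, rng) -> np.ndarray:
    """Band-limited chirp; half in-band, half elsewhere in the spectrum."""
    fs = cfg.sample_rate_hz
    dur = rng.uniform(0.08, 0.15)
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    if rng.random() < 0.5:
        # near-band interferer: starts around the target band but sweeps
        # across it, so it triggers detections without cloning a call
        f0 = cfg.dominant_freq_hz + rng.uniform(-300.0, 300.0)
        f1 = f0 + rng.choice([-1.0, 1.0]) * rng.uniform(300.0, 700.0)
    else:
        f0 = rng.uniform(300.0, 0.45 * fs)
        f1 = f0 + rng.uniform(-200.0, 200.0)
    f1 = np.clip(f1, 100.0, 0.48 * fs)
    env = 0.5 * (1.0 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))
    return env * _sig.chirp(t, f0=f0, f1=f1, t1=dur, phi=np.degrees(rng.uniform(0, 2 * np.pi)))


def _make_noise(n: int, color: str, rng) -> np.ndarray:
    white = rng.standard_normal(n)
    if color == "white":
        noise = white
    else:  # pink: 1/sqrt(f) spectral shaping
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n)
        shaping = np.ones_like(freqs)
        nonzero = freqs > 0
        shaping[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
        noise = np.fft.irfft(spec * shaping, n)
    rms = np.sqrt(np.mean(noise**2))
    return noise * (NOISE_RMS / rms)


def _segment_mask(intervals, duration_s: float, segment_s: float = 1.0):
    """Boolean per grid segment: does the segment overlap any interval."""
    n_seg = int(duration_s / segment_s)
    mask = np.zeros(n_seg, dtype=bool)
    for s, e in intervals:
        lo = max(int(np.floor(s / segment_s)), 0)
        hi = min(int(np.ceil(e / segment_s)), n_seg)
        mask[lo:hi] = True
    return mask


def _synth_recording(
    rec_id: str,
    site_id: str,
    year: str,
    group: str,
    site_eff_hz: float,
    cfg: SceneConfig,
    rng,
    min_calls: int = 0,
) -> tuple[Recording, list[TrueCall]]:
    fs = cfg.sample_rate_hz
    n_samples = int(round(cfg.duration_s * fs))
    call_buf = np.zeros(n_samples)
    interf_buf = np.zeros(n_samples)
    rec_eff = rng.normal(0.0, cfg.sd_recording_hz)

    n_calls = rng.poisson(cfg.calls_per_recording) if cfg.calls_per_recording > 0 else 0
    n_calls = max(n_calls, min_calls)
    probs = np.asarray(cfg.syllable_count_probs, dtype=float)
    calls: list[TrueCall] = []
    for _ in range(n_calls):
        n_syl = int(rng.choice(np.arange(1, 5), p=probs))
        freq = cfg.dominant_freq_hz + site_eff_hz + rec_eff + rng.normal(0.0, cfg.sd_call_hz)
        wave = _render_call(freq, n_syl, cfg, rng)
        start = rng.uniform(0.0, cfg.duration_s - len(wave) / fs)
        i0 = int(round(start * fs))
        call_buf[i0 : i0 + len(wave)] += wave
        calls.append(
            TrueCall(
                recording_id=rec_id,
                start_s=i0 / fs,
                end_s=(i0 + len(wave)) / fs,
                n_syllables=n_syl,
                site_id=site_id,
                year_label=year,
                freq_hz=float(freq),
            )
        )
    calls.sort(key=lambda c: c.start_s)

    n_interf = rng.poisson(cfg.interferer_rate_per_min * cfg.duration_s / 60.0)
    for _ in range(n_interf):
        wave = _render_interferer(cfg, rng)
        if len(wave) >= n_samples:
            continue
        start = rng.uniform(0.0, cfg.duration_s - len(wave) / fs)
        i0 = int(round(start * fs))
        interf_buf[i0 : i0 + len(wave)] += wave

    noise = _make_noise(n_samples, cfg.noise_color, rng)

    # Calibrate the call gain so the segment-based SNR estimator recovers
    # cfg.snr_db: in call-containing 1-s segments the expected power is
    # a^2*p_sig + P_n, so SNR_dB = 10*log10(1 + a^2*p_sig/P_n).
    gain = 1.0
    if calls:
        mask = _segment_mask([(c.start_s, c.end_s) for c in calls], cfg.duration_s)
        seg_len = fs  # 1-s segments
        p_sig = 0.0
        n_sig_seg = 0
        for i in np.flatnonzero(mask):
            seg = call_buf[i * seg_len : (i + 1) * seg_len]
            p_sig += np.mean(seg**2)
            n_sig_seg += 1
        p_sig /= max(n_sig_seg, 1)
        p_noise = NOISE_RMS**2
        if p_sig > 0:
            gain = np.sqrt(p_noise * (10.0 ** (cfg.snr_db / 10.0) - 1.0) / p_sig)

    samples = gain * call_buf + gain * interf_buf + noise
    rec = Recording(
        recording_id=rec_id,
        site_id=site_id,
        year_label=year,
        group_label=group,
        sample_rate_hz=fs,
        samples=samples,
    )
    return rec, calls


def synth_scene(
    config: SceneConfig, seed: int | None = None
) -> tuple[list[Recording], list[TrueCall]]:
    """Synthesize a full scene (all sites x recordings) with annotations.

    Deterministic given (config, seed); ``seed`` overrides ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    site_ids = [f"S{i:03d}" for i in range(config.n_sites)]
    site_effects = rng.normal(0.0, config.sd_site_hz, size=config.n_sites)
    recordings: list[Recording] = []
    annotations: list[TrueCall] = []
    for i, site in enumerate(site_ids):
        for j in range(config.recordings_per_site):
            rec_id = f"{site}_r{j:02d}"
            rec, calls = _synth_recording(
                rec_id, site, "Y1", "train", site_effects[i], config, rng
            )
            recordings.append(rec)
            annotations.extend(calls)
    return recordings, annotations


# ---------------------------------------------------------------------------
# symbolic match tables
# ---------------------------------------------------------------------------


def synth_match_table(
    cfg: SymbolicMatchConfig,
    annotations: list[TrueCall],
    seed: int | None = None,
    *,
    duration_s: float = 300.0,
    recording_ids: list[str] | None = None,
):
    """Generate a verified match table directly from annotations (no audio).

    Each non-missed call yields one TP match over its interval (plus an extra
    syllable-level hit with probability ``extra_hit_prob``); FPs are placed
    uniformly in call-free time at ``fp_per_min``.
    """
    from .recognizer import Match  # local import to avoid a cycle

    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rec_ids = list(dict.fromkeys([c.recording_id for c in annotations]))
    if recording_ids is not None:
        rec_ids = list(dict.fromkeys(rec_ids + list(recording_ids)))

    def _tp_score():
        return float(np.clip(rng.normal(cfg.tp_score_mean, cfg.tp_score_sd), 0.0, 100.0))

    matches = []
    by_rec: dict[str, list[TrueCall]] = {r: [] for r in rec_ids}
    for c in annotations:
        by_rec[c.recording_id].append(c)

    for rec_id in rec_ids:
        calls = by_rec[rec_id]
        for c in calls:
            if rng.random() < cfg.miss_prob:
                continue
            matches.append(Match(rec_id, c.start_s, c.end_s, _tp_score(), "TP"))
            if rng.random() < cfg.extra_hit_prob:
                mid = 0.5 * (c.start_s + c.end_s)
                matches.append(Match(rec_id, c.start_s, mid, _tp_score(), "TP"))
        n_fp = rng.poisson(cfg.fp_per_min * duration_s / 60.0)
        for _ in range(n_fp):
            for _attempt in range(200):
                s = rng.uniform(0.0, max(duration_s - 0.1, 0.0))
                e = s + 0.1
                if not any(s < c.end_s and e > c.start_s for c in calls):
                    score = float(
                        np.clip(rng.normal(cfg.fp_score_mean, cfg.fp_score_sd), 0.0, 100.0)
                    )
                    matches.append(Match(rec_id, s, e, score, "FP"))
                    break
    matches.sort(key=lambda m: (m.recording_id, m.start_s))
    return matches


# ---------------------------------------------------------------------------
# dataset groups for transferability experiments
# ---------------------------------------------------------------------------


def build_dataset_groups(
    config: SceneConfig,
    seed: int | None = None,
    *,
    years: tuple[str, str] = ("Y1", "Y2"),
    recordings_per_group: int = 8,
    n_with_calls: int = 5,
    d_site_shift_hz: float | None = None,
    d_snr_offset_db: float = -3.0,
) -> list[DatasetGroup]:
    """Build the train/A/B/C/D dataset groups for transferability evaluation.

    Train: its own sites and year.  A: same sites, different year.  B:
    different sites, same year.  C: different sites and year.  D: a disjoint
    region (shifted site-effect distribution, degraded SNR).  Every group
    mixes ``n_with_calls`` call-containing recordings with
    ``recordings_per_group - n_with_calls`` call-free ones.
    """
    config.validate()
    if config.n_sites < 2:
        raise ValueError("need at least 2 sites to build dataset groups")
    if len(set(years)) < 2:
        raise ValueError("need at least 2 distinct year labels")
    if not 0 < n_with_calls <= recordings_per_group:
        raise ValueError("n_with_calls must be in 1..recordings_per_group")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    shift = 2.0 * config.sd_site_hz if d_site_shift_hz is None else d_site_shift_hz

    train_sites = [f"S{i:03d}" for i in range(config.n_sites)]
    test_sites = [f"T{i:03d}" for i in range(config.n_sites)]
    d_sites = [f"D{i:03d}" for i in range(config.n_sites)]
    effects = {s: rng.normal(0.0, config.sd_site_hz) for s in train_sites + test_sites}
    effects.update({s: shift + rng.normal(0.0, config.sd_site_hz) for s in d_sites})

    plan = [
        ("train", train_sites, years[0], True, True, True, 0.0),
        ("A", train_sites, years[1], True, False, True, 0.0),
        ("B", test_sites, years[0], False, True, True, 0.0),
        ("C", test_sites, years[1], False, False, True, 0.0),
        ("D", d_sites, years[1], False, False, False, d_snr_offset_db),
    ]
    groups: list[DatasetGroup] = []
    for label, sites, year, same_sites, same_year, same_region, snr_off in plan:
        recs: list[Recording] = []
        calls: list[TrueCall] = []
        for k in range(recordings_per_group):
            site = sites[k % len(sites)]
            with_calls = k < n_with_calls
            cfg_k = replace(
                config,
                calls_per_recording=config.calls_per_recording if with_calls else 0.0,
                snr_db=config.snr_db + snr_off,
            )
            rec_id = f"{label}_{site}_r{k:02d}"
            rec, rc = _synth_recording(
                rec_id, site, year, label, effects[site], cfg_k, rng,
                min_calls=1 if with_calls else 0,
            )
            recs.append(rec)
            calls.extend(rc)
        groups.append(
            DatasetGroup(
                label=label,
                recordings=recs,
                calls=calls,
                same_sites=same_sites,
                same_year=same_year,
                same_region=same_region,
            )
        )
    return groups
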