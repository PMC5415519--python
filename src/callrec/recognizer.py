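"""Surrogate spectrogram-based call recognizer.

The recognizer is a template matcher: training calls are summarized as a
fixed-size band-limited log-spectral envelope, averaged into a template, and
candidate events found by adaptive energy segmentation are scored against the
template with a normalized cross-correlation mapped to [0, 100].  Nine build
variables are tunable; the frequency band is fixed and excluded from tuning.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as _ndi
from scipy import signal as _sig

from .scenes import Recording, TrueCall

__all__ = [
    "RecognizerSettings",
    "Template",
    "Match",
    "TUNABLE_VARIABLES",
    "segment_syllables",
    "train_recognizer",
    "detect",
    "extract_features",
]

#: The nine build variables subject to the sensitivity analysis; the fixed
#: frequency band (band_min_hz / band_max_hz) is deliberately excluded.
TUNABLE_VARIABLES = (
    "fft_size",
    "fft_overlap",
    "background_filter_s",
    "dynamic_range_db",
    "max_syllable_ms",
    "max_syllable_gap_ms",
    "max_song_ms",
    "min_syllables",
    "feature_vector_length",
)

#: Fixed detection-threshold offset above the post-filter median band energy.
#: Documented constant, not tunable, so the tunable set stays at nine.
THRESHOLD_OFFSET_DB = 6.0

#: Number of time columns in the fixed-size feature summary.
N_FEATURE_COLUMNS = 12

_EPS_POWER = 1e-30


@dataclass(frozen=True)
class RecognizerSettings:
    fft_size: int = 256
    fft_overlap: float = 0.5
    background_filter_s: float = 5.0
    dynamic_range_db: float = 80.0
    max_syllable_ms: float = 300.0
    max_syllable_gap_ms: float = 50.0
    max_song_ms: float = 1000.0
    min_syllables: int = 1
    feature_vector_length: int = 4
    band_min_hz: float = 600.0
    band_max_hz: float = 2000.0

    def validate(self, sample_rate_hz: int | None = None) -> None:
        if self.fft_size < 8 or (self.fft_size & (self.fft_size - 1)) != 0:
            raise ValueError("fft_size must be a power of 2 (>= 8)")
        if not 0.0 <= self.fft_overlap < 1.0:
            raise ValueError("fft_overlap must be in [0, 1)")
        if not 0.0 < self.band_min_hz < self.band_max_hz:
            raise ValueError("need 0 < band_min_hz < band_max_hz")
        if sample_rate_hz is not None and self.band_max_hz >= sample_rate_hz / 2:
            raise ValueError("band_max_hz must be below the Nyquist frequency")
        for name in (
            "background_filter_s",
            "dynamic_range_db",
            "max_syllable_ms",
            "max_syllable_gap_ms",
            "max_song_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_syllables < 1:
            raise ValueError("min_syllables must be >= 1")
        if self.feature_vector_length < 1:
            raise ValueError("feature_vector_length must be >= 1")

    def fingerprint(self) -> str:
        payload = repr(dataclasses.astuple(self)).encode()
        return hashlib.sha1(payload).hexdigest()[:16]

    def hop_s(self, sample_rate_hz: int) -> float:
        return (self.fft_size - int(self.fft_overlap * self.fft_size)) / sample_rate_hz


@dataclass(frozen=True)
class Template:
    """Mean feature summary of the training calls."""

    features: np.ndarray
    settings_fingerprint: str
    n_training_calls: int
    sample_rate_hz: int


@dataclass(frozen=True)
class Match:
    recording_id: str
    start_s: float
    end_s: float
    score: float
    label: str = "unverified"

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("end_s must exceed start_s")
        if not 0.0 <= self.score <= 100.0:
            raise ValueError("score must be in [0, 100]")


# ---------------------------------------------------------------------------
# spectrogram front end
# ---------------------------------------------------------------------------


def _band_spectrogram(x: np.ndarray, fs: int, s: RecognizerSettings):
    noverlap = int(s.fft_overlap * s.fft_size)
    freqs, times, power = _sig.spectrogram(
        x,
        fs=fs,
        window="hann",
        nperseg=s.fft_size,
        noverlap=noverlap,
        mode="psd",
        detrend=False,
    )
    keep = (freqs >= s.band_min_hz) & (freqs <= s.band_max_hz)
    if not np.any(keep):
        raise ValueError("no spectrogram bins fall inside the detection band")
    return freqs[keep], times, 10.0 * np.log10(power[keep] + _EPS_POWER)


def _processed_band_energy(band_db: np.ndarray, settings: RecognizerSettings, hop_s: float):
    """Dynamic-range clamp then running-average background subtraction."""
    floor = band_db.max() - settings.dynamic_range_db
    clamped = np.maximum(band_db, floor)
    w = max(1, int(round(settings.background_filter_s / hop_s)))
    background = _ndi.uniform_filter1d(clamped, w, mode="nearest")
    return clamped - background


def _segment_frames(resid_db: np.ndarray, settings: RecognizerSettings, hop_s: float):
    """Above-threshold frame runs -> bridged, length-filtered syllables.

    Returns (start_frame, end_frame, n_bursts) triples; ``n_bursts`` counts
    the primitive above-threshold bursts merged into the syllable, so a call
    whose intra-call gaps were bridged still exposes its syllable structure
    to the ``min_syllables`` song filter.
    """
    if resid_db.size == 0:
        return []
    threshold = np.median(resid_db) + THRESHOLD_OFFSET_DB
    above = resid_db > threshold
    if not np.any(above):
        return []
    idx = np.flatnonzero(above)
    runs: list[list[int]] = [[idx[0], idx[0]]]
    for i in idx[1:]:
        if i == runs[-1][1] + 1:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    # bridge short gaps, keeping count of merged bursts
    max_gap_s = settings.max_syllable_gap_ms / 1000.0
    bridged: list[list[int]] = [[runs[0][0], runs[0][1], 1]]
    for a, b in runs[1:]:
        gap_s = (a - bridged[-1][1] - 1) * hop_s
        if gap_s <= max_gap_s + 1e-9:
            bridged[-1][1] = b
            bridged[-1][2] += 1
        else:
            bridged.append([a, b, 1])
    max_syl_s = settings.max_syllable_ms / 1000.0
    return [(a, b, n) for a, b, n in bridged if (b - a + 1) * hop_s <= max_syl_s + 1e-9]


def segment_syllables(
    band_energy_db: np.ndarray, settings: RecognizerSettings, sample_rate_hz: int
) -> list[tuple[float, float]]:
    """Segment a per-frame band-energy dB vector into syllable intervals (s).

    Frames above an adaptive threshold (median + fixed offset, after
    background filtering and dynamic-range clamping) are merged; gaps no
    longer than ``max_syllable_gap_ms`` are bridged; syllables longer than
    ``max_syllable_ms`` are discarded.
    """
    settings.validate()
    band_energy_db = np.asarray(band_energy_db, dtype=float)
    hop = settings.hop_s(sample_rate_hz)
    resid = _processed_band_energy(band_energy_db, settings, hop)
    win_s = settings.fft_size / sample_rate_hz
    out = []
    for a, b, _n in _segment_frames(resid, settings, hop):
        start = max(a * hop, 0.0)
        end = b * hop + win_s
        out.append((start, end))
    return out


def _assemble_songs(runs, settings: RecognizerSettings, hop_s: float):
    """Group syllable runs into candidate songs.

    Consecutive syllables with inter-syllable gaps <= max_syllable_gap_ms
    join one song as long as the total span stays <= max_song_ms; songs
    containing fewer than min_syllables primitive bursts are dropped.
    """
    if not runs:
        return []
    max_gap_s = settings.max_syllable_gap_ms / 1000.0
    max_song_s = settings.max_song_ms / 1000.0
    songs = []
    cur = [runs[0]]
    for run in runs[1:]:
        gap_s = (run[0] - cur[-1][1] - 1) * hop_s
        span_s = (run[1] - cur[0][0] + 1) * hop_s
        if gap_s <= max_gap_s + 1e-9 and span_s <= max_song_s + 1e-9:
            cur.append(run)
        else:
            songs.append(cur)
            cur = [run]
    songs.append(cur)
    out = []
    for grp in songs:
        span_s = (grp[-1][1] - grp[0][0] + 1) * hop_s
        n_bursts = sum(r[2] for r in grp)
        if n_bursts >= settings.min_syllables and span_s <= max_song_s + 1e-9:
            out.append((grp[0][0], grp[-1][1], n_bursts))
    return out


# ---------------------------------------------------------------------------
# features, training and detection
# ---------------------------------------------------------------------------


def _pool_axis(a: np.ndarray, n_out: int, axis: int) -> np.ndarray:
    """Resample one axis to n_out: mean pooling when shrinking (keeps narrow
    spectral peaks), linear interpolation when stretching."""
    n_in = a.shape[axis]
    if n_in >= n_out:
        chunks = np.array_split(np.arange(n_in), n_out)
        return np.stack([a.take(c, axis=axis).mean(axis=axis) for c in chunks], axis=axis)
    coords = np.linspace(0.0, n_in - 1.0, n_out)
    moved = np.moveaxis(a, axis, 0)
    out = np.empty((n_out,) + moved.shape[1:])
    grid = np.arange(n_in, dtype=float)
    for idx in np.ndindex(moved.shape[1:]):
        out[(slice(None),) + idx] = np.interp(coords, grid, moved[(slice(None),) + idx])
    return np.moveaxis(out, 0, axis)


def _resize(a: np.ndarray, n_rows: int, n_cols: int) -> np.ndarray:
    return _pool_axis(_pool_axis(a, n_rows, 0), n_cols, 1)


def _features_from_block(block_db: np.ndarray, settings: RecognizerSettings) -> np.ndarray:
    feats = _resize(block_db, settings.feature_vector_length, N_FEATURE_COLUMNS)
    return feats - feats.mean()


def _frames_for_interval(times: np.ndarray, win_s: float, start_s: float, end_s: float):
    """Indices of frames whose window intersects [start_s, end_s)."""
    starts = times - win_s / 2.0
    ends = times + win_s / 2.0
    sel = np.flatnonzero((starts < end_s) & (ends > start_s))
    return sel


def extract_features(
    recording: Recording, start_s: float, end_s: float, settings: RecognizerSettings
) -> np.ndarray:
    """Fixed-size band-limited log-spectral summary of an interval."""
    fs = recording.sample_rate_hz
    settings.validate(fs)
    _, times, band_db = _band_spectrogram(recording.samples, fs, settings)
    sel = _frames_for_interval(times, settings.fft_size / fs, start_s, end_s)
    if sel.size == 0:
        raise ValueError(f"interval [{start_s}, {end_s}) covers no spectrogram frames")
    return _features_from_block(band_db[:, sel[0] : sel[-1] + 1], settings)


def train_recognizer(
    recordings: list[Recording],
    annotations: list[TrueCall],
    settings: RecognizerSettings,
) -> Template:
    """Average the feature summaries of the annotated training calls."""
    if not annotations:
        raise ValueError("cannot train a recognizer with zero annotations")
    by_id = {r.recording_id: r for r in recordings}
    rates = {r.sample_rate_hz for r in recordings}
    if len(rates) != 1:
        raise ValueError("training recordings must share one sample rate")
    settings.validate(next(iter(rates)))
    stacks = []
    for ann in annotations:
        rec = by_id.get(ann.recording_id)
        if rec is None:
            raise ValueError(f"annotation references unknown recording {ann.recording_id!r}")
        if ann.end_s > rec.duration_s + 1e-9:
            raise ValueError(f"annotation extends beyond recording {ann.recording_id!r}")
        stacks.append(extract_features(rec, ann.start_s, ann.end_s, settings))
    features = np.mean(stacks, axis=0)
    return Template(
        features=features,
        settings_fingerprint=settings.fingerprint(),
        n_training_calls=len(annotations),
        sample_rate_hz=next(iter(rates)),
    )


def _score(candidate: np.ndarray, template: np.ndarray) -> float:
    x = candidate.ravel() - candidate.mean()
    y = template.ravel() - template.mean()
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return min(100.0, 100.0 * max(0.0, float(x @ y / (nx * ny))))


def detect(
    recording: Recording, template: Template, settings: RecognizerSettings
) -> list[Match]:
    """Scan one recording and emit scored, unverified matches."""
    if settings.fingerprint() != template.settings_fingerprint:
        raise ValueError("settings do not match the template's fingerprint")
    if recording.sample_rate_hz != template.sample_rate_hz:
        raise ValueError("recording sample rate differs from template training data")
    fs = recording.sample_rate_hz
    settings.validate(fs)
    _, times, band_spec_db = _band_spectrogram(recording.samples, fs, settings)
    band_energy_db = 10.0 * np.log10(np.sum(10.0 ** (band_spec_db / 10.0), axis=0) + _EPS_POWER)
    hop = settings.hop_s(fs)
    resid = _processed_band_energy(band_energy_db, settings, hop)
    runs = _segment_frames(resid, settings, hop)
    songs = _assemble_songs(runs, settings, hop)
    win_s = settings.fft_size / fs
    matches: list[Match] = []
    for a, b, _n in songs:
        feats = _features_from_block(band_spec_db[:, a : b + 1], settings)
        score = _score(feats, template.features)
        if score > 0.0:
            matches.append(
                Match(
                    recording_id=recording.recording_id,
                    start_s=max(a * hop, 0.0),
                    end_s=b * hop + win_s,
                    score=score,
                )
            )
    return matches
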