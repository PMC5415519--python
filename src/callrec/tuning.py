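"""Variable sensitivity analysis and weighted-error setting selection.

Each of the nine recognizer build variables is evaluated independently over a
grid (all other variables held at base values); the coefficient of variation
of the resulting conditional metrics ranks how sensitive performance is to
each variable, and the per-variable values minimizing a weighted Type-I/II
error are assembled into a final recognizer (local, not joint, optimization).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .evaluation import label_matches, subsample_penalty
from .recognizer import TUNABLE_VARIABLES, RecognizerSettings, detect, train_recognizer
from .scenes import Recording, TrueCall

__all__ = [
    "SettingGridResult",
    "SensitivityRanking",
    "WeightScheme",
    "SelectedRecognizer",
    "evaluate_grid",
    "metric_cv",
    "sensitivity_ranking",
    "weighted_error",
    "select_settings",
]

#: CV at or above which a variable counts as performance-sensitive.
CV_SENSITIVE_THRESHOLD = 0.1


@dataclass(frozen=True)
class SettingGridResult:
    variable_name: str
    values: tuple
    mean_precision: tuple  # per value, mean over recordings (may contain None)
    mean_sensitivity: tuple
    mean_penalized_precision: tuple
    mean_penalized_sensitivity: tuple


@dataclass(frozen=True)
class SensitivityRanking:
    variable_name: str
    cv_precision: float | None
    cv_sensitivity: float | None

    @property
    def sensitive_precision(self) -> bool:
        return self.cv_precision is not None and self.cv_precision >= CV_SENSITIVE_THRESHOLD

    @property
    def sensitive_sensitivity(self) -> bool:
        return (
            self.cv_sensitivity is not None
            and self.cv_sensitivity >= CV_SENSITIVE_THRESHOLD
        )


@dataclass(frozen=True)
class WeightScheme:
    w_type1: float
    w_type2: float

    def __post_init__(self) -> None:
        if self.w_type1 <= 0 or self.w_type2 <= 0:
            raise ValueError("weights must be positive")


#: The three monitoring-objective schemes: balanced, Type-I-averse (5:1) and
#: Type-II-averse (1:5).
DEFAULT_SCHEMES = (WeightScheme(1, 1), WeightScheme(5, 1), WeightScheme(1, 5))


@dataclass(frozen=True)
class SelectedRecognizer:
    settings: RecognizerSettings
    scheme: WeightScheme
    weighted_error: float | None
    threshold: float | None
    provenance: dict


def _mean_or_none(values) -> float | None:
    xs = [v for v in values if v is not None]
    return float(np.mean(xs)) if xs else None


def evaluate_grid(
    variable: str,
    values,
    base_settings: RecognizerSettings,
    training_recordings: list[Recording],
    annotations: list[TrueCall],
    *,
    train_recordings: list[Recording] | None = None,
    train_annotations: list[TrueCall] | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    matching_mode: str = "per-match",
) -> SettingGridResult:
    """Evaluate one variable over a grid, all others held at base settings.

    For each value a recognizer is trained (on ``train_*`` when given, else on
    the evaluation recordings themselves), run over every evaluation
    recording, labeled against ground truth, and summarized by penalized
    conditional metrics averaged across recordings.
    """
    if variable not in TUNABLE_VARIABLES:
        raise ValueError(
            f"{variable!r} is not tunable; the frequency band is fixed and "
            f"excluded from the sensitivity analysis"
        )
    values = tuple(values)
    if len(values) < 2:
        raise ValueError("a setting grid needs at least 2 values")
    train_recs = train_recordings if train_recordings is not None else training_recordings
    train_anns = train_annotations if train_annotations is not None else annotations

    by_rec: dict[str, list[TrueCall]] = {}
    for c in annotations:
        by_rec.setdefault(c.recording_id, []).append(c)

    cols = {k: [] for k in ("p", "s", "pp", "ps")}
    for vi, value in enumerate(values):
        settings = dataclasses.replace(base_settings, **{variable: value})
        settings.validate(training_recordings[0].sample_rate_hz)
        template = train_recognizer(train_recs, train_anns, settings)
        per_rec = {k: [] for k in cols}
        for ri, rec in enumerate(training_recordings):
            calls = by_rec.get(rec.recording_id, [])
            matches = detect(rec, template, settings)
            if not calls:
                # empty recording: every match is an FP; contributes to
                # precision only (sensitivity is undefined without calls)
                if matches:
                    per_rec["p"].append(0.0)
                    per_rec["pp"].append(0.0)
                continue
            labeled = label_matches(matches, calls, matching_mode)
            try:
                cm = subsample_penalty(
                    labeled, calls, n_reps=n_reps, seed=seed * 100003 + vi * 1009 + ri
                )
            except ValueError:
                continue
            per_rec["p"].append(cm.precision)
            per_rec["s"].append(cm.sensitivity)
            per_rec["pp"].append(cm.penalized_precision)
            per_rec["ps"].append(cm.penalized_sensitivity)
        for k in cols:
            cols[k].append(_mean_or_none(per_rec[k]))
    return SettingGridResult(
        variable_name=variable,
        values=values,
        mean_precision=tuple(cols["p"]),
        mean_sensitivity=tuple(cols["s"]),
        mean_penalized_precision=tuple(cols["pp"]),
        mean_penalized_sensitivity=tuple(cols["ps"]),
    )


def _cv(values) -> float | None:
    xs = np.array([v for v in values if v is not None], dtype=float)
    if len(xs) < 2:
        return None
    mean = xs.mean()
    if mean <= 0:
        return None
    return float(xs.std(ddof=1) / mean)


def metric_cv(
    grid: SettingGridResult, *, use_penalized: bool = True
) -> tuple[float | None, float | None]:
    """Coefficient of variation (sd/mean) of each metric across the grid."""
    if use_penalized:
        return _cv(grid.mean_penalized_precision), _cv(grid.mean_penalized_sensitivity)
    return _cv(grid.mean_precision), _cv(grid.mean_sensitivity)


def sensitivity_ranking(
    grids: list[SettingGridResult], *, use_penalized: bool = True
) -> list[SensitivityRanking]:
    """Per-variable CV table, sorted by descending precision CV."""
    out = []
    for g in grids:
        cv_p, cv_s = metric_cv(g, use_penalized=use_penalized)
        out.append(SensitivityRanking(g.variable_name, cv_p, cv_s))
    return sorted(out, key=lambda r: -(r.cv_precision if r.cv_precision is not None else -1.0))


def weighted_error(
    precision: float, sensitivity: float, scheme: WeightScheme
) -> float:
    """Normalized weighted average of Type I and Type II error rates.

    Sensitivity is clipped to [0, 1] (the penalty does not fully prevent
    values above 1; clipping prevents a negative Type II error).
    """
    if not 0.0 <= precision <= 1.0:
        raise ValueError("precision must be in [0, 1]")
    sens = min(max(sensitivity, 0.0), 1.0)
    w1, w2 = scheme.w_type1, scheme.w_type2
    return (w1 * (1.0 - precision) + w2 * (1.0 - sens)) / (w1 + w2)


def select_settings(
    grids: list[SettingGridResult],
    scheme: WeightScheme,
    base_settings: RecognizerSettings,
    *,
    use_penalized: bool = True,
) -> SelectedRecognizer:
    """Assemble final settings by local per-variable weighted-error minima.

    Ties resolve to the value closest to the base setting.  One grid per
    tunable variable is required.
    """
    seen = {g.variable_name for g in grids}
    missing = set(TUNABLE_VARIABLES) - seen
    if missing:
        raise ValueError(f"missing grids for variables: {sorted(missing)}")

    chosen = {}
    provenance = {}
    for g in grids:
        precs = g.mean_penalized_precision if use_penalized else g.mean_precision
        senss = g.mean_penalized_sensitivity if use_penalized else g.mean_sensitivity
        base_value = getattr(base_settings, g.variable_name)
        best_value, best_err = None, np.inf
        for value, p, s in zip(g.values, precs, senss):
            if p is None or s is None:
                continue
            err = weighted_error(p, s, scheme)
            better = err < best_err - 1e-12
            tie = abs(err - best_err) <= 1e-12
            if better or (
                tie
                and best_value is not None
                and abs(float(value) - float(base_value))
                < abs(float(best_value) - float(base_value))
            ):
                best_value, best_err = value, min(err, best_err)
        if best_value is None:
            best_value = base_value  # fully undefined grid: keep the base
        chosen[g.variable_name] = best_value
        provenance[g.variable_name] = {"values": g.values, "chosen": best_value}

    settings = dataclasses.replace(base_settings, **chosen)
    return SelectedRecognizer(
        settings=settings,
        scheme=scheme,
        weighted_error=None,
        threshold=None,
        provenance=provenance,
    )
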