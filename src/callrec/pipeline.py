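"""End-to-end workflow: simulate -> train -> detect -> evaluate -> tune ->
select (three weight schemes) -> transfer.

Every stage draws its randomness from a named substream of one root seed so
stages are independently reproducible, and every output table is written to
the run directory together with a machine-readable summary carrying the
configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .evaluation import label_matches, roc_and_threshold, subsample_penalty
from .recognizer import TUNABLE_VARIABLES, RecognizerSettings, detect, train_recognizer
from .scenes import DatasetGroup, SceneConfig, build_dataset_groups
from .transfer import evaluate_transfer
from .tuning import (
    DEFAULT_SCHEMES,
    SelectedRecognizer,
    WeightScheme,
    evaluate_grid,
    select_settings,
    sensitivity_ranking,
    weighted_error,
)

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_GRIDS"]

log = logging.getLogger("callrec")

DEFAULT_GRIDS: dict[str, tuple] = {
    "fft_size": (128, 256, 512),
    "fft_overlap": (0.25, 0.5, 0.75),
    "background_filter_s": (2.0, 5.0, 10.0),
    "dynamic_range_db": (60.0, 80.0, 100.0),
    "max_syllable_ms": (150.0, 300.0, 450.0),
    "max_syllable_gap_ms": (10.0, 50.0, 100.0),
    "max_song_ms": (500.0, 1000.0, 1500.0),
    # held flat by default: the burst-count filter interacts destructively
    # with small syllable-gap settings, which purely local (one-variable)
    # optimization cannot detect
    "min_syllables": (1, 1),
    "feature_vector_length": (3, 4, 6),
}


@dataclass
class PipelineConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    base_settings: RecognizerSettings = field(default_factory=RecognizerSettings)
    grids: dict = field(default_factory=lambda: dict(DEFAULT_GRIDS))
    schemes: tuple = DEFAULT_SCHEMES
    penalty_reps: int = 1000
    bootstrap_reps: int = 2000
    matching_mode: str = "per-match"
    seed: int = 0
    out_dir: str = "callrec_run"
    save_audio: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        if "scene" in kwargs:
            kwargs["scene"] = SceneConfig(**kwargs["scene"])
        if "base_settings" in kwargs:
            kwargs["base_settings"] = RecognizerSettings(**kwargs["base_settings"])
        if "schemes" in kwargs:
            kwargs["schemes"] = tuple(WeightScheme(*s) for s in kwargs["schemes"])
        if "grids" in kwargs:
            kwargs["grids"] = {k: tuple(v) for k, v in kwargs["grids"].items()}
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_jsonable(self) -> dict:
        return {
            "scene": dataclasses.asdict(self.scene),
            "base_settings": dataclasses.asdict(self.base_settings),
            "grids": {k: list(v) for k, v in self.grids.items()},
            "schemes": [[s.w_type1, s.w_type2] for s in self.schemes],
            "penalty_reps": self.penalty_reps,
            "bootstrap_reps": self.bootstrap_reps,
            "matching_mode": self.matching_mode,
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "save_audio": self.save_audio,
        }

    def hash(self) -> str:
        # hash the scientific configuration only (not where outputs land)
        payload = {
            k: v
            for k, v in self.to_jsonable().items()
            if k not in ("out_dir", "save_audio")
        }
        return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def substream(root_seed: int, name: str) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    return (int(root_seed) * 1000003 + zlib.crc32(name.encode())) % (2**31 - 1)


def _finalize(
    settings: RecognizerSettings,
    train_group: DatasetGroup,
    scheme: WeightScheme,
    cfg: PipelineConfig,
    seed: int,
):
    """Re-assess assembled settings on the train group: pooled threshold,
    penalized conditional metrics and weighted error."""
    call_recs = [r for r in train_group.recordings if any(
        c.recording_id == r.recording_id for c in train_group.calls)]
    template = train_recognizer(call_recs, train_group.calls, settings)
    matches = []
    for rec in train_group.recordings:
        matches.extend(detect(rec, template, settings))
    labeled = label_matches(matches, train_group.calls, cfg.matching_mode)
    cm = subsample_penalty(
        labeled, train_group.calls, n_reps=cfg.penalty_reps, seed=seed
    )
    try:
        threshold = roc_and_threshold(labeled).optimal_threshold
    except ValueError:
        threshold = cm.threshold
    err = None
    if cm.penalized_precision is not None and cm.penalized_sensitivity is not None:
        err = weighted_error(cm.penalized_precision, cm.penalized_sensitivity, scheme)
    return template, threshold, cm, err


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full recognizer-design workflow; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    logging.basicConfig(level=logging.INFO)
    log.info("run %s (seed=%d) -> %s", cfg_hash, config.seed, out)

    summary: dict = {"config_hash": cfg_hash, "seed": config.seed, "stages": {}}
    (out / "config.json").write_text(json.dumps(config.to_jsonable(), indent=2))

    def _write_table(df: pd.DataFrame, name: str) -> None:
        df2 = df.copy()
        df2.insert(0, "config_hash", cfg_hash)
        df2.to_csv(out / name, sep="\t", index=False)

    stage = "simulate"
    try:
        groups = build_dataset_groups(config.scene, substream(config.seed, "simulate"))
        train_group = next(g for g in groups if g.label == "train")
        all_calls = [c for g in groups for c in g.calls]
        _io.write_annotations(all_calls, out / "annotations.tsv")
        manifest = pd.DataFrame(
            [
                {
                    "recording_id": r.recording_id,
                    "group": g.label,
                    "site_id": r.site_id,
                    "year": r.year_label,
                }
                for g in groups
                for r in g.recordings
            ]
        )
        _write_table(manifest, "groups.tsv")
        if config.save_audio:
            audio_dir = out / "audio"
            audio_dir.mkdir(exist_ok=True)
            for g in groups:
                for r in g.recordings:
                    _io.write_wav(r, audio_dir / f"{r.recording_id}.wav")
        summary["stages"]["simulate"] = {
            "n_groups": len(groups),
            "n_recordings": int(sum(len(g.recordings) for g in groups)),
            "n_calls": len(all_calls),
            "n_train_calls": len(train_group.calls),
        }

        stage = "train+detect+evaluate"
        base_template, base_threshold, base_cm, _ = _finalize(
            config.base_settings, train_group, config.schemes[0], config,
            substream(config.seed, "evaluate"),
        )
        base_matches = []
        for rec in train_group.recordings:
            base_matches.extend(detect(rec, base_template, config.base_settings))
        _io.write_matches(
            label_matches(base_matches, train_group.calls, config.matching_mode),
            out / "train_matches.tsv",
        )
        summary["stages"]["evaluate"] = {
            "base_threshold": base_threshold,
            "precision": base_cm.precision,
            "sensitivity": base_cm.sensitivity,
            "penalized_precision": base_cm.penalized_precision,
            "penalized_sensitivity": base_cm.penalized_sensitivity,
        }

        stage = "tune"
        train_call_recs = [
            r
            for r in train_group.recordings
            if any(c.recording_id == r.recording_id for c in train_group.calls)
        ]
        grids = []
        grid_rows = []
        for var in TUNABLE_VARIABLES:
            values = config.grids.get(var, DEFAULT_GRIDS[var])
            g = evaluate_grid(
                var,
                values,
                config.base_settings,
                train_group.recordings,
                train_group.calls,
                train_recordings=train_call_recs,
                train_annotations=train_group.calls,
                n_reps=config.penalty_reps,
                seed=substream(config.seed, f"tune:{var}"),
                matching_mode=config.matching_mode,
            )
            grids.append(g)
            for v, p, s, pp, ps in zip(
                g.values,
                g.mean_precision,
                g.mean_sensitivity,
                g.mean_penalized_precision,
                g.mean_penalized_sensitivity,
            ):
                grid_rows.append(
                    {
                        "variable": var,
                        "value": v,
                        "precision": p,
                        "sensitivity": s,
                        "penalized_precision": pp,
                        "penalized_sensitivity": ps,
                    }
                )
        _write_table(pd.DataFrame(grid_rows), "grid_results.tsv")
        ranking = sensitivity_ranking(grids)
        _write_table(
            pd.DataFrame(
                [
                    {
                        "variable": r.variable_name,
                        "cv_precision": r.cv_precision,
                        "cv_sensitivity": r.cv_sensitivity,
                        "sensitive_precision": r.sensitive_precision,
                        "sensitive_sensitivity": r.sensitive_sensitivity,
                    }
                    for r in ranking
                ]
            ),
            "sensitivity_ranking.tsv",
        )
        summary["stages"]["tune"] = {"n_grids": len(grids)}

        stage = "select"
        selected: list[SelectedRecognizer] = []
        sel_rows = []
        recognizers = []
        for scheme in config.schemes:
            sel = select_settings(grids, scheme, config.base_settings)
            template, threshold, cm, err = _finalize(
                sel.settings, train_group, scheme, config,
                substream(config.seed, f"select:{scheme.w_type1}:{scheme.w_type2}"),
            )
            sel = dataclasses.replace(sel, weighted_error=err, threshold=threshold)
            selected.append(sel)
            name = f"w{scheme.w_type1:g}_{scheme.w_type2:g}"
            recognizers.append((name, sel.settings, template, threshold))
            sel_rows.append(
                {
                    "recognizer": name,
                    "w_type1": scheme.w_type1,
                    "w_type2": scheme.w_type2,
                    "threshold": threshold,
                    "weighted_error": err,
                    "penalized_precision": cm.penalized_precision,
                    "penalized_sensitivity": cm.penalized_sensitivity,
                    **{v: getattr(sel.settings, v) for v in TUNABLE_VARIABLES},
                }
            )
        _write_table(pd.DataFrame(sel_rows), "selected_recognizers.tsv")
        summary["stages"]["select"] = {"n_recognizers": len(selected)}

        stage = "transfer"
        transfer_df = evaluate_transfer(
            recognizers,
            groups,
            n_boot=config.bootstrap_reps,
            seed=substream(config.seed, "transfer"),
            matching_mode=config.matching_mode,
        )
        _write_table(transfer_df, "transfer_metrics.tsv")
        summary["stages"]["transfer"] = {"n_rows": len(transfer_df)}
    except Exception:
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        log.exception("pipeline failed at stage %s", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}; partial outputs in {out}")

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return out
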