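"""Training-data scaling: nested subsets and beta-regression model selection.

Training annotations can be expanded along three variability axes — more
calls per recording (within-recording), more recordings per site
(among-recording), more sites (among-site).  Recognizers trained on nested
subsets along each axis are scored, and the relationship between training
amount/source and conditional metrics is modelled with logit-link beta
regressions compared by small-sample AICc, Akaike weights and evidence
ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit

from .scenes import TrueCall

__all__ = [
    "TrainingSubsetSpec",
    "BetaRegressionFit",
    "build_training_subsets",
    "fit_beta_regression",
    "aicc",
    "rank_models",
    "run_scaling_experiment",
]

AXES = ("within_recording", "among_recording", "among_site", "all_sources")


@dataclass(frozen=True)
class TrainingSubsetSpec:
    axis: str
    target_calls_per_recording: int
    target_recordings_per_site: int
    target_sites: int
    achieved_calls_per_recording: float
    achieved_recordings_per_site: float
    achieved_sites: int
    total_calls: int
    calls: tuple = field(repr=False, default=())


def build_training_subsets(
    library: list[TrueCall],
    axis: str,
    levels,
    *,
    calls_per_recording: int | None = None,
    recordings_per_site: int | None = None,
    n_sites: int | None = None,
    seed: int | None = None,
) -> list[TrainingSubsetSpec]:
    """Nested training subsets along one variability axis.

    The varied axis takes the values in ``levels`` while the other two axes
    are held at the given constants; subsets are nested (each level's calls
    are a superset of the previous level's).  When the library cannot supply
    a target count the achieved count falls short and is recorded as such.
    """
    if axis not in ("within_recording", "among_recording", "among_site"):
        raise ValueError(f"unknown axis {axis!r}")
    levels = sorted(set(int(v) for v in levels))
    if not levels or levels[0] < 1:
        raise ValueError("levels must be positive integers")

    rng = np.random.default_rng(seed)
    # site -> recording -> calls, each level shuffled once so that taking
    # prefixes yields nested random subsets
    tree: dict[str, dict[str, list[TrueCall]]] = {}
    for c in library:
        tree.setdefault(c.site_id, {}).setdefault(c.recording_id, []).append(c)
    site_order = sorted(tree)
    rng.shuffle(site_order)
    rec_order = {}
    call_order = {}
    for s in site_order:
        recs = sorted(tree[s])
        rng.shuffle(recs)
        rec_order[s] = recs
        for r in recs:
            calls = sorted(tree[s][r], key=lambda c: c.start_s)
            rng.shuffle(calls)
            call_order[(s, r)] = calls

    def pick(n_site: int, n_rec: int, n_call: int):
        sites = site_order[:n_site]
        chosen: list[TrueCall] = []
        per_rec_counts: list[int] = []
        per_site_counts: list[int] = []
        for s in sites:
            recs = rec_order[s][:n_rec]
            per_site_counts.append(len(recs))
            for r in recs:
                calls = call_order[(s, r)][:n_call]
                per_rec_counts.append(len(calls))
                chosen.extend(calls)
        return sites, per_site_counts, per_rec_counts, chosen

    const_calls = calls_per_recording if calls_per_recording is not None else max(levels)
    const_recs = recordings_per_site if recordings_per_site is not None else max(levels)
    const_sites = n_sites if n_sites is not None else len(site_order)
    if axis == "among_site" and max(levels) > len(site_order):
        raise ValueError("library has fewer sites than the largest level")

    out = []
    for level in levels:
        if axis == "within_recording":
            n_site, n_rec, n_call = const_sites, const_recs, level
        elif axis == "among_recording":
            n_site, n_rec, n_call = const_sites, level, const_calls
        else:
            n_site, n_rec, n_call = level, const_recs, const_calls
        sites, per_site, per_rec, chosen = pick(n_site, n_rec, n_call)
        if not chosen:
            raise ValueError(f"no calls available for axis={axis} level={level}")
        out.append(
            TrainingSubsetSpec(
                axis=axis,
                target_calls_per_recording=n_call,
                target_recordings_per_site=n_rec,
                target_sites=n_site,
                achieved_calls_per_recording=float(np.mean(per_rec)),
                achieved_recordings_per_site=float(np.mean(per_site)),
                achieved_sites=len(sites),
                total_calls=len(chosen),
                calls=tuple(chosen),
            )
        )
    return out


# ---------------------------------------------------------------------------
# beta regression with logit link
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BetaRegressionFit:
    """ML fit of a logit-link beta regression (constant precision phi)."""

    coefficients: np.ndarray  # mean-model coefficients on the logit scale
    standard_errors: np.ndarray
    phi: float
    loglik: float
    K: int  # mean coefficients + 1 precision parameter
    n: int
    pseudo_r2: float
    endog: np.ndarray = field(repr=False, default=None)
    exog: np.ndarray = field(repr=False, default=None)


def shrink_unit_interval(y: np.ndarray) -> np.ndarray:
    """Pull exact 0/1 responses into (0, 1) via (y*(n-1) + 0.5)/n."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("responses must lie in [0, 1]")
    if np.any(y <= 0) or np.any(y >= 1):
        return (y * (n - 1) + 0.5) / n
    return y


def fit_beta_regression(y, X) -> BetaRegressionFit:
    """Maximum-likelihood beta regression of y in (0,1) on design matrix X.

    Mean model uses a logit link; the precision parameter phi is constant.
    Boundary responses are shrunk into the open interval first.  Pseudo-R^2
    is the squared correlation between the linear predictor and logit(y).
    """
    from statsmodels.othermod.betareg import BetaModel

    y = shrink_unit_interval(np.asarray(y, dtype=float))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) != X.shape[0]:
        raise ValueError("y and X have incompatible shapes")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    model = BetaModel(y, X)  # logit mean link, log precision link
    res = model.fit(disp=False)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(f"beta regression did not converge: {res.mle_retvals}")
    k_mean = X.shape[1]
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    eta = X @ params[:k_mean]
    z = logit(y)
    if np.ptp(eta) < 1e-12:
        pseudo_r2 = 0.0
    else:
        pseudo_r2 = float(np.corrcoef(eta, z)[0, 1] ** 2)
    return BetaRegressionFit(
        coefficients=params[:k_mean],
        standard_errors=bse[:k_mean],
        phi=float(np.exp(params[k_mean])),
        loglik=float(res.llf),
        K=k_mean + 1,
        n=len(y),
        pseudo_r2=pseudo_r2,
        endog=y,
        exog=X,
    )


def aicc(fit: BetaRegressionFit) -> float:
    """Small-sample AICc: -2 loglik + 2K + 2K(K+1)/(n-K-1)."""
    if fit.n <= fit.K + 1:
        raise ValueError("AICc requires n > K + 1")
    return -2.0 * fit.loglik + 2.0 * fit.K + 2.0 * fit.K * (fit.K + 1) / (fit.n - fit.K - 1)


def rank_models(fits: list[BetaRegressionFit], labels: list[str]) -> pd.DataFrame:
    """AICc model-selection table with Akaike weights and evidence ratios.

    Evidence ratio of each model is the best model's weight divided by its
    weight (1 for the best model itself).
    """
    if len(fits) < 2 or len(fits) != len(labels):
        raise ValueError("need >= 2 fits with matching labels")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError("all fits must be on the same responses (equal n)")
    aiccs = np.array([aicc(f) for f in fits])
    delta = aiccs - aiccs.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    table = pd.DataFrame(
        {
            "model": labels,
            "K": [f.K for f in fits],
            "aicc": aiccs,
            "delta_aicc": delta,
            "weight": w,
            "evidence_ratio": w.max() / w,
            "loglik": [f.loglik for f in fits],
            "pseudo_r2": [f.pseudo_r2 for f in fits],
        }
    )
    return table.sort_values("aicc", ignore_index=True)


def run_scaling_experiment(
    library_config,
    eval_config,
    settings,
    *,
    site_levels=(1, 2, 4, 8),
    recording_levels=(1, 2),
    calls_per_recording: int = 3,
    seed: int = 0,
    penalty_reps: int = 50,
) -> pd.DataFrame:
    """Train recognizers on nested site x recording subsets and score them.

    Synthesizes a training library and an independent evaluation scene,
    trains one recognizer per (n_sites, n_recordings) combination on a
    nested subset of the library annotations, and records the penalized
    conditional sensitivity and precision of each recognizer on the
    evaluation scene.  The returned frame is ready for the beta-regression
    model comparison (one row per recognizer).
    """
    from .evaluation import label_matches, subsample_penalty
    from .recognizer import detect, train_recognizer
    from .scenes import synth_scene

    lib_recs, lib_anns = synth_scene(library_config, seed)
    eval_recs, eval_anns = synth_scene(eval_config, seed + 1000)
    by_rec = {r.recording_id: r for r in lib_recs}
    rows = []
    for n_sites in site_levels:
        for n_recordings in recording_levels:
            (subset,) = build_training_subsets(
                lib_anns,
                "among_site",
                [n_sites],
                calls_per_recording=calls_per_recording,
                recordings_per_site=n_recordings,
                seed=seed,
            )
            calls = list(subset.calls)
            recs = [by_rec[rid] for rid in sorted({c.recording_id for c in calls})]
            template = train_recognizer(recs, calls, settings)
            matches = [m for r in eval_recs for m in detect(r, template, settings)]
            labeled = label_matches(matches, eval_anns)
            cm = subsample_penalty(labeled, eval_anns, n_reps=penalty_reps, seed=seed)
            rows.append(
                {
                    "n_sites": n_sites,
                    "n_recordings": n_recordings,
                    "total_calls": subset.total_calls,
                    "penalized_sensitivity": cm.penalized_sensitivity,
                    "penalized_precision": cm.penalized_precision,
                }
            )
    return pd.DataFrame(rows)
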