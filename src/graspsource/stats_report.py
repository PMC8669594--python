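"""Statistical comparisons and the end-to-end pipeline driver.

Two tests mirror the study design: a two-sided Wilcoxon rank-sum test per
time point comparing a ROI's source traces between a movement condition and
no-movement (uncorrected p < 0.05 mask), and a one-way repeated-measures
ANOVA on peak decoding accuracies across feature-window sizes.

:func:`run_pipeline` chains every stage -- simulate, events, preprocess,
source imaging, decoding, connectivity, network metrics, statistics --
on a synthetic experiment and writes the result tables; identical
configuration and seed reproduce the output files byte for byte.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist, mannwhitneyu

from . import connectivity, decode, events, inverse, netmetrics, preprocess
from .synthdata import (
    MOVEMENT_TASKS,
    NO_MOVEMENT,
    SimConfig,
    simulate_experiment,
)

EXACT_RANKSUM_MAX_N = 20
FLOAT_FMT = "%.10g"


@dataclass
class SignificanceTrack:
    """Per-time-point rank-sum p-values for one ROI and condition pair."""

    roi: str
    cond_a: str
    cond_b: str
    times: np.ndarray
    p_values: np.ndarray
    alpha: float = 0.05

    @property
    def mask(self) -> np.ndarray:
        return self.p_values < self.alpha


def ranksum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when the pooled sample is small (<= 20) and tie-free,
    otherwise the tie-corrected normal approximation.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    exact = pooled.size <= EXACT_RANKSUM_MAX_N and np.unique(pooled).size == pooled.size
    method = "exact" if exact else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def ranksum_timecourse(
    smrcp: inverse.SourceEpochs,
    roi: str,
    cond_a: str,
    cond_b: str = NO_MOVEMENT,
    alpha: float = 0.05,
) -> SignificanceTrack:
    """Rank-sum test across trials at every time point of one ROI's sMRCP."""
    a = smrcp.condition(cond_a)
    b = smrcp.condition(cond_b)
    if a.n_trials < 2 or b.n_trials < 2:
        raise ValueError("need >= 2 trials per condition")
    xa, xb = a.roi(roi), b.roi(roi)
    p = np.array([ranksum(xa[:, t], xb[:, t]) for t in range(xa.shape[1])])
    return SignificanceTrack(
        roi=roi, cond_a=cond_a, cond_b=cond_b, times=smrcp.time, p_values=p, alpha=alpha
    )


def rm_anova(table: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA (subjects x conditions table).

    Returns ``(F, p)`` with subject as the repeated factor and no sphericity
    correction.  All-equal cells give (0, 1); zero within-cell error with a
    nonzero effect gives (inf, 0).
    """
    x = np.asarray(table, float)
    if x.ndim != 2 or np.isnan(x).any():
        raise ValueError("need a complete 2-D subjects x conditions table")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    grand = x.mean()
    cond = x.mean(axis=0)
    subj = x.mean(axis=1)
    ss_cond = n * np.sum((cond - grand) ** 2)
    resid = x - subj[:, None] - cond[None, :] + grand
    ss_err = np.sum(resid**2)
    df_c, df_e = k - 1, (n - 1) * (k - 1)
    scale = max(np.sum((x - grand) ** 2), 1.0)
    if ss_cond / scale < 1e-12:
        return 0.0, 1.0
    if ss_err / scale < 1e-12:
        return float("inf"), 0.0
    F = (ss_cond / df_c) / (ss_err / df_e)
    return float(F), float(f_dist.sf(F, df_c, df_e))


def rm_anova_window_sizes(peaks: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """RM-ANOVA on peak accuracies: rows = subjects (runs), columns = sizes."""
    if isinstance(peaks, pd.DataFrame):
        peaks = peaks.to_numpy(float)
    return rm_anova(peaks)


# ---------------------------------------------------------------------------
# End-to-end pipeline


@dataclass
class PipelineConfig:
    """Everything one reproducible end-to-end run needs."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str | Path = "results/run"
    folds: int = 5
    repeats: int = 10
    decode_window_s: float = 1.0
    decode_stride: int = 1  # evaluate every n-th sliding-window position
    inverse_snr: float = 3.0
    plv_threshold: float = connectivity.PLV_THRESHOLD
    metric_times: tuple[float, ...] = (-1.0, 0.0, 1.4)
    stats_roi: str = "BA4a-L"


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle to ``cfg.out_dir``.

    Returns a dict with the in-memory results of each stage.  Any stage
    failure is re-raised tagged with the stage name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    results: dict = {}

    def stage(name, fn):
        t0 = _time.perf_counter()
        try:
            results[name] = fn()
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        timings[name] = round(_time.perf_counter() - t0, 3)
        return results[name]

    sessions, rest, truth, leadfield = stage(
        "simulate", lambda: simulate_experiment(cfg.sim)
    )

    def _events():
        tables = []
        for rec in sessions:
            tr = truth.trials[truth.trials["session"] == rec.session]
            wrong = (tr["executed_task"] != tr["task"]).to_numpy()
            tables.append(
                events.apply_discard_rules(
                    events.build_event_table(rec), wrong_movement=wrong
                )
            )
        combined = events.assign_pseudo_onsets(pd.concat(tables, ignore_index=True))
        events.write_events_tsv(combined, out / "events.tsv")
        return combined

    table = stage("events", _events)

    def _preprocess():
        sets = []
        for rec in sessions:
            ev = table[table["session"] == rec.session]
            sets.append(preprocess.preprocess_session(rec, ev))
        return preprocess.concatenate(sets)

    epochs = stage("preprocess", _preprocess)

    def _source():
        rest_proc = preprocess.preprocess_rest(rest)
        cov = inverse.estimate_noise_cov(rest_proc)
        op = inverse.sloreta_operator(leadfield, cov, snr=cfg.inverse_snr)
        return inverse.apply_inverse(epochs, op)

    smrcp = stage("source", _source)

    def _decode():
        smrcp16 = decode.resample_sources(smrcp)
        subset = np.arange(0, decode.count_models(), cfg.decode_stride)
        res = decode.cross_validated_curves(
            smrcp16,
            folds=cfg.folds,
            repeats=cfg.repeats,
            seed=cfg.sim.seed,
            window_s=cfg.decode_window_s,
            window_subset=subset,
        )
        curves = pd.DataFrame({"window_end_s": res.window_ends, "accuracy": res.accuracy,
                               "accuracy_sd": res.accuracy_sd})
        for i, c in enumerate(res.classes):
            curves[f"precision_{c}"] = res.precision[i]
        curves.to_csv(out / "decoding_accuracy.csv", index=False, float_format=FLOAT_FMT)
        pd.DataFrame(
            res.confusion_at(res.peak_time), index=res.classes, columns=res.classes
        ).to_csv(out / "confusion_peak.csv", float_format=FLOAT_FMT)
        (out / "peaks.json").write_text(
            json.dumps(
                dict(
                    peak_accuracy=res.peak_accuracy,
                    peak_time=res.peak_time,
                    chance_level=res.chance,
                    n_trials=int(smrcp.n_trials),
                ),
                indent=2,
                sort_keys=True,
            )
        )
        return res

    decoding = stage("decode", _decode)

    def _connect():
        tensors = {}
        for task in cfg.sim.tasks:
            sub = smrcp.condition(task)
            tensors[task] = connectivity.plv_matrix(sub, interval=preprocess.TROI)
        return tensors

    tensors = stage("connect", _connect)

    def _metrics():
        rows = [
            netmetrics.metrics_timecourse(
                tensors[task],
                task,
                times=cfg.metric_times,
                threshold=cfg.plv_threshold,
                seed=cfg.sim.seed,
            )
            for task in cfg.sim.tasks
        ]
        df = pd.concat(rows, ignore_index=True)
        df.to_csv(out / "network_metrics.csv", index=False, float_format=FLOAT_FMT)
        return df

    metrics = stage("metrics", _metrics)

    def _stats():
        tracks = []
        for task in MOVEMENT_TASKS:
            if task not in cfg.sim.tasks:
                continue
            tr = ranksum_timecourse(smrcp, cfg.stats_roi, task)
            tracks.append(
                pd.DataFrame(
                    dict(
                        roi=tr.roi,
                        condition=tr.cond_a,
                        time_s=tr.times,
                        p_value=tr.p_values,
                        significant=tr.mask.astype(int),
                    )
                )
            )
        df = pd.concat(tracks, ignore_index=True)
        df.to_csv(out / "significance.csv", index=False, float_format=FLOAT_FMT)
        return df

    stats = stage("stats", _stats)

    manifest = dict(
        stages=list(timings),
        timings_s=timings,
        seed=cfg.sim.seed,
        n_sessions=cfg.sim.n_sessions,
        total_trials=cfg.sim.total_trials,
        retained_trials=int(smrcp.n_trials),
        folds=cfg.folds,
        repeats=cfg.repeats,
        plv_threshold=cfg.plv_threshold,
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return dict(
        events=table,
        epochs=epochs,
        smrcp=smrcp,
        decoding=decoding,
        plv=tensors,
        metrics=metrics,
        stats=stats,
        manifest=manifest,
    )
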