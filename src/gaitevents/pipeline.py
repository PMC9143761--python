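"""End-to-end orchestration: simulate, annotate, window, train, evaluate.

The full loop mirrors the validation protocol the package implements:
a cohort of subjects walks short bouts at three speeds; marker
trajectories are annotated by the velocity-extremum reference method;
IMU streams are normalized per trial, windowed, and used to train the
TCN on the training subjects (with random-rotation augmentation);
detection and stride-parameter agreement are then scored on the
held-out test subjects, feeding complete trials to the network.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .agreement import bland_altman, compute_stride_params, trial_is_valid
from .evaluation import (MatchResult, PeakConfig, detection_metrics,
                         match_events, pick_peaks, time_error_stats)
from .events import GaitEvents
from .markers import FilterSpec, detect_reference_events
from .preprocessing import (concat_window_sets, encode_event_labels,
                            make_windows, normalize_channels, split_cohort)
from .synthetic import (LOCATIONS, SPEED_FACTORS, SyntheticTrial,
                        apply_random_rotation, generate_cohort, simulate_trial)
from .tcn import TcnConfig, TcnModel, TrainConfig, build_model, predict_trial, train_model

__all__ = ["EndToEndResult", "run_end_to_end", "evaluate_trials",
           "trial_seed", "reference_events"]


def trial_seed(base_seed: int, *keys) -> int:
    """Stable per-trial sub-seed derived from a base seed and labels (< 2^31)."""
    ss = np.random.SeedSequence([base_seed & 0x7FFFFFFF,
                                 *(zlib.crc32(str(k).encode()) for k in keys)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def reference_events(trial: SyntheticTrial,
                     filter_spec: FilterSpec | None = None) -> GaitEvents:
    """Marker-based reference annotation of one trial."""
    return detect_reference_events(
        trial.markers, filter_spec or FilterSpec(fs=trial.fs))


def _foot_of(location: str) -> str:
    return "left" if location.startswith("left") else "right"


def _window_sets_for_trial(trial: SyntheticTrial, events: GaitEvents,
                           trial_id: str, locations, window: int,
                           overlap: float, sigma_samples: float,
                           n_augment: int, seed: int):
    """Per-location window sets; optionally adds rotated copies of each stream."""
    out = []
    n = next(iter(trial.imu.values())).n_samples
    for loc in locations:
        stream = trial.imu[loc]
        labels = encode_event_labels(events[_foot_of(loc)], n, trial.fs,
                                     sigma_samples=sigma_samples)
        variants = [stream]
        for a in range(n_augment):
            variants.append(apply_random_rotation(
                stream, seed=trial_seed(seed, trial_id, loc, a)))
        for v_idx, v in enumerate(variants):
            ws = make_windows(normalize_channels(v.X), labels.stacked,
                              trial_id=f"{trial_id}/{loc}/r{v_idx}",
                              window=window, overlap=overlap)
            if len(ws):
                out.append(ws)
    return out


@dataclass
class TrialScore:
    """Detection and stride results of one (trial, sensor-location) pair."""

    trial_id: str
    location: str
    match_ic: MatchResult
    match_fc: MatchResult
    valid: bool
    ref_strides: list = field(default_factory=list)
    pred_strides: list = field(default_factory=list)


def evaluate_trials(model: TcnModel, trials: list[tuple[str, SyntheticTrial, GaitEvents]],
                    tolerance_s: float, peak_cfg: PeakConfig | None = None,
                    locations=LOCATIONS) -> list[TrialScore]:
    """Score each (trial, location): predict, pick peaks, match, extract strides.

    Each sensor is scored against its own side's foot events.  Stride
    parameters are extracted only from "valid" pairs (no miss, no false
    positive for either event type), pairing reference and predicted
    strides by order — with a complete one-to-one event matching both
    sequences align stride for stride.
    """
    peak_cfg = peak_cfg or PeakConfig(threshold=0.3, min_separation_s=0.3)
    scores = []
    for trial_id, trial, events in trials:
        for loc in locations:
            stream = trial.imu[loc]
            traces = predict_trial(model, normalize_channels(stream.X), fs=trial.fs)
            pred_ic = pick_peaks(traces.yic, trial.fs, peak_cfg)
            pred_fc = pick_peaks(traces.yfc, trial.fs, peak_cfg)
            foot = events[_foot_of(loc)]
            m_ic = match_events(foot.ic_times, pred_ic, tolerance_s)
            m_fc = match_events(foot.fc_times, pred_fc, tolerance_s)
            valid = trial_is_valid(m_ic, m_fc)
            score = TrialScore(trial_id=trial_id, location=loc,
                               match_ic=m_ic, match_fc=m_fc, valid=valid)
            if valid:
                from .events import FootEvents
                score.ref_strides = compute_stride_params(foot)
                score.pred_strides = compute_stride_params(
                    FootEvents(pred_ic, pred_fc))
            scores.append(score)
    return scores


def summarize_scores(scores: list[TrialScore]) -> dict:
    """Pool trial scores into detection, timing and agreement summaries."""
    total_ic = sum((s.match_ic for s in scores), MatchResult([], 0, 0))
    total_fc = sum((s.match_fc for s in scores), MatchResult([], 0, 0))
    met_ic = detection_metrics(total_ic)
    met_fc = detection_metrics(total_fc)
    errors = np.concatenate([total_ic.time_errors, total_fc.time_errors])
    med, iqr = time_error_stats(errors)
    med_abs = float(np.median(np.abs(errors)))

    out = {
        "recall_ic": met_ic.recall, "precision_ic": met_ic.precision,
        "f1_ic": met_ic.f1,
        "recall_fc": met_fc.recall, "precision_fc": met_fc.precision,
        "f1_fc": met_fc.f1,
        "tp_ic": total_ic.tp, "fn_ic": total_ic.fn, "fp_ic": total_ic.fp,
        "tp_fc": total_fc.tp, "fn_fc": total_fc.fn, "fp_fc": total_fc.fp,
        "median_error_s": med, "iqr_error_s": iqr,
        "median_abs_error_s": med_abs,
        "n_trial_scores": len(scores),
        "n_valid": sum(s.valid for s in scores),
    }
    for param in ("stride_time_s", "stance_time_s", "swing_time_s"):
        ref = [getattr(p, param) for s in scores for p in s.ref_strides]
        pred = [getattr(p, param) for s in scores for p in s.pred_strides]
        if len(ref) >= 2:
            stats, _, _ = bland_altman(ref, pred)
            out[f"{param[:-2]}_mean_diff_s"] = stats.mean_difference_s
            out[f"{param[:-2]}_loa_low_s"] = stats.loa_low_s
            out[f"{param[:-2]}_loa_high_s"] = stats.loa_high_s
            out[f"{param[:-2]}_n"] = stats.n
    return out


@dataclass
class EndToEndResult:
    summary: dict
    scores: list[TrialScore]
    history: object
    model: TcnModel
    split: object


def run_end_to_end(n_subjects: int = 60, seed: int = 0,
                   tcn_config: TcnConfig | None = None,
                   train_cfg: TrainConfig | None = None,
                   n_strides: int = 8, fs: float = 200.0,
                   train_locations=("left_ankle", "right_shank"),
                   eval_locations=LOCATIONS,
                   window: int = 400, overlap: float = 0.5,
                   sigma_samples: float = 5.0, n_augment: int = 1,
                   tolerance_s: float = 0.25,
                   peak_cfg: PeakConfig | None = None) -> EndToEndResult:
    """Simulate a cohort, train the TCN, and score the held-out test subjects.

    Subjects are split into thirds at the subject level (stratified by
    group and gender); training windows are drawn from two sensor
    locations covering both sides and both attachment sites, each stream
    additionally re-rotated ``n_augment`` times; evaluation feeds every
    complete test trial of every location to the network.
    """
    tcn_config = tcn_config or TcnConfig()
    train_cfg = train_cfg or TrainConfig(max_epochs=30, patience=6, seed=seed)
    cohort = generate_cohort(n_subjects, seed=seed)
    split = split_cohort(cohort, seed=trial_seed(seed, "split"))
    by_id = {s.subject_id: s for s in cohort}

    def simulate_all(subject_ids):
        for sid in subject_ids:
            for speed in SPEED_FACTORS:
                trial = simulate_trial(by_id[sid], speed=speed, fs=fs,
                                       seed=trial_seed(seed, sid, speed),
                                       n_strides=n_strides)
                yield f"{sid}_{speed}", trial, reference_events(trial)

    def window_sets(subject_ids, augment):
        sets = []
        for trial_id, trial, events in simulate_all(subject_ids):
            sets += _window_sets_for_trial(
                trial, events, trial_id, train_locations, window, overlap,
                sigma_samples, n_augment=augment, seed=trial_seed(seed, "aug"))
        return concat_window_sets(sets)

    train_ws = window_sets(split.train, n_augment)
    val_ws = window_sets(split.validation, 0)

    model = build_model(tcn_config, seed=trial_seed(seed, "init"))
    history = train_model(model, train_ws, val_ws, train_cfg)

    test_trials = list(simulate_all(split.test))
    scores = evaluate_trials(model, test_trials, tolerance_s, peak_cfg,
                             locations=eval_locations)
    summary = summarize_scores(scores)
    summary["n_train_windows"] = len(train_ws)
    summary["n_test_trials"] = len(test_trials)
    return EndToEndResult(summary=summary, scores=scores, history=history,
                          model=model, split=split)
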