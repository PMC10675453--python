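"""Reduced-scale ground-truth recovery experiment shared by the acceptance
tests.

The study conditions (waveform structure, CO prior, QC thresholds) are the
package defaults; only the problem size is reduced — 64 Hz sampling,
2-second 128-sample windows, ~1,200 segments, a narrow model — so one CPU
can train both the dual-channel and the PPG-only variant in a few minutes.
"""

from __future__ import annotations

import numpy as np

from cowave.evaluation import PairedEstimates, compute_agreement
from cowave.model import (
    ModelConfig,
    TrainConfig,
    build_model,
    predict_co,
    split_dataset,
    train_model,
)
from cowave.preprocessing import normalize_segment, segment_record
from cowave.qc import screen_dataset
from cowave.synthetic import SimConfig, generate_dataset

REDUCED_SIM = SimConfig(sampling_rate=64.0, duration=22.0, co_interval=2.0)
REDUCED_WINDOW = 128  # 2 s at 64 Hz


def reduced_model_config(channels=("ppg", "art"), seed: int = 0) -> ModelConfig:
    return ModelConfig(
        input_length=REDUCED_WINDOW,
        channels=tuple(channels),
        depth=3,
        base_filters=8,
        bottleneck_lstm_units=16,
        head_lstm_units=16,
        seed=seed,
    )


def make_reduced_dataset(n_cases: int, seed: int):
    """Clean, screened, normalized reduced-scale segments."""
    records = generate_dataset(REDUCED_SIM, n_cases, seed=seed)
    segments = []
    for rec in records:
        segments.extend(segment_record(rec, window=REDUCED_WINDOW))
    kept, report = screen_dataset(segments)
    return [normalize_segment(s) for s in kept], report


def run_recovery_experiment(
    seed: int = 11,
    n_cases: int = 120,
    epochs: int = 25,
    with_ppg_only: bool = True,
) -> dict:
    """Train on the reduced-scale dataset; return held-out agreement numbers.

    Returns r against the simulator's noise-free ground truth (``r_true``),
    the full agreement report against the reference labels, and the held-out
    MSE of the dual-channel vs the PPG-only model on the same split.
    """
    data, qc_report = make_reduced_dataset(n_cases, seed)
    train_set, test_set = split_dataset(data, 0.8, seed=seed + 1)
    tc = TrainConfig(epochs=epochs, batch_size=32, seed=seed + 2)

    dual = train_model(build_model(reduced_model_config(seed=seed + 3)), train_set, tc)
    preds = predict_co(dual, test_set)
    y_true = np.array([s.true_co for s in test_set])
    y_ref = np.array([s.co_label for s in test_set])
    rep_true = compute_agreement(PairedEstimates(y_ref=y_true, y_pred=preds))
    rep_ref = compute_agreement(PairedEstimates(y_ref=y_ref, y_pred=preds))

    out = {
        "n_segments": len(data),
        "n_train": len(train_set),
        "n_test": len(test_set),
        "qc_kept": qc_report.n_passed,
        "qc_candidates": qc_report.n_candidates,
        "r_true": rep_true.pearson_r,
        "agreement_truth": rep_true,
        "agreement_ref": rep_ref,
        "mse_dual": float(np.mean((preds - y_ref) ** 2)),
        "best_epoch_dual": dual.best_epoch,
    }
    if with_ppg_only:
        ppg_only = train_model(
            build_model(reduced_model_config(channels=("ppg",), seed=seed + 3)),
            train_set,
            tc,
        )
        p1 = predict_co(ppg_only, test_set)
        out["mse_ppg"] = float(np.mean((p1 - y_ref) ** 2))
        out["r_true_ppg"] = compute_agreement(
            PairedEstimates(y_ref=y_true, y_pred=p1)
        ).pearson_r
    return out
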