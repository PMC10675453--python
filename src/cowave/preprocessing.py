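"""Filtering, windowing, segmentation, and normalization.

Raw records are band-pass filtered (second-order Butterworth, 0.5-10 Hz,
zero-phase by default), the middle analysis window is extracted, and one
candidate 2048-sample two-channel segment is cut per CO reading, spanning the
1024 samples before and after the reading's aligned sample. Quality control
runs on the *raw* windows (the high-pass removes the DC level the absolute
amplitude thresholds refer to); model inputs are the filtered windows min-max
scaled to [0, 1] per segment and channel, with CO labels affinely mapped from
the fixed physiologic range [2, 10] L/min to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from cowave.errors import MissingValuesError, RecordTooShortError, ValidationError
from cowave.synthetic import CO_MAX, CO_MIN, WaveformRecord

#: model window length in samples: 4.096 s at 500 Hz, divisible by 16
SEGMENT_LENGTH = 2048


@dataclass(frozen=True)
class FilterConfig:
    order: int = 2
    low_cut: float = 0.5  # Hz
    high_cut: float = 10.0  # Hz
    family: str = "butterworth"
    zero_phase: bool = True

    def validate(self, sampling_rate: float) -> None:
        if self.family != "butterworth":
            raise ValidationError(f"unsupported filter family {self.family!r}")
        if not (0 < self.low_cut < self.high_cut):
            raise ValidationError(
                f"need 0 < low_cut < high_cut, got {self.low_cut}, {self.high_cut}"
            )
        if self.high_cut >= sampling_rate / 2:
            raise ValidationError(
                f"high_cut {self.high_cut} Hz must be below the Nyquist frequency "
                f"{sampling_rate / 2} Hz"
            )
        if self.order < 1:
            raise ValidationError(f"order must be >= 1, got {self.order}")


@dataclass
class Segment:
    """One training sample: raw windows for QC, filtered/normalized inputs."""

    case_id: str
    ppg_raw: np.ndarray
    art_raw: np.ndarray
    ppg_in: np.ndarray  # filtered; [0, 1] after normalize_segment
    art_in: np.ndarray
    co_label: float  # L/min
    co_label_scaled: float  # unitless, (co - 2) / 8
    center_index: int
    true_co: Optional[float] = None
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return int(self.ppg_raw.size)


def scale_label(co: float) -> float:
    """Map CO in L/min to [0, 1] using the fixed [2, 10] physiologic range."""
    return (co - CO_MIN) / (CO_MAX - CO_MIN)


def unscale_label(scaled):
    """Exact inverse of :func:`scale_label`; accepts scalars or arrays."""
    return CO_MIN + np.asarray(scaled, dtype=float) * (CO_MAX - CO_MIN)


def bandpass_filter(
    signal: np.ndarray, sampling_rate: float, config: FilterConfig = FilterConfig()
) -> np.ndarray:
    """Butterworth band-pass; forward-backward (zero-phase) when configured."""
    config.validate(sampling_rate)
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise MissingValuesError(
            "signal contains non-finite samples; run the missing-value screen "
            "(extract_middle_window / QC completeness rule) before filtering"
        )
    if x.size <= 3 * config.order:
        raise ValidationError(f"signal too short ({x.size}) for order {config.order}")
    sos = sps.butter(
        config.order,
        [config.low_cut, config.high_cut],
        btype="bandpass",
        fs=sampling_rate,
        output="sos",
    )
    if config.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def extract_middle_window(record: WaveformRecord, window_s: float = 60.0) -> WaveformRecord:
    """Return the centered *window_s* sub-record with CO readings re-based.

    Raises :class:`RecordTooShortError` when the record cannot cover the
    window and :class:`MissingValuesError` when the window contains undefined
    samples (such cases are excluded from analysis, mirroring the deletion of
    empty-valued exports).
    """
    n_window = int(round(window_s * record.sampling_rate))
    if record.n_samples < n_window:
        raise RecordTooShortError(
            f"case {record.case_id}: record of {record.duration:.1f} s is shorter "
            f"than the {window_s:.1f} s analysis window"
        )
    start = (record.n_samples - n_window) // 2
    stop = start + n_window
    ppg = record.ppg[start:stop]
    art = record.art[start:stop]
    if not (np.all(np.isfinite(ppg)) and np.all(np.isfinite(art))):
        raise MissingValuesError(
            f"case {record.case_id}: empty values inside the analysis window; case excluded"
        )
    keep = (record.co_sample_indices >= start) & (record.co_sample_indices < stop)
    return WaveformRecord(
        case_id=record.case_id,
        sampling_rate=record.sampling_rate,
        ppg=ppg.copy(),
        art=art.copy(),
        co_values=record.co_values[keep].copy(),
        co_sample_indices=record.co_sample_indices[keep] - start,
        true_co=None if record.true_co is None else record.true_co[keep].copy(),
        meta=dict(record.meta),
    )


def segment_record(
    record: WaveformRecord,
    window: int = SEGMENT_LENGTH,
    filter_config: Optional[FilterConfig] = FilterConfig(),
) -> List[Segment]:
    """Cut one candidate segment per CO reading.

    Each candidate spans the half-open window ``[c - window/2, c + window/2)``
    around the reading's aligned sample ``c``; candidates that would extend
    past either end of the record are silently dropped (callers recover the
    count as ``len(co_values) - len(segments)``). When *filter_config* is
    given, the full channels are filtered once and the filtered windows are
    stored as the (not yet normalized) model inputs.
    """
    if window < 2 or window % 2:
        raise ValidationError(f"window must be a positive even sample count, got {window}")
    half = window // 2
    if filter_config is not None:
        ppg_f = bandpass_filter(record.ppg, record.sampling_rate, filter_config)
        art_f = bandpass_filter(record.art, record.sampling_rate, filter_config)
    else:
        ppg_f, art_f = record.ppg, record.art
    segments: List[Segment] = []
    for k, c in enumerate(record.co_sample_indices):
        start, stop = int(c) - half, int(c) + half
        if start < 0 or stop > record.n_samples:
            continue
        co = float(record.co_values[k])
        segments.append(
            Segment(
                case_id=record.case_id,
                ppg_raw=record.ppg[start:stop].copy(),
                art_raw=record.art[start:stop].copy(),
                ppg_in=ppg_f[start:stop].copy(),
                art_in=art_f[start:stop].copy(),
                co_label=co,
                co_label_scaled=scale_label(co),
                center_index=int(c),
                true_co=None if record.true_co is None else float(record.true_co[k]),
            )
        )
    return segments


def normalize_segment(segment: Segment) -> Segment:
    """Min-max scale each filtered channel to [0, 1], per segment per channel."""
    channels = {}
    for name in ("ppg_in", "art_in"):
        x = getattr(segment, name)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi - lo <= 0:
            raise ValidationError(
                f"channel {name} has zero peak-to-peak amplitude; the segment "
                "should have been removed by the peak-to-peak screening rule"
            )
        channels[name] = (x - lo) / (hi - lo)
    return Segment(
        case_id=segment.case_id,
        ppg_raw=segment.ppg_raw,
        art_raw=segment.art_raw,
        ppg_in=channels["ppg_in"],
        art_in=channels["art_in"],
        co_label=segment.co_label,
        co_label_scaled=segment.co_label_scaled,
        center_index=segment.center_index,
        true_co=segment.true_co,
        normalized=True,
        meta=dict(segment.meta),
    )
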