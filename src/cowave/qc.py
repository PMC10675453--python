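"""Segment quality screening.

Seven waveform/label rules plus a completeness check, applied to the *raw*
(unfiltered) windows so the absolute amplitude thresholds keep their physical
meaning:

- ``co_range``          label within [2, 10] L/min
- ``art_amplitude``     every ART sample within [30, 200] mmHg
- ``ppg_amplitude``     every PPG sample within [10, 100] a.u.
- ``art_peak_to_peak``  ART max - min >= 30 mmHg (pulse pressure present)
- ``ppg_peak_to_peak``  PPG max - min >= 20 a.u. (no flatline)
- ``ppg_slew``          max |x[i+1] - x[i]| <= 20 a.u. per sample
- ``art_slew``          max |x[i+1] - x[i]| <= 30 mmHg per sample
- ``completeness``      no undefined (NaN) samples

Amplitude rules require every sample in range; slew rules bound the absolute
adjacent-sample difference (catching both polarities). A segment failing
several rules is counted once in ``n_failed`` but appears in each rule's
tally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Dict, Iterable, List, Tuple

import numpy as np

from cowave.errors import ValidationError
from cowave.preprocessing import Segment

RULE_NAMES = (
    "co_range",
    "art_amplitude",
    "ppg_amplitude",
    "art_peak_to_peak",
    "ppg_peak_to_peak",
    "ppg_slew",
    "art_slew",
    "completeness",
)


@dataclass(frozen=True)
class QCConfig:
    co_min: float = 2.0  # L/min
    co_max: float = 10.0
    art_min: float = 30.0  # mmHg
    art_max: float = 200.0
    ppg_min: float = 10.0  # a.u.
    ppg_max: float = 100.0
    art_pp_min: float = 30.0  # mmHg
    ppg_pp_min: float = 20.0  # a.u.
    ppg_slew_max: float = 20.0  # a.u. per sample
    art_slew_max: float = 30.0  # mmHg per sample

    def validate(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValidationError(f"{f.name} must be positive")
        if self.co_min >= self.co_max:
            raise ValidationError("co_min must be below co_max")
        if self.art_min >= self.art_max:
            raise ValidationError("art_min must be below art_max")
        if self.ppg_min >= self.ppg_max:
            raise ValidationError("ppg_min must be below ppg_max")


@dataclass(frozen=True)
class QCResult:
    co_range: bool
    art_amplitude: bool
    ppg_amplitude: bool
    art_peak_to_peak: bool
    ppg_peak_to_peak: bool
    ppg_slew: bool
    art_slew: bool
    completeness: bool

    @property
    def passed(self) -> bool:
        return all(getattr(self, name) for name in RULE_NAMES)

    def failed_rules(self) -> Tuple[str, ...]:
        return tuple(name for name in RULE_NAMES if not getattr(self, name))


@dataclass
class QCReport:
    n_candidates: int = 0
    n_passed: int = 0
    n_failed: int = 0
    failure_tally: Dict[str, int] = field(
        default_factory=lambda: {name: 0 for name in RULE_NAMES}
    )
    results: List[QCResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_candidates": self.n_candidates,
            "n_passed": self.n_passed,
            "n_failed": self.n_failed,
            "failure_tally": dict(self.failure_tally),
            "segments": [
                {"passed": r.passed, "failed_rules": list(r.failed_rules())}
                for r in self.results
            ],
        }


def _nanmax_abs_diff(x: np.ndarray) -> float:
    d = np.abs(np.diff(x))
    d = d[np.isfinite(d)]
    return float(d.max()) if d.size else 0.0


def evaluate_rules(segment: Segment, config: QCConfig = QCConfig()) -> QCResult:
    """Evaluate every screening rule on a segment's raw windows and label.

    NaN samples fail only the completeness rule: the other rules are
    evaluated on the finite samples so that failure attribution stays
    targeted.
    """
    config.validate()
    ppg, art = np.asarray(segment.ppg_raw, float), np.asarray(segment.art_raw, float)
    if ppg.size != art.size or ppg.size < 2:
        raise ValidationError(
            f"raw windows must be equal-length (>= 2 samples); got {ppg.size} and {art.size}"
        )
    ppg_fin, art_fin = ppg[np.isfinite(ppg)], art[np.isfinite(art)]
    complete = ppg_fin.size == ppg.size and art_fin.size == art.size
    return QCResult(
        co_range=bool(config.co_min <= segment.co_label <= config.co_max),
        art_amplitude=bool(
            art_fin.size and art_fin.min() >= config.art_min and art_fin.max() <= config.art_max
        ),
        ppg_amplitude=bool(
            ppg_fin.size and ppg_fin.min() >= config.ppg_min and ppg_fin.max() <= config.ppg_max
        ),
        art_peak_to_peak=bool(art_fin.size and np.ptp(art_fin) >= config.art_pp_min),
        ppg_peak_to_peak=bool(ppg_fin.size and np.ptp(ppg_fin) >= config.ppg_pp_min),
        ppg_slew=bool(_nanmax_abs_diff(ppg) <= config.ppg_slew_max),
        art_slew=bool(_nanmax_abs_diff(art) <= config.art_slew_max),
        completeness=complete,
    )


def screen_dataset(
    segments: Iterable[Segment], config: QCConfig = QCConfig()
) -> Tuple[List[Segment], QCReport]:
    """Screen segments, preserving order of the kept ones; tally every rule."""
    report = QCReport()
    kept: List[Segment] = []
    for seg in segments:
        result = evaluate_rules(seg, config)
        report.n_candidates += 1
        report.results.append(result)
        if result.passed:
            report.n_passed += 1
            kept.append(seg)
        else:
            report.n_failed += 1
            for rule in result.failed_rules():
                report.failure_tally[rule] += 1
    return kept, report
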