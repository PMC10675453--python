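"""Method-comparison statistics between predicted and reference cardiac output.

Conventions (method-comparison standard for CO monitors):

- differences are ``y_pred - y_ref``; bias is their signed mean
- std is the population (1/n) standard deviation of the differences
- LOA half-width = 1.96 * std; limits of agreement = bias +/- 1.96 * std
- RMSNE = 100 * RMSE / mean(y_ref), in percent
- PE (percentage error) = 100 * LOA half-width / mean(y_ref), in percent;
  PE < 30% is the conventional clinical-acceptability threshold
- Pearson r on a constant sequence is an explicit condition, never a silent 0
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Tuple

import numpy as np

from cowave.errors import ConstantInputError, ValidationError

PE_CLINICAL_THRESHOLD = 30.0  # percent
LOA_FACTOR = 1.96  # 95% limits of agreement


@dataclass(frozen=True)
class PairedEstimates:
    """Paired reference / predicted CO sequences, both in L/min."""

    y_ref: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "y_ref", np.asarray(self.y_ref, dtype=float))
        object.__setattr__(self, "y_pred", np.asarray(self.y_pred, dtype=float))
        if self.y_ref.shape != self.y_pred.shape or self.y_ref.ndim != 1:
            raise ValidationError(
                f"y_ref and y_pred must be equal-length 1-D sequences, got "
                f"{self.y_ref.shape} and {self.y_pred.shape}"
            )
        if self.n < 2:
            raise ValidationError(f"need at least 2 pairs, got {self.n}")
        if not (np.all(np.isfinite(self.y_ref)) and np.all(np.isfinite(self.y_pred))):
            raise ValidationError("paired estimates must be finite")

    @property
    def n(self) -> int:
        return int(self.y_ref.size)

    @property
    def differences(self) -> np.ndarray:
        return self.y_pred - self.y_ref


@dataclass(frozen=True)
class AgreementReport:
    n: int
    bias: float  # L/min, mean(y_pred - y_ref)
    std: float  # L/min, population SD of differences
    loa_half_width: float  # L/min, 1.96 * std
    loa_lower: float
    loa_upper: float
    mse: float  # (L/min)^2
    mae: float  # L/min
    rmse: float  # L/min
    rmsne: float  # percent
    pe: float  # percent
    pearson_r: float  # NaN when undefined (see notes)
    mean_ref_co: float  # L/min
    clinically_acceptable: bool  # pe < 30
    notes: Tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["notes"] = list(self.notes)
        return d


@dataclass(frozen=True)
class BlandAltmanData:
    means: np.ndarray  # (y_pred + y_ref) / 2
    differences: np.ndarray  # y_pred - y_ref
    mean_difference: float  # bias line
    loa_lower: float
    loa_upper: float


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; raises :class:`ConstantInputError` on constant input."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError(
            "Pearson correlation is undefined for a constant sequence"
        )
    return float(np.corrcoef(x, y)[0, 1])


def compute_agreement(pairs: PairedEstimates) -> AgreementReport:
    """All paired-comparison statistics for one prediction/reference set.

    When either sequence is constant the Pearson coefficient is reported as
    NaN with an explanatory note in ``notes`` (the remaining statistics are
    still well defined).
    """
    d = pairs.differences
    mean_ref = float(np.mean(pairs.y_ref))
    if mean_ref == 0:
        raise ValidationError("mean reference CO is zero; RMSNE and PE are undefined")
    bias = float(np.mean(d))
    std = float(np.std(d))  # population (1/n) normalization
    loa_half = LOA_FACTOR * std
    mse = float(np.mean(d**2))
    mae = float(np.mean(np.abs(d)))
    rmse = math.sqrt(mse)
    notes: Tuple[str, ...] = ()
    try:
        r = pearson_r(pairs.y_ref, pairs.y_pred)
    except ConstantInputError as exc:
        r = float("nan")
        notes = (f"pearson_r undefined: {exc}",)
    pe = 100.0 * loa_half / mean_ref
    return AgreementReport(
        n=pairs.n,
        bias=bias,
        std=std,
        loa_half_width=loa_half,
        loa_lower=bias - loa_half,
        loa_upper=bias + loa_half,
        mse=mse,
        mae=mae,
        rmse=rmse,
        rmsne=100.0 * rmse / mean_ref,
        pe=pe,
        pearson_r=r,
        mean_ref_co=mean_ref,
        clinically_acceptable=bool(pe < PE_CLINICAL_THRESHOLD),
        notes=notes,
    )


def bland_altman(pairs: PairedEstimates) -> BlandAltmanData:
    """Per-pair mean/difference points plus the bias and agreement lines."""
    report = compute_agreement(pairs)
    return BlandAltmanData(
        means=(pairs.y_pred + pairs.y_ref) / 2.0,
        differences=pairs.differences,
        mean_difference=report.bias,
        loa_lower=report.loa_lower,
        loa_upper=report.loa_upper,
    )


def identity_fit(pairs: PairedEstimates) -> Tuple[float, float]:
    """Ordinary least squares of y_pred on y_ref: returns (slope, intercept).

    Perfect agreement gives slope 1, intercept 0 (the identity line of a
    prediction-vs-reference scatter plot).
    """
    if np.ptp(pairs.y_ref) == 0:
        raise ConstantInputError("least-squares fit is undefined for constant y_ref")
    slope, intercept = np.polyfit(pairs.y_ref, pairs.y_pred, 1)
    return float(slope), float(intercept)
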