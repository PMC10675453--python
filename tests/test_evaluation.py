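"""Agreement statistics: naive-loop oracle equivalence, hand-computed
examples, Bland-Altman consistency, least-squares identity fit, and the
symmetry/scale invariances of method-comparison metrics."""

import math

import numpy as np
import pytest

from cowave.errors import ConstantInputError, ValidationError
from cowave.evaluation import (
    PairedEstimates,
    bland_altman,
    compute_agreement,
    identity_fit,
    pearson_r,
)


def naive_agreement(y_ref, y_pred):
    """Loop-based oracle for every statistic (kept independent of numpy
    vector semantics on purpose)."""
    n = len(y_ref)
    d = [p - r for p, r in zip(y_pred, y_ref)]
    bias = sum(d) / n
    var = sum((x - bias) ** 2 for x in d) / n
    std = math.sqrt(var)
    mse = sum(x**2 for x in d) / n
    mae = sum(abs(x) for x in d) / n
    rmse = math.sqrt(mse)
    mean_ref = sum(y_ref) / n
    mx = sum(y_ref) / n
    my = sum(y_pred) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(y_ref, y_pred))
    sxx = math.sqrt(sum((a - mx) ** 2 for a in y_ref))
    syy = math.sqrt(sum((b - my) ** 2 for b in y_pred))
    r = sxy / (sxx * syy) if sxx > 0 and syy > 0 else None
    return {
        "bias": bias,
        "std": std,
        "loa_half_width": 1.96 * std,
        "loa_lower": bias - 1.96 * std,
        "loa_upper": bias + 1.96 * std,
        "mse": mse,
        "mae": mae,
        "rmse": rmse,
        "rmsne": 100 * rmse / mean_ref,
        "pe": 100 * 1.96 * std / mean_ref,
        "pearson_r": r,
        "mean_ref_co": mean_ref,
    }


class TestComputeAgreement:
    def test_matches_naive_oracle_on_random_pairs(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            y_ref = rng.uniform(2, 10, n)
            y_pred = y_ref + rng.normal(0, 0.6, n)
            rep = compute_agreement(PairedEstimates(y_ref=y_ref, y_pred=y_pred))
            want = naive_agreement(list(y_ref), list(y_pred))
            for key, value in want.items():
                if value is None:
                    continue
                assert getattr(rep, key) == pytest.approx(value, abs=1e-9), key

    def test_identity_predictions(self, rng):
        y = rng.uniform(2, 10, 25)
        rep = compute_agreement(PairedEstimates(y_ref=y, y_pred=y.copy()))
        for key in ("bias", "std", "mse", "rmse", "mae", "pe", "rmsne"):
            assert getattr(rep, key) == pytest.approx(0.0, abs=1e-12)
        assert rep.clinically_acceptable

    def test_hand_computed_three_pair_example(self):
        rep = compute_agreement(
            PairedEstimates(y_ref=np.array([4.0, 5.0, 6.0]), y_pred=np.array([5.0, 5.0, 5.0]))
        )
        assert rep.bias == pytest.approx(0.0)
        assert rep.mae == pytest.approx(2 / 3)
        assert rep.mse == pytest.approx(2 / 3)
        # constant predictions: correlation undefined, flagged explicitly
        assert math.isnan(rep.pearson_r)
        assert any("pearson" in note for note in rep.notes)

    def test_pearson_helper_raises_on_constant(self):
        with pytest.raises(ConstantInputError):
            pearson_r(np.array([1.0, 2.0]), np.array([3.0, 3.0]))

    def test_report_internal_invariants(self, rng):
        y_ref = rng.uniform(2, 10, 60)
        y_pred = y_ref + rng.normal(0, 0.5, 60)
        rep = compute_agreement(PairedEstimates(y_ref=y_ref, y_pred=y_pred))
        assert rep.rmse**2 == pytest.approx(rep.mse, rel=1e-12)
        assert rep.loa_half_width == pytest.approx(1.96 * rep.std)
        assert rep.loa_lower == pytest.approx(rep.bias - rep.loa_half_width)
        assert rep.loa_upper == pytest.approx(rep.bias + rep.loa_half_width)
        assert rep.rmsne == pytest.approx(100 * rep.rmse / rep.mean_ref_co)
        assert rep.pe == pytest.approx(100 * rep.loa_half_width / rep.mean_ref_co)
        assert -1 <= rep.pearson_r <= 1

    def test_swap_symmetry(self, rng):
        y_ref = rng.uniform(2, 10, 40)
        y_pred = y_ref + rng.normal(0, 0.5, 40)
        a = compute_agreement(PairedEstimates(y_ref=y_ref, y_pred=y_pred))
        b = compute_agreement(PairedEstimates(y_ref=y_pred, y_pred=y_ref))
        assert b.bias == pytest.approx(-a.bias)
        for key in ("std", "mse", "mae", "rmse", "pearson_r"):
            assert getattr(b, key) == pytest.approx(getattr(a, key))

    def test_positive_scaling_behaviour(self, rng):
        y_ref = rng.uniform(2, 10, 40)
        y_pred = y_ref + rng.normal(0, 0.5, 40)
        a = compute_agreement(PairedEstimates(y_ref=y_ref, y_pred=y_pred))
        c = 2.5
        b = compute_agreement(PairedEstimates(y_ref=c * y_ref, y_pred=c * y_pred))
        for key in ("bias", "std", "mae", "rmse"):
            assert getattr(b, key) == pytest.approx(c * getattr(a, key))
        for key in ("rmsne", "pe", "pearson_r"):
            assert getattr(b, key) == pytest.approx(getattr(a, key))

    def test_validation(self):
        with pytest.raises(ValidationError):
            PairedEstimates(y_ref=np.array([1.0]), y_pred=np.array([1.0]))
        with pytest.raises(ValidationError):
            PairedEstimates(y_ref=np.array([1.0, np.nan]), y_pred=np.array([1.0, 2.0]))
        with pytest.raises(ValidationError, match="zero"):
            compute_agreement(
                PairedEstimates(y_ref=np.array([-1.0, 1.0]), y_pred=np.array([0.0, 0.5]))
            )


class TestBlandAltman:
    def test_identical_pairs_all_lines_at_zero(self, rng):
        y = rng.uniform(2, 10, 20)
        ba = bland_altman(PairedEstimates(y_ref=y, y_pred=y.copy()))
        assert np.allclose(ba.differences, 0)
        assert ba.mean_difference == ba.loa_lower == ba.loa_upper == 0

    def test_two_pair_symmetry(self):
        ba = bland_altman(
            PairedEstimates(y_ref=np.array([4.0, 6.0]), y_pred=np.array([5.0, 5.0]))
        )
        assert np.allclose(ba.differences, [1.0, -1.0])
        assert ba.mean_difference == pytest.approx(0.0)
        assert np.allclose(ba.means, [4.5, 5.5])

    def test_lines_consistent_with_agreement(self, rng):
        y_ref = rng.uniform(2, 10, 50)
        y_pred = y_ref + rng.normal(0, 0.5, 50)
        pairs = PairedEstimates(y_ref=y_ref, y_pred=y_pred)
        rep = compute_agreement(pairs)
        ba = bland_altman(pairs)
        assert ba.mean_difference == pytest.approx(rep.bias)
        assert ba.loa_lower == pytest.approx(rep.loa_lower)
        assert ba.loa_upper == pytest.approx(rep.loa_upper)


class TestIdentityFit:
    def test_perfect_agreement(self, rng):
        y = rng.uniform(2, 10, 30)
        slope, intercept = identity_fit(PairedEstimates(y_ref=y, y_pred=y.copy()))
        assert slope == pytest.approx(1.0) and intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_data(self, rng):
        y = rng.uniform(2, 10, 30)
        slope, intercept = identity_fit(PairedEstimates(y_ref=y, y_pred=2 * y + 1))
        assert slope == pytest.approx(2.0) and intercept == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self, rng):
        y_ref = rng.uniform(2, 10, 50)
        y_pred = y_ref + rng.normal(0, 0.5, 50)
        slope, intercept = identity_fit(PairedEstimates(y_ref=y_ref, y_pred=y_pred))
        # closed-form normal equations
        n = 50
        sx, sy = y_ref.sum(), y_pred.sum()
        sxx, sxy = (y_ref**2).sum(), (y_ref * y_pred).sum()
        slope_o = (n * sxy - sx * sy) / (n * sxx - sx**2)
        intercept_o = (sy - slope_o * sx) / n
        assert slope == pytest.approx(slope_o, abs=1e-9)
        assert intercept == pytest.approx(intercept_o, abs=1e-9)

    def test_constant_reference_rejected(self):
        with pytest.raises(ConstantInputError):
            identity_fit(PairedEstimates(y_ref=np.array([5.0, 5.0]), y_pred=np.array([4.0, 6.0])))
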