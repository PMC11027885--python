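"""Referencing, transport ratios, standard curves and vesicle analysis."""

import numpy as np
import pandas as pd
import pytest

from pgpflux.assay import (StandardCurve, absorbance_to_concentration,
                           correct_sampling_dilution, double_reference,
                           fit_standard_curve, transport_efficiency,
                           transport_ratio, vesicle_assay_efficiency)
from pgpflux.reference import DEMO_RATES
from pgpflux.synth import generate_sensorgram_set, make_paired_condition_set
from pgpflux.transport import ObservableParams, PhaseSchedule


class TestDoubleReference:
    def test_zero_references_identity(self):
        s = np.array([1.0, 2.0, 3.0])
        z = np.zeros(3)
        assert np.array_equal(double_reference(s, z, z), s)

    def test_sample_equal_to_reference_plus_blank_annihilates(self):
        r = np.array([0.5, 1.0, 2.0])
        b = np.array([0.1, 0.2, 0.3])
        assert np.allclose(double_reference(r + b, r, b), 0.0)

    def test_constant_offsets(self):
        out = double_reference(np.full(4, 10.0), np.full(4, 3.0), np.full(4, 2.5))
        assert np.allclose(out, 4.5)

    def test_linearity_in_sample(self):
        rng = np.random.default_rng(0)
        a, b, r, bl = (rng.normal(size=50) for _ in range(4))
        lhs = double_reference(a + b, r, bl)
        rhs = double_reference(a, r, bl) + b
        assert np.allclose(lhs, rhs)

    def test_misaligned_grids_rejected(self):
        t1 = np.linspace(0, 10, 11)
        t2 = t1 + 0.5
        z = np.zeros(11)
        with pytest.raises(ValueError, match="misaligned"):
            double_reference(z, z, z, times=(t1, t2, t1))


@pytest.fixture(scope="module")
def paired():
    phases = PhaseSchedule(300.0, 500.0)
    kw = dict(observable=ObservableParams(k=1e6, c=10.0), phases=phases,
              dt=4.0, concentrations_um=[500.0, 125.0, 31.25])
    atp = make_paired_condition_set(DEMO_RATES, True, **kw)
    apo = make_paired_condition_set(DEMO_RATES, False, **kw)
    return atp, apo


class TestTransportRatio:
    def test_identical_sets_give_exactly_one(self, paired):
        atp, _ = paired
        tr = transport_ratio(atp, atp)
        assert tr.ratio == 1.0 and tr.sd == 0.0

    def test_active_transport_gives_ratio_above_one(self, paired):
        atp, apo = paired
        tr = transport_ratio(atp, apo)
        assert tr.ratio > 1.0
        assert tr.n == 3

    def test_constructed_proportionality(self, paired):
        _, apo = paired
        boosted = make_paired_condition_set(
            DEMO_RATES, False, observable=ObservableParams(k=1e6, c=10.0),
            phases=PhaseSchedule(300.0, 500.0), dt=4.0,
            concentrations_um=[500.0, 125.0, 31.25])
        # amplitudes are baseline-referenced, so scaling (RU - C) by 1.3
        # makes every amplitude exactly 1.3x the reference arm's
        boosted.traces = 10.0 + 1.3 * (boosted.traces - 10.0)
        tr = transport_ratio(boosted, apo)
        assert tr.ratio == pytest.approx(1.30, rel=1e-9)
        assert tr.sd == pytest.approx(0.0, abs=1e-9)

    def test_scale_invariance(self, paired):
        atp, apo = paired
        base = transport_ratio(atp, apo).ratio
        atp2, apo2 = paired
        atp_scaled = make_paired_condition_set(
            DEMO_RATES, True, observable=ObservableParams(k=1e6, c=10.0),
            phases=PhaseSchedule(300.0, 500.0), dt=4.0,
            concentrations_um=[500.0, 125.0, 31.25])
        apo_scaled = make_paired_condition_set(
            DEMO_RATES, False, observable=ObservableParams(k=1e6, c=10.0),
            phases=PhaseSchedule(300.0, 500.0), dt=4.0,
            concentrations_um=[500.0, 125.0, 31.25])
        atp_scaled.traces = atp_scaled.traces * 7.0
        apo_scaled.traces = apo_scaled.traces * 7.0
        assert transport_ratio(atp_scaled, apo_scaled).ratio == pytest.approx(base)

    def test_nonpositive_reference_amplitudes_excluded(self, paired):
        atp, apo = paired
        flat = make_paired_condition_set(
            DEMO_RATES, False, observable=ObservableParams(k=0.0, c=10.0),
            phases=PhaseSchedule(300.0, 500.0), dt=4.0,
            concentrations_um=[500.0, 125.0, 31.25])
        with pytest.raises(ValueError, match="undefined"):
            with pytest.warns(UserWarning, match="excluding"):
                transport_ratio(atp, flat)


class TestTransportEfficiency:
    @pytest.mark.parametrize("initial,sample,expected",
                             [(100.0, 100.0, 0.0), (100.0, 0.0, 100.0),
                              (100.0, 83.0, 17.0)])
    def test_endpoint_and_midpoint_values(self, initial, sample, expected):
        assert transport_efficiency(initial, sample) == pytest.approx(expected)

    def test_affine_in_sample_concentration(self):
        initial = 40.0
        s = np.linspace(0, 80, 9)
        with np.errstate(all="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                eff = np.array([transport_efficiency(initial, x) for x in s])
        slopes = np.diff(eff) / np.diff(s)
        assert np.allclose(slopes, -100.0 / initial)

    def test_zero_initial_rejected(self):
        with pytest.raises(ZeroDivisionError):
            transport_efficiency(0.0, 1.0)

    def test_negative_efficiency_flagged(self):
        with pytest.warns(UserWarning, match="negative"):
            assert transport_efficiency(10.0, 12.0) == pytest.approx(-20.0)


class TestStandardCurve:
    def test_perfect_dilution_series_roundtrip(self):
        conc = 100.0 / 2 ** np.arange(8)
        curve_truth = StandardCurve(slope=0.01, intercept=0.05)
        absorb = curve_truth.slope * conc + curve_truth.intercept
        fit = fit_standard_curve(conc, absorb)
        assert fit.r_squared == pytest.approx(1.0)
        back = absorbance_to_concentration(absorb, fit)
        assert np.max(np.abs(back - conc)) < 1e-10

    def test_arithmetic_example(self):
        curve = StandardCurve(slope=0.01, intercept=0.05)
        assert absorbance_to_concentration(0.55, curve) == pytest.approx(50.0)
        assert absorbance_to_concentration(0.05, curve) == pytest.approx(0.0)

    def test_below_intercept_clips_with_warning(self):
        curve = StandardCurve(slope=0.01, intercept=0.05)
        with pytest.warns(UserWarning, match="clipping"):
            assert absorbance_to_concentration(0.01, curve) == 0.0

    def test_invalid_slope_and_sparse_curve_rejected(self):
        with pytest.raises(ValueError):
            StandardCurve(slope=-1.0, intercept=0.0)
        with pytest.raises(ValueError, match=">= 4"):
            fit_standard_curve([1, 2, 3], [0.1, 0.2, 0.3])


class TestVesicleAssay:
    def test_dilution_correction_accumulates_removed_analyte(self):
        measured = np.array([10.0, 10.0, 10.0, 10.0])
        corrected = correct_sampling_dilution(measured, 0.2, 20.0)
        expected = measured + 0.01 * np.array([0.0, 10.0, 20.0, 30.0])
        assert np.allclose(corrected, expected)

    def test_efficiency_time_course_tidy_output(self):
        curve = StandardCurve(slope=0.01, intercept=0.0)
        rows = []
        for rep in (1, 2):
            for t, eff in ((10, 10.0), (30, 12.0), (60, 15.0), (120, 17.0)):
                conc = 100.0 * (1 - eff / 100.0)
                rows.append({"time_min": t, "abs550": 0.01 * conc,
                             "condition": "ATP", "replicate": rep})
        out = vesicle_assay_efficiency(pd.DataFrame(rows), 100.0, curve)
        assert set(out["condition"]) == {"ATP"}
        assert list(out["n"]) == [2, 2, 2, 2]
        # sampling correction slightly lowers the apparent efficiency
        at_10 = out[out["time_min"] == 10]["efficiency_pct_mean"].item()
        assert at_10 == pytest.approx(10.0, abs=0.01)
        at_120 = out[out["time_min"] == 120]["efficiency_pct_mean"].item()
        assert 14.0 < at_120 < 17.0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            vesicle_assay_efficiency(pd.DataFrame({"time_min": []}), 100.0,
                                     StandardCurve(slope=1.0, intercept=0.0))
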