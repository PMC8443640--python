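"""IICR curve container: validation, evaluation, unit conversions, distance
metric, PSMC-style discretization and TSV round trips."""

import numpy as np
import pytest

from demoscope import (
    IICRCurve,
    ScalingConstants,
    curve_distance,
    discretize_like_psmc,
    read_curve_tsv,
    rescale_curve,
    write_curve_tsv,
)


def sampled_curve(**kw):
    return IICRCurve(np.array([0.1, 1.0, 10.0]), np.array([1.0, 2.0, 4.0]), **kw)


def step_curve(**kw):
    return IICRCurve(np.array([0.1, 1.0, 10.0]), np.array([1.0, 5.0]), kind="step", **kw)


class TestValidation:
    def test_sampled_length_mismatch(self):
        with pytest.raises(ValueError, match="times"):
            IICRCurve(np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]))

    def test_step_needs_one_more_edge(self):
        with pytest.raises(ValueError):
            IICRCurve(np.array([1.0, 2.0]), np.array([1.0, 2.0]), kind="step")
        step_curve()  # valid

    def test_times_strictly_increasing(self):
        with pytest.raises(ValueError, match="increasing"):
            IICRCurve(np.array([1.0, 1.0, 2.0]), np.array([1.0, 2.0, 3.0]))

    def test_values_positive_finite(self):
        with pytest.raises(ValueError):
            IICRCurve(np.array([1.0, 2.0]), np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            IICRCurve(np.array([1.0, 2.0]), np.array([1.0, np.inf]))

    def test_unit_tags(self):
        with pytest.raises(ValueError, match="time units"):
            sampled_curve(time_units="days")
        with pytest.raises(ValueError, match="size units"):
            sampled_curve(size_units="absolute")
        with pytest.raises(ValueError, match="kind"):
            sampled_curve(kind="spline")

    def test_scaling_constants_positive(self):
        with pytest.raises(ValueError):
            ScalingConstants(mu=0.0)
        with pytest.raises(ValueError):
            ScalingConstants(g=-1.0)
        with pytest.raises(ValueError):
            ScalingConstants(s=0)


class TestEvaluation:
    def test_step_is_piecewise_constant(self):
        c = step_curve()
        t = np.array([0.05, 0.5, 0.999, 1.0, 5.0, 20.0])
        assert np.array_equal(c(t), [1.0, 1.0, 1.0, 5.0, 5.0, 5.0])

    def test_sampled_loglog_interpolation(self):
        c = sampled_curve()
        # halfway in log time between 1 and 10 -> geometric mean of 2 and 4
        mid = np.sqrt(1.0 * 10.0)
        assert c(np.array([mid]))[0] == pytest.approx(np.sqrt(2.0 * 4.0))

    def test_constant_extrapolation(self):
        c = sampled_curve()
        assert c(np.array([1e-6]))[0] == pytest.approx(1.0)
        assert c(np.array([1e6]))[0] == pytest.approx(4.0)

    def test_mean_over_constant_curve(self):
        c = IICRCurve(np.array([0.01, 100.0]), np.array([3.0, 3.0]))
        levels = c.mean_over(np.geomspace(0.1, 10.0, 6))
        assert np.allclose(levels, 3.0)


class TestRescale:
    def test_coalescent_to_years(self):
        c = sampled_curve()
        out = rescale_curve(c, ScalingConstants(g=2.5), N_ref=5000.0, time_units="years")
        # 1 coalescent unit = 2 * 5000 * 2.5 = 25,000 years
        assert out.times[1] == pytest.approx(25_000.0)
        assert out.time_units == "years"

    def test_effective_size_scaling(self):
        c = sampled_curve()
        out = rescale_curve(
            c, ScalingConstants(), N_ref=1000.0,
            time_units="coalescent", size_units="effective",
        )
        assert np.allclose(out.values, c.values * 1000.0)

    def test_round_trip_exact(self):
        c = step_curve()
        there = rescale_curve(c, ScalingConstants(g=2.5), N_ref=777.0,
                              time_units="years", size_units="effective")
        back = rescale_curve(there, ScalingConstants(g=2.5), N_ref=777.0,
                             time_units="coalescent", size_units="relative")
        assert np.array_equal(back.times, c.times)
        assert np.array_equal(back.values, c.values)

    def test_nref_required(self):
        with pytest.raises(ValueError, match="N_ref"):
            rescale_curve(sampled_curve(), ScalingConstants(), time_units="years")


class TestDistance:
    def test_zero_on_identical(self):
        a = sampled_curve()
        assert curve_distance(a, a) == 0.0

    def test_symmetric(self):
        a, b = sampled_curve(), step_curve()
        assert curve_distance(a, b) == pytest.approx(curve_distance(b, a))

    def test_scale_free_in_value_ratio(self):
        # multiplying both curves by the same factor leaves the distance alone
        a, b = sampled_curve(), step_curve()
        a2 = IICRCurve(a.times, a.values * 7.0)
        b2 = IICRCurve(b.times, b.values * 7.0, kind="step")
        assert curve_distance(a2, b2) == pytest.approx(curve_distance(a, b))

    def test_unit_mismatch_raises(self):
        a = sampled_curve()
        b = sampled_curve(time_units="years")
        with pytest.raises(ValueError, match="units"):
            curve_distance(a, b)

    def test_disjoint_support_raises(self):
        a = IICRCurve(np.array([0.01, 0.1]), np.array([1.0, 1.0]))
        b = IICRCurve(np.array([10.0, 100.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="disjoint"):
            curve_distance(a, b)


class TestDiscretize:
    def test_constant_curve_levels(self):
        c = IICRCurve(np.array([0.01, 100.0]), np.array([2.0, 2.0]))
        step = discretize_like_psmc(c, 16)
        assert step.kind == "step"
        assert len(step.values) == 16
        assert np.allclose(step.values, 2.0)

    def test_needs_two_intervals(self):
        with pytest.raises(ValueError):
            discretize_like_psmc(sampled_curve(), 1)

    def test_provenance_records_intervals(self):
        step = discretize_like_psmc(sampled_curve(), 8)
        assert step.provenance["discretized"]["n_intervals"] == 8


class TestTSVRoundTrip:
    @pytest.mark.parametrize("make", [sampled_curve, step_curve])
    def test_lossless(self, tmp_path, make):
        c = make(time_units="years", size_units="effective")
        # 'effective' values must be positive but can be large
        c = IICRCurve(c.times, c.values * 12345.678, time_units="years",
                      size_units="effective", kind=c.kind,
                      provenance={"note": "round-trip"})
        path = tmp_path / "curve.tsv"
        write_curve_tsv(c, str(path))
        back = read_curve_tsv(str(path))
        assert np.array_equal(back.times, c.times)
        assert np.array_equal(back.values, c.values)
        assert back.kind == c.kind
        assert back.time_units == c.time_units
        assert back.size_units == c.size_units
        assert back.provenance == c.provenance

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("time\tiicr\tunits\n1.0\t2.0\tcoalescent\n")
        with pytest.raises(ValueError, match="header"):
            read_curve_tsv(str(path))
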