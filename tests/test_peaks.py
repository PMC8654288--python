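"""Peak-table I/O, intensity corrections, CSPs and secondary shifts."""

import math

import numpy as np
import pytest

from nmrdyn import peaks
from nmrdyn.errors import FormatError, ValidationError


@pytest.fixture
def ctx():
    return peaks.AcquisitionContext(temperature=298.15, scans=4,
                                    pulse90_length=9.0)


def _rec(res, h, n, atom="HN", intensity=1.0):
    return peaks.PeakRecord(res, "A", atom, {"1H": h, "15N": n}, intensity,
                            0.01)


class TestIO:
    def test_read_well_formed(self, tmp_path, ctx):
        p = tmp_path / "t.tsv"
        p.write_text(
            "residue\tresidue_type\tatom_group\tshift_1H\tshift_15N\t"
            "intensity\tintensity_error\n"
            "1\tM\tHN\t8.1234\t120.5\t1.0\t0.01\n"
            "2\tG\tHN\t7.9\t109.2\t0.8\t0.01\n"
            "3\tL\tHN\t8.6\t122.1\t1.2\t0.01\n")
        table = peaks.read_peak_table(p, condition=ctx)
        assert len(table) == 3
        assert table.get(1, "HN").shifts["1H"] == pytest.approx(8.1234)

    def test_round_trip_lossless(self, tmp_path, ctx):
        table = peaks.PeakTable([_rec(1, 8.1234, 120.5678),
                                 _rec(2, 7.9, 109.2)], ctx)
        path = tmp_path / "rt.tsv"
        peaks.write_peak_table(table, path)
        back = peaks.read_peak_table(path, condition=ctx)
        for a, b in zip(table.records, back.records):
            assert a.residue_number == b.residue_number
            assert a.shifts == pytest.approx(b.shifts)
            assert a.intensity == pytest.approx(b.intensity)
            assert a.intensity_error == pytest.approx(b.intensity_error)

    def test_non_numeric_shift_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("residue\tshift_1H\tshift_15N\n"
                     "1\t8.1\t120.0\n"
                     "2\toops\t121.0\n")
        with pytest.raises(FormatError, match="line 3"):
            peaks.read_peak_table(p)

    def test_missing_mandatory_column(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("shift_1H\tshift_15N\n8.1\t120.0\n")
        with pytest.raises(FormatError, match="residue"):
            peaks.read_peak_table(p)

    def test_duplicate_peak_rejected(self, ctx):
        with pytest.raises(ValidationError, match="duplicate"):
            peaks.PeakTable([_rec(1, 8.0, 120.0), _rec(1, 8.1, 121.0)], ctx)


class TestIntensityCorrection:
    def test_identical_contexts_unchanged(self, ctx):
        out = peaks.correct_intensities([1.0, 2.0], ctx, ctx)
        assert out == pytest.approx([1.0, 2.0])

    def test_double_scans_halves(self, ctx):
        ctx2 = peaks.AcquisitionContext(298.15, 8, 9.0)
        out = peaks.correct_intensities([1.0, 2.0], ctx, ctx2)
        assert out == pytest.approx([0.5, 1.0])

    def test_dilution_and_pulse_factors(self, ctx):
        ctx2 = peaks.AcquisitionContext(298.15, 4, 18.0, dilution_factor=2.0)
        out = peaks.correct_intensities([1.0], ctx, ctx2)
        # dilution halves, pulse ratio doubles -> net unity
        assert out == pytest.approx([1.0])

    def test_cross_temperature_scale(self, ctx):
        # a 25 degC table scaled against a 50 degC reference retains ~70%
        # of the reference signal after transverse-relaxation compensation
        ctx25 = peaks.AcquisitionContext(298.15, 4, 9.0)
        out = peaks.correct_intensities([1.0], ctx, ctx25, extra_scale=0.7)
        assert out == pytest.approx([0.7])


class TestCSP:
    def test_zero_change_zero_csp(self):
        r = _rec(1, 8.0, 120.0)
        c = peaks.amide_csp(r, r)
        assert c.csp == 0.0 and not c.significant

    def test_amide_hand_value(self):
        ref = _rec(5, 8.00, 120.00)
        new = _rec(5, 8.03, 120.20)
        c = peaks.amide_csp(ref, new)
        assert c.csp == pytest.approx(0.05, abs=1e-12)
        assert c.significant  # exactly at the default threshold

    def test_methyl_hand_value_and_symmetry(self):
        ref = peaks.PeakRecord(7, "I", "Ile-d1", {"1H": 0.8, "13C": 13.0})
        new = peaks.PeakRecord(7, "I", "Ile-d1", {"1H": 0.8, "13C": 13.4})
        assert peaks.methyl_csp(ref, new).csp == pytest.approx(0.1)
        assert peaks.methyl_csp(new, ref).csp == pytest.approx(
            peaks.methyl_csp(ref, new).csp)

    def test_missing_nucleus_errors(self):
        ref = peaks.PeakRecord(1, "A", "HN", {"1H": 8.0})
        with pytest.raises(ValidationError, match="15N"):
            peaks.amide_csp(ref, ref)

    @pytest.mark.parametrize("dh,dn", [(0.01, 0.1), (-0.04, 0.3),
                                       (0.0, -0.5), (0.2, 0.0)])
    def test_nonnegative_and_swap_invariant(self, dh, dn):
        ref = _rec(1, 8.0, 120.0)
        new = _rec(1, 8.0 + dh, 120.0 + dn)
        fwd = peaks.amide_csp(ref, new).csp
        assert fwd >= 0
        assert fwd == pytest.approx(peaks.amide_csp(new, ref).csp)
        assert fwd == pytest.approx(math.hypot(dh, dn / 5.0))


class TestSecondaryShifts:
    def test_observed_equals_coil_all_zero(self):
        ca = [56.0, 57.0, 58.0]
        cb = [30.0, 31.0, 32.0]
        out = peaks.secondary_shifts(ca, cb, ca, cb)
        assert out == pytest.approx([0.0, 0.0, 0.0])

    def test_constant_offset_preserved(self):
        coil_ca = np.array([56.0, 57.0, 58.0, 59.0])
        coil_cb = np.array([30.0, 31.0, 32.0, 33.0])
        out = peaks.secondary_shifts(coil_ca + 1.0, coil_cb, coil_ca,
                                     coil_cb)
        assert out == pytest.approx(np.ones(4))

    def test_interior_121_weighting(self):
        out = peaks.smooth_121([0.0, 4.0, 0.0, 0.0, 0.0])
        assert out[1] == pytest.approx(2.0)  # (1*0 + 2*4 + 1*0)/4

    def test_terminus_renormalised(self):
        out = peaks.smooth_121([4.0, 0.0, 0.0])
        assert out[0] == pytest.approx(8.0 / 3.0)  # (2*4 + 1*0)/3

    def test_support_extends_at_most_one_residue(self):
        v = np.zeros(9)
        v[4] = 5.0
        out = peaks.smooth_121(v)
        assert np.all(out[[0, 1, 2, 6, 7, 8]] == 0.0)
        assert np.all(out[3:6] > 0.0)

    def test_missing_residue_skipped_not_interpolated(self):
        v = [1.0, np.nan, 1.0]
        out = peaks.smooth_121(v)
        assert np.isnan(out[1])
        assert out[0] == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            peaks.secondary_shifts([1.0], [1.0, 2.0], [1.0], [1.0])
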