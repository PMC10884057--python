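"""Tube-model transfer functions against the quarter-wave closed form."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hootube.tube_acoustics import (
    AcousticConstants,
    FormantEstimate,
    NumericalDegeneracyError,
    PeakCountError,
    TransferFunction,
    TubeSegment,
    TubeSequence,
    find_formants,
    transfer_function,
    uniform_tube_resonances,
)


class TestUniformTubeResonances:
    @pytest.mark.parametrize(
        "length,c,n,expected",
        [
            (18.0, 35_000.0, 3, [486.11, 1458.33, 2430.56]),
            (22.0, 35_000.0, 2, [397.73, 1193.18]),
            (18.0, 70_000.0, 1, [972.22]),
        ],
    )
    def test_closed_form(self, length, c, n, expected):
        got = uniform_tube_resonances(length, c, n)
        assert np.allclose(got, expected, atol=0.005)

    def test_doubling_speed_doubles_resonances(self):
        assert np.allclose(
            np.array(uniform_tube_resonances(18, 70_000, 3)),
            2 * np.array(uniform_tube_resonances(18, 35_000, 3)),
        )

    @pytest.mark.parametrize("bad", [{"length": -1}, {"speed_of_sound": 0}, {"n": 0}])
    def test_preconditions(self, bad):
        kwargs = {"length": 18.0, "speed_of_sound": 35_000.0, "n": 2, **bad}
        with pytest.raises(ValueError):
            uniform_tube_resonances(**kwargs)


class TestTransferFunctionOracle:
    @pytest.mark.parametrize("length", [5.0, 9.0, 14.0, 18.0, 22.0, 30.0])
    @pytest.mark.parametrize("c", [34_300.0, 35_000.0])
    def test_single_segment_matches_quarter_wave(self, length, c):
        """Peaks of a one-segment tract sit on the closed-open series."""
        constants = AcousticConstants(speed_of_sound=c)
        tf = transfer_function(TubeSequence([TubeSegment(length, 1.0)]), constants)
        expected = [f for f in uniform_tube_resonances(length, c, 6) if 60 < f < 4900]
        est = find_formants(tf, n_formants=len(expected))
        assert np.allclose(est.all_formants, expected, atol=1.0)  # one grid step

    def test_lossless_limit_also_matches(self):
        constants = AcousticConstants(damping_fraction=0.0)
        tf = transfer_function(TubeSequence([TubeSegment(18.0, 1.0)]), constants)
        est = find_formants(tf, n_formants=2)
        assert np.allclose([est.f1, est.f2], [486.11, 1458.33], atol=1.0)

    def test_normalized_to_zero_db_at_f_min(self):
        tf = transfer_function(TubeSequence([TubeSegment(18.0, 1.0)]))
        assert tf.magnitude_db[0] == pytest.approx(0.0)


class TestInvariances:
    def _peaks(self, segments, **kw):
        tf = transfer_function(TubeSequence(segments), **kw)
        est = find_formants(tf, n_formants=2)
        return np.array([est.f1, est.f2])

    @given(k=st.integers(min_value=2, max_value=6))
    @settings(deadline=None, max_examples=5)
    def test_splitting_invariance(self, k):
        """Subdividing a segment into k equal parts changes nothing."""
        whole = [TubeSegment(2.0, 6.0), TubeSegment(18.0, 1.0)]
        split = [TubeSegment(2.0, 6.0)] + [TubeSegment(18.0 / k, 1.0)] * k
        tf_whole = transfer_function(TubeSequence(whole))
        tf_split = transfer_function(TubeSequence(split))
        assert np.allclose(tf_whole.magnitude_db, tf_split.magnitude_db, atol=1e-6)
        assert np.allclose(
            self._peaks(whole), self._peaks(split), atol=0.5
        )

    @given(scale=st.floats(min_value=0.2, max_value=8.0))
    @settings(deadline=None, max_examples=8)
    def test_area_scaling_invariance(self, scale):
        """A common area factor leaves peak frequencies unchanged."""
        base = [TubeSegment(2.0, 4.0), TubeSegment(16.0, 1.0)]
        scaled = [TubeSegment(s.length, s.area * scale) for s in base]
        assert np.allclose(self._peaks(base), self._peaks(scaled), atol=0.5)

    def test_elongation_monotonicity(self):
        """Longer uniform tubes resonate lower, strictly."""
        peaks = [
            self._peaks([TubeSegment(length, 1.0)])
            for length in np.linspace(10, 30, 9)
        ]
        diffs = np.diff(np.stack(peaks), axis=0)
        assert np.all(diffs < 0)

    def test_formants_strictly_increasing(self):
        tf = transfer_function(TubeSequence([TubeSegment(17.0, 1.0)]))
        est = find_formants(tf, n_formants=3)
        assert 0 < est.f1 < est.f2 < est.higher[0]


class TestFindFormants:
    def test_uniform_tube_two_formants(self):
        tf = transfer_function(TubeSequence([TubeSegment(18.0, 1.0)]))
        est = find_formants(tf, n_formants=2)
        assert est.f1 == pytest.approx(486.11, abs=1.0)
        assert est.f2 == pytest.approx(1458.33, abs=1.0)

    def test_monotone_curve_reports_zero_peaks(self):
        freqs = np.arange(50.0, 500.0)
        tf = TransferFunction(freqs, np.linspace(0.0, -30.0, len(freqs)))
        with pytest.raises(PeakCountError, match="0 qualifying"):
            find_formants(tf, n_formants=1)

    def test_single_formant_request_is_flagged_partial_container(self):
        tf = transfer_function(TubeSequence([TubeSegment(18.0, 1.0)]))
        est = find_formants(tf, n_formants=1)
        assert est.f2 is None and est.flags


class TestValidation:
    @pytest.mark.parametrize("length,area", [(0, 1), (-2, 1), (1, 0), (1, -0.5)])
    def test_bad_segment_rejected(self, length, area):
        with pytest.raises(ValueError):
            TubeSegment(length, area)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            TubeSequence([])

    def test_total_length_is_sum(self):
        seq = TubeSequence([TubeSegment(2.0, 1.0), TubeSegment(16.0, 1.5)])
        assert seq.total_length == pytest.approx(18.0)

    @pytest.mark.parametrize(
        "kwargs", [{"speed_of_sound": -1}, {"damping_fraction": 0.5}, {"air_density": 0}]
    )
    def test_bad_constants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AcousticConstants(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [{"f_min": 0.5}, {"f_max": 40.0}, {"f_step": 0.0}],
    )
    def test_bad_grid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            transfer_function(TubeSequence([TubeSegment(18, 1)]), **kwargs)

    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError):
            TransferFunction(np.array([100.0, 90.0]), np.array([0.0, 0.0]))

    def test_non_increasing_formants_rejected(self):
        with pytest.raises(ValueError):
            FormantEstimate(f1=500.0, f2=400.0)

    def test_partial_estimate_requires_flag(self):
        with pytest.raises(ValueError):
            FormantEstimate(f1=500.0, f2=None)


def test_transfer_function_csv_round_trip(tmp_path):
    tf = transfer_function(
        TubeSequence([TubeSegment(18.0, 1.0)]), f_min=50, f_max=200, f_step=10
    )
    path = tmp_path / "tf.csv"
    tf.to_csv(path)
    lines = path.read_text().splitlines()
    assert lines[0] == "frequency_hz,magnitude_db"
    assert len(lines) == len(tf.frequencies) + 1
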