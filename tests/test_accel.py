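"""Accelerometer preprocessing: cleaning, jump sync, annotation/trim,
stop-move filtering, and windowing."""
import numpy as np
import pandas as pd
import pytest

from patype import accel
from patype.core import SensorStream
from patype.synthetic import ProtocolSpec, default_protocols, generate_participant, random_profile

from conftest import make_stream


class TestClean:
    def test_duplicates_and_nan_rows_removed(self):
        s = make_stream(n=100)
        df = s.samples.copy()
        df.loc[10, "t"] = df.loc[9, "t"]  # duplicate timestamp
        df.loc[20, "t"] = df.loc[19, "t"]
        df.loc[30, "ax"] = np.nan
        out = accel.clean_stream(SensorStream("chest", df))
        assert len(out) == 97

    def test_idempotent_on_clean_input(self):
        s = make_stream(n=50)
        out = accel.clean_stream(s)
        pd.testing.assert_frame_equal(out.samples, s.samples)

    def test_unordered_timestamps_sorted(self):
        s = make_stream(n=50)
        shuffled = s.samples.sample(frac=1.0, random_state=0).reset_index(drop=True)
        out = accel.clean_stream(SensorStream("chest", shuffled))
        assert (np.diff(out.samples["t"]) > 0).all()
        np.testing.assert_allclose(out.samples["t"], np.sort(shuffled["t"]))

    def test_empty_result_raises(self):
        s = make_stream(n=5)
        s.samples["ax"] = np.nan
        with pytest.raises(ValueError, match="no usable samples"):
            accel.clean_stream(s)


class TestJumpPeaks:
    def _with_transients(self, times, height=5.0, n=3000):
        s = make_stream(n=n)
        t = s.samples["t"].to_numpy()
        for tj in times:
            s.samples.loc[np.abs(t - tj).argmin(), "ay"] += height
        return s

    def test_injected_transients_recovered_at_injection_times(self):
        times = [5.0, 15.0, 30.0, 50.0]
        s = self._with_transients(times)
        peaks = accel.detect_jump_peaks(s, min_height=2.5)
        assert len(peaks) == 4
        np.testing.assert_allclose(peaks, times, atol=1 / 50.0)

    def test_constant_stream_yields_no_peaks(self):
        assert len(accel.detect_jump_peaks(make_stream(n=500))) == 0

    def test_close_transients_collapse_to_higher_one(self):
        s = make_stream(n=500)
        t = s.samples["t"].to_numpy()
        s.samples.loc[np.abs(t - 5.0).argmin(), "ay"] += 4.0
        s.samples.loc[np.abs(t - 5.1).argmin(), "ay"] += 5.0
        peaks = accel.detect_jump_peaks(s, min_height=2.5, min_separation=1.0)
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(5.1, abs=1 / 50.0)


class TestSynchronize:
    @pytest.mark.parametrize("seed", range(20))
    def test_offset_recovery_within_one_sample(self, terrain, seed):
        """Injected inter-stream clock offsets in +/-2 s are recovered to
        within 20 ms from the jump markers, across random subjects."""
        rng = np.random.default_rng(seed)
        profile = random_profile(f"R{seed}", rng)
        spec = [ProtocolSpec("semi_structured",
                             [("walking_normal", 20.0, "leisure"), ("running", 20.0, "leisure")],
                             gps_gap_rate=0.0)]
        p = generate_participant(profile, spec, terrain, seed=seed)
        cleaned = {k: accel.clean_stream(s) for k, s in p.streams.items()}
        _, shifts = accel.synchronize(cleaned, reference="chest")
        for pos, shift in shifts.items():
            assert abs(shift + p.clock_offsets[pos]) <= 0.020, pos

    def test_zero_offsets_give_identity_shifts(self, small_participant):
        cleaned = {k: accel.clean_stream(s) for k, s in small_participant.streams.items()}
        for s in cleaned.values():
            s.samples["t"] -= small_participant.clock_offsets[s.position]
        _, shifts = accel.synchronize(cleaned, reference="chest")
        assert all(abs(v) <= 0.020 for v in shifts.values())

    def test_missing_jump_raises_naming_stream(self, small_participant):
        cleaned = {k: accel.clean_stream(s) for k, s in small_participant.streams.items()}
        df = cleaned["knee"].samples
        # blank out the final marker's jump on one stream
        t = df["t"] - small_participant.clock_offsets["knee"]
        last = small_participant.jump_times[-1]
        mask = (t >= last - 1.0) & (t <= last + 1.0)
        df.loc[mask, ["ax", "az"]] = 0.0
        df.loc[mask, "ay"] = 1.0
        with pytest.raises(accel.SyncError, match="knee"):
            accel.synchronize(cleaned, reference="chest")


def _annotated(stream, rows, trim=10.0):
    log = pd.DataFrame(rows, columns=["activity", "start", "end", "protocol", "environment"])
    return accel.annotate_and_trim(stream, log, trim=trim)


class TestAnnotateAndTrim:
    def test_trim_removes_ten_seconds_each_side(self):
        s = make_stream(n=60 * 50)
        out = _annotated(s, [("walking_normal", 0.0, 60.0, "semi_structured", "leisure")])
        t = out.samples["t"]
        assert len(out) == 40 * 50
        assert t.min() == pytest.approx(10.0, abs=0.02)
        assert t.max() < 50.0

    def test_short_row_skipped(self, caplog):
        s = make_stream(n=60 * 50)
        out = _annotated(s, [("sitting", 0.0, 15.0, "semi_structured", "leisure")])
        assert len(out) == 0

    def test_raw_labels_grouped(self):
        s = make_stream(n=60 * 50)
        out = _annotated(s, [("walking_upstairs", 0.0, 60.0, "real_life", "urban")])
        assert set(out.samples["label"]) == {"non_level_walking"}


class TestStops:
    def _walking_with_plateau(self, plateau_s, total_s=60.0, seed=0):
        rng = np.random.default_rng(seed)
        n = int(total_s * 50)
        t = np.arange(n) / 50.0
        y = 1.0 + 0.4 * np.sin(2 * np.pi * 1.8 * t) + rng.normal(0, 0.02, n)
        mid = (t >= (total_s - plateau_s) / 2) & (t < (total_s + plateau_s) / 2)
        y[mid] = 1.0 + rng.normal(0, 0.01, mid.sum())
        df = pd.DataFrame({"t": t, "ax": 0.0, "ay": y, "az": 0.0})
        df["label"] = "walking"
        df["task_id"] = 0
        df["protocol"] = "semi_structured"
        df["environment"] = "leisure"
        return SensorStream("chest", df)

    def test_injected_plateau_detected_once(self):
        s = self._walking_with_plateau(5.0)
        stops = accel.detect_stops(s, window=1.0, threshold=0.05, min_stop=1.0)
        assert len(stops) == 1
        t0, t1 = stops[0]
        assert t0 == pytest.approx(27.5, abs=1.0)
        assert t1 == pytest.approx(32.5, abs=1.0)

    def test_continuous_walking_has_no_stops(self):
        s = self._walking_with_plateau(0.0)
        assert accel.detect_stops(s) == []

    def test_sub_second_plateau_ignored(self):
        s = self._walking_with_plateau(0.5)
        assert accel.detect_stops(s, min_stop=1.0) == []

    def test_remove_stops_drops_exactly_stop_samples(self):
        s = self._walking_with_plateau(5.0)
        stops = accel.detect_stops(s)
        out = accel.remove_stops(s, stops)
        t = s.samples["t"].to_numpy()
        expected_removed = sum(((t >= a) & (t <= b)).sum() for a, b in stops)
        assert len(s) - len(out) == expected_removed

    def test_posture_spans_untouched(self):
        s = self._walking_with_plateau(5.0)
        s.samples["label"] = "sitting"  # relabel: stop removal must not apply
        stops = [(25.0, 35.0)]
        out = accel.remove_stops(s, stops)
        assert len(out) == len(s)

    def test_empty_stop_list_is_identity(self):
        s = self._walking_with_plateau(5.0)
        out = accel.remove_stops(s, [])
        assert out.samples is s.samples


class TestSegment:
    def _labeled(self, seconds=40.0):
        s = make_stream(n=int(seconds * 50))
        return _annotated(s, [("walking_normal", -10.0, seconds + 10.0, "semi_structured", "leisure")])

    def test_window_counts_at_half_overlap(self):
        segs = accel.segment(self._labeled(40.0), 10.0, 0.5)
        assert len(segs) == 7  # floor((40-10)/5)+1

    def test_window_counts_no_overlap(self):
        segs = accel.segment(self._labeled(40.0), 10.0, 0.0)
        assert len(segs) == 4

    def test_windows_are_half_open_and_complete(self):
        segs = accel.segment(self._labeled(40.0), 10.0, 0.5)
        for seg in segs:
            assert len(seg.samples) == 500
            assert seg.samples["t"].max() < seg.t_end - 1e-9

    def test_no_mixed_label_segments(self):
        s = make_stream(n=80 * 50)
        out = _annotated(
            s,
            [("walking_normal", -10.0, 30.0, "semi_structured", "leisure"),
             ("sitting", 30.0, 90.0, "semi_structured", "leisure")],
        )
        segs = accel.segment(out, 10.0, 0.5)
        for seg in segs:
            assert seg.samples["label"].nunique() if "label" in seg.samples else 1 == 1
            assert seg.label in ("walking", "sitting")

    def test_overlap_zero_conserves_duration(self):
        segs = accel.segment(self._labeled(40.0), 10.0, 0.0)
        assert sum(s.duration for s in segs) <= 40.0

    def test_window_longer_than_span_yields_nothing(self):
        segs = accel.segment(self._labeled(40.0), 60.0, 0.5)
        assert segs == []
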