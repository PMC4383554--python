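"""Detection filtering, shower/curtain annotation and stream sizing."""

import numpy as np
import pytest

from airemboli.acoustics import AcousticContext, InvalidInputError, forward_mebr
from airemboli.events import (
    PatientRecord,
    SurgicalTimeline,
    detect_showers,
    filter_detections,
    haematocrit_at,
    mark_curtains,
    size_stream,
    summarize_patient,
)


@pytest.fixture()
def patient() -> PatientRecord:
    return PatientRecord(
        id="p1",
        mca_diameter_left=3.0,
        mca_diameter_right=2.8,
        procedure="CABG",
        haematocrit_samples=[(0.0, 0.30), (180.0, 0.28)],
        signal_loss_intervals={"left": [(0.0, 300.0)]},
    )


class TestFilterDetections:
    def test_threshold_is_inclusive_at_7db(self):
        cands = [(0.0, "left", 6.9), (1.0, "left", 7.0), (2.0, "right", 12.0)]
        kept = filter_detections(cands)
        assert [e.mebr for e in kept] == [7.0, 12.0]

    def test_empty_and_all_pass(self):
        assert filter_detections([]) == []
        cands = [(float(t), "left", 20.0) for t in range(100)]
        assert len(filter_detections(cands)) == 100

    def test_idempotent(self):
        cands = [(0.0, "left", 8.0), (1.0, "right", 9.0)]
        once = filter_detections(cands)
        twice = filter_detections([(e.time, e.side, e.mebr) for e in once])
        assert [(e.time, e.mebr) for e in once] == [(e.time, e.mebr) for e in twice]

    def test_rejects_unsorted(self):
        with pytest.raises(InvalidInputError):
            filter_detections([(2.0, "left", 8.0), (1.0, "left", 9.0)])


class TestDetectShowers:
    def test_burst_of_ten_in_one_second(self):
        events = filter_detections([(i * 0.1, "left", 10.0) for i in range(10)])
        showers = detect_showers(events)
        assert len(showers) == 1 and showers[0].n_events == 10
        assert all(e.background_window_start == showers[0].start for e in events)

    def test_slow_stream_is_not_a_shower(self):
        events = filter_detections([(float(i), "left", 10.0) for i in range(20)])
        assert detect_showers(events) == []

    def test_two_bursts_split_by_silence(self):
        times = [i * 0.1 for i in range(8)] + [10.0 + i * 0.1 for i in range(8)]
        events = filter_detections([(t, "left", 10.0) for t in times])
        showers = detect_showers(events)
        assert len(showers) == 2
        assert {s.n_events for s in showers} == {8}


class TestCurtains:
    def test_durations_sum_per_side(self):
        durations = mark_curtains([], {"left": [(0.0, 7.0), (100.0, 107.0)]})
        assert durations["left"] == 14.0 and durations["right"] == 0.0

    def test_overlap_merges(self):
        durations = mark_curtains([], {"right": [(0.0, 10.0), (5.0, 12.0)]})
        assert durations["right"] == 12.0

    def test_members_flagged_and_excluded_from_sizing(self, patient):
        events = filter_detections(
            [(1.0, "left", 20.0), (50.0, "left", 20.0)]
        )
        mark_curtains(events, {"left": [(0.0, 10.0)]})
        assert events[0].curtain_member and not events[1].curtain_member
        sized = size_stream(events, patient, "left")
        assert len(sized) == 1


class TestHaematocritAt:
    @pytest.mark.parametrize("t, expected", [(90.0, 0.30), (-1.0, 0.30), (180.0, 0.28)])
    def test_locf(self, patient, t, expected):
        assert haematocrit_at(patient, t) == expected

    def test_no_samples_is_a_configuration_error(self):
        p = PatientRecord(
            id="x", mca_diameter_left=3.0, mca_diameter_right=3.0,
            procedure="CABG", haematocrit_samples=[],
        )
        with pytest.raises(InvalidInputError):
            haematocrit_at(p, 0.0)


class TestSizeStream:
    def test_noise_free_round_trip(self, patient, rng):
        true_d = np.exp(rng.uniform(np.log(8.0), np.log(1500.0), 200))
        ctx = AcousticContext(vessel_diameter=3.0, haematocrit=0.30)
        cands = [
            (float(t), "left", float(forward_mebr(d, ctx)))
            for t, d in zip(np.linspace(0.0, 100.0, 200), true_d)
        ]
        events = filter_detections(cands)
        sized = size_stream(events, patient, "left")
        rel = [abs(b.diameter - d) / d for b, d in zip(sized, true_d)]
        assert np.median(rel) < 0.01

    def test_haematocrit_misspecification_biases_one_direction(self, rng):
        """Sizing against the wrong haematocrit shifts every diameter the
        same way (the blood term is common to all events)."""
        truth_ctx = AcousticContext(vessel_diameter=3.0, haematocrit=0.30)
        p_wrong = PatientRecord(
            id="w", mca_diameter_left=3.0, mca_diameter_right=3.0,
            procedure="CABG", haematocrit_samples=[(0.0, 0.37)],
        )
        true_d = np.exp(rng.uniform(np.log(15.0), np.log(400.0), 50))
        cands = [
            (float(t), "left", float(forward_mebr(d, truth_ctx)))
            for t, d in zip(np.arange(50.0), np.sort(true_d))
        ]
        sized = size_stream(filter_detections(cands), p_wrong, "left")
        deltas = np.array(
            [b.diameter - d for b, d in zip(sized, np.sort(true_d))]
        )
        assert np.all(deltas > 0) or np.all(deltas < 0)

    def test_empty_stream(self, patient):
        assert size_stream([], patient, "left") == []

    def test_diameters_stay_inside_model_domain(self, patient, rng):
        mebrs = rng.uniform(-5.0, 80.0, 100)
        cands = [(float(t), "left", float(m)) for t, m in zip(np.arange(100.0), mebrs)]
        sized = size_stream(filter_detections(cands), patient, "left")
        for b in sized:
            assert 5.0 <= b.diameter <= patient.mca_diameter_left * 1e3


class TestSummarize:
    def test_counts_and_volume(self, patient):
        ctx = AcousticContext(vessel_diameter=3.0)
        ml = filter_detections(
            [(float(t), "left", float(forward_mebr(1000.0, ctx))) for t in range(1)]
        )
        mr = []
        sized_l = size_stream(ml, patient, "left")
        summary = summarize_patient(patient, sized_l, [])
        assert summary.n_emboli_left == 1 and summary.n_emboli_right == 0
        assert summary.total_volume == pytest.approx(5.236e-4, rel=0.02)
        assert summary.signal_loss_left == pytest.approx(5.0)

    def test_volume_additive_and_permutation_invariant(self, patient, rng):
        ctx = AcousticContext(vessel_diameter=3.0, haematocrit=0.30)
        d = np.exp(rng.uniform(np.log(10.0), np.log(800.0), 40))
        mebrs = forward_mebr(d, ctx)
        cands = [(float(t), "left", float(m)) for t, m in zip(np.arange(40.0), mebrs)]
        sized = size_stream(filter_detections(cands), patient, "left")
        v1 = summarize_patient(patient, sized, []).total_volume
        v2 = summarize_patient(patient, sized[::-1], []).total_volume
        assert v1 == pytest.approx(v2, rel=1e-12)
        half = summarize_patient(patient, sized[:20], []).total_volume
        other = summarize_patient(patient, sized[20:], []).total_volume
        assert half + other == pytest.approx(v1, rel=1e-12)


class TestTimeline:
    def test_stage_lookup_and_validation(self):
        tl = SurgicalTimeline(
            [("pre-CPB", 0.0, 100.0), ("CPB", 100.0, 500.0), ("post-AxC", 500.0, 700.0)]
        )
        assert tl.stage_at(50.0) == "pre-CPB"
        assert tl.stage_at(100.0) == "CPB"
        assert tl.stage_at(800.0) is None
        with pytest.raises(InvalidInputError):
            SurgicalTimeline([("a", 0.0, 10.0), ("b", 5.0, 20.0)])
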