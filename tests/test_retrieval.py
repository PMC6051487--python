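"""Stream annotation, best-frame retrieval, motion-gated background sampling."""

import numpy as np
import pytest

import sononet as sn
from sononet.preprocess import Frame, normalise_frame
from sononet.retrieval import (ConfidenceTrace, annotate_stream,
                               match_freeze_frame, retrieve_best_frames,
                               sample_background_frames)
from tests.conftest import make_tiny_net

rng = np.random.default_rng(0)


def make_trace(conf):
    conf = np.asarray(conf, dtype=float)
    return ConfidenceTrace(conf, np.arange(len(conf)))


class TestAnnotate:
    def test_empty_stream(self):
        net = make_tiny_net(0)
        trace, labels = annotate_stream(net, [])
        assert len(trace) == 0 and labels == []

    def test_single_frame_matches_classify(self):
        net = make_tiny_net(0)
        frame = normalise_frame(Frame(rng.uniform(size=(32, 32))))
        trace, labels = annotate_stream(net, [frame])
        assert len(trace) == 1
        assert labels[0] == sn.classify_frame(net, frame)
        assert trace.confidences[0].sum() == pytest.approx(1.0, abs=1e-6)

    def test_identical_frames_identical_rows(self):
        net = make_tiny_net(1)
        frame = normalise_frame(Frame(rng.uniform(size=(32, 32))))
        trace, _ = annotate_stream(net, [frame] * 4)
        for row in trace.confidences[1:]:
            np.testing.assert_array_equal(row, trace.confidences[0])

    def test_failing_frame_recorded_and_skipped(self):
        net = make_tiny_net(0)
        good = normalise_frame(Frame(rng.uniform(size=(32, 32))))
        bad = Frame(rng.uniform(size=(30, 30)))  # not /16
        with pytest.warns(UserWarning, match="failed"):
            trace, _ = annotate_stream(net, [good, bad, good])
        assert len(trace) == 2
        assert len(trace.errors) == 1 and trace.errors[0][0] == 1

    def test_trace_csv_round_trip(self, tmp_path):
        trace = make_trace([[0.2, 0.8], [0.6, 0.4]])
        trace.class_names = ["a", "b"]
        trace.to_csv(tmp_path / "t.csv")
        back = ConfidenceTrace.from_csv(tmp_path / "t.csv")
        np.testing.assert_allclose(back.confidences, trace.confidences)
        assert back.class_names == ["a", "b"]


class TestRetrieve:
    def test_argmax_per_class(self):
        trace = make_trace([[0.8, 0.1, 0.1],
                            [0.1, 0.2, 0.7],
                            [0.1, 0.8, 0.1]])
        result = retrieve_best_frames(trace)
        assert result.best[1] == (2, 0.8)
        assert result.best[2] == (1, 0.7)

    def test_constant_trace_ties_to_first_frame(self):
        trace = make_trace(np.full((5, 3), 1 / 3))
        result = retrieve_best_frames(trace)
        assert all(v[0] == 0 for v in result.best.values())

    def test_matches_brute_force_scan(self):
        conf = np.random.default_rng(3).dirichlet(np.ones(6), size=100)
        trace = make_trace(conf)
        result = retrieve_best_frames(trace)
        for k in range(6):
            best, best_i = -1.0, None
            for i in range(100):  # linear-scan oracle
                if conf[i, k] > best:
                    best, best_i = conf[i, k], i
            assert result.best[k] == (best_i, pytest.approx(best))

    def test_foreground_restriction(self):
        trace = make_trace(np.random.default_rng(0).dirichlet(
            np.ones(4), size=10))
        result = retrieve_best_frames(trace, foreground=[0, 2])
        assert set(result.best) == {0, 2}

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            retrieve_best_frames(ConfidenceTrace(np.empty((0, 3)),
                                                 np.empty(0, int)))


def moving_video(n=40, move_every=2, amplitude=1.0, seed=0):
    """Alternating still/moving frames; returns (frames, moving indices)."""
    r = np.random.default_rng(seed)
    base = r.uniform(size=(16, 16))
    frames, moving = [], []
    cur = base
    for i in range(n):
        if i > 0 and i % move_every == 0:
            cur = cur + amplitude * r.uniform(size=(16, 16))
            moving.append(i)
        frames.append(Frame(cur.copy(), frame_index=i))
    return frames, moving


class TestBackgroundSampling:
    def test_static_video_yields_nothing(self):
        frame = Frame(rng.uniform(size=(16, 16)))
        with pytest.warns(UserWarning, match="eligible"):
            out = sample_background_frames([frame] * 10, 5,
                                           motion_threshold=0.1,
                                           rng=np.random.default_rng(0))
        assert len(out) == 0

    def test_zero_threshold_makes_all_but_first_eligible(self):
        frames, _ = moving_video(10, move_every=1)
        out = sample_background_frames(frames, 9, motion_threshold=0.0,
                                       rng=np.random.default_rng(0))
        assert sorted(out) == list(range(1, 10))

    def test_only_moving_frames_ever_sampled(self):
        frames, moving = moving_video(40, move_every=2)
        for seed in range(50):
            out = sample_background_frames(frames, 5, motion_threshold=1e-6,
                                           rng=np.random.default_rng(seed))
            assert set(out) <= set(moving)

    def test_exclusion_window_respected(self):
        frames, moving = moving_video(40, move_every=1)
        for seed in range(20):
            out = sample_background_frames(
                frames, 10, motion_threshold=0.0, exclusion_indices=[20],
                exclusion_halfwidth=3, rng=np.random.default_rng(seed))
            assert not set(out) & set(range(17, 24))

    def test_default_threshold_is_self_calibrating(self):
        frames, moving = moving_video(40, move_every=2)
        out = sample_background_frames(frames, 8,
                                       rng=np.random.default_rng(1))
        # still frames have distance 0 = below any positive percentile
        assert set(out) <= set(moving)


class TestFreezeFrameMatching:
    def test_exact_copy_recovered(self):
        frames, _ = moving_video(20, move_every=1, seed=2)
        assert match_freeze_frame(frames, frames[13]) == 13

    def test_all_equidistant_ties_to_first(self):
        frame = Frame(rng.uniform(size=(8, 8)))
        still = Frame(frame.pixels + 1.0)
        assert match_freeze_frame([frame] * 5, still) == 0

    def test_perturbed_copy_recovered(self):
        frames, _ = moving_video(30, move_every=1, seed=3)
        still = Frame(frames[17].pixels +
                      0.001 * rng.normal(size=(16, 16)))
        assert match_freeze_frame(frames, still) == 17

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            match_freeze_frame([], Frame(np.zeros((4, 4))))
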