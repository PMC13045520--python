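"""Velopharyngeal closure detection, event extraction and event matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prored.closure import (ClosureEvent, ClosureSequence, detect_closure_frame,
                            events_to_sequence, extract_events, frame_accuracy,
                            load_closure_csv, match_events, save_closure_csv)
from prored.masks import SPEECH_CLASS_NAMES, LabelMask

HEAD = SPEECH_CLASS_NAMES.index("head")
PALATE = SPEECH_CLASS_NAMES.index("soft_palate")


def _frame(gap: int, h: int = 12, w: int = 16) -> LabelMask:
    """Posterior wall at the right edge, a horizontal palate bar with ``gap``
    empty columns before the wall (gap=0 → contact)."""
    grid = np.zeros((h, w), dtype=int)
    grid[:, w - 2:] = HEAD
    grid[5:7, 2:w - 2 - gap] = PALATE
    return LabelMask(grid)


class TestDetectClosureFrame:
    def test_two_pixel_gap_is_open(self):
        assert detect_closure_frame(_frame(gap=2)) == 0

    def test_contact_is_closed(self):
        assert detect_closure_frame(_frame(gap=0)) == 1

    def test_diagonal_contact_counts(self):
        grid = np.zeros((6, 6), dtype=int)
        grid[2, 2] = PALATE
        grid[3, 3] = HEAD
        assert detect_closure_frame(LabelMask(grid)) == 1

    def test_anterior_attachment_excluded_by_posterior_roi(self):
        # palate touches head only at its anterior attachment (left side);
        # a posterior ROI excludes that permanent contact
        grid = np.zeros((10, 20), dtype=int)
        grid[4:6, 0:2] = HEAD          # anterior hard-palate attachment
        grid[4:6, 2:12] = PALATE       # flap, far from the posterior wall
        grid[:, 18:] = HEAD            # posterior wall
        mask = LabelMask(grid)
        assert detect_closure_frame(mask) == 1                    # full frame sees contact
        assert detect_closure_frame(mask, roi=(0, 10, 6, 20)) == 0

    def test_missing_palate_class_warns_open(self, caplog):
        grid = np.zeros((5, 5), dtype=int)
        grid[:, 3:] = HEAD
        with caplog.at_level("WARNING"):
            assert detect_closure_frame(LabelMask(grid)) == 0
        assert "soft-palate" in caplog.text


class TestExtractEvents:
    @pytest.mark.parametrize("labels,expected", [
        ([0, 0, 1, 1, 0, 1, 0], [(2, 3), (5, 5)]),
        ([0, 0, 0], []),
        ([1, 1, 1], [(0, 2)]),
    ])
    def test_run_extraction(self, labels, expected):
        events = extract_events(ClosureSequence(np.array(labels)))
        assert [(e.start, e.end) for e in events] == expected

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
    @settings(deadline=None, derandomize=True)
    def test_roundtrip_through_sequence(self, labels):
        seq = ClosureSequence(np.array(labels))
        events = extract_events(seq)
        rebuilt = events_to_sequence(events, len(labels))
        assert np.array_equal(rebuilt.labels, seq.labels)
        assert extract_events(rebuilt) == events


class TestMatchEvents:
    def test_one_frame_extension_is_correct(self):
        rep = match_events([ClosureEvent(5, 10)], [ClosureEvent(4, 10)])
        assert (rep.correct, rep.additional, rep.merged, rep.missed) == (1, 0, 0, 0)

    def test_one_frame_shrinkage_also_within_tolerance(self):
        rep = match_events([ClosureEvent(5, 10)], [ClosureEvent(6, 10)])
        assert rep.correct == 1

    def test_two_frame_shift_not_correct(self):
        rep = match_events([ClosureEvent(5, 10)], [ClosureEvent(3, 10)])
        assert rep.correct == 0 and rep.additional == 1

    def test_merged_event(self):
        rep = match_events([ClosureEvent(5, 10), ClosureEvent(15, 20)],
                           [ClosureEvent(5, 20)])
        assert (rep.total_pred, rep.correct, rep.additional, rep.merged,
                rep.missed) == (1, 0, 0, 1, 0)

    def test_empty_sides(self):
        assert match_events([ClosureEvent(5, 10)], []).missed == 1
        rep = match_events([], [ClosureEvent(3, 4)])
        assert rep.additional == 1 and rep.missed == 0

    def test_self_match_is_all_correct(self):
        events = [ClosureEvent(2, 4), ClosureEvent(8, 8), ClosureEvent(12, 20)]
        rep = match_events(events, events)
        assert (rep.correct, rep.additional, rep.merged, rep.missed) == (3, 0, 0, 0)

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            match_events([ClosureEvent(0, 5), ClosureEvent(5, 8)], [])

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=50),
           st.lists(st.integers(0, 1), min_size=1, max_size=50))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_total_pred_decomposition_invariant(self, gt_labels, pred_labels):
        gt = extract_events(ClosureSequence(np.array(gt_labels)))
        pred = extract_events(ClosureSequence(np.array(pred_labels)))
        rep = match_events(gt, pred)
        # every predicted event is exactly one of correct/additional/merged
        assert rep.total_pred == rep.correct + rep.additional + rep.merged
        assert rep.correct <= len(gt)
        assert rep.missed <= len(gt)
        # brute-force overlap matrix: missed = GT rows with no overlap
        overlap = [[p.overlaps(g) for p in pred] for g in gt]
        assert rep.missed == sum(1 for row in overlap if not any(row))


class TestFrameAccuracy:
    def test_identical_sequences(self):
        seq = ClosureSequence(np.array([0, 1, 1, 0]))
        assert frame_accuracy(seq, seq) == (100.0, 0.0, 0.0)

    def test_all_false_positive(self):
        gt = ClosureSequence(np.zeros(10, dtype=int))
        pred = ClosureSequence(np.ones(10, dtype=int))
        assert frame_accuracy(gt, pred) == (0.0, 100.0, 0.0)

    def test_single_error_in_hundred(self):
        gt = ClosureSequence(np.zeros(100, dtype=int))
        pred_labels = np.zeros(100, dtype=int)
        pred_labels[42] = 1
        acc, fp, fn = frame_accuracy(gt, ClosureSequence(pred_labels))
        assert acc == 99.0 and fp == 1.0 and fn == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            frame_accuracy(ClosureSequence(np.array([0])), ClosureSequence(np.array([0, 1])))

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=80),
           st.lists(st.integers(0, 1), min_size=1, max_size=80))
    @settings(deadline=None, derandomize=True)
    def test_partition_sums_to_hundred(self, a, b):
        n = min(len(a), len(b))
        acc, fp, fn = frame_accuracy(ClosureSequence(np.array(a[:n])),
                                     ClosureSequence(np.array(b[:n])))
        assert acc + fp + fn == pytest.approx(100.0)


def test_closure_csv_roundtrip(tmp_path):
    seq = ClosureSequence(np.array([0, 1, 1, 0, 1]), "s1")
    save_closure_csv(seq, tmp_path / "c.csv")
    again = load_closure_csv(tmp_path / "c.csv", "s1")
    assert np.array_equal(seq.labels, again.labels)
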