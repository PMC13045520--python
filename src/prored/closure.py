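"""Velopharyngeal closure analysis.

A frame is *closed* when the soft palate contacts the posterior pharyngeal
wall (part of the "head" label): any soft-palate pixel 8-adjacent to a head
pixel.  Maximal runs of closed frames form closure events, which are matched
against ground truth as correct / additional / merged / missed with a
one-frame tolerance on each endpoint.

An optional rectangular ROI restricts the contact test to the posterior
region; real anatomy attaches the soft palate to the hard palate anteriorly,
and the ROI excludes that permanent contact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .masks import LabelMask

__all__ = ["ClosureSequence", "ClosureEvent", "EventMatchReport",
           "detect_closure_frame", "extract_events", "events_to_sequence",
           "match_events", "frame_accuracy",
           "save_closure_csv", "load_closure_csv"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClosureEvent:
    """Inclusive frame interval of continuous closure."""

    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("event start must not exceed its end")

    def overlaps(self, other: "ClosureEvent") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class ClosureSequence:
    """Per-frame binary labels (1 = velopharyngeal port closed)."""

    labels: np.ndarray
    series_id: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("closure labels must be a 1-D sequence")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("closure labels must be 0 (open) or 1 (closed)")

    def __len__(self):
        return len(self.labels)


@dataclass
class EventMatchReport:
    """Closure-event bookkeeping in the style of an event-analysis table."""

    total_pred: int
    correct: int
    additional: int
    merged: int
    missed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"Total": self.total_pred, "Correct": self.correct,
                              "Additional": self.additional, "Merged": self.merged,
                              "Missed": self.missed}])


def detect_closure_frame(mask: LabelMask,
                         roi: tuple[int, int, int, int] | None = None) -> int:
    """1 iff any soft-palate pixel is 8-adjacent to a head pixel within the ROI.

    ``roi`` is (row_start, row_stop, col_start, col_stop), end-exclusive;
    default is the full frame.  A mask with no soft-palate pixels at all
    yields 0 with a logged warning.
    """
    grid = mask.grid
    head = mask.class_id("head")
    palate = mask.class_id("soft_palate")
    if roi is not None:
        r0, r1, c0, c1 = roi
        grid = grid[r0:r1, c0:c1]
    palate_px = grid == palate
    if not (mask.grid == palate).any():
        logger.warning("mask contains no soft-palate pixels; treating frame as open")
        return 0
    if not palate_px.any():
        return 0
    head_pad = np.pad(grid == head, 1)
    # dilate the head set by one pixel in all 8 directions
    h, w = grid.shape
    dilated = np.zeros((h, w), dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            dilated |= head_pad[1 + dr:1 + dr + h, 1 + dc:1 + dc + w]
    return int((palate_px & dilated).any())


def extract_events(seq: ClosureSequence) -> list[ClosureEvent]:
    """Maximal runs of consecutive closed frames, as inclusive intervals."""
    labels = seq.labels
    events = []
    start = None
    for i, v in enumerate(labels):
        if v and start is None:
            start = i
        elif not v and start is not None:
            events.append(ClosureEvent(start, i - 1))
            start = None
    if start is not None:
        events.append(ClosureEvent(start, len(labels) - 1))
    return events


def events_to_sequence(events: list[ClosureEvent], n_frames: int,
                       series_id: str = "") -> ClosureSequence:
    labels = np.zeros(n_frames, dtype=np.int64)
    for ev in events:
        labels[ev.start:ev.end + 1] = 1
    return ClosureSequence(labels, series_id)


def _check_disjoint_sorted(events: list[ClosureEvent], name: str) -> None:
    for a, b in zip(events, events[1:]):
        if b.start <= a.end:
            raise ValueError(f"{name} events must be sorted and disjoint")


def match_events(gt: list[ClosureEvent], pred: list[ClosureEvent],
                 tolerance: int = 1) -> EventMatchReport:
    """Classify predicted closure events against ground truth.

    A predicted event overlapping no GT event is *additional*; one overlapping
    two or more GT events is *merged*; one overlapping exactly one GT event is
    *correct* when both endpoints are within ``tolerance`` frames (and that GT
    event is not already matched), otherwise additional.  A GT event with no
    overlapping prediction is *missed*; GT events covered only by a merged
    prediction are neither correct nor missed.
    """
    gt = sorted(gt, key=lambda e: e.start)
    pred = sorted(pred, key=lambda e: e.start)
    _check_disjoint_sorted(gt, "gt")
    _check_disjoint_sorted(pred, "pred")
    correct = additional = merged = 0
    matched_gt: set[int] = set()
    overlapped_gt: set[int] = set()
    for p in pred:
        hits = [i for i, g in enumerate(gt) if p.overlaps(g)]
        overlapped_gt.update(hits)
        if not hits:
            additional += 1
        elif len(hits) >= 2:
            merged += 1
        else:
            i = hits[0]
            g = gt[i]
            within = (abs(p.start - g.start) <= tolerance
                      and abs(p.end - g.end) <= tolerance)
            if within and i not in matched_gt:
                matched_gt.add(i)
                correct += 1
            else:
                additional += 1
    missed = sum(1 for i in range(len(gt)) if i not in overlapped_gt)
    return EventMatchReport(len(pred), correct, additional, merged, missed)


def frame_accuracy(gt: ClosureSequence, pred: ClosureSequence
                   ) -> tuple[float, float, float]:
    """(accuracy %, false-positive %, false-negative %) over frames.

    FP: predicted closed, GT open.  FN: predicted open, GT closed.
    The three percentages partition the frames: accuracy + FP + FN = 100.
    """
    if len(gt) != len(pred):
        raise ValueError("sequences must have equal length")
    n = len(gt)
    agree = int((gt.labels == pred.labels).sum())
    fp = int(((pred.labels == 1) & (gt.labels == 0)).sum())
    fn = int(((pred.labels == 0) & (gt.labels == 1)).sum())
    return 100.0 * agree / n, 100.0 * fp / n, 100.0 * fn / n


# ------------------------------------------------------------------------ I/O

def save_closure_csv(seq: ClosureSequence, path: str | Path) -> None:
    pd.DataFrame({"frame_index": np.arange(len(seq)),
                  "closed": seq.labels}).to_csv(path, index=False)


def load_closure_csv(path: str | Path, series_id: str = "") -> ClosureSequence:
    df = pd.read_csv(path)
    order = np.argsort(df["frame_index"].to_numpy())
    return ClosureSequence(df["closed"].to_numpy()[order], series_id)
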