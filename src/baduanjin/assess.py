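"""Formative-assessment engine: grade, recognize, and check sequence integrity.

A lesson session is a list of pre-segmented captures (one file per
motion).  Each capture is recognized (motion class 1-8) and graded
(Fail/Pass/Good), its DTW distance to the matching expert template is
attached, and the recognized class sequence is compared with the
lesson's expected sequence to detect missing motions and ordering
errors.  Across lessons, :func:`track_progress` tabulates the grades and
distances so a teacher can follow each student through the course.

Sequence integrity uses the longest common subsequence (LCS) between the
recognized and expected class lists: classes absent from the recognized
list are missing; classes present but outside the LCS are reported as
adjacent transpositions (paired with the inverted neighbour).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bvh import MotionSequence
from .classify import MotionClassifier
from .dtw import motion_distance

__all__ = ["SessionReport", "detect_sequence_errors", "assess_session", "track_progress"]


@dataclass
class SessionReport:
    """Per-lesson assessment outcome for one student."""

    subject_id: str
    lesson: int | None
    recognized_sequence: list[int]
    expected_sequence: list[int]
    grades: list
    missing: set[int]
    order_errors: list[tuple[int, int]]
    distances: list[float]  # DTW total vs the template of the recognized class

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "lesson": self.lesson,
            "recognized_sequence": [int(c) for c in self.recognized_sequence],
            "expected_sequence": [int(c) for c in self.expected_sequence],
            "grades": [
                g.name if hasattr(g, "name") else (int(g) if isinstance(g, (int, np.integer)) else g)
                for g in self.grades
            ],
            "missing": sorted(int(c) for c in self.missing),
            "order_errors": [[int(a), int(b)] for a, b in self.order_errors],
            "distances": [float(d) for d in self.distances],
        }


def _lcs(a: list[int], b: list[int]) -> list[int]:
    """One longest common subsequence of a and b (standard DP)."""
    n, m = len(a), len(b)
    L = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if a[i] == b[j]:
                L[i, j] = 1 + L[i + 1, j + 1]
            else:
                L[i, j] = max(L[i + 1, j], L[i, j + 1])
    out = []
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j]:
            out.append(a[i])
            i += 1
            j += 1
        elif L[i + 1, j] >= L[i, j + 1]:
            i += 1
        else:
            j += 1
    return out


def detect_sequence_errors(
    recognized: list[int], expected: list[int]
) -> tuple[set[int], list[tuple[int, int]]]:
    """Missing classes and adjacent transpositions in a recognized sequence.

    ``expected`` must not contain duplicate classes.  A class of the
    expected sequence that never appears in the recognized list is
    missing.  A class that appears but falls outside the LCS with the
    expected order was performed out of turn; it is paired with the
    neighbouring recognized class it is inverted against, and the pair is
    reported in expected order.
    """
    recognized = [int(c) for c in recognized]
    expected = [int(c) for c in expected]
    if len(set(expected)) != len(expected):
        raise ValueError("expected sequence must not contain duplicate classes")

    exp_pos = {c: i for i, c in enumerate(expected)}
    present = set(recognized)
    missing = {c for c in expected if c not in present}

    # only recognized classes that belong to the expected set take part
    rec_known = [c for c in recognized if c in exp_pos]
    matched = _lcs(rec_known, expected)

    # classes present but outside the LCS: find the neighbour they are
    # transposed with (adjacent in the recognized order, inverted in the
    # expected order)
    matched_count: dict[int, int] = {}
    for c in matched:
        matched_count[c] = matched_count.get(c, 0) + 1
    order_errors: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    counts: dict[int, int] = {}
    for i, c in enumerate(rec_known):
        counts[c] = counts.get(c, 0) + 1
        if counts[c] <= matched_count.get(c, 0):
            continue  # this occurrence is matched by the LCS
        for k in (i - 1, i + 1):
            if not 0 <= k < len(rec_known):
                continue
            d = rec_known[k]
            if d == c:
                continue
            # inversion: recognized order disagrees with expected order
            rec_before = k < i
            exp_before = exp_pos[d] < exp_pos[c]
            if rec_before != exp_before:
                pair = tuple(sorted((c, d), key=exp_pos.get))
                if pair not in seen:
                    seen.add(pair)
                    order_errors.append(pair)
                break
    order_errors.sort(key=lambda p: exp_pos[p[0]])
    return missing, order_errors


def assess_session(
    captured: list[MotionSequence],
    recognizer: MotionClassifier,
    grader: MotionClassifier,
    expert_templates: dict[int, MotionSequence],
    expected_sequence: list[int],
    band_fraction: float = 0.10,
    subject_id: str = "",
    lesson: int | None = None,
) -> SessionReport:
    """Assess one captured session against the lesson's expected sequence.

    Each capture is recognized, graded, and scored (DTW total distance to
    the expert template of its recognized class, when a template exists).
    """
    for model, what in ((recognizer, "recognizer"), (grader, "grader")):
        if not getattr(model, "_fitted", False):
            raise RuntimeError(f"{what} must be fitted before assessment")

    if captured:
        recognized = [int(c) for c in recognizer.predict(captured)]
        grades = list(grader.predict(captured))
    else:
        recognized, grades = [], []

    distances = []
    for m, cls in zip(captured, recognized):
        tpl = expert_templates.get(cls)
        if tpl is None:
            distances.append(float("nan"))
        else:
            distances.append(
                motion_distance(m, tpl, band_fraction=band_fraction, keep_paths=False).total_distance
            )

    missing, order_errors = detect_sequence_errors(recognized, expected_sequence)
    return SessionReport(
        subject_id=subject_id,
        lesson=lesson,
        recognized_sequence=recognized,
        expected_sequence=[int(c) for c in expected_sequence],
        grades=grades,
        missing=missing,
        order_errors=order_errors,
        distances=distances,
    )


def track_progress(reports: list[SessionReport]) -> pd.DataFrame:
    """Tabulate per-lesson, per-motion outcomes across a course.

    One row per expected motion of each report, with columns ``subject``,
    ``lesson``, ``motion``, ``performed``, ``grade`` and ``distance``;
    motions the student did not perform are flagged and left ungraded.
    """
    rows = []
    for r in reports:
        by_class: dict[int, int] = {}
        for i, c in enumerate(r.recognized_sequence):
            by_class.setdefault(c, i)
        for c in r.expected_sequence:
            i = by_class.get(c)
            rows.append(
                {
                    "subject": r.subject_id,
                    "lesson": r.lesson,
                    "motion": c,
                    "performed": i is not None,
                    "grade": getattr(r.grades[i], "name", r.grades[i]) if i is not None else None,
                    "distance": r.distances[i] if i is not None else np.nan,
                }
            )
    return pd.DataFrame(
        rows, columns=["subject", "lesson", "motion", "performed", "grade", "distance"]
    )
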