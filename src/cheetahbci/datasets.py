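"""Bundled reference score sheets for the worked examples.

These are per-subject classification score sheets from an 18-subject,
four-task motor-imagery BCI session (nine male subjects S01-S09, nine
female subjects S10-S18; 10 trials per task per subject; one offline and
one online run each).  Each sheet records, per subject, the number of
correctly classified trials for each task; they are the canonical inputs
for exercising the session-aggregation operations without refitting
anything.

The female offline sheet is known to be internally inconsistent in its
source: the per-task count grid implies 23 wrongly classified trials while
the per-subject wrong-count column (which matches the per-subject accuracy
column) sums to 22.  Both are bundled; aggregates that concern subject-wise
accuracy should be driven by the wrong-count column, task-wise aggregates
by the count grid.
"""

from __future__ import annotations

import pandas as pd

TASK_COLUMNS = ["right", "forward", "stop", "left"]

_MALE_SUBJECTS = [f"S{i:02d}" for i in range(1, 10)]
_FEMALE_SUBJECTS = [f"S{i:02d}" for i in range(10, 19)]


def _sheet(rows: list[list[int]], subjects: list[str]) -> pd.DataFrame:
    return pd.DataFrame(rows, index=pd.Index(subjects, name="subject_id"), columns=TASK_COLUMNS)


def offline_male_scoresheet() -> pd.DataFrame:
    """Offline single-trial correct counts, male subjects (out of 10 per cell)."""
    return _sheet(
        [
            [10, 10, 9, 9],
            [10, 10, 9, 9],
            [10, 10, 10, 10],
            [9, 10, 10, 9],
            [10, 10, 10, 10],
            [9, 9, 9, 9],
            [10, 10, 9, 10],
            [9, 9, 9, 9],
            [10, 10, 10, 9],
        ],
        _MALE_SUBJECTS,
    )


def offline_female_scoresheet() -> pd.DataFrame:
    """Offline single-trial correct counts, female subjects."""
    return _sheet(
        [
            [10, 9, 9, 9],
            [10, 9, 9, 10],
            [9, 10, 10, 9],
            [10, 9, 9, 9],
            [10, 10, 9, 9],
            [9, 9, 10, 9],
            [9, 9, 10, 9],
            [9, 10, 10, 10],
            [9, 9, 9, 9],
        ],
        _FEMALE_SUBJECTS,
    )


def offline_female_wrong_counts() -> pd.Series:
    """Per-subject wrongly-classified trial counts (out of 40), female offline.

    Consistent with that sheet's per-subject accuracy column; see the module
    docstring for why this differs from the count grid.
    """
    return pd.Series(
        [3, 2, 2, 3, 2, 3, 2, 1, 4], index=pd.Index(_FEMALE_SUBJECTS, name="subject_id")
    )


def online_male_scoresheet() -> pd.DataFrame:
    """Online single-trial correct counts, male subjects."""
    return _sheet(
        [
            [9, 9, 9, 9],
            [10, 10, 9, 9],
            [10, 10, 9, 10],
            [9, 10, 9, 9],
            [9, 9, 9, 9],
            [9, 9, 10, 9],
            [10, 10, 10, 10],
            [10, 10, 9, 9],
            [9, 10, 10, 9],
        ],
        _MALE_SUBJECTS,
    )


def online_female_scoresheet() -> pd.DataFrame:
    """Online single-trial correct counts, female subjects."""
    return _sheet(
        [
            [9, 9, 10, 9],
            [9, 9, 9, 9],
            [9, 10, 9, 9],
            [10, 9, 9, 9],
            [9, 9, 9, 9],
            [10, 10, 9, 9],
            [9, 9, 8, 9],
            [9, 9, 10, 10],
            [9, 10, 10, 9],
        ],
        _FEMALE_SUBJECTS,
    )


def trialwise_mean_accuracies() -> dict[str, pd.Series]:
    """Per-subject mean classification accuracy (%) over repeated trials."""
    male = pd.Series(
        [94.77, 94.28, 94.36, 94.84, 95.90, 94.64, 95.02, 94.78, 95.14],
        index=pd.Index(_MALE_SUBJECTS, name="subject_id"),
    )
    female = pd.Series(
        [93.56, 93.96, 93.82, 93.66, 94.43, 94.39, 93.70, 95.12, 93.78],
        index=pd.Index(_FEMALE_SUBJECTS, name="subject_id"),
    )
    return {"male": male, "female": female}
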