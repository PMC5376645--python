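"""Ordinal grading of laser-induced CNV lesions from masked rater scores.

Four masked observers score the late-phase angiogram of each lesion on a
1–4 severity scale; the per-lesion mean score is binned into Grades I–IV:

* Grade I:   mean in [1, 1.5)
* Grade II:  mean in [1.5, 2.5)
* Grade III: mean in [2.5, 3.5)
* Grade IV:  mean in [3.5, 4]

With four integer raters the mean moves in quarter steps, so the half-open
extension of the published decimal bin edges never reclassifies a real
average; it only makes non-quarter averages (e.g. from a missing rater)
classifiable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["GRADES", "grade_from_average", "grade_lesions", "grade_distribution"]

logger = logging.getLogger(__name__)

GRADES = ("I", "II", "III", "IV")
_BIN_EDGES = (1.5, 2.5, 3.5)  # right-open upper edges of grades I..III


def grade_from_average(average: float) -> str:
    """Map a mean severity score in [1, 4] to its ordinal grade."""
    if not np.isfinite(average) or not (1.0 <= average <= 4.0):
        raise ValueError(f"average score {average!r} outside [1, 4]")
    for grade, edge in zip(GRADES, _BIN_EDGES):
        if average < edge:
            return grade
    return "IV"


def grade_lesions(scores: pd.DataFrame) -> pd.DataFrame:
    """Append per-lesion ``average``, ``grade`` and ``n_scores`` columns.

    Score columns are those named ``score_*``.  Missing scores (NaN) are
    tolerated: the average is taken over available raters and the lesion is
    flagged via ``incomplete=True``.  At least one score per lesion is
    required and every score must lie in [1, 4].
    """
    score_cols = [c for c in scores.columns if c.startswith("score_")]
    if not score_cols:
        raise ValueError("no score_* columns found")
    vals = scores[score_cols].to_numpy(dtype=float)
    present = np.isfinite(vals)
    if not present.any(axis=1).all():
        raise ValueError("every lesion needs at least one score")
    bad = present & ((vals < 1) | (vals > 4))
    if bad.any():
        raise ValueError("scores outside [1, 4] found")
    out = scores.copy()
    with np.errstate(invalid="ignore"):
        out["average"] = np.nanmean(vals, axis=1)
    out["n_scores"] = present.sum(axis=1)
    out["incomplete"] = out["n_scores"] < len(score_cols)
    out["grade"] = [grade_from_average(a) for a in out["average"]]
    return out


def grade_distribution(graded: pd.DataFrame, by: str = "group") -> pd.DataFrame:
    """Per-group grade counts and the Grade-IV fraction.

    Returns one row per non-empty group with columns ``count_I..count_IV``,
    ``total`` and ``grade_IV_fraction``.  Groups with no lesions are omitted
    with a logged warning.
    """
    if "grade" not in graded.columns:
        raise ValueError("input must be graded (run grade_lesions first)")
    if by not in graded.columns:
        raise ValueError(f"grouping column {by!r} not found")
    rows = []
    for group, sub in graded.groupby(by, sort=True, dropna=False):
        if sub.empty:
            logger.warning("group %r has no lesions; omitted", group)
            continue
        counts = {g: int((sub["grade"] == g).sum()) for g in GRADES}
        total = int(len(sub))
        rows.append(
            {
                by: group,
                **{f"count_{g}": counts[g] for g in GRADES},
                "total": total,
                "grade_IV_fraction": counts["IV"] / total,
            }
        )
    return pd.DataFrame(rows)
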