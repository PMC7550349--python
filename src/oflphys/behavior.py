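"""Contingency-awareness classification and Likert-rating summaries.

An observer counts as contingency-aware when their forced-choice answer
names the CS+ *and* is consistent with the earlier questionnaire stages:
they either reported the rule for the correct stimulus or assigned the
(uniquely) highest shock-probability rating to it.  Post-experiment Likert
ratings of the demonstration are summarized as min / max / median / IQR per
question and compared between aware and unaware groups with the
Kruskal-Wallis test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import LIKERT_QUESTIONS, QuestionnaireAnswers

__all__ = ["ContingencyLabel", "classify_contingency", "summarize_likert"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyLabel:
    subject_id: str
    aware: bool
    basis: str  # "rule_reported_correct", "pct_rating_correct" or "none"

    def __post_init__(self) -> None:
        if self.aware and self.basis == "none":
            raise ValueError("aware classification requires a basis")


def _unique_argmax(ratings: dict[str, float]) -> str | None:
    """Stimulus with the strictly highest rating, or None on ties."""
    if not ratings:
        return None
    best = max(ratings.values())
    winners = [k for k, v in ratings.items() if v == best]
    return winners[0] if len(winners) == 1 else None


def classify_contingency(
    answers: QuestionnaireAnswers,
    cs_plus_identity: str = "CS_PLUS",
) -> ContingencyLabel:
    """Label one subject aware or unaware from their questionnaire answers.

    Aware iff the forced choice equals *cs_plus_identity* and either the
    reported rule names it or it uniquely carries the highest percentage
    rating (a tie does not count: "highest" requires a unique maximum).
    Missing percentage ratings with no rule report classify unaware with
    basis ``"none"`` and a logged warning.
    """
    if answers.forced_choice != cs_plus_identity:
        return ContingencyLabel(answers.subject_id, False, "none")
    if answers.rule_reported and answers.rule_stimulus == cs_plus_identity:
        return ContingencyLabel(answers.subject_id, True, "rule_reported_correct")
    if not answers.pct_ratings:
        if not answers.rule_reported:
            logger.warning(
                "subject %s: no percentage ratings and no rule report; "
                "classifying unaware", answers.subject_id,
            )
        return ContingencyLabel(answers.subject_id, False, "none")
    if _unique_argmax(answers.pct_ratings) == cs_plus_identity:
        return ContingencyLabel(answers.subject_id, True, "pct_rating_correct")
    return ContingencyLabel(answers.subject_id, False, "none")


def summarize_likert(
    cohort_answers: list[QuestionnaireAnswers],
    labels: list[ContingencyLabel] | None = None,
) -> pd.DataFrame:
    """Min / max / median / IQR per Likert question, per group and overall.

    Quartiles use linear interpolation.  When *labels* is given, rows are
    emitted for the aware group, the unaware group and the whole cohort;
    group comparison (Kruskal-Wallis) lives in the stats module.
    """
    aware_by_id = {lab.subject_id: lab.aware for lab in labels} if labels else {}
    records = []
    for ans in cohort_answers:
        row = {"subject_id": ans.subject_id, **ans.likert_ratings}
        row["group"] = (
            ("aware" if aware_by_id[ans.subject_id] else "unaware")
            if ans.subject_id in aware_by_id
            else "all"
        )
        records.append(row)
    df = pd.DataFrame(records)
    groups: list[tuple[str, pd.DataFrame]] = [("all", df)]
    if labels:
        groups += [(g, sub) for g, sub in df.groupby("group") if g != "all"]
    rows = []
    for gname, sub in groups:
        for q in LIKERT_QUESTIONS:
            vals = sub[q].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
            rows.append(
                {
                    "group": gname,
                    "question": q,
                    "n": vals.size,
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "median": float(med),
                    "iqr": float(q3 - q1),
                }
            )
    return pd.DataFrame(rows)
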