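"""Survey eligibility screening and branch-aware tabulation.

Eligibility mirrors the Phase-1 screen: the respondent's youngest child
must have been born 2020-2024 and have received breastmilk or a
breastmilk/formula combination in the first six months — or formula
only, provided the respondent attempted to breastfeed and consented to
the inclusion of their experience.

Tabulation is denominator-aware ("of whom" style): freezer-duration and
freeze-reason questions are tabulated over freezer users, discard
reasons over discarders, sensory and rejection questions over storers.
Multi-select questions count each selected option once per respondent,
so their percentages may total more than 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import InvalidArgumentError, ValidationError

ELIGIBLE_BIRTH_YEARS = (2020, 2024)

#: question -> (denominator rule, multi-select flag)
QUESTIONS = {
    "feeding_first6mo": ("all", False),
    "delivery_mode": ("all", False),
    "stored_milk": ("all", False),
    "storage_methods": ("storers", True),
    "freezer_duration": ("freezer_users", False),
    "freeze_reasons": ("freezer_users", True),
    "discarded": ("all", False),
    "discard_reasons": ("discarders", True),
    "sensory_change": ("storers", False),
    "infant_rejection": ("storers", False),
    "race_ethnicity": ("all", True),
    "employment": ("all", False),
    "income_band": ("all", False),
}

DENOMINATOR_RULES = ("all", "storers", "freezer_users", "refrigerator_only_users", "discarders")

_REQUIRED_FIELDS = [
    "respondent_id", "youngest_child_birth_year", "feeding_first6mo",
    "attempted_breastfeeding", "consent_to_include", "stored_milk",
]


def _is_freezer_user(rec) -> bool:
    return bool(rec.stored_milk) and "freezer" in str(rec.storage_methods).split(";")


def _is_refrigerator_only(rec) -> bool:
    methods = str(rec.storage_methods).split(";")
    return bool(rec.stored_milk) and "refrigerator" in methods and "freezer" not in methods


def apply_eligibility(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into eligible respondents and an exclusion log.

    The log gives the first failing rule per excluded record:
    ``birth-year``, then ``feeding-mode`` (formula-only without an
    attempted breastfeeding experience or without consent).
    """
    missing = [f for f in _REQUIRED_FIELDS if f not in records.columns]
    if missing:
        raise ValidationError(f"records missing required fields: {missing}")
    lo, hi = ELIGIBLE_BIRTH_YEARS
    exclusions = []
    keep = []
    for rec in records.itertuples(index=True):
        year = int(rec.youngest_child_birth_year)
        if not lo <= year <= hi:
            exclusions.append((rec.respondent_id, "birth-year"))
            continue
        feeding = rec.feeding_first6mo
        if feeding in ("breastmilk_only", "combination"):
            keep.append(rec.Index)
        elif feeding == "formula_only":
            if bool(rec.attempted_breastfeeding) and bool(rec.consent_to_include):
                keep.append(rec.Index)
            else:
                exclusions.append((rec.respondent_id, "feeding-mode"))
        else:
            raise ValidationError(f"unknown feeding mode {feeding!r}")
    log = pd.DataFrame(exclusions, columns=["respondent_id", "rule"])
    return records.loc[keep].reset_index(drop=True), log


def _denominator_mask(records: pd.DataFrame, rule: str) -> pd.Series:
    if rule == "all":
        return pd.Series(True, index=records.index)
    stored = records["stored_milk"].astype(bool)
    if rule == "storers":
        return stored
    if rule == "freezer_users":
        return pd.Series(
            [_is_freezer_user(r) for r in records.itertuples()], index=records.index
        )
    if rule == "refrigerator_only_users":
        return pd.Series(
            [_is_refrigerator_only(r) for r in records.itertuples()], index=records.index
        )
    if rule == "discarders":
        return records["discarded"].astype(bool)
    raise InvalidArgumentError(f"unknown denominator rule {rule!r}")


@dataclass
class Tabulation:
    """Counts and one-decimal percentages over an explicit denominator."""

    question: str
    denominator_rule: str
    denominator: int
    counts: dict
    percentages: dict
    multi_select: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "question": self.question,
                "category": list(self.counts),
                "count": list(self.counts.values()),
                "percent": [self.percentages[c] for c in self.counts],
                "denominator": self.denominator,
                "denominator_rule": self.denominator_rule,
            }
        )


def check_branch_consistency(records: pd.DataFrame) -> None:
    """Reject tables with answers that violate the branching rules."""
    for rec in records.itertuples():
        freezer = _is_freezer_user(rec)
        if str(rec.freezer_duration) not in ("", "nan") and not freezer:
            raise ValidationError(
                f"{rec.respondent_id}: freezer_duration answered by non-freezer user"
            )
        if freezer and str(rec.freezer_duration) in ("", "nan"):
            raise ValidationError(
                f"{rec.respondent_id}: freezer user lacks freezer_duration"
            )
        if str(rec.discard_reasons) not in ("", "nan") and not bool(rec.discarded):
            raise ValidationError(
                f"{rec.respondent_id}: discard reasons without discarding"
            )


def tabulate(
    records: pd.DataFrame,
    question: str,
    denominator_rule: str | None = None,
) -> Tabulation:
    """Tabulate one question over its rule-defined denominator.

    Single-select percentages (one decimal) sum to 100 up to rounding;
    multi-select options are each counted once per respondent.
    """
    if question not in QUESTIONS:
        raise InvalidArgumentError(f"unknown question {question!r}")
    default_rule, multi = QUESTIONS[question]
    rule = denominator_rule or default_rule
    if rule not in DENOMINATOR_RULES:
        raise InvalidArgumentError(f"unknown denominator rule {rule!r}")
    mask = _denominator_mask(records, rule)
    denom_records = records.loc[mask]
    denom = int(len(denom_records))
    if denom == 0:
        raise InvalidArgumentError(f"empty denominator for rule {rule!r}")
    counts: dict = {}
    if multi:
        for cell in denom_records[question]:
            for token in str(cell).split(";"):
                token = token.strip()
                if token and token != "nan":
                    counts[token] = counts.get(token, 0) + 1
    else:
        vc = denom_records[question].astype(str).value_counts()
        counts = {k: int(v) for k, v in vc.items() if k not in ("", "nan")}
    if any(c > denom for c in counts.values()):
        raise ValidationError("category count exceeds denominator")
    percentages = {k: round(100.0 * v / denom, 1) for k, v in counts.items()}
    return Tabulation(question, rule, denom, counts, percentages, multi)


def crosstab(
    records: pd.DataFrame,
    q_row: str,
    q_col: str,
    denominator_rule: str = "all",
) -> pd.DataFrame:
    """Contingency table of two single-select questions.

    Rows/columns are the observed categories over the rule-defined
    denominator; every respondent in the denominator must have answered
    both questions (branching violations are reported with offending ids).
    """
    for q in (q_row, q_col):
        if q in QUESTIONS and QUESTIONS[q][1]:
            raise InvalidArgumentError(f"{q} is multi-select; crosstab needs single-select")
    mask = _denominator_mask(records, denominator_rule)
    sub = records.loc[mask, [q_row, q_col, "respondent_id"]].copy()
    for q in (q_row, q_col):
        blank = sub[q].astype(str).isin(("", "nan"))
        if blank.any():
            ids = sub.loc[blank, "respondent_id"].tolist()[:5]
            raise ValidationError(
                f"{q} unanswered within denominator {denominator_rule!r}: e.g. {ids}"
            )
    table = pd.crosstab(sub[q_row].astype(str), sub[q_col].astype(str))
    return table
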