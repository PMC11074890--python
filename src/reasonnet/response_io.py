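"""Read, validate and summarize long-format coded survey responses.

The on-disk format is a UTF-8 CSV with one row per (respondent, reason)
mention: required columns ``respondent_id``, ``group``, ``reason_code``;
optional demographic columns ``age_group``, ``sex``, ``education``,
``employment``, ``chronic_condition``.  Rows are grouped by respondent into
deduplicated reason sets — the weighting scheme downstream treats a
respondent's mentions as a set of distinct reasons, so repeated mentions
collapse with a warning rather than an error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .codebook import Codebook, GROUPS

__all__ = [
    "AGE_GROUPS",
    "SEXES",
    "EDUCATION_LEVELS",
    "EMPLOYMENT_LEVELS",
    "YES_NO",
    "OTHER_CODE",
    "Respondent",
    "ResponseSet",
    "ResponseError",
    "read_responses",
    "write_responses",
    "reason_frequencies",
    "demographic_table",
]

logger = logging.getLogger(__name__)

#: Age bins used throughout (survey strata); "unknown" is allowed per respondent.
AGE_GROUPS = ("18-24", "25-34", "35-44", "45-54", "55-64", "65plus")
SEXES = ("female", "male")
EDUCATION_LEVELS = ("primary_or_less", "secondary", "tertiary_or_more")
EMPLOYMENT_LEVELS = ("employed", "student_homemaker_retiree", "unemployed")
YES_NO = ("yes", "no")

#: Synthetic bucket for out-of-codebook codes when reading permissively.
OTHER_CODE = "other"

_DEMO_FIELDS = {
    "age_group": AGE_GROUPS,
    "sex": SEXES,
    "education": EDUCATION_LEVELS,
    "employment": EMPLOYMENT_LEVELS,
    "chronic_condition": YES_NO,
}


class ResponseError(ValueError):
    """Raised for invalid response data."""


@dataclass(frozen=True)
class Respondent:
    """One survey respondent with demographics and a deduplicated reason set."""

    id: str
    group: str
    reasons: frozenset
    age_group: str = "unknown"
    sex: str = "unknown"
    education: str = "unknown"
    employment: str = "unknown"
    chronic_condition: str = "unknown"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ResponseError(f"respondent {self.id!r}: unknown group {self.group!r}")
        reasons = frozenset(self.reasons)
        object.__setattr__(self, "reasons", reasons)
        if not reasons:
            raise ResponseError(f"respondent {self.id!r} has no reasons")
        for name, allowed in _DEMO_FIELDS.items():
            value = getattr(self, name)
            if value != "unknown" and value not in allowed:
                raise ResponseError(
                    f"respondent {self.id!r}: invalid {name} {value!r}; "
                    f"expected one of {allowed} or 'unknown'"
                )


@dataclass(frozen=True)
class ResponseSet:
    """A validated collection of respondents sharing one outcome group."""

    group: str
    codebook: Codebook
    respondents: tuple = ()

    def __post_init__(self) -> None:
        respondents = tuple(self.respondents)
        object.__setattr__(self, "respondents", respondents)
        if self.group != self.codebook.group:
            raise ResponseError(
                f"response-set group {self.group!r} does not match codebook "
                f"group {self.codebook.group!r}"
            )
        valid = set(self.codebook.codes) | {OTHER_CODE}
        seen_ids: set = set()
        for r in respondents:
            if r.group != self.group:
                raise ResponseError(
                    f"respondent {r.id!r} has group {r.group!r}, set is {self.group!r}"
                )
            if r.id in seen_ids:
                raise ResponseError(f"duplicate respondent id {r.id!r}")
            seen_ids.add(r.id)
            bad = r.reasons - valid
            if bad:
                raise ResponseError(
                    f"respondent {r.id!r} mentions codes not in the "
                    f"{self.group} codebook: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.respondents)

    def subset(self, predicate) -> "ResponseSet":
        """New ResponseSet keeping respondents for which ``predicate`` is true."""
        return ResponseSet(
            group=self.group,
            codebook=self.codebook,
            respondents=tuple(r for r in self.respondents if predicate(r)),
        )


_COLUMNS = ["respondent_id", "group", "reason_code"] + list(_DEMO_FIELDS)


def read_responses(path, codebook: Codebook, allow_other: bool = False) -> ResponseSet:
    """Read a long-format mention CSV into a validated :class:`ResponseSet`.

    Parameters
    ----------
    path
        CSV with one row per mention; header required.
    codebook
        Codebook defining the valid reason codes for the set's group.
    allow_other
        If true, out-of-codebook reason codes are bucketed under the
        synthetic ``"other"`` code instead of raising.

    Raises
    ------
    ResponseError
        Unknown reason code (unless ``allow_other``), respondent with zero
        valid reasons, or one respondent appearing under both groups.
    """
    df = pd.read_csv(path, dtype=str).fillna("unknown")
    missing = {"respondent_id", "group", "reason_code"} - set(df.columns)
    if missing:
        raise ResponseError(f"input file lacks required columns: {sorted(missing)}")

    valid = set(codebook.codes)
    respondents = []
    for rid, rows in df.groupby("respondent_id", sort=False):
        groups = set(rows["group"])
        if len(groups) > 1:
            raise ResponseError(f"respondent {rid!r} appears under mixed groups {sorted(groups)}")
        codes = list(rows["reason_code"])
        if len(codes) != len(set(codes)):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            logger.warning("respondent %r: duplicate mentions of %s collapsed", rid, dupes)
        reasons = set()
        for code in codes:
            if code in valid:
                reasons.add(code)
            elif allow_other:
                reasons.add(OTHER_CODE)
            else:
                raise ResponseError(
                    f"respondent {rid!r} mentions unknown reason code {code!r}"
                )
        demo = {}
        for name in _DEMO_FIELDS:
            if name in rows.columns:
                values = set(rows[name]) - {"unknown"}
                demo[name] = values.pop() if len(values) == 1 else "unknown"
        respondents.append(
            Respondent(id=str(rid), group=groups.pop(), reasons=frozenset(reasons), **demo)
        )
    return ResponseSet(group=codebook.group, codebook=codebook, respondents=tuple(respondents))


def write_responses(rs: ResponseSet, path) -> None:
    """Write a ResponseSet back to the long-format CSV (stable row order)."""
    rows = []
    order = {c: i for i, c in enumerate(rs.codebook.codes)}
    order[OTHER_CODE] = len(order)
    for r in rs.respondents:
        for code in sorted(r.reasons, key=lambda c: order[c]):
            rows.append(
                {
                    "respondent_id": r.id,
                    "group": r.group,
                    "reason_code": code,
                    "age_group": r.age_group,
                    "sex": r.sex,
                    "education": r.education,
                    "employment": r.employment,
                    "chronic_condition": r.chronic_condition,
                }
            )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def reason_frequencies(rs: ResponseSet) -> pd.DataFrame:
    """Per-reason mention counts.

    Returns a DataFrame with one row per codebook reason (canonical order):
    ``n_mentioned`` counts respondents whose reason set contains the reason;
    ``n_sole_mention`` counts respondents whose set is exactly that reason.
    """
    codes = list(rs.codebook.codes)
    n_mentioned = dict.fromkeys(codes, 0)
    n_sole = dict.fromkeys(codes, 0)
    for r in rs.respondents:
        for code in r.reasons:
            if code in n_mentioned:
                n_mentioned[code] += 1
        if len(r.reasons) == 1:
            (only,) = r.reasons
            if only in n_sole:
                n_sole[only] += 1
    return pd.DataFrame(
        {
            "reason": codes,
            "n_mentioned": [n_mentioned[c] for c in codes],
            "n_sole_mention": [n_sole[c] for c in codes],
        }
    )


def _demographic_counts(rs: ResponseSet, variable: str, levels) -> dict:
    counts = dict.fromkeys(levels, 0)
    counts["unknown"] = 0
    for r in rs.respondents:
        counts[getattr(r, variable)] += 1
    return counts


def demographic_table(rs_accept: ResponseSet, rs_resist: ResponseSet) -> pd.DataFrame:
    """Demographic comparison table between accepting and resistant samples.

    One row per (variable, category).  Column percentages use the group
    totals (all respondents in the group) as denominators; ``unknown``
    categories are reported as counts with no percentage.
    """
    if rs_accept.group != "acceptance" or rs_resist.group != "resistance":
        raise ResponseError("expected an acceptance set and a resistance set, in that order")
    n_a, n_r = len(rs_accept), len(rs_resist)
    rows = []
    for variable, levels in _DEMO_FIELDS.items():
        counts_a = _demographic_counts(rs_accept, variable, levels)
        counts_r = _demographic_counts(rs_resist, variable, levels)
        for level in list(levels) + ["unknown"]:
            ca, cr = counts_a[level], counts_r[level]
            if level == "unknown" and ca == 0 and cr == 0:
                continue
            rows.append(
                {
                    "variable": variable,
                    "category": level,
                    "n_accepting": ca,
                    "pct_accepting": round(100.0 * ca / n_a, 1) if level != "unknown" and n_a else float("nan"),
                    "n_resistant": cr,
                    "pct_resistant": round(100.0 * cr / n_r, 1) if level != "unknown" and n_r else float("nan"),
                }
            )
    return pd.DataFrame(rows)
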