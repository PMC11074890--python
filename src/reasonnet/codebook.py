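"""Closed vocabularies of coded vaccination reasons and their 5C(+context) mapping.

Survey respondents give free-text reasons for accepting or resisting COVID-19
vaccination; qualitative coding collapses them into a closed set of reason
codes per outcome group.  Each code maps onto one or more categories of the
extended 5C model of vaccine hesitancy: complacency, confidence, convenience,
(risk) calculation, collective responsibility, plus a sixth "context" category
covering mandate-, incentive- and preference-driven reasons.

The two default codebooks shipped with the package (10 acceptance reasons,
10 resistance reasons) are ordered by descending mention frequency in the
source survey; this order is the canonical row/column order of every
downstream matrix and the deterministic tie-break for rankings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "CATEGORIES",
    "GROUPS",
    "Reason",
    "Codebook",
    "CodebookError",
    "load_codebook",
    "default_codebook",
    "categories_of",
    "dump_codebook",
]

#: The six admissible reason categories (5C model plus "context").
CATEGORIES = frozenset(
    {
        "complacency",
        "confidence",
        "convenience",
        "calculation",
        "collective_responsibility",
        "context",
    }
)

#: The two vaccination outcome groups.
GROUPS = ("acceptance", "resistance")


class CodebookError(ValueError):
    """Raised for malformed, inconsistent or unknown codebook content."""


@dataclass(frozen=True)
class Reason:
    """A single coded reason.

    Parameters
    ----------
    code
        Short machine-safe snake_case identifier, unique within its group.
    label
        Human-readable wording of the reason.
    group
        Outcome group this reason belongs to: ``"acceptance"`` or
        ``"resistance"``.
    categories
        Non-empty set of 5C(+context) categories the reason maps onto.
    """

    code: str
    label: str
    group: str
    categories: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.code or not self.code.isidentifier():
            raise CodebookError(f"reason code {self.code!r} is not a valid identifier")
        if self.group not in GROUPS:
            raise CodebookError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        cats = frozenset(self.categories)
        object.__setattr__(self, "categories", cats)
        if not cats:
            raise CodebookError(f"reason {self.code!r} has an empty category set")
        unknown = cats - CATEGORIES
        if unknown:
            raise CodebookError(f"reason {self.code!r} has unknown categories {sorted(unknown)}")


@dataclass(frozen=True)
class Codebook:
    """An ordered, validated collection of :class:`Reason` for one group.

    The order of ``reasons`` is fixed: it defines matrix row/column order
    and ranking tie-breaks downstream.
    """

    group: str
    reasons: tuple = ()

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CodebookError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        reasons = tuple(self.reasons)
        object.__setattr__(self, "reasons", reasons)
        seen: set = set()
        for r in reasons:
            if not isinstance(r, Reason):
                raise CodebookError("codebook entries must be Reason instances")
            if r.group != self.group:
                raise CodebookError(
                    f"reason {r.code!r} has group {r.group!r}, codebook is {self.group!r}"
                )
            if r.code in seen:
                raise CodebookError(f"duplicate reason code {r.code!r}")
            seen.add(r.code)
        if not reasons:
            raise CodebookError("codebook has no reasons")

    @property
    def codes(self) -> tuple:
        """Reason codes in canonical order."""
        return tuple(r.code for r in self.reasons)

    @property
    def labels(self) -> Mapping[str, str]:
        return {r.code: r.label for r in self.reasons}

    def __len__(self) -> int:
        return len(self.reasons)

    def __contains__(self, code: object) -> bool:
        return code in set(self.codes)

    def index(self, code: str) -> int:
        """Position of ``code`` in the canonical order."""
        try:
            return self.codes.index(code)
        except ValueError:
            raise CodebookError(f"unknown reason code {code!r} in {self.group} codebook") from None

    def __getitem__(self, code: str) -> Reason:
        return self.reasons[self.index(code)]

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "reasons": [
                {
                    "code": r.code,
                    "label": r.label,
                    "categories": sorted(r.categories),
                }
                for r in self.reasons
            ],
        }


def _from_dict(doc: Mapping, group: str | None = None) -> Codebook:
    try:
        doc_group = doc["group"]
        raw_reasons = doc["reasons"]
    except (KeyError, TypeError) as exc:
        raise CodebookError(f"malformed codebook document: missing {exc}") from exc
    if group is not None and doc_group != group:
        raise CodebookError(f"codebook group {doc_group!r} does not match requested {group!r}")
    reasons = []
    for entry in raw_reasons:
        try:
            reasons.append(
                Reason(
                    code=entry["code"],
                    label=entry.get("label", entry["code"]),
                    group=doc_group,
                    categories=frozenset(entry["categories"]),
                )
            )
        except (KeyError, TypeError) as exc:
            raise CodebookError(f"malformed reason entry {entry!r}") from exc
    return Codebook(group=doc_group, reasons=tuple(reasons))


def load_codebook(source, group: str | None = None) -> Codebook:
    """Load and validate a codebook from a JSON document.

    Parameters
    ----------
    source
        Path to a JSON file, a JSON string, or an already-parsed mapping
        with keys ``group`` and ``reasons``.
    group
        If given, the document's group must match; a mismatch is an error.

    Raises
    ------
    CodebookError
        On malformed documents, unknown categories or duplicate codes.
    """
    if isinstance(source, Mapping):
        return _from_dict(source, group)
    if isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("{")):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CodebookError(f"codebook document is not valid JSON: {exc}") from exc
    return _from_dict(doc, group)


def default_codebook(group: str) -> Codebook:
    """The shipped default codebook for ``group`` (10 reasons each)."""
    if group not in GROUPS:
        raise CodebookError(f"unknown group {group!r}; expected one of {GROUPS}")
    ref = resources.files("reasonnet.data").joinpath(f"{group}_codebook.json")
    return load_codebook(json.loads(ref.read_text(encoding="utf-8")), group)


def categories_of(codebook: Codebook, code: str) -> frozenset:
    """Category set a reason code maps onto (may have more than one member)."""
    return codebook[code].categories


def dump_codebook(codebook: Codebook, path) -> None:
    """Serialize a codebook to JSON; round-trips through :func:`load_codebook`."""
    Path(path).write_text(json.dumps(codebook.to_dict(), indent=2) + "\n", encoding="utf-8")
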