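"""Age-stratified networks/centralities and demographic group comparison.

Stratification rebuilds the co-mention matrix and recomputes normalized
eigenvector centrality within each of the six survey age bins.  Because the
centrality vectors are renormalized to a common norm, values are directly
comparable across strata — the basis for asking whether a reason matters
more to younger or older respondents.  Respondents with unknown age are
kept in the pooled analysis but excluded from every stratum, so the strata
matrices sum (entrywise, plus the unknown-age matrix) to the pooled matrix.

Demographic composition of two samples is compared with the Pearson
chi-square test of homogeneity, without continuity correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import CentralityResult, normalized_eigencentrality
from .network import CoMentionMatrix, build_matrix
from .response_io import AGE_GROUPS, ResponseSet

__all__ = [
    "StratumResult",
    "StratifiedResult",
    "stratified_centrality",
    "stratified_table",
    "pearson_chi_square",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StratumResult:
    matrix: CoMentionMatrix
    centrality: CentralityResult
    n_respondents: int


@dataclass(frozen=True)
class StratifiedResult:
    """Per-age-bin co-mention matrices and centralities plus the pooled result."""

    strata: dict
    pooled: StratumResult
    n_unknown_age: int

    @property
    def n_stratified(self) -> int:
        return sum(s.n_respondents for s in self.strata.values())


def stratified_centrality(
    rs: ResponseSet,
    diagonal_mode: str = "self_weight",
    norm: str = "l2",
) -> StratifiedResult:
    """Build matrices and normalized eigencentralities per age bin and pooled.

    Age bins with zero respondents are skipped with a warning.  Unknown-age
    respondents enter the pooled network only.
    """
    if len(rs) == 0:
        raise ValueError("cannot stratify an empty ResponseSet")
    pooled_matrix = build_matrix(rs, diagonal_mode=diagonal_mode)
    pooled = StratumResult(
        matrix=pooled_matrix,
        centrality=normalized_eigencentrality(pooled_matrix, norm=norm),
        n_respondents=len(rs),
    )
    strata = {}
    n_unknown = 0
    for age in AGE_GROUPS:
        sub = rs.subset(lambda r, age=age: r.age_group == age)
        if len(sub) == 0:
            logger.warning("age stratum %s has no respondents; skipped", age)
            continue
        m = build_matrix(sub, diagonal_mode=diagonal_mode)
        strata[age] = StratumResult(
            matrix=m,
            centrality=normalized_eigencentrality(m, norm=norm),
            n_respondents=len(sub),
        )
    n_unknown = len(rs) - sum(s.n_respondents for s in strata.values())
    if not strata:
        raise ValueError("no age stratum has any respondents")
    return StratifiedResult(strata=strata, pooled=pooled, n_unknown_age=n_unknown)


def stratified_table(sr: StratifiedResult) -> pd.DataFrame:
    """Long table (reason x age_group) of centralities, shaped for grouped bars."""
    rows = []
    for age, stratum in sr.strata.items():
        for reason, value in zip(stratum.centrality.reasons, stratum.centrality.X):
            rows.append(
                {
                    "reason": reason,
                    "age_group": age,
                    "centrality": float(value),
                    "n_respondents": stratum.n_respondents,
                }
            )
    return pd.DataFrame(rows, columns=["reason", "age_group", "centrality", "n_respondents"])


def pearson_chi_square(counts) -> tuple:
    """Pearson chi-square test of homogeneity on a 2-way contingency table.

    No continuity correction is applied.  Returns ``(statistic, dof,
    p_value)`` with ``dof = (r - 1)(c - 1)``.  Tables with a zero marginal
    row or column are rejected; expected counts below 5 trigger a warning
    (the usual small-cell caveat).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (table < 0).any():
        raise ValueError("contingency table entries must be nonnegative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("contingency table has a zero marginal row or column")
    res = stats.chi2_contingency(table, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn("expected count below 5 in at least one cell", stacklevel=2)
    return float(res.statistic), int(res.dof), float(res.pvalue)
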