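"""Synthetic survey-response generator with plantable network structure.

The raw respondent-level data behind the source survey are not public, so
every downstream stage is exercised on generated ResponseSets that mimic
their statistical structure: each respondent mentions 1..m reasons, with a
configurable distribution over the number of reasons, marginal salience per
reason, pairwise co-mention affinity, and optional age-group-specific
profiles (so that, e.g., a reason can be made to dominate only among the
youngest respondents).

Sampling is sequential and conditional: the first reason is drawn with
probability proportional to salience; each subsequent reason j (without
replacement) with probability proportional to salience[j] x
affinity[last drawn, j].  This keeps generation simple and seedable while
inducing controllable pairwise co-occurrence.  All randomness flows through
one ``numpy`` generator seeded from a single integer, so identical configs
and seeds reproduce byte-identical output.

Default marginal salience is proportional to the per-reason mention counts
reported for the source survey, and default sample sizes are its group
totals (5559 accepting, 982 resistant), so an unmodified config generates
data at the scale and skew of the study the package models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codebook import Codebook, default_codebook
from .response_io import AGE_GROUPS, EDUCATION_LEVELS, EMPLOYMENT_LEVELS, SEXES, YES_NO, Respondent, ResponseSet

__all__ = [
    "SyntheticConfig",
    "AgeProfile",
    "PlantedTruth",
    "generate",
    "planted_truth",
    "default_config",
    "DEFAULT_M_DIST",
    "REPORTED_MENTION_COUNTS",
    "REPORTED_N",
]

#: Published per-reason mention counts; the default salience is proportional
#: to these, so generated marginals track the real survey's skew.
REPORTED_MENTION_COUNTS = {
    "acceptance": {
        "disease_risk": 3689,
        "protecting_others": 2354,
        "back_to_normal_life": 877,
        "confidence_in_vaccines": 703,
        "vaccine_mandates": 548,
        "progovernment": 140,
        "social_norms": 100,
        "convenience": 83,
        "incentives": 40,
        "trust_in_experts": 15,
    },
    "resistance": {
        "lack_of_vaccine_confidence": 501,
        "complacency": 376,
        "poor_health_status": 116,
        "vaccine_mandates": 52,
        "distrust_in_government": 27,
        "lack_of_social_support": 18,
        "no_incentives": 12,
        "inconvenience": 11,
        "social_norms": 7,
        "medical_preference": 6,
    },
}

#: Published group totals (respondents providing reasons).
REPORTED_N = {"acceptance": 5559, "resistance": 982}

#: Default distribution over the number of reasons a respondent mentions.
#: Sole mentions dominate, matching the survey's reported prevalence of
#: single-reason answers; the exact distribution is a documented choice.
DEFAULT_M_DIST = {1: 0.55, 2: 0.30, 3: 0.15}

# Demographic marginals for generated respondents, matching the published
# per-group distributions (age is drawn separately via age profiles).
_DEFAULT_DEMOGRAPHICS = {
    "acceptance": {
        "sex": {"female": 3103, "male": 2456},
        "education": {"primary_or_less": 711, "secondary": 2555, "tertiary_or_more": 2207},
        "employment": {"employed": 2773, "student_homemaker_retiree": 2524, "unemployed": 175},
        "chronic_condition": {"yes": 1546, "no": 4013},
    },
    "resistance": {
        "sex": {"female": 551, "male": 431},
        "education": {"primary_or_less": 130, "secondary": 359, "tertiary_or_more": 474},
        "employment": {"employed": 476, "student_homemaker_retiree": 434, "unemployed": 56},
        "chronic_condition": {"yes": 279, "no": 703},
    },
}

_DEFAULT_AGE_WEIGHTS = {
    "acceptance": {"18-24": 289, "25-34": 584, "35-44": 946, "45-54": 1079, "55-64": 1028, "65plus": 1498},
    "resistance": {"18-24": 129, "25-34": 206, "35-44": 146, "45-54": 118, "55-64": 123, "65plus": 225},
}

_DEMO_LEVELS = {
    "sex": SEXES,
    "education": EDUCATION_LEVELS,
    "employment": EMPLOYMENT_LEVELS,
    "chronic_condition": YES_NO,
}


@dataclass(frozen=True)
class AgeProfile:
    """Per-age-group overrides: mixing weight plus optional salience/affinity."""

    weight: float
    salience: np.ndarray | None = None
    affinity: np.ndarray | None = None


@dataclass
class SyntheticConfig:
    """Ground-truth parameters for generating a ResponseSet.

    Parameters
    ----------
    n_respondents
        Sample size (defaults to the published group total).
    codebook
        Codebook whose reasons are generated over.
    m_dist
        Probability of mentioning m reasons, for m = 1..m_max
        (m_max <= number of reasons); must sum to 1.
    salience
        Strictly positive marginal-salience vector over reasons
        (normalized internally).
    affinity
        Symmetric matrix with strictly positive off-diagonal entries;
        the diagonal is ignored (no self-pairs are drawn).
    age_profiles
        Optional map age_group -> :class:`AgeProfile`; respondents draw
        their age group from the mixing weights and their reasons from the
        profile's (or the base) salience/affinity.  Absent profiles mean a
        uniform draw over the six age bins with base parameters.
    demographics
        Map variable -> {level: weight} for non-age demographics.
    seed
        Single integer governing all randomness.
    """

    group: str
    codebook: Codebook
    n_respondents: int
    m_dist: dict = field(default_factory=lambda: dict(DEFAULT_M_DIST))
    salience: np.ndarray | None = None
    affinity: np.ndarray | None = None
    age_profiles: dict | None = None
    demographics: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.codebook)
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be positive")
        if self.salience is None:
            counts = REPORTED_MENTION_COUNTS.get(self.group, {})
            self.salience = np.array([float(counts.get(c, 1.0)) for c in self.codebook.codes])
        self.salience = np.asarray(self.salience, dtype=float)
        if self.salience.shape != (k,) or (self.salience <= 0).any():
            raise ValueError("salience must be a strictly positive vector over reasons")
        if self.affinity is None:
            self.affinity = np.ones((k, k))
        self.affinity = np.asarray(self.affinity, dtype=float)
        if self.affinity.shape != (k, k):
            raise ValueError("affinity must be a square matrix over reasons")
        if not np.allclose(self.affinity, self.affinity.T):
            raise ValueError("affinity matrix must be symmetric")
        off = self.affinity[~np.eye(k, dtype=bool)]
        if (off <= 0).any():
            raise ValueError("affinity must be strictly positive off-diagonal")
        if not self.m_dist:
            raise ValueError("m_dist must be non-empty")
        probs = np.array([self.m_dist[m] for m in sorted(self.m_dist)], dtype=float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("m_dist entries must be >= 0 and sum to 1 (within 1e-12)")
        if max(self.m_dist) > k:
            raise ValueError(f"m_dist support exceeds codebook size ({max(self.m_dist)} > {k})")
        if min(self.m_dist) < 1:
            raise ValueError("m_dist support must start at 1")
        if self.age_profiles:
            for age, prof in self.age_profiles.items():
                if age not in AGE_GROUPS:
                    raise ValueError(f"unknown age group {age!r} in age_profiles")
                if prof.weight < 0:
                    raise ValueError("age-profile mixing weights must be >= 0")
                if prof.salience is not None and (np.asarray(prof.salience) <= 0).any():
                    raise ValueError("age-profile salience must be strictly positive")


def default_config(group: str, n_respondents: int | None = None, seed: int = 0, **overrides) -> SyntheticConfig:
    """Config emulating the source survey: published sample size, mention-count
    salience, uniform affinity, published age and demographic marginals."""
    codebook = overrides.pop("codebook", None) or default_codebook(group)
    age_profiles = overrides.pop("age_profiles", None)
    if age_profiles is None:
        age_profiles = {
            age: AgeProfile(weight=float(w))
            for age, w in _DEFAULT_AGE_WEIGHTS[group].items()
        }
    return SyntheticConfig(
        group=group,
        codebook=codebook,
        n_respondents=n_respondents if n_respondents is not None else REPORTED_N[group],
        age_profiles=age_profiles,
        demographics=overrides.pop("demographics", _DEFAULT_DEMOGRAPHICS[group]),
        seed=seed,
        **overrides,
    )


def _draw_reasons(rng, codes, salience, affinity, m) -> frozenset:
    k = len(codes)
    p = salience / salience.sum()
    first = rng.choice(k, p=p)
    drawn = [first]
    available = np.ones(k, dtype=bool)
    available[first] = False
    while len(drawn) < m:
        w = salience * affinity[drawn[-1]]
        w = np.where(available, w, 0.0)
        w_sum = w.sum()
        if w_sum == 0:
            break
        nxt = rng.choice(k, p=w / w_sum)
        drawn.append(nxt)
        available[nxt] = False
    return frozenset(codes[i] for i in drawn)


def generate(config: SyntheticConfig) -> ResponseSet:
    """Generate a validated ResponseSet; deterministic given config and seed."""
    rng = np.random.default_rng(config.seed)
    codes = list(config.codebook.codes)
    m_support = sorted(config.m_dist)
    m_probs = np.array([config.m_dist[m] for m in m_support], dtype=float)
    m_probs = m_probs / m_probs.sum()

    if config.age_profiles:
        ages = list(config.age_profiles)
        age_w = np.array([config.age_profiles[a].weight for a in ages], dtype=float)
        age_p = age_w / age_w.sum()
    else:
        ages = list(AGE_GROUPS)
        age_p = np.full(len(ages), 1.0 / len(ages))

    demo_draws = {}
    demographics = config.demographics or {}
    for var, levels in _DEMO_LEVELS.items():
        weights = demographics.get(var)
        if weights:
            lv = list(weights)
            pw = np.array([weights[x] for x in lv], dtype=float)
            demo_draws[var] = (lv, pw / pw.sum())
        else:
            demo_draws[var] = (list(levels), np.full(len(levels), 1.0 / len(levels)))

    respondents = []
    for i in range(config.n_respondents):
        age = ages[rng.choice(len(ages), p=age_p)]
        prof = (config.age_profiles or {}).get(age)
        salience = config.salience if prof is None or prof.salience is None else np.asarray(prof.salience, dtype=float)
        affinity = config.affinity if prof is None or prof.affinity is None else np.asarray(prof.affinity, dtype=float)
        m = m_support[rng.choice(len(m_support), p=m_probs)]
        reasons = _draw_reasons(rng, codes, salience, affinity, m)
        demo = {var: lv[rng.choice(len(lv), p=pv)] for var, (lv, pv) in demo_draws.items()}
        respondents.append(
            Respondent(
                id=f"s{i:06d}",
                group=config.group,
                reasons=reasons,
                age_group=age,
                **demo,
            )
        )
    return ResponseSet(group=config.group, codebook=config.codebook, respondents=tuple(respondents))


@dataclass(frozen=True)
class PlantedTruth:
    """Expected dominance ordering implied by a config's parameters.

    ``ordering`` lists reason codes by descending salience x total affinity
    (row sum over other reasons); ``has_signal`` is false when all scores tie
    (no planted structure, so no ordering should be recovered).
    """

    ordering: tuple
    scores: dict
    has_signal: bool


def planted_truth(config: SyntheticConfig, age_group: str | None = None) -> PlantedTruth:
    """Dominance ordering used as the parameter-recovery target in tests.

    With ``age_group`` given and a matching profile present, the profile's
    overrides replace the base parameters.
    """
    salience = config.salience
    affinity = config.affinity
    if age_group is not None and config.age_profiles and age_group in config.age_profiles:
        prof = config.age_profiles[age_group]
        if prof.salience is not None:
            salience = np.asarray(prof.salience, dtype=float)
        if prof.affinity is not None:
            affinity = np.asarray(prof.affinity, dtype=float)
    k = len(config.codebook)
    off_diag = affinity * (1.0 - np.eye(k))
    scores = salience * off_diag.sum(axis=1)
    codes = config.codebook.codes
    order = sorted(range(k), key=lambda i: (-scores[i], i))
    has_signal = not np.allclose(scores, scores[0])
    return PlantedTruth(
        ordering=tuple(codes[i] for i in order),
        scores={codes[i]: float(scores[i]) for i in range(k)},
        has_signal=has_signal,
    )
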