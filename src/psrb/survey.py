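"""Monitoring-capacity scores and scale-preference tabulation from questionnaires."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataIntegrityError, UndefinedScoreError

__all__ = [
    "STATUSES",
    "SCALES",
    "SECTORS",
    "INDICATORS",
    "SurveyResponse",
    "MonitoringScore",
    "monitoring_score",
    "scale_preferences",
    "compute_score_table",
    "read_survey_csv",
    "write_survey_csv",
]

STATUSES = ("Monitored", "LimitedMonitoring", "NotMonitored", "Unknown")
SCALES = ("regional", "national", "sub-national", "watershed", "site")
SECTORS = ("public", "civil_society", "academic")
INDICATORS = ("forest", "rli", "kba_protection", "freshwater")


@dataclass(frozen=True)
class SurveyResponse:
    respondent_id: str
    country_id: str
    sector: str
    indicator: str
    status: str
    scales_wanted: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise DataIntegrityError(f"unknown status {self.status!r}")
        unknown = self.scales_wanted - set(SCALES)
        if unknown:
            raise DataIntegrityError(f"unknown scales {sorted(unknown)}")


@dataclass(frozen=True)
class MonitoringScore:
    country_id: str
    indicator: str
    score: float
    p1: float  # fraction answering "Monitored"
    p2: float  # fraction answering "LimitedMonitoring"
    n: int


def monitoring_score(
    responses: Sequence[SurveyResponse],
    country_id: str | None = None,
    indicator: str | None = None,
    include_unknown: bool = True,
) -> MonitoringScore:
    """Score = p1 + 0.5 * p2, scaled 0 (not monitored) to 1 (monitored).

    p1 and p2 are the fractions of respondents answering "Monitored" and
    "Limited Monitoring".  "Unknown" answers stay in the denominator by
    default; ``include_unknown=False`` drops them.
    """
    subset = [
        r
        for r in responses
        if (country_id is None or r.country_id == country_id)
        and (indicator is None or r.indicator == indicator)
    ]
    if not include_unknown:
        subset = [r for r in subset if r.status != "Unknown"]
    if not subset:
        raise UndefinedScoreError("monitoring score undefined with zero responses")
    n = len(subset)
    p1 = sum(r.status == "Monitored" for r in subset) / n
    p2 = sum(r.status == "LimitedMonitoring" for r in subset) / n
    return MonitoringScore(
        country_id=country_id or "all",
        indicator=indicator or "all",
        score=p1 + 0.5 * p2,
        p1=p1,
        p2=p2,
        n=n,
    )


def scale_preferences(responses: Sequence[SurveyResponse]) -> dict[str, float]:
    """Percent of distinct respondents naming each monitoring scale.

    Multiple selections are allowed, so the columns need not sum to 100.
    """
    by_respondent: dict[str, set[str]] = {}
    for r in responses:
        by_respondent.setdefault(r.respondent_id, set()).update(r.scales_wanted)
    if not by_respondent:
        raise UndefinedScoreError("scale preferences undefined with zero respondents")
    total = len(by_respondent)
    return {
        scale: 100.0 * sum(scale in wanted for wanted in by_respondent.values()) / total
        for scale in SCALES
    }


def compute_score_table(
    responses: Sequence[SurveyResponse], include_unknown: bool = True
) -> pd.DataFrame:
    """Tidy per-country x indicator score table (respondent-pooled)."""
    pairs = sorted({(r.country_id, r.indicator) for r in responses})
    rows = []
    for country, indicator in pairs:
        s = monitoring_score(responses, country, indicator, include_unknown=include_unknown)
        rows.append(
            {
                "country_id": country,
                "indicator": indicator,
                "score": s.score,
                "p1": s.p1,
                "p2": s.p2,
                "n": s.n,
            }
        )
    return pd.DataFrame(rows)


def write_survey_csv(responses: Iterable[SurveyResponse], path: str) -> None:
    pd.DataFrame(
        [
            {
                "respondent_id": r.respondent_id,
                "country": r.country_id,
                "sector": r.sector,
                "indicator": r.indicator,
                "status": r.status,
                "scales": ";".join(sorted(r.scales_wanted)),
            }
            for r in responses
        ]
    ).to_csv(path, index=False)


def read_survey_csv(path: str) -> list[SurveyResponse]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        SurveyResponse(
            respondent_id=row["respondent_id"],
            country_id=row["country"],
            sector=row["sector"],
            indicator=row["indicator"],
            status=row["status"],
            scales_wanted=frozenset(row["scales"].split(";")) if row["scales"] else frozenset(),
        )
        for _, row in df.iterrows()
    ]
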