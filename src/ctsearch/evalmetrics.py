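"""Retrieval-relevance and questionnaire metrics.

The evaluation protocol this implements: assessors mark each returned
result relevant or irrelevant with respect to its query, markings are
persisted append-only, and from them the harness computes

* precision@k per query (both the per-query mean and the pooled
  total-relevant / total-marked aggregate, since either aggregation is
  defensible),
* the at-least-one-relevant rate across queries (reported rounded to the
  nearest integer percent, with the unrounded value retained),
* a *study-level* precision@k for image search, where a study counts as
  relevant iff at least one of its shown images was marked relevant —
  image-level precision@10 is misleading when up to five images per study
  are shown and ten images may represent only two studies,

plus standard usability-questionnaire scores: the 10-item, 5-point System
Usability Scale (SUS, scored 0–100) and the 30-item, 7-point USE
questionnaire (usefulness / ease of use / ease of learning / satisfaction),
summarized by medians with not-applicable items excluded.
"""

from __future__ import annotations

import logging
import statistics
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "RelevanceMarking",
    "SUSResponse",
    "USEResponse",
    "DEFAULT_USE_DIMENSIONS",
    "precision_at_k",
    "mean_precision_at_k",
    "pooled_precision_at_k",
    "at_least_one_relevant_rate",
    "study_level_precision_at_k",
    "sus_score",
    "use_summary",
    "append_markings",
    "load_markings",
    "load_sus_responses",
    "load_use_responses",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RelevanceMarking:
    """One persisted relevance judgment for one result of one query."""

    session_id: str
    query_id: str
    result_id: str  # study_id, or image id for image-search markings
    rank: int  # 1-based position in the result list
    relevant: bool
    study_id: str | None = None  # parent study for image markings
    timestamp: float = field(default_factory=time.time)

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


def _ordered_ranks(markings: list[RelevanceMarking]) -> list[RelevanceMarking]:
    ordered = sorted(markings, key=lambda m: m.rank)
    ranks = [m.rank for m in ordered]
    if ranks != list(range(1, len(ordered) + 1)):
        raise ValueError(
            f"markings must cover ranks 1..n without gaps or duplicates, got {ranks}"
        )
    return ordered


def precision_at_k(markings: list[RelevanceMarking], k: int) -> float | None:
    """Fraction of the top-k marked results judged relevant.

    When fewer than k results exist the denominator is the number of
    results actually returned, so a 4-relevant-of-5 query scores 0.8 at
    k=10. Returns None (undefined) for a query with no results.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = _ordered_ranks(markings)
    if not ordered:
        return None
    denom = min(k, len(ordered))
    hits = sum(1 for m in ordered[:k] if m.relevant)
    return hits / denom


def mean_precision_at_k(per_query: list[float | None]) -> float:
    """Unweighted arithmetic mean over queries with defined precision."""
    defined = [v for v in per_query if v is not None]
    if not defined:
        raise ValueError("no queries with defined precision")
    return sum(defined) / len(defined)


def pooled_precision_at_k(
    queries: list[list[RelevanceMarking]], k: int
) -> float:
    """Total relevant / total marked within rank <= k, pooled over queries."""
    hits = total = 0
    for markings in queries:
        ordered = _ordered_ranks(markings)
        top = ordered[:k]
        hits += sum(1 for m in top if m.relevant)
        total += len(top)
    if total == 0:
        raise ValueError("no marked results in any query")
    return hits / total


def at_least_one_relevant_rate(
    queries: list[list[RelevanceMarking]],
) -> tuple[int, float]:
    """Percent of queries with >=1 relevant marking: (rounded, unrounded).

    Rounded to the nearest integer percent for reporting; invariant to the
    order of queries.
    """
    if not queries:
        raise ValueError("at least one query required")
    successes = sum(1 for markings in queries if any(m.relevant for m in markings))
    rate = 100.0 * successes / len(queries)
    return int(round(rate)), rate


def study_level_precision_at_k(
    markings: list[RelevanceMarking], k: int
) -> float | None:
    """Precision over the first k distinct *studies* in an image result list.

    Image markings must carry their parent study_id. A study is relevant
    iff any of its marked images is relevant.
    """
    ordered = _ordered_ranks(markings)
    if not ordered:
        return None
    study_relevant: dict[str, bool] = {}
    for m in ordered:
        if m.study_id is None:
            raise ValueError(
                f"image marking for result {m.result_id!r} lacks a study_id"
            )
        study_relevant[m.study_id] = study_relevant.get(m.study_id, False) or m.relevant
    studies = list(study_relevant)[:k]  # dict preserves first-appearance order
    return sum(study_relevant[s] for s in studies) / min(k, len(study_relevant))


# ---------------------------------------------------------------------------
# Questionnaires

@dataclass(frozen=True)
class SUSResponse:
    respondent_id: str
    items: tuple[int, ...]  # exactly 10 integers, each 1..5

    def __post_init__(self) -> None:
        if len(self.items) != 10:
            raise ValueError(f"SUS requires exactly 10 items, got {len(self.items)}")
        bad = [v for v in self.items if not (isinstance(v, int) and 1 <= v <= 5)]
        if bad:
            raise ValueError(f"SUS items must be integers in 1..5, got {bad}")


def sus_score(response: SUSResponse) -> float:
    """Standard SUS scoring, 0..100.

    Odd-numbered items (positively phrased) contribute response − 1;
    even-numbered items (negatively phrased) contribute 5 − response; the
    contribution sum is multiplied by 2.5.
    """
    contributions = 0
    for i, item in enumerate(response.items, start=1):
        contributions += (item - 1) if i % 2 == 1 else (5 - item)
    return 2.5 * contributions


#: Standard 30-item USE layout: items 1-8 usefulness, 9-19 ease of use,
#: 20-23 ease of learning, 24-30 satisfaction.
DEFAULT_USE_DIMENSIONS: dict[int, str] = {
    **{i: "usefulness" for i in range(1, 9)},
    **{i: "ease_of_use" for i in range(9, 20)},
    **{i: "ease_of_learning" for i in range(20, 24)},
    **{i: "satisfaction" for i in range(24, 31)},
}


@dataclass(frozen=True)
class USEResponse:
    respondent_id: str
    items: tuple[int | None, ...]  # exactly 30; None = not applicable
    dimension_map: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_USE_DIMENSIONS)
    )

    def __post_init__(self) -> None:
        if len(self.items) != 30:
            raise ValueError(f"USE requires exactly 30 items, got {len(self.items)}")
        bad = [v for v in self.items if v is not None and not 1 <= v <= 7]
        if bad:
            raise ValueError(f"USE items must be in 1..7 or NA, got {bad}")
        if set(self.dimension_map) != set(range(1, 31)):
            raise ValueError("dimension_map must cover items 1..30")


def use_summary(responses: list[USEResponse]) -> dict:
    """Per-respondent overall medians and per-dimension medians, NA excluded.

    The median of an even count is the mean of the two central values.
    Respondents with all items NA are excluded with a logged warning.
    """
    if not responses:
        raise ValueError("at least one USE response required")
    per_respondent: dict[str, float] = {}
    dimension_values: dict[str, list[int]] = {}
    for resp in responses:
        values = [v for v in resp.items if v is not None]
        if not values:
            logger.warning(
                "USE respondent %s answered NA to every item; excluded",
                resp.respondent_id,
            )
            continue
        per_respondent[resp.respondent_id] = statistics.median(values)
        for i, v in enumerate(resp.items, start=1):
            if v is not None:
                dimension_values.setdefault(resp.dimension_map[i], []).append(v)
    if not per_respondent:
        raise ValueError("every USE respondent was all-NA")
    all_values = [v for vals in dimension_values.values() for v in vals]
    return {
        "per_respondent_median": per_respondent,
        "per_dimension_median": {
            dim: statistics.median(vals) for dim, vals in dimension_values.items()
        },
        "overall_median": statistics.median(all_values),
    }


# ---------------------------------------------------------------------------
# Persistence (append-only CSV for markings; one-row-per-respondent CSVs
# for questionnaires)

_MARKING_COLUMNS = [
    "session_id", "query_id", "result_id", "rank", "relevant", "study_id",
    "timestamp",
]


def append_markings(markings: list[RelevanceMarking], path: str | Path) -> None:
    """Append markings to a CSV ledger, writing the header if absent."""
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "session_id": m.session_id,
                "query_id": m.query_id,
                "result_id": m.result_id,
                "rank": m.rank,
                "relevant": m.relevant,
                "study_id": m.study_id or "",
                "timestamp": m.timestamp,
            }
            for m in markings
        ],
        columns=_MARKING_COLUMNS,
    )
    df.to_csv(path, mode="a", header=not path.exists(), index=False)


def load_markings(path: str | Path) -> dict[tuple[str, str], list[RelevanceMarking]]:
    """Read the marking ledger, grouped by (session_id, query_id)."""
    df = pd.read_csv(path, dtype={"study_id": str}, keep_default_na=False)
    grouped: dict[tuple[str, str], list[RelevanceMarking]] = {}
    for row in df.itertuples(index=False):
        m = RelevanceMarking(
            session_id=str(row.session_id),
            query_id=str(row.query_id),
            result_id=str(row.result_id),
            rank=int(row.rank),
            relevant=str(row.relevant).strip().lower() in {"true", "1", "t", "yes"},
            study_id=str(row.study_id) or None,
            timestamp=float(row.timestamp),
        )
        grouped.setdefault((m.session_id, m.query_id), []).append(m)
    return grouped


def load_sus_responses(path: str | Path) -> list[SUSResponse]:
    """CSV with columns respondent_id,item_1..item_10."""
    df = pd.read_csv(path)
    return [
        SUSResponse(
            respondent_id=str(row["respondent_id"]),
            items=tuple(int(row[f"item_{i}"]) for i in range(1, 11)),
        )
        for _, row in df.iterrows()
    ]


def load_use_responses(path: str | Path) -> list[USEResponse]:
    """CSV with columns respondent_id,item_1..item_30; NA/blank = not applicable."""
    df = pd.read_csv(path)
    responses = []
    for _, row in df.iterrows():
        items = []
        for i in range(1, 31):
            v = row[f"item_{i}"]
            items.append(None if pd.isna(v) else int(v))
        responses.append(
            USEResponse(respondent_id=str(row["respondent_id"]), items=tuple(items))
        )
    return responses
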