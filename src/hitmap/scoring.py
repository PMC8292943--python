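"""Inclusion/exclusion filters and fractional H-I-T scores.

Scoring is per *code*, not per descriptor: each tree number of each
major-topic descriptor is classified independently, so a descriptor sitting
in two category branches contributes two counts.  The fractional score
divides each category's code count by the total count over the three
categories; codes outside H/I/T are ignored.  An article with 2 H, 1 I and
0 T codes therefore scores (2/3, 1/3, 0).

A corpus enters the mapped dataset only when its major topics hit both the
health-demand and informatics-supply branches (the H x I co-indexing rule),
and secondary-research records are excluded first: articles whose major
topics include "Systematic Reviews as Topic" or "Meta-Analysis as Topic",
review or retracted publication types, and titles containing "bibliometric".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .categories import CategoryScheme, classify_code
from .corpus import ArticleRecord, major_topics
from .vocabulary import MeshTree

logger = logging.getLogger(__name__)

EXCLUDED_MAJOR_TOPICS = frozenset(
    {"Systematic Reviews as Topic", "Meta-Analysis as Topic"})
EXCLUDED_PUBLICATION_TYPES = frozenset({"Review", "Retracted Publication"})
TITLE_EXCLUSION_KEYWORD = "bibliometric"


class ScoringError(ValueError):
    pass


class UnscorableArticle(ScoringError):
    """No major-topic code falls in any H-I-T category."""


@dataclass(frozen=True)
class HITCounts:
    """Counts of category-classified tree-number codes among major topics."""

    n_h: int
    n_i: int
    n_t: int

    def __post_init__(self) -> None:
        if min(self.n_h, self.n_i, self.n_t) < 0:
            raise ScoringError("negative category count")

    @property
    def total(self) -> int:
        return self.n_h + self.n_i + self.n_t


@dataclass(frozen=True)
class HITScore:
    """Fractional (h, i, t) composition; sums to 1 for scorable articles."""

    h: float
    i: float
    t: float

    def __post_init__(self) -> None:
        for v in (self.h, self.i, self.t):
            if not (-1e-9 <= v <= 1 + 1e-9):
                raise ScoringError(f"score component out of [0,1]: {v}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.h, self.i, self.t)


def exclusion_reason(record: ArticleRecord) -> str | None:
    """First matching exclusion reason, or None for an eligible record.

    Checked in order: secondary-research major topic, excluded publication
    type, 'bibliometric' in the title (case-insensitive substring).
    """
    for name in major_topics(record):
        if name in EXCLUDED_MAJOR_TOPICS:
            return f"major_topic:{name}"
    for pt in record.publication_types:
        if pt in EXCLUDED_PUBLICATION_TYPES:
            return f"publication_type:{pt}"
    if TITLE_EXCLUSION_KEYWORD in record.title.lower():
        return "title_keyword:bibliometric"
    return None


def _major_topic_codes(
    record: ArticleRecord, tree: MeshTree
) -> list[tuple[str, str]]:
    """(descriptor name, tree number) pairs for all resolvable major topics.

    Names absent from the vocabulary (version drift between corpus and tree)
    are logged and skipped, never fatal.
    """
    out: list[tuple[str, str]] = []
    for name in major_topics(record):
        if name not in tree.by_name:
            logger.warning("pmid %s: descriptor %r not in MeSH %s; ignored",
                           record.pmid, name, tree.version)
            continue
        for code in tree.by_name[name].tree_numbers:
            out.append((name, code))
    return out


def includes_h_and_i(
    record: ArticleRecord, tree: MeshTree, scheme: CategoryScheme | None = None
) -> bool:
    """H x I co-indexing rule: >=1 major-topic code in H and >=1 in I."""
    scheme = scheme or CategoryScheme()
    labels = {classify_code(code, scheme)
              for _, code in _major_topic_codes(record, tree)}
    return "H" in labels and "I" in labels


def hit_counts(
    record: ArticleRecord,
    tree: MeshTree,
    scheme: CategoryScheme | None = None,
    per_descriptor: bool = False,
) -> HITCounts:
    """Classify every tree number of every major topic.

    With ``per_descriptor=True`` (sensitivity mode) each descriptor counts at
    most once per category regardless of how many of its codes land there.
    """
    scheme = scheme or CategoryScheme()
    tallies = {"H": 0, "I": 0, "T": 0}
    if per_descriptor:
        pairs = _major_topic_codes(record, tree)
        names = {name for name, _ in pairs}
        for name in names:
            labels = {classify_code(code, scheme)
                      for n, code in pairs if n == name}
            for label in labels:
                if label in tallies:
                    tallies[label] += 1
    else:
        for _, code in _major_topic_codes(record, tree):
            label = classify_code(code, scheme)
            if label in tallies:
                tallies[label] += 1
    return HITCounts(tallies["H"], tallies["I"], tallies["T"])


def hit_score(counts: HITCounts) -> HITScore:
    """Fractional score: each category count over the three-category total.

    Raises :class:`UnscorableArticle` on a zero total; callers skip such
    articles when placing points on the triangle.
    """
    if counts.total == 0:
        raise UnscorableArticle("no H-I-T category codes; article unscorable")
    return HITScore(counts.n_h / counts.total,
                    counts.n_i / counts.total,
                    counts.n_t / counts.total)


def mean_scores(scores: Sequence[HITScore]) -> tuple[float, float, float]:
    """Arithmetic mean (h, i, t) over a non-empty corpus; components sum to 1."""
    scores = list(scores)
    if not scores:
        raise ScoringError("mean_scores of an empty corpus")
    n = len(scores)
    return (sum(s.h for s in scores) / n,
            sum(s.i for s in scores) / n,
            sum(s.t for s in scores) / n)


def percent_share(part: int, total: int, ndigits: int = 1) -> float:
    """Percentage of a subset in a corpus, rounded as conventionally printed."""
    if total <= 0:
        raise ScoringError("total must be positive")
    return round(100.0 * part / total, ndigits)


@dataclass(frozen=True)
class ScoredArticle:
    """One pipeline output row."""

    pmid: str
    counts: HITCounts
    score: HITScore | None
    included: bool
    exclusion: str | None


def score_corpus(
    records: Iterable[ArticleRecord],
    tree: MeshTree,
    scheme: CategoryScheme | None = None,
    apply_filters: bool = True,
    per_descriptor: bool = False,
) -> list[ScoredArticle]:
    """Run the full filter + scoring pipeline over a corpus.

    ``included`` means: not excluded, satisfies the H x I rule, and scorable.
    Exclusion and inclusion are independent per-record predicates, so their
    evaluation order cannot change final membership.
    """
    scheme = scheme or CategoryScheme()
    out: list[ScoredArticle] = []
    tally = {"excluded": 0, "not_h_and_i": 0, "unscorable": 0, "included": 0}
    for rec in records:
        reason = exclusion_reason(rec) if apply_filters else None
        counts = hit_counts(rec, tree, scheme, per_descriptor=per_descriptor)
        try:
            score = hit_score(counts)
        except UnscorableArticle:
            score = None
        included = (reason is None
                    and (not apply_filters or includes_h_and_i(rec, tree, scheme))
                    and score is not None)
        if reason is not None:
            tally["excluded"] += 1
        elif score is None:
            tally["unscorable"] += 1
        elif not included:
            tally["not_h_and_i"] += 1
        else:
            tally["included"] += 1
        out.append(ScoredArticle(rec.pmid, counts, score, included, reason))
    logger.info("score_corpus: %s", tally)
    return out
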