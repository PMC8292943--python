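"""Category rollups and H-I-T co-occurrence interaction matrices.

Deep tree-number codes are *rolled up* to the label of their ancestor at a
fixed depth before co-occurrence counting: diseases to the first level of the
C branch, techniques to the first level of E, and informatics concepts two
segments into L (the L branch has a single first-level node, so the
informative groups — Computing Methodologies, Informatics, Communications
Media — live one level deeper).  The two population-health subtrees,
Health [N01.400] and Public Health [N06.850], merge into a single
"Population Health" display label (the Public Health discipline subtree
H02.403.720 rolls there too, since it represents the same demand).

An interaction matrix counts, per article, each unordered pair of distinct
rolled labels across two axes among the article's major-topic codes —
deduplicated within the article, so an article with three cardiovascular
codes and one telemedicine code adds 1, not 3 (per-code counting available
via ``per_code=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .categories import CategoryScheme, classify_code
from .corpus import ArticleRecord
from .scoring import _major_topic_codes
from .vocabulary import MeshTree, is_under, split_segments

POPULATION_HEALTH_PREFIXES = ("N01.400", "N06.850", "H02.403.720")
POPULATION_HEALTH_LABEL = "Population Health"

class InteractionError(ValueError):
    pass


@dataclass(frozen=True)
class RollupScheme:
    """Per-category rollup depth (leading segments retained) plus merge rules.

    Defaults: 1 segment for H (C14, C10, ...) and T (E01..E07), 2 segments
    for I (L01.224 Computing Methodologies, ...); population-health codes
    merge to one display label regardless of depth.
    """

    depths: dict[str, int] = field(
        default_factory=lambda: {"H": 1, "I": 2, "T": 1})
    merges: tuple[tuple[str, str], ...] = field(
        default_factory=lambda: tuple(
            (p, POPULATION_HEALTH_LABEL) for p in POPULATION_HEALTH_PREFIXES))

    def __post_init__(self) -> None:
        for label, d in self.depths.items():
            if d < 1:
                raise InteractionError(f"rollup depth for {label!r} must be >= 1")


def rollup_code(
    code: str,
    tree: MeshTree,
    rollup: RollupScheme | None = None,
    scheme: CategoryScheme | None = None,
) -> str:
    """Display label for one categorized code.

    Merge rules win first (any population-health code maps to its display
    label); otherwise the code is truncated to the configured number of
    segments for its category and the descriptor at that position names the
    label.  If no descriptor sits at the truncated position (or the code is
    shorter than the depth), the deepest available ancestor label is used,
    falling back to the truncated code itself.
    """
    rollup = rollup or RollupScheme()
    scheme = scheme or CategoryScheme()
    for prefix, label in rollup.merges:
        if is_under(code, prefix):
            return label
    category = classify_code(code, scheme)
    if category is None:
        raise InteractionError(f"code {code!r} classifies to no category")
    depth = rollup.depths.get(category, 1)
    segments = split_segments(code)
    for k in range(min(depth, len(segments)), 0, -1):
        truncated = ".".join(segments[:k])
        if truncated in tree.by_code:
            return tree.by_code[truncated].name
    return ".".join(segments[:depth])


_AXES = {"HxI": ("H", "I"), "HxT": ("H", "T"), "IxT": ("I", "T")}


@dataclass
class InteractionMatrix:
    """Integer co-occurrence counts between rolled labels of two categories."""

    axis: str
    table: pd.DataFrame  # rows = first-category labels, cols = second
    vocabulary_version: str = "2020"

    @property
    def total(self) -> int:
        return int(self.table.to_numpy().sum())


def _article_labels(
    record: ArticleRecord,
    tree: MeshTree,
    scheme: CategoryScheme,
    rollup: RollupScheme,
) -> dict[str, list[str]]:
    """Category -> rolled labels (with per-code multiplicity) for one article."""
    out: dict[str, list[str]] = {"H": [], "I": [], "T": []}
    for _, code in _major_topic_codes(record, tree):
        category = classify_code(code, scheme)
        if category in out:
            out[category].append(rollup_code(code, tree, rollup, scheme))
    return out


def cooccurrence_matrix(
    corpus: Iterable[ArticleRecord],
    tree: MeshTree,
    scheme: CategoryScheme | None = None,
    rollup: RollupScheme | None = None,
    axis: str = "HxI",
    per_code: bool = False,
) -> InteractionMatrix:
    """Co-occurrence matrix over an already-filtered (included) corpus.

    Per-article deduplication by default: each distinct label pair increments
    its cell once per article.  With ``per_code=True`` a pair increments once
    per code-pair combination.
    """
    if axis not in _AXES:
        raise InteractionError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    scheme = scheme or CategoryScheme()
    rollup = rollup or RollupScheme()
    cat_a, cat_b = _AXES[axis]
    counts: dict[tuple[str, str], int] = {}
    for record in corpus:
        labels = _article_labels(record, tree, scheme, rollup)
        if per_code:
            pairs: Iterable[tuple[str, str]] = (
                (la, lb) for la in labels[cat_a] for lb in labels[cat_b]
                if la != lb)
        else:
            pairs = {(la, lb) for la in labels[cat_a] for lb in labels[cat_b]
                     if la != lb}
        for pair in pairs:
            counts[pair] = counts.get(pair, 0) + 1
    rows = sorted({a for a, _ in counts})
    cols = sorted({b for _, b in counts})
    table = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for (a, b), k in counts.items():
        table.loc[a, b] = k
    return InteractionMatrix(axis=axis, table=table,
                             vocabulary_version=tree.version)


def subset_by_subtree(
    corpus: Iterable[ArticleRecord],
    tree: MeshTree,
    root: str,
) -> list[ArticleRecord]:
    """Articles with >=1 major-topic code under *root*'s subtree.

    Used for topical sub-datasets such as Artificial Intelligence (the AI
    node and everything beneath it) or Electronic Health Records.
    """
    root_desc = tree.resolve(root)
    prefixes = root_desc.tree_numbers
    out = []
    for record in corpus:
        codes = [code for _, code in _major_topic_codes(record, tree)]
        if any(is_under(code, p) for code in codes for p in prefixes):
            out.append(record)
    return out


def subtree_rollup(tree: MeshTree, root: str,
                   base: RollupScheme | None = None) -> RollupScheme:
    """Rollup whose I depth is one level below *root* (for sub-analyses).

    For the AI sub-dataset the informatics axis is rolled to the secondary
    terms under the AI node, i.e. depth = depth(root) + 1.
    """
    base = base or RollupScheme()
    root_desc = tree.resolve(root)
    if not root_desc.tree_numbers:
        raise InteractionError(f"root {root!r} has no tree numbers")
    depth = min(len(split_segments(c)) for c in root_desc.tree_numbers) + 1
    depths = dict(base.depths)
    depths["I"] = depth
    return RollupScheme(depths=depths, merges=base.merges)


def sankey_edges(
    matrix: InteractionMatrix, min_count: int = 1
) -> list[tuple[str, str, int]]:
    """Edge list (source, target, weight) for cells with count >= min_count."""
    edges = []
    for a in matrix.table.index:
        for b in matrix.table.columns:
            w = int(matrix.table.loc[a, b])
            if w >= min_count:
                edges.append((str(a), str(b), w))
    return edges
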