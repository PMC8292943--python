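"""Synthetic vocabulary and corpus generation with known H-I-T composition.

Every pipeline stage is testable offline: :func:`make_fixture_tree` builds a
small synthetic MeSH-like vocabulary covering all category branches (C,
N01.400, N06.850, H02.403.720, L, E) plus distractor branches that classify
to no category, and :func:`generate_corpus` draws article records whose
major topics follow a target (h, i, t) category mixture, recording exact
per-article ground-truth counts.

Defaults emulate the mapped-literature conditions: a per-article topic count
of 1 + Poisson(5) (typical records carry about 5-10 major terms) and the
mixture (0.45, 0.27, 0.28) — the approximate average composition of the
Chinese informatics-health corpus.  Draws are per code: every sampled topic
contributes exactly one categorized tree number, so the expected mean score
equals the mixture exactly and recovery can be checked against binomial
standard errors.  What the generator does not emulate: realistic term
frequencies, MEDLINE indexing depth, or correlated topic choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .categories import CategoryScheme, classify_descriptor
from .corpus import ArticleRecord, MeshHeading
from .vocabulary import MeshDescriptor, MeshTree

DEFAULT_BRANCH_COUNTS: dict[str, int] = {
    "C": 16, "N01.400": 4, "N06.850": 4, "H02.403.720": 3,
    "L": 12, "E": 14, "B": 5, "D": 4,
}

#: Branches that must be populated for the category scheme to be exercised.
REQUIRED_BRANCHES = ("C", "N01.400", "N06.850", "L", "E")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    n_articles: int = 1000
    mixture: tuple[float, float, float] = (0.45, 0.27, 0.28)
    topics_mean: float = 6.0
    topics_min: int = 1
    seed: int = 0
    branch_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BRANCH_COUNTS))
    included_only: bool = False
    distractor_rate: float = 0.2
    excluded_rate: float = 0.0
    start_year: int = 2010
    end_year: int = 2020

    def __post_init__(self) -> None:
        if self.n_articles < 1:
            raise SimulationError("n_articles must be >= 1")
        if abs(sum(self.mixture) - 1.0) > 1e-9 or min(self.mixture) < 0:
            raise SimulationError(f"mixture must be a probability vector, "
                                  f"got {self.mixture}")
        if self.topics_min < 1:
            raise SimulationError("topics_min must be >= 1")
        for branch in REQUIRED_BRANCHES:
            if self.branch_counts.get(branch, 0) < 1:
                raise SimulationError(
                    f"required branch {branch!r} has no descriptors")
        if self.included_only and (self.mixture[0] == 0 or self.mixture[1] == 0):
            raise SimulationError(
                "included-only corpus is infeasible with a zero H or I weight")


def _branch_descriptors(branch: str, count: int, ui_start: int) -> list[MeshDescriptor]:
    """Deterministic synthetic descriptors for one branch.

    Single-letter branches get first-level group nodes (C01, C02, ...) with
    leaves beneath them; dotted prefixes get a root descriptor at the prefix
    plus leaves.  Every third leaf carries a child descriptor one level
    deeper so subtree queries have real descendants to find.
    """
    out: list[MeshDescriptor] = []
    ui = ui_start

    def make(name: str, codes: tuple[str, ...]) -> MeshDescriptor:
        nonlocal ui
        d = MeshDescriptor(ui=f"S{ui:06d}", name=name, tree_numbers=codes)
        ui += 1
        return d

    if "." in branch or len(branch) > 1:
        root_code = branch
        out.append(make(f"Synthetic {branch} Root", (root_code,)))
        parents = [root_code]
    else:
        n_groups = max(1, count // 4)
        parents = []
        for g in range(1, n_groups + 1):
            code = f"{branch}{g:02d}"
            out.append(make(f"Synthetic {branch} Group {g:02d}", (code,)))
            parents.append(code)
        # single-letter branches also get a depth-2 group layer so depth-2
        # rollups (the informatics convention) resolve to a named descriptor
        if branch == "L":
            sub = []
            for p in parents:
                code = f"{p}.500"
                out.append(make(f"Synthetic {branch} Subgroup {code}", (code,)))
                sub.append(code)
            parents = sub
    for k in range(count):
        parent = parents[k % len(parents)]
        code = f"{parent}.{100 + 10 * k}"
        leaf = make(f"Synthetic {branch} Term {k:03d}", (code,))
        out.append(leaf)
        if k % 3 == 0:
            out.append(make(f"Synthetic {branch} Term {k:03d} Child",
                            (f"{code}.500",)))
    return out


def make_fixture_tree(config: GeneratorConfig | None = None) -> MeshTree:
    """Build the synthetic vocabulary (deterministic for a given config).

    Includes one descriptor holding codes in two H branches (N06.850 and
    H02.403.720) and one excluded-topic descriptor, so multi-code
    classification and the exclusion filter are exercised.
    """
    config = config or GeneratorConfig()
    descriptors: list[MeshDescriptor] = []
    ui_start = 1
    for branch, count in sorted(config.branch_counts.items()):
        batch = _branch_descriptors(branch, count, ui_start)
        descriptors.extend(batch)
        ui_start += len(batch) + 10
    descriptors.append(MeshDescriptor(
        ui="S900001", name="Synthetic Public Health Discipline",
        tree_numbers=("N06.850.999", "H02.403.720.999")))
    descriptors.append(MeshDescriptor(
        ui="S900002", name="Meta-Analysis as Topic",
        tree_numbers=("N06.850.520.830.500",)))
    descriptors.append(MeshDescriptor(
        ui="S900003", name="Synthetic Unclassifiable", tree_numbers=()))
    return MeshTree(descriptors, version=f"synthetic-{config.seed}")


def _pools(tree: MeshTree, scheme: CategoryScheme) -> dict[str, list[MeshDescriptor]]:
    """Sampling pools: descriptors contributing exactly one code to one category.

    Multi-code and excluded-topic descriptors stay out of the pools so each
    draw adds exactly one categorized code to the ground truth.
    """
    pools: dict[str, list[MeshDescriptor]] = {"H": [], "I": [], "T": [], "none": []}
    for d in tree:
        if d.name == "Meta-Analysis as Topic" or not d.classifiable:
            continue
        multi = classify_descriptor(d, scheme)
        if not multi:
            pools["none"].append(d)
        elif sum(multi.values()) == 1:
            pools[next(iter(multi))].append(d)
    return pools


@dataclass(frozen=True)
class GroundTruth:
    pmid: str
    n_h: int
    n_i: int
    n_t: int

    @property
    def total(self) -> int:
        return self.n_h + self.n_i + self.n_t


def generate_corpus(
    config: GeneratorConfig | None = None,
    tree: MeshTree | None = None,
    scheme: CategoryScheme | None = None,
) -> tuple[list[ArticleRecord], list[GroundTruth]]:
    """Draw a corpus with known per-article category counts.

    Each article samples ``1 + Poisson(topics_mean - 1)`` (floored at
    ``topics_min``) category draws from the mixture, then picks distinct
    descriptors from the matching pools.  With ``included_only`` articles are
    rejection-sampled until they hold at least one H and one I topic.
    Distractor major topics (classifying to no category) and non-major
    filler headings are added on top and never enter the ground truth.
    """
    config = config or GeneratorConfig()
    tree = tree if tree is not None else make_fixture_tree(config)
    scheme = scheme or CategoryScheme()
    rng = np.random.default_rng(config.seed)
    pools = _pools(tree, scheme)
    for label, weight in zip(("H", "I", "T"), config.mixture):
        if weight > 0 and not pools[label]:
            raise SimulationError(f"no pool descriptors for category {label}")

    records: list[ArticleRecord] = []
    truths: list[GroundTruth] = []
    labels = ("H", "I", "T")
    countries = ("China", "United States", "United Kingdom", None)
    for idx in range(config.n_articles):
        for _attempt in range(1000):
            k = max(config.topics_min,
                    1 + int(rng.poisson(max(config.topics_mean - 1.0, 0.0))))
            cat_draws = rng.choice(3, size=k, p=list(config.mixture))
            counts = {"H": 0, "I": 0, "T": 0}
            for c in cat_draws:
                counts[labels[c]] += 1
            if not config.included_only or (counts["H"] > 0 and counts["I"] > 0):
                break
        else:
            raise SimulationError("included-only rejection sampling failed")
        chosen: list[MeshDescriptor] = []
        for label in labels:
            pool = pools[label]
            want = counts[label]
            if want == 0:
                continue
            take = min(want, len(pool))
            picks = rng.choice(len(pool), size=take, replace=False)
            chosen.extend(pool[j] for j in picks)
            counts[label] = take  # pool exhaustion shrinks the truth too
        if pools["none"] and rng.random() < config.distractor_rate:
            chosen.append(pools["none"][int(rng.integers(len(pools["none"])))])
        headings = []
        for d in chosen:
            if rng.random() < 0.15:  # starred via a qualifier, not the term
                headings.append(MeshHeading(
                    descriptor_name=d.name, descriptor_ui=d.ui, major=False,
                    qualifiers=(("methods", True),)))
            else:
                headings.append(MeshHeading(
                    descriptor_name=d.name, descriptor_ui=d.ui, major=True))
        if pools["none"] and rng.random() < 0.3:  # non-major filler heading
            d = pools["none"][int(rng.integers(len(pools["none"])))]
            headings.append(MeshHeading(
                descriptor_name=d.name, descriptor_ui=d.ui, major=False))
        pmid = f"S{idx + 1:07d}"
        title = f"Synthetic article {pmid}"
        pub_types = ("Journal Article",)
        if config.excluded_rate and rng.random() < config.excluded_rate:
            pub_types = ("Journal Article", "Review")
        records.append(ArticleRecord(
            pmid=pmid, title=title,
            year=int(rng.integers(config.start_year, config.end_year + 1)),
            language="chi" if rng.random() < 0.05 else "eng",
            country=countries[int(rng.integers(len(countries)))],
            publication_types=pub_types,
            headings=tuple(headings)))
        truths.append(GroundTruth(pmid, counts["H"], counts["I"], counts["T"]))
    return records, truths


def write_truth_table(truths: Iterable[GroundTruth], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pmid\tn_h\tn_i\tn_t\n")
        for t in truths:
            fh.write(f"{t.pmid}\t{t.n_h}\t{t.n_i}\t{t.n_t}\n")
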