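"""The H / I / T category scheme over MeSH branches.

Health demand (H) is the entire Diseases branch [C] plus Health [N01.400],
Public Health [N06.850] and the Public Health discipline branch [H02.403.720];
Informatics supply (I) is Information Science [L]; Technological applications
(T) is Analytical, Diagnostic and Therapeutic Techniques, and Equipment [E].
A tree-number code classifies to the category one of whose prefixes is its
segment-wise ancestor; branch prefix sets must be disjoint, so each code has
at most one category.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .vocabulary import MeshDescriptor, MeshTree, is_under, validate_tree_number

DEFAULT_PREFIXES: dict[str, tuple[str, ...]] = {
    "H": ("C", "N01.400", "N06.850", "H02.403.720"),
    "I": ("L",),
    "T": ("E",),
}


class SchemeError(ValueError):
    """Raised when a category scheme is internally inconsistent."""


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered mapping of category label -> tree-number prefixes.

    Loading fails if any prefix of one category lies under a prefix of
    another (or of the same category twice): overlapping prefixes would make
    classification ambiguous, and the default branches are disjoint by
    construction.

    Parameters
    ----------
    categories
        Label -> prefix tuple.  Defaults to the H/I/T scheme above.
    include_public_health_discipline
        Drop the ``H02.403.720`` prefix from H when False.  The Public Health
        *discipline* subtree (Epidemiology, Preventive Medicine, ...) is part
        of health demand by default.
    """

    categories: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PREFIXES))

    def __post_init__(self) -> None:
        seen: list[tuple[str, str]] = []
        for label, prefixes in self.categories.items():
            if not prefixes:
                raise SchemeError(f"category {label!r} has no prefixes")
            for p in prefixes:
                validate_tree_number(p)
                for other_label, q in seen:
                    if is_under(p, q) or is_under(q, p):
                        raise SchemeError(
                            f"overlapping prefixes: {p!r} ({label}) vs "
                            f"{q!r} ({other_label})")
                seen.append((label, p))

    @classmethod
    def default(cls, include_public_health_discipline: bool = True) -> "CategoryScheme":
        cats = {k: tuple(v) for k, v in DEFAULT_PREFIXES.items()}
        if not include_public_health_discipline:
            cats["H"] = tuple(p for p in cats["H"] if p != "H02.403.720")
        return cls(cats)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.categories)

    def describe(self) -> str:
        """Human-readable scheme listing (for ``--show-scheme``)."""
        return "\n".join(
            f"{label}: {', '.join(prefixes)}"
            for label, prefixes in self.categories.items())


def classify_code(code: str, scheme: CategoryScheme | None = None) -> str | None:
    """Category label for one tree number, or None if no branch matches."""
    scheme = scheme or CategoryScheme()
    for label, prefixes in scheme.categories.items():
        if any(is_under(code, p) for p in prefixes):
            return label
    return None


def classify_descriptor(
    descriptor: MeshDescriptor, scheme: CategoryScheme | None = None
) -> Counter:
    """Multiset of category labels, one entry per classifying tree number.

    A descriptor sitting in two H branches contributes ``{"H": 2}``; codes
    outside every category contribute nothing.
    """
    scheme = scheme or CategoryScheme()
    out: Counter = Counter()
    for code in descriptor.tree_numbers:
        label = classify_code(code, scheme)
        if label is not None:
            out[label] += 1
    return out


def count_category_terms(
    tree: MeshTree,
    scheme: CategoryScheme | None = None,
    convention: str = "descriptors",
) -> dict[str, int]:
    """Per-category term counts under either counting convention.

    ``"descriptors"`` counts unique descriptors with at least one code in the
    category; ``"tree_positions"`` counts tree-number codes.  The two differ
    exactly for descriptors holding several codes in one category.
    """
    scheme = scheme or CategoryScheme()
    if convention not in ("descriptors", "tree_positions"):
        raise ValueError(f"unknown convention {convention!r}")
    counts = {label: 0 for label in scheme.labels}
    for d in tree:
        multi = classify_descriptor(d, scheme)
        for label, k in multi.items():
            counts[label] += 1 if convention == "descriptors" else k
    return counts
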