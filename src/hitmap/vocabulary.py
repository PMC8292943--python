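"""MeSH vocabulary loading and tree-number queries.

The Medical Subject Headings (MeSH) thesaurus arranges descriptors in a
hierarchy of 16 letter-coded branches.  A descriptor (e.g. ``Hypertension``,
UI ``D006973``) may occupy several positions in that hierarchy, each position
identified by a dot-delimited *tree number* such as ``C14.907.489``.  Subtree
membership is decided segment-wise on those codes: ``C14.907.489.480`` lies
under ``C14.907.489``, but ``C14.907`` does *not* lie under ``C14.9`` because
``907`` and ``9`` are different path segments.

Two loaders are provided: the official NLM descriptor XML (``desc2020`` style)
and a compact tab-separated dialect used for fixtures and small extracts::

    ui <TAB> name <TAB> tree_number[|tree_number...]

Both produce the same :class:`MeshTree` for equivalent content.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from lxml import etree

logger = logging.getLogger(__name__)

#: Tree numbers are dot-joined segments; the first segment is a letter-prefixed
#: branch code (``C14``, ``N01``, ``L01``, ``H02`` ...), later segments numeric.
_TREE_NUMBER_RE = re.compile(r"^[A-Z][A-Za-z0-9]*(\.[A-Za-z0-9]+)*$")


class VocabularyError(ValueError):
    """Raised for malformed vocabulary files or unresolvable queries."""


def validate_tree_number(code: str) -> str:
    """Return *code* if it is a syntactically valid MeSH tree number.

    Raises
    ------
    VocabularyError
        If the code is empty, has empty segments, or does not start with a
        letter-prefixed branch segment.
    """
    if not isinstance(code, str) or not _TREE_NUMBER_RE.match(code or ""):
        raise VocabularyError(f"malformed tree number: {code!r}")
    return code


def split_segments(code: str) -> tuple[str, ...]:
    """Split a validated tree number into its path segments."""
    return tuple(validate_tree_number(code).split("."))


def is_under(code: str, prefix: str) -> bool:
    """True iff *code* equals *prefix* or extends it at a dot boundary.

    Matching is segment-wise, never raw string prefixing: ``C14.9`` is not an
    ancestor of ``C14.907``.  One exception mirrors MeSH branch semantics: a
    bare branch letter (``C``, ``L``, ``E`` ...) denotes the whole branch and
    matches every code whose first segment carries that letter (``C14.280``
    is under ``C``), since no descriptor sits at the letter itself.
    """
    code_segs = split_segments(code)
    prefix_segs = split_segments(prefix)
    if len(prefix_segs) == 1 and len(prefix) == 1 and prefix.isalpha():
        return code_segs[0][0] == prefix
    if len(prefix_segs) > len(code_segs):
        return False
    return code_segs[: len(prefix_segs)] == prefix_segs


@dataclass(frozen=True)
class MeshDescriptor:
    """One MeSH descriptor: unique identifier, preferred term, tree positions."""

    ui: str
    name: str
    tree_numbers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise VocabularyError(f"descriptor {self.ui!r} has an empty name")
        for code in self.tree_numbers:
            validate_tree_number(code)

    @property
    def classifiable(self) -> bool:
        """Descriptors without tree numbers load but classify to no category."""
        return bool(self.tree_numbers)


class MeshTree:
    """A descriptor set indexed by tree number, name, and UI.

    Every tree number maps to exactly one descriptor (duplicates are a hard
    error at load time); one descriptor may own several tree numbers.
    """

    def __init__(self, descriptors: list[MeshDescriptor], version: str = "2020"):
        self.version = version
        self.descriptors: list[MeshDescriptor] = list(descriptors)
        self.by_code: dict[str, MeshDescriptor] = {}
        self.by_name: dict[str, MeshDescriptor] = {}
        self.by_ui: dict[str, MeshDescriptor] = {}
        for d in self.descriptors:
            if d.ui in self.by_ui:
                raise VocabularyError(f"duplicate descriptor UI {d.ui!r}")
            self.by_ui[d.ui] = d
            self.by_name[d.name] = d
            if not d.classifiable:
                logger.debug("descriptor %s (%s) has no tree numbers; "
                             "it will classify to no category", d.ui, d.name)
            for code in d.tree_numbers:
                if code in self.by_code:
                    raise VocabularyError(
                        f"tree number {code!r} assigned to both "
                        f"{self.by_code[code].ui!r} and {d.ui!r}")
                self.by_code[code] = d

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    def resolve(self, root: str) -> MeshDescriptor:
        """Resolve *root* by descriptor name, UI, or tree number.

        Raises :class:`VocabularyError` listing near-matches when unresolvable.
        """
        for index in (self.by_name, self.by_ui, self.by_code):
            if root in index:
                return index[root]
        near = [n for n in self.by_name if root.lower() in n.lower()][:5]
        raise VocabularyError(
            f"cannot resolve {root!r} in MeSH {self.version}"
            + (f"; near matches: {near}" if near else ""))

    def descendants(self, root: str) -> set[MeshDescriptor]:
        """All descriptors with >=1 tree number under any of *root*'s codes.

        Includes the root descriptor itself.  *root* may be a descriptor name,
        UI, or a bare tree number; a bare tree number restricts the query to
        that single subtree.
        """
        if _TREE_NUMBER_RE.match(root) and root not in self.by_name:
            prefixes: tuple[str, ...] = (root,)
        else:
            prefixes = self.resolve(root).tree_numbers
            if not prefixes:
                raise VocabularyError(f"root {root!r} has no tree numbers")
        out: set[MeshDescriptor] = set()
        for d in self.descriptors:
            if any(is_under(code, p) for code in d.tree_numbers for p in prefixes):
                out.add(d)
        return out


def load_mesh_xml(path: str, version: str = "2020") -> MeshTree:
    """Load a MeSH descriptor XML file (NLM ``desc`` format).

    Every DescriptorRecord is retained; records without TreeNumbers are kept
    but flagged unclassifiable.  Malformed XML raises an error naming the
    position reported by the parser; duplicate tree numbers are a hard error.
    """
    try:
        doc = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise VocabularyError(f"malformed MeSH XML {path}: {exc}") from exc
    descriptors = []
    for rec in doc.iter("DescriptorRecord"):
        ui = rec.findtext("DescriptorUI", default="").strip()
        name = rec.findtext("DescriptorName/String", default="").strip()
        codes = tuple(
            el.text.strip() for el in rec.findall("TreeNumberList/TreeNumber")
            if el.text and el.text.strip())
        descriptors.append(MeshDescriptor(ui=ui, name=name, tree_numbers=codes))
    return MeshTree(descriptors, version=version)


def load_mesh_table(path: str, version: str = "2020") -> MeshTree:
    """Load the tab-separated fixture dialect: ``ui\\tname\\tcode|code|...``.

    Blank lines and ``#`` comment lines are skipped (blank lines with a
    warning).  A line with fewer than two columns is an error naming the line
    number.  The third column may be empty for unclassifiable descriptors.
    """
    descriptors = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                continue
            if not line.strip():
                logger.warning("%s:%d: blank line skipped", path, lineno)
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise VocabularyError(
                    f"{path}:{lineno}: expected ui<TAB>name[<TAB>codes], "
                    f"got {len(parts)} column(s)")
            ui, name = parts[0].strip(), parts[1].strip()
            codes_field = parts[2].strip() if len(parts) > 2 else ""
            codes = tuple(c.strip() for c in codes_field.split("|") if c.strip())
            descriptors.append(MeshDescriptor(ui=ui, name=name, tree_numbers=codes))
    return MeshTree(descriptors, version=version)


def descendants(tree: MeshTree, root: str) -> set[MeshDescriptor]:
    """Functional alias for :meth:`MeshTree.descendants`."""
    return tree.descendants(root)
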