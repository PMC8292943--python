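"""Disease-burden mapping: ICD-10 -> MeSH subtrees and effort regression.

Each disease in the WHO burden tables is matched to one or more MeSH
subtrees (with optional excluded subtrees): an article maps to the disease
when some major-topic tree number lies under a matched subtree but under no
excluded subtree.  Exclusion always wins — an article on pregnancy-induced
hypertension (C14.907.489.480, excluded) does not count toward hypertensive
heart disease even though its code lies under the matched C14.907.489.
Subtree membership means the whole descendant set, so "Diabetic
Nephropathies" maps to "Kidney Diseases" without the broader term being
assigned.

Publication counts per disease are then regressed through the origin on
DALYs (Disability-Adjusted Life Years), the conventional zero-intercept
model for effort-vs-burden comparisons: slope = Σxy/Σx²; R² uses the
uncentered total sum of squares Σy² (a centered variant is available, but
with no intercept the uncentered form is the standard convention).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .corpus import ArticleRecord
from .scoring import _major_topic_codes
from .vocabulary import MeshTree, is_under, validate_tree_number


class BurdenError(ValueError):
    pass


@dataclass(frozen=True)
class IcdMeshEntry:
    """One disease row of the ICD-10 <-> MeSH correspondence table."""

    disease: str
    icd10: str
    matched: tuple[str, ...]
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.matched:
            raise BurdenError(f"{self.disease!r}: no matched tree numbers")
        for code in self.matched + self.excluded:
            validate_tree_number(code)


@dataclass(frozen=True)
class BurdenRecord:
    """Disease burden in DALYs (units as provided by the burden table)."""

    disease: str
    dalys: float

    def __post_init__(self) -> None:
        if self.dalys < 0:
            raise BurdenError(f"{self.disease!r}: negative DALYs")


def _split_codes(cell: str) -> tuple[str, ...]:
    """Semicolon-separated multi-code cells; 'N/A' and blanks mean none."""
    cell = (cell or "").strip()
    if not cell or cell.upper().startswith("N/A"):
        return ()
    return tuple(c.strip() for c in cell.split(";") if c.strip())


def read_icd_mesh_table(path: str) -> list[IcdMeshEntry]:
    """Read a TSV of disease, ICD-10 range, matched codes, excluded codes."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 3:
                raise BurdenError(
                    f"{path}:{lineno}: expected disease/icd10/matched[/excluded]")
            entries.append(IcdMeshEntry(
                disease=row[0].strip(), icd10=row[1].strip(),
                matched=_split_codes(row[2]),
                excluded=_split_codes(row[3]) if len(row) > 3 else ()))
    return entries


def read_burden_table(path: str) -> list[BurdenRecord]:
    """Read a TSV of disease, DALYs."""
    records = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise BurdenError(f"{path}:{lineno}: expected disease<TAB>DALYs")
            records.append(BurdenRecord(row[0].strip(), float(row[1])))
    return records


def assign_diseases(
    record: ArticleRecord,
    table: Sequence[IcdMeshEntry],
    tree: MeshTree,
) -> set[str]:
    """Diseases whose matched-but-not-excluded subtrees cover a major topic.

    An article may map to several diseases; exclusion precedence is per code:
    a code under any excluded subtree of an entry cannot satisfy that entry.
    """
    codes = [code for _, code in _major_topic_codes(record, tree)]
    out: set[str] = set()
    for entry in table:
        for code in codes:
            if any(is_under(code, m) for m in entry.matched) and \
                    not any(is_under(code, x) for x in entry.excluded):
                out.add(entry.disease)
                break
    return out


def publications_per_disease(
    corpus: Iterable[ArticleRecord],
    table: Sequence[IcdMeshEntry],
    tree: MeshTree,
) -> dict[str, int]:
    """Per-disease article counts; an article counts once per mapped disease."""
    counts = {entry.disease: 0 for entry in table}
    for record in corpus:
        for disease in assign_diseases(record, table, tree):
            counts[disease] += 1
    return counts


@dataclass(frozen=True)
class OriginFit:
    """Through-origin least-squares fit y = slope * x."""

    slope: float
    r_squared: float
    n: int

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float)


def fit_through_origin(
    x: Sequence[float], y: Sequence[float], centered_r2: bool = False
) -> OriginFit:
    """Zero-intercept regression of publication counts on DALYs.

    slope = Σxy / Σx²; R² = 1 − Σ(y−ŷ)²/Σy² (uncentered) by default, or
    1 − Σ(y−ŷ)²/Σ(y−ȳ)² with ``centered_r2=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise BurdenError("x and y must be equal-length vectors of length >= 2")
    if np.any(y < 0):
        raise BurdenError("publication counts must be non-negative")
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise BurdenError("all-zero x: slope undefined")
    slope = float(np.dot(x, y)) / sxx
    resid = y - slope * x
    ss_res = float(np.dot(resid, resid))
    if centered_r2:
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    else:
        ss_tot = float(np.dot(y, y))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return OriginFit(slope=slope, r_squared=r2, n=len(x))


def burden_effort_table(
    corpus: Iterable[ArticleRecord],
    table: Sequence[IcdMeshEntry],
    burden: Sequence[BurdenRecord],
    tree: MeshTree,
):
    """Join per-disease counts with DALYs and fit the through-origin line.

    Returns (DataFrame[disease, dalys, publications], OriginFit).  Diseases
    present in the burden table but absent from the ICD map (or vice versa)
    are dropped from the regression.
    """
    import pandas as pd

    counts = publications_per_disease(corpus, table, tree)
    rows = [(b.disease, b.dalys, counts[b.disease])
            for b in burden if b.disease in counts]
    df = pd.DataFrame(rows, columns=["disease", "dalys", "publications"])
    fit = fit_through_origin(df["dalys"], df["publications"])
    return df, fit
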