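"""Publication records: MEDLINE/PubMed XML and a JSONL dialect.

A record carries the fields the downstream filters consume: PMID, title,
year, language, affiliation country, publication types, and the MeSH headings
with their major-topic flags.  A heading is *major* — starred on PubMed —
when the flag is set on the descriptor or on any of its subheading
(qualifier) combinations; only major headings enter scoring.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator

from lxml import etree

logger = logging.getLogger(__name__)

JSONL_SCHEMA_VERSION = 1

_REQUIRED_FIELDS = ("pmid", "title", "year", "headings")


class CorpusError(ValueError):
    """Raised for malformed corpus files."""


@dataclass(frozen=True)
class MeshHeading:
    """One MeSH heading of a record with descriptor/qualifier major flags."""

    descriptor_name: str
    descriptor_ui: str | None = None
    major: bool = False
    qualifiers: tuple[tuple[str, bool], ...] = ()

    def __post_init__(self) -> None:
        if not self.descriptor_name:
            raise CorpusError("heading with empty descriptor name")

    @property
    def is_major(self) -> bool:
        """Starred at descriptor level or on any qualifier combination."""
        return self.major or any(flag for _, flag in self.qualifiers)


@dataclass(frozen=True)
class ArticleRecord:
    pmid: str
    title: str = ""
    year: int = 2020
    language: str = "eng"
    country: str | None = None
    publication_types: tuple[str, ...] = ()
    headings: tuple[MeshHeading, ...] = ()

    def __post_init__(self) -> None:
        if not (1900 <= self.year <= 2100):
            raise CorpusError(f"pmid {self.pmid}: implausible year {self.year}")


def major_topics(record: ArticleRecord) -> list[str]:
    """Descriptor names of the record's major topics.

    Deduplicated (a descriptor starred via two qualifiers appears once) with
    input order preserved; idempotent.
    """
    seen: dict[str, None] = {}
    for h in record.headings:
        if h.is_major and h.descriptor_name not in seen:
            seen[h.descriptor_name] = None
    return list(seen)


# ---------------------------------------------------------------------------
# PubMed / MEDLINE citation XML

def _parse_heading(el: etree._Element) -> MeshHeading:
    desc = el.find("DescriptorName")
    name = (desc.text or "").strip() if desc is not None else ""
    ui = desc.get("UI") if desc is not None else None
    major = (desc.get("MajorTopicYN", "N") == "Y") if desc is not None else False
    quals = tuple(
        ((q.text or "").strip(), q.get("MajorTopicYN", "N") == "Y")
        for q in el.findall("QualifierName"))
    return MeshHeading(descriptor_name=name, descriptor_ui=ui,
                       major=major, qualifiers=quals)


def read_pubmed_xml(path: str) -> Iterator[ArticleRecord]:
    """Stream ArticleRecords from a PubMed/MEDLINE citation set.

    Citations without a PMID are skipped with a warning; malformed XML raises
    an error carrying the parser position.
    """
    try:
        doc = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusError(f"malformed PubMed XML {path}: {exc}") from exc
    for idx, cit in enumerate(doc.iter("MedlineCitation")):
        pmid = (cit.findtext("PMID") or "").strip()
        if not pmid:
            logger.warning("%s: citation %d has no PMID; skipped", path, idx)
            continue
        art = cit.find("Article")
        title = (art.findtext("ArticleTitle") or "").strip() if art is not None else ""
        language = (art.findtext("Language") or "eng").strip() if art is not None else "eng"
        year_text = None
        if art is not None:
            year_text = art.findtext("Journal/JournalIssue/PubDate/Year")
        year = int(year_text) if year_text and year_text.strip().isdigit() else 2020
        pub_types = tuple(
            (pt.text or "").strip()
            for pt in cit.findall("Article/PublicationTypeList/PublicationType")
            if pt.text and pt.text.strip())
        country = None
        if art is not None:
            aff = art.findtext(
                "AuthorList/Author/AffiliationInfo/Affiliation")
            if aff:
                country = _country_from_affiliation(aff)
        headings = tuple(
            _parse_heading(mh)
            for mh in cit.findall("MeshHeadingList/MeshHeading"))
        yield ArticleRecord(pmid=pmid, title=title, year=year, language=language,
                            country=country, publication_types=pub_types,
                            headings=headings)


#: Minimal built-in gazetteer for first-author affiliation strings; a fuller
#: mapping can be supplied via configuration.
_GAZETTEER = {
    "china": "China", "beijing": "China", "shanghai": "China",
    "usa": "United States", "united states": "United States",
    "united kingdom": "United Kingdom", "uk.": "United Kingdom",
    "germany": "Germany", "canada": "Canada", "australia": "Australia",
    "italy": "Italy", "japan": "Japan", "france": "France",
    "netherlands": "The Netherlands",
}


def _country_from_affiliation(aff: str, gazetteer: dict[str, str] | None = None) -> str | None:
    text = aff.lower()
    for key, country in (gazetteer or _GAZETTEER).items():
        if key in text:
            return country
    return None


# ---------------------------------------------------------------------------
# JSONL dialect

def _heading_to_dict(h: MeshHeading) -> dict:
    return {"descriptor_name": h.descriptor_name,
            "descriptor_ui": h.descriptor_ui,
            "major": h.major,
            "qualifiers": [[n, f] for n, f in h.qualifiers]}


def record_to_dict(record: ArticleRecord) -> dict:
    return {"pmid": record.pmid, "title": record.title, "year": record.year,
            "language": record.language, "country": record.country,
            "publication_types": list(record.publication_types),
            "headings": [_heading_to_dict(h) for h in record.headings]}


def record_from_dict(obj: dict) -> ArticleRecord:
    headings = tuple(
        MeshHeading(descriptor_name=h["descriptor_name"],
                    descriptor_ui=h.get("descriptor_ui"),
                    major=bool(h.get("major", False)),
                    qualifiers=tuple((n, bool(f))
                                     for n, f in h.get("qualifiers", [])))
        for h in obj["headings"])
    return ArticleRecord(pmid=str(obj["pmid"]), title=obj.get("title", ""),
                         year=int(obj.get("year", 2020)),
                         language=obj.get("language", "eng"),
                         country=obj.get("country"),
                         publication_types=tuple(obj.get("publication_types", [])),
                         headings=headings)


def read_jsonl(path: str) -> Iterator[ArticleRecord]:
    """Stream records from the line-delimited JSON dialect.

    Schema violations raise :class:`CorpusError` naming the line and the
    missing field.
    """
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            for field_name in _REQUIRED_FIELDS:
                if field_name not in obj:
                    raise CorpusError(
                        f"{path}:{lineno}: missing field {field_name!r}")
            try:
                yield record_from_dict(obj)
            except (KeyError, TypeError, ValueError) as exc:
                raise CorpusError(f"{path}:{lineno}: {exc}") from exc


def write_jsonl(records: Iterable[ArticleRecord], path: str) -> int:
    """Write records as JSONL; round-trips bit-exactly with :func:`read_jsonl`."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(record_to_dict(rec), ensure_ascii=False,
                                sort_keys=True) + "\n")
            n += 1
    return n
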