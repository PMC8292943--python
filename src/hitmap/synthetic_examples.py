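"""Synthetic stand-in fixtures for the two worked scoring examples.

The original records (PMIDs 28117445 and 25981148) and the official MeSH
2020 descriptor file are external downloads; these fixtures are *synthetic
stand-ins* that reproduce the documented structure of those examples
exactly:

* example 1 — three major-topic terms expanding to six tree-number codes,
  of which 2 classify H, 1 classifies I and 0 classify T, so the score is
  (2/3, 1/3, 0);
* example 2 — the six named major-topic descriptors ("Heart Diseases",
  "Quality of Life", "Telemedicine", "Cardiac Resynchronization Therapy
  Devices", "Defibrillators, Implantable", "Remote Sensing Technology")
  expanding to 10 category codes split 2 H / 2 I / 6 T, so the score is
  (0.2, 0.2, 0.6).

Descriptor names in example 2 are the real ones; tree numbers marked
``synthetic`` below are invented stand-ins placed in the correct branches
(real codes are used where they are published, e.g. Heart Diseases C14.280,
Hypertension C14.907.489).
"""

from __future__ import annotations

from .corpus import ArticleRecord, MeshHeading
from .vocabulary import MeshDescriptor, MeshTree

_EXAMPLE_DESCRIPTORS = [
    # --- example 1: three synthetic terms, six codes, (H,I,T) = (2,1,0) ---
    MeshDescriptor("SX00001", "Health Services Needs (synthetic)",
                   ("C23.550.100", "N06.850.490")),          # 2 x H
    MeshDescriptor("SX00002", "Consumer Health Information (synthetic)",
                   ("L01.143.350", "N03.700.200")),          # 1 x I + none
    MeshDescriptor("SX00003", "Program Context (synthetic)",
                   ("B01.050.150", "G01.100.200")),          # 2 x none
    # --- example 2: the six named descriptors, 10 category codes (2,2,6) ---
    MeshDescriptor("D006331", "Heart Diseases", ("C14.280",)),
    MeshDescriptor("D011788", "Quality of Life",
                   ("K01.752.400.750", "N06.850.505.400")),  # synthetic N06 code
    MeshDescriptor("D017216", "Telemedicine",
                   ("L01.178.847.652", "L01.658.500")),      # synthetic codes
    MeshDescriptor("D058406", "Cardiac Resynchronization Therapy Devices",
                   ("E07.305.250.200", "E07.695.200")),      # synthetic codes
    MeshDescriptor("D017147", "Defibrillators, Implantable",
                   ("E07.305.250.375", "E07.695.180")),      # synthetic codes
    MeshDescriptor("D058998", "Remote Sensing Technology",
                   ("E05.816.300", "E07.850.600")),          # synthetic codes
    # --- Table 2 descriptors (published tree numbers) ---
    MeshDescriptor("D006973", "Hypertension", ("C14.907.489",)),
    MeshDescriptor("D046110", "Hypertension, Pregnancy-Induced",
                   ("C13.703.395", "C14.907.489.480")),
    MeshDescriptor("D017202", "Myocardial Ischemia",
                   ("C14.280.647", "C14.907.585")),
    # a subordinate disease under a broader entry, for subtree assignment
    MeshDescriptor("D007674", "Kidney Diseases", ("C12.777.419",)),
    MeshDescriptor("D003928", "Diabetic Nephropathies",
                   ("C12.777.419.192", "C19.246.099.500")),
]


def worked_example_tree() -> MeshTree:
    """Synthetic vocabulary subset backing the worked examples."""
    return MeshTree(list(_EXAMPLE_DESCRIPTORS), version="synthetic-examples")


def _record(pmid: str, title: str, names: list[str]) -> ArticleRecord:
    return ArticleRecord(
        pmid=pmid, title=title, year=2017, language="eng",
        publication_types=("Journal Article",),
        headings=tuple(MeshHeading(descriptor_name=n, major=True)
                       for n in names))


def worked_example_1() -> ArticleRecord:
    """Synthetic stand-in record for the first scoring example."""
    return _record(
        "28117445", "Synthetic stand-in for worked example 1",
        ["Health Services Needs (synthetic)",
         "Consumer Health Information (synthetic)",
         "Program Context (synthetic)"])


def worked_example_2() -> ArticleRecord:
    """Stand-in record for the second example (real descriptor names)."""
    return _record(
        "25981148", "Synthetic stand-in for worked example 2",
        ["Heart Diseases", "Quality of Life", "Telemedicine",
         "Cardiac Resynchronization Therapy Devices",
         "Defibrillators, Implantable", "Remote Sensing Technology"])
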