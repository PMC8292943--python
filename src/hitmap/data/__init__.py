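"""Packaged fixture tables.

``icd10_mesh_cardiovascular.tsv`` carries the published ICD-10/MeSH
correspondence rows for the two cardiovascular diseases; the DALY table is a
synthetic stand-in (see its header).
"""

from importlib import resources


def path(name: str) -> str:
    """Filesystem path of a packaged data file."""
    return str(resources.files(__package__) / name)


ICD10_MESH_CARDIOVASCULAR = "icd10_mesh_cardiovascular.tsv"
SYNTHETIC_DALYS = "synthetic_dalys.tsv"
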