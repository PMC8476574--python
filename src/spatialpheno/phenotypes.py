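"""Shared vocabulary for spatial immunophenotypes.

Three spatial phenotypes of CD8+ T cell localization are used throughout:

* ``excluded`` — T cells accumulate at the invasive border but not the tumor
  center,
* ``ignored``  — near-absence of T cells at both border and center,
* ``inflamed`` — T cells distributed across border and center alike.

Every module that consumes or produces phenotype labels uses the fixed
ordering defined here, so confusion matrices, centroid tables and reports
are always aligned the same way.
"""

from __future__ import annotations

#: Canonical phenotype ordering (rows/columns of confusion matrices,
#: centroid columns, report fields).
PHENOTYPES: tuple[str, str, str] = ("excluded", "ignored", "inflamed")

#: Sentinel label for samples/scans no rule or classifier call applies to.
UNASSIGNED: str = "unassigned"

#: Response labels for anti-PD1 outcome (responder = CR/PR/SD > 24 weeks,
#: nonresponder = PD). Encoded as an enum-like pair, never re-derived.
RESPONSE_LABELS: tuple[str, str] = ("nonresponder", "responder")


def validate_phenotype(label: str) -> str:
    """Return *label* if it is a known phenotype, else raise ``ValueError``."""
    if label not in PHENOTYPES:
        raise ValueError(
            f"unknown phenotype {label!r}; expected one of {PHENOTYPES}"
        )
    return label
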