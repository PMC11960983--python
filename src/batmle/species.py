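"""Canonical species set for northeastern-US bat acoustic surveys.

Nine species routinely monitored in New York / New England acoustic
surveys, identified by their standard 4-letter codes. ``NOID`` is a
pseudo-label for files the classifier leaves unidentified; it is a valid
*assigned* label but never a true species.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Canonical 4-letter codes, in fixed order. All arrays in this package
#: are aligned to this order unless a ConfusionMatrix restricts them.
CODES: tuple[str, ...] = (
    "EPFU",
    "LABO",
    "LACI",
    "LANO",
    "MYLE",
    "MYLU",
    "MYSE",
    "MYSO",
    "PESU",
)

NOID = "NOID"

SCIENTIFIC_NAMES: dict[str, str] = {
    "EPFU": "Eptesicus fuscus",
    "LABO": "Lasiurus borealis",
    "LACI": "Lasiurus cinereus",
    "LANO": "Lasionycteris noctivagans",
    "MYLE": "Myotis leibii",
    "MYLU": "Myotis lucifugus",
    "MYSE": "Myotis septentrionalis",
    "MYSO": "Myotis sodalis",
    "PESU": "Perimyotis subflavus",
}

#: Acoustically similar group: Myotis calls overlap heavily with each
#: other, so misclassification concentrates within this set.
MYOTIS_GROUP: frozenset[str] = frozenset({"MYLE", "MYLU", "MYSE", "MYSO"})


@dataclass(frozen=True)
class SpeciesLabel:
    """A bat species identified by its 4-letter survey code."""

    code: str

    def __post_init__(self) -> None:
        if self.code not in CODES:
            raise ValueError(
                f"unknown species code {self.code!r}; expected one of {CODES}"
            )

    @property
    def scientific_name(self) -> str:
        return SCIENTIFIC_NAMES[self.code]


def species_index(code: str, species: tuple[str, ...] = CODES) -> int:
    """Index of ``code`` within an ordered species tuple (KeyError if absent)."""
    try:
        return species.index(code)
    except ValueError:
        raise KeyError(f"species {code!r} not in {species}") from None
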