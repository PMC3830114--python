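"""Controlled vocabulary of cotton QTL trait codes.

The 43 trait codes cover fiber quality, yield and yield components, seed
quality, plant morphology, biotic/abiotic stress resistance, physiology and
drought tolerance as studied in tetraploid cotton (*Gossypium hirsutum* x
*G. barbadense*). Source studies spell trait names inconsistently
("Micronaire", "Leaf morph", "Nematode related", ...), so a synonym table
normalizes labels to canonical codes at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["TraitVocabulary", "TRAIT_CATEGORIES", "DEFAULT_VOCABULARY", "UnknownTraitError"]

#: canonical code -> trait category
TRAIT_CATEGORIES: dict[str, str] = {
    # fiber quality
    "FS": "fiber quality",          # fiber strength (g/denier)
    "FL": "fiber quality",          # upper-half mean fiber length (mm)
    "Micro": "fiber quality",       # micronaire (fineness/maturity)
    "FU": "fiber quality",          # fiber length uniformity (%)
    "FE": "fiber quality",          # fiber elongation (%)
    "Color": "fiber quality",       # fiber color / yellowness
    "FM": "fiber quality",          # fiber maturity
    "Perimeter": "fiber quality",   # fiber perimeter
    "WT": "fiber quality",          # weight fitness (arealometer)
    "WallThick": "fiber quality",   # secondary wall thickness
    "SLF": "fiber quality",         # short lint fiber content (%)
    # yield and yield components
    "HI": "yield",                  # harvest index
    "BW": "yield",                  # boll weight (g)
    "LI": "yield",                  # lint index (g / 100 seeds)
    "LP": "yield",                  # lint percent
    "SCY": "yield",                 # seedcotton yield (kg/ha)
    "LY": "yield",                  # lint yield (kg/ha)
    "BN": "yield",                  # boll number per plant
    "LB": "yield",                  # log(locule no.)/log(boll no.)
    # seed quality
    "Gossypol": "seed quality",
    "Protein": "seed quality",
    "Oil": "seed quality",
    "HP": "seed quality",           # hull percentage
    "EPP": "seed quality",          # embryo protein percentage
    "LargenumFS": "seed quality",   # number of large fiber seeds
    "NOFuzFib": "seed quality",     # fuzzless-seed trait
    "SW": "seed quality",           # seed weight (g)
    "SI": "seed quality",           # seed index (g / 100 seeds)
    "SM": "seed quality",           # seed mass per unit area
    # morphological
    "FBNum": "morphological",       # fruiting branch number
    "FBNode": "morphological",      # fruiting branch nodes
    "Pubescence": "morphological",
    "NFFB": "morphological",        # node of first fruiting branch
    "HNFFB": "morphological",       # height of node of first fruiting branch
    "LeafMorph": "morphological",   # leaf size/shape
    # resistance
    "Nematode": "resistance",       # root-knot / reniform nematode
    "VW": "resistance",             # Verticillium wilt
    "Fusarium": "resistance",       # Fusarium wilt
    "Xcm": "resistance",            # bacterial blight
    # physiological
    "Chlorophyll": "physiological",
    # drought tolerance
    "OP": "drought tolerance",      # osmotic potential
    "CIR": "drought tolerance",     # carbon isotope ratio
    "CT": "drought tolerance",      # canopy temperature
}

#: alternate spellings seen in source tables and call names -> canonical code
_SYNONYMS: dict[str, str] = {
    "micronaire": "Micro",
    "microanaire": "Micro",  # recurrent typo in published call names
    "micro": "Micro",
    "color": "Color",
    "colour": "Color",
    "leaf": "LeafMorph",
    "leaf morph": "LeafMorph",
    "leafmorph": "LeafMorph",
    "leaf morphology": "LeafMorph",
    "wall thick": "WallThick",
    "wallthick": "WallThick",
    "wall thickness": "WallThick",
    "fb num": "FBNum",
    "fbnum": "FBNum",
    "fb node": "FBNode",
    "fbnode": "FBNode",
    "nematode": "Nematode",
    "nematode related": "Nematode",
    "verticillium": "VW",
    "vw": "VW",
}


class UnknownTraitError(ValueError):
    """Raised when a trait label cannot be resolved against the vocabulary."""


@dataclass(frozen=True)
class TraitVocabulary:
    """The canonical trait codes and their category assignment."""

    category: dict[str, str] = field(default_factory=lambda: dict(TRAIT_CATEGORIES))

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.category)

    def __contains__(self, code: str) -> bool:
        return code in self.category

    def resolve(self, label: str) -> str:
        """Normalize ``label`` to a canonical code.

        Exact codes pass through; otherwise a case-insensitive synonym
        lookup is applied. Raises :class:`UnknownTraitError` if neither
        matches.
        """
        if label in self.category:
            return label
        key = label.strip().lower()
        if key in _SYNONYMS:
            return _SYNONYMS[key]
        for code in self.category:  # case-insensitive direct match
            if code.lower() == key:
                return code
        raise UnknownTraitError(f"unknown trait: {label!r}")


DEFAULT_VOCABULARY = TraitVocabulary()
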