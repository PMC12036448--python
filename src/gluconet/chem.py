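"""Monoisotopic mass constants for glucuronide fingerprinting.

All diagnostic masses used by the pattern queries are derived at import time
from elemental monoisotopic masses (via :mod:`pyteomics.mass`) rather than
hard-coded decimals, so the arithmetic behind every tolerance window is
auditable:

* ``GLUCURONIDE_NL`` -- loss of the dehydrated glucuronic-acid moiety
  (C6H8O6, 176.0321 Da), the canonical glucuronide neutral loss seen in both
  ESI polarities.
* ``GLUCURONIC_ACID_NL`` -- loss of intact glucuronic acid (C6H10O7,
  194.0425 Da), the rarer benzylic-glucuronide neutral loss.
* ``FRAG_GLUCURONATE_113`` / ``FRAG_GLUCURONATE_85`` -- the two most common
  negative-mode product ions of the glucuronate moiety (C5H5O3- at 113.0244;
  CO loss from it gives 85.0295).
* ``FRAG_GALACTURONIDE_115`` -- C4H3O4- at 115.0038, the high-intensity
  fragment that discriminates galacturonic-acid (C6 epimer) conjugates from
  true glucuronides.
* ``GLUCURONIDE_SULFATE_DELTA`` -- precursor spacing between a glucuronide
  and the matching sulfate conjugate (C6H8O6 - SO3 = 96.0753 Da), used when
  re-adding pruned network edges.
"""

from __future__ import annotations

from pyteomics import mass as _mass

__all__ = [
    "monoisotopic",
    "PROTON",
    "ELECTRON",
    "WATER",
    "CO",
    "GLUCURONIDE_NL",
    "GLUCURONIC_ACID_NL",
    "SULFATE_MOIETY",
    "GLUCURONIDE_SULFATE_DELTA",
    "FRAG_GLUCURONATE_113",
    "FRAG_GLUCURONATE_85",
    "FRAG_GLUCURONATE_75",
    "FRAG_GLUCURONATE_71",
    "FRAG_GALACTURONIDE_115",
    "APAP_GLUCURONIDE_MH_NEG",
]


def monoisotopic(formula: str, charge: int = 0) -> float:
    """Monoisotopic mass (Da) or m/z of ``formula``.

    ``charge=-1`` returns the m/z of the deprotonated ion [M-H]-,
    ``charge=+1`` of [M+H]+ (pyteomics proton-transfer convention).
    """
    return float(_mass.calculate_mass(formula=formula, charge=charge))


PROTON: float = monoisotopic("H+")
ELECTRON: float = _mass.nist_mass["e*"][0][0]
WATER: float = monoisotopic("H2O")
CO: float = monoisotopic("CO")

#: Neutral loss of dehydrated glucuronic acid, C6H8O6 (176.0321 Da).
GLUCURONIDE_NL: float = monoisotopic("C6H8O6")
#: Neutral loss of intact glucuronic acid, C6H10O7 (194.0425 Da).
GLUCURONIC_ACID_NL: float = monoisotopic("C6H10O7")
#: Sulfate conjugate moiety, SO3 (79.9568 Da).
SULFATE_MOIETY: float = monoisotopic("SO3")
#: Glucuronide-vs-sulfate precursor spacing (96.0753 Da).
GLUCURONIDE_SULFATE_DELTA: float = GLUCURONIDE_NL - SULFATE_MOIETY

#: Glucuronate product ion C5H5O3- (113.0244).
FRAG_GLUCURONATE_113: float = monoisotopic("C5H6O3", charge=-1)
#: CO loss from the 113.0244 ion (85.0295).
FRAG_GLUCURONATE_85: float = FRAG_GLUCURONATE_113 - CO
#: Less common glucuronate product ion C2H3O3- (75.0088); off by default in queries.
FRAG_GLUCURONATE_75: float = monoisotopic("C2H4O3", charge=-1)
#: Less common glucuronate product ion C3H3O2- (71.0139); off by default in queries.
FRAG_GLUCURONATE_71: float = monoisotopic("C3H4O2", charge=-1)
#: Galacturonide discriminator C4H3O4- (115.0038).
FRAG_GALACTURONIDE_115: float = monoisotopic("C4H4O4", charge=-1)

#: Acetaminophen glucuronide [M-H]-, C14H17NO8 (326.0882) -- reference value.
APAP_GLUCURONIDE_MH_NEG: float = monoisotopic("C14H17NO8", charge=-1)
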