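"""Monoisotopic mass arithmetic and SUMO2/3 C-terminal remnant definitions.

SUMOylation leaves a C-terminal fragment of SUMO ("remnant" or mass tag)
isopeptide-linked to the substrate lysine after proteolysis.  Which remnant
is left depends on the protease: Lys-C leaves the entire ~5.6 kDa C-terminal
region, trypsin a 32-residue tag, Asp-N the short DVFQQQTGG tag that makes
site-level MS practical.  This module holds the element and residue mass
tables, formula parsing, diagnostic b-/internal-ion m/z computation and the
built-in catalogue of remnant definitions with their neutral losses and
diagnostic ions.

Remnant masses are *modification* masses: the tag is attached through an
isopeptide bond, so no terminal water is added (a remnant's mass is the bare
sum of its residue masses).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping

__all__ = [
    "ELEMENT_MASSES",
    "RESIDUE_COMPOSITIONS",
    "RESIDUE_MASSES",
    "PROTON_MASS",
    "WATER_MASS",
    "CO_MASS",
    "MASS_TOL",
    "ElementalComposition",
    "RemnantDefinition",
    "parse_composition",
    "composition_mass",
    "residue_composition",
    "residue_mass_sum",
    "diagnostic_ion_mz",
    "builtin_remnants",
    "get_remnant",
]

# Monoisotopic element masses (Da).  These reproduce the printed remnant
# masses (e.g. 731.3602 from C33H49N9O10) to the fourth decimal.
ELEMENT_MASSES: Mapping[str, float] = {
    "C": 12.000000,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

# Residue (i.e. dehydrated amino-acid) elemental compositions.
RESIDUE_COMPOSITIONS: Mapping[str, Mapping[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

PROTON_MASS: float = 1.00727646677
WATER_MASS: float = 2 * ELEMENT_MASSES["H"] + ELEMENT_MASSES["O"]
CO_MASS: float = ELEMENT_MASSES["C"] + ELEMENT_MASSES["O"]

#: tolerance for comparing against masses printed at four decimals
MASS_TOL: float = 5e-4


class CompositionError(ValueError):
    """Raised for malformed chemical formulas or unknown symbols."""


@dataclass(frozen=True)
class ElementalComposition:
    """An element -> count mapping with monoisotopic mass semantics."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for element, count in self.counts.items():
            if count < 0:
                raise CompositionError(
                    f"negative count {count} for element {element!r}"
                )

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged: Dict[str, int] = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) + count
        return ElementalComposition(merged)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    @property
    def mass(self) -> float:
        return composition_mass(self)

    def formula(self) -> str:
        """Hill-ish formula string, elements in a stable order."""
        order = ["H", "C", "N", "O", "S"]
        extra = sorted(e for e in self.counts if e not in order)
        return "".join(
            f"{e}{self.counts[e]}" for e in order + extra if self.counts.get(e, 0)
        )


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d+)")


def parse_composition(text: str) -> ElementalComposition:
    """Parse a formula string like ``"H60C41N12O15"``.

    Subscript markers (underscores) are tolerated and stripped.  Repeated
    element symbols accumulate.  Raises :class:`CompositionError` on an empty
    string, an unknown element symbol, or trailing garbage.
    """
    cleaned = text.replace("_", "").strip()
    if not cleaned:
        raise CompositionError("empty composition string")
    counts: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(cleaned):
        if match.start() != pos:
            raise CompositionError(
                f"unparseable composition fragment {cleaned[pos:match.start()]!r}"
            )
        element, n = match.group(1), int(match.group(2))
        if element not in ELEMENT_MASSES:
            raise CompositionError(f"unknown element symbol {element!r}")
        counts[element] = counts.get(element, 0) + n
        pos = match.end()
    if pos != len(cleaned):
        raise CompositionError(f"unparseable composition fragment {cleaned[pos:]!r}")
    return ElementalComposition(counts)


def composition_mass(comp: ElementalComposition | Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of an elemental composition."""
    counts = comp.counts if isinstance(comp, ElementalComposition) else comp
    total = 0.0
    for element, count in counts.items():
        try:
            total += ELEMENT_MASSES[element] * count
        except KeyError:
            raise CompositionError(f"no mass for element {element!r}") from None
    return total


def residue_composition(seq: str) -> ElementalComposition:
    """Summed residue composition of ``seq`` (no terminal water)."""
    counts: Dict[str, int] = {}
    for i, aa in enumerate(seq):
        try:
            comp = RESIDUE_COMPOSITIONS[aa]
        except KeyError:
            raise CompositionError(
                f"unknown residue {aa!r} at position {i + 1}"
            ) from None
        for element, count in comp.items():
            counts[element] = counts.get(element, 0) + count
    return ElementalComposition(counts)


RESIDUE_MASSES: Mapping[str, float] = {
    aa: composition_mass(comp) for aa, comp in RESIDUE_COMPOSITIONS.items()
}


def residue_mass_sum(seq: str) -> float:
    """Sum of residue monoisotopic masses of ``seq`` (Da, no water).

    This is the mass a sequence contributes as an isopeptide-linked branch,
    e.g. a SUMO remnant on a substrate lysine.
    """
    total = 0.0
    for i, aa in enumerate(seq):
        try:
            total += RESIDUE_MASSES[aa]
        except KeyError:
            raise CompositionError(
                f"unknown residue {aa!r} at position {i + 1}"
            ) from None
    return total


_ION_RE = re.compile(r"^(?:b(?P<n>\d+)-)?(?P<res>[A-Z]+)(?P<loss>(?:-(?:H2O|CO))*)$")


def diagnostic_ion_mz(seq: str, ion_label: str, charge: int = 1) -> float:
    """m/z of a diagnostic remnant fragment ion.

    ``ion_label`` is either a b-type prefix ion like ``"b2-DV"`` (optionally
    with ``-H2O`` / ``-CO`` neutral losses, e.g. ``"b2-VF-CO"``) or a bare
    internal fragment like ``"FQQ"``.  Both are computed as residue-mass sum
    plus ``charge`` protons, divided by ``charge``; neutral-loss suffixes
    subtract the corresponding neutral mass.
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    match = _ION_RE.match(ion_label)
    if match is None:
        raise ValueError(f"cannot parse ion label {ion_label!r}")
    residues = match.group("res")
    if match.group("n") is not None:
        n = int(match.group("n"))
        if len(residues) != n:
            raise ValueError(
                f"ion label {ion_label!r}: b{n} but {len(residues)} residues"
            )
        if not seq.startswith(residues):
            raise ValueError(
                f"b-ion residues {residues!r} are not a prefix of {seq!r}"
            )
    elif residues not in seq:
        raise ValueError(f"internal fragment {residues!r} not found in {seq!r}")
    neutral = 0.0
    for loss in match.group("loss").split("-"):
        if loss == "H2O":
            neutral += WATER_MASS
        elif loss == "CO":
            neutral += CO_MASS
    return (residue_mass_sum(residues) - neutral + charge * PROTON_MASS) / charge


@dataclass(frozen=True)
class RemnantDefinition:
    """A protease-specific SUMO2/3 C-terminal remnant.

    ``composition`` (and hence ``monoisotopic_mass``) is the authoritative
    modification mass.  For the Glu-C and trypsin variants the recorded
    composition corresponds to the remnant sequence truncated before its
    C-terminal GG, while the Asp-N composition covers the full sequence;
    ``composition_matches_sequence`` records which situation holds — the two
    are deliberately kept as recorded, never reconciled.
    """

    name: str
    protease: str
    sequence: str
    composition: ElementalComposition
    monoisotopic_mass: float
    neutral_losses: List[str] = field(default_factory=list)
    diagnostic_ions: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(composition_mass(self.composition) - self.monoisotopic_mass) > MASS_TOL:
            raise ValueError(
                f"{self.name}: composition mass "
                f"{composition_mass(self.composition):.4f} != stored "
                f"{self.monoisotopic_mass:.4f}"
            )
        for label in self.neutral_losses:
            frag = label.split("-")[-1] if label.startswith("b") else label
            if frag not in self.sequence:
                raise ValueError(f"{self.name}: neutral loss {label!r} not in sequence")
        for label in self.diagnostic_ions:
            # validates the label against the sequence (prefix/substring)
            diagnostic_ion_mz(self.sequence, label)

    @property
    def composition_matches_sequence(self) -> bool:
        return (
            residue_composition(self.sequence).counts
            == dict(self.composition.counts)
        )

    def ion_table(self, charge: int = 1) -> List[tuple]:
        """(label, m/z) pairs for all diagnostic ions at ``charge``."""
        return [
            (label, diagnostic_ion_mz(self.sequence, label, charge))
            for label in self.diagnostic_ions
        ]


def _remnant(name, protease, sequence, formula, mass, neutral_losses, ions):
    return RemnantDefinition(
        name=name,
        protease=protease,
        sequence=sequence,
        composition=parse_composition(formula),
        monoisotopic_mass=mass,
        neutral_losses=list(neutral_losses),
        diagnostic_ions=list(ions),
    )


def builtin_remnants() -> List[RemnantDefinition]:
    """The eight built-in SUMO2/3 remnant definitions.

    One per second-stage protease search: Asp-N; Glu-C variants 1-3 plus the
    oxidized form of variant 3 (one extra oxygen on the methionine); trypsin
    variants 1-2 (variant 2 carries the additional FR prefix from a missed
    cleavage); and the WALP remnant, which is di-glycine and therefore
    indistinguishable from the tryptic ubiquitin remnant.
    """
    gluc3_ox_comp = parse_composition("H105C70N17O29S1") + ElementalComposition({"O": 1})
    return [
        _remnant(
            "aspn_dvfqqqtgg", "aspn", "DVFQQQTGG", "H60C41N12O15", 960.4301,
            ["b7-DVFQQQT"],
            ["b2-DV", "b3-DVF", "b4-DVFQ", "b5-DVFQQ", "b6-DVFQQQ",
             "b7-DVFQQQT", "b9-DVFQQQTGG", "QQ", "FQ", "FQQ"],
        ),
        _remnant(
            "gluc_variant1", "gluc", "VFQQQTGG", "H49C33N9O10", 731.3602,
            ["b6-VFQQQT"],
            ["b2-VF-CO", "b2-VF", "b3-VFQ", "b4-VFQQ", "b5-VFQQQ",
             "b6-VFQQQT", "b7-VFQQQTG", "b8-VFQQQTGG"],
        ),
        _remnant(
            "gluc_variant2", "gluc", "DTIDVFQQQTGG", "H77C51N13O19", 1175.5459,
            ["b10-DTIDVFQQQT"],
            ["b2-DT", "b3-DTI", "b4-DTID", "b5-DTIDV-H2O", "b5-DTIDV",
             "b6-DTIDVF", "b7-DTIDVFQ", "b8-DTIDVFQQ", "b9-DTIDVFQQQ",
             "b10-DTIDVFQQQT"],
        ),
        _remnant(
            "gluc_variant3", "gluc", "MEDEDTIDVFQQQTGG", "H105C70N17O29S1",
            1679.6985,
            ["b14-MEDEDTIDVFQQQT"],
            ["b2-ME", "b3-MED", "b4-MEDE", "b5-MEDED", "b6-MEDEDT",
             "b6-MEDEDT-H2O", "b7-MEDEDTI", "b7-MEDEDTI-H2O", "b8-MEDEDTID",
             "b8-MEDEDTID-H2O"],
        ),
        RemnantDefinition(
            name="gluc_variant3_oxidized",
            protease="gluc",
            sequence="MEDEDTIDVFQQQTGG",
            composition=gluc3_ox_comp,
            monoisotopic_mass=composition_mass(gluc3_ox_comp),
            neutral_losses=["b14-MEDEDTIDVFQQQT"],
            diagnostic_ions=[],
        ),
        _remnant(
            "trypsin_variant1", "trypsin",
            "FDGQPINETDTPAQLEMEDEDTIDVFQQQTGG", "H218C146N36O58S1", 3435.4936,
            ["b30-FDGQPINETDTPAQLEMEDEDTIDVFQQQT"],
            ["b4-FDGQ", "b6-FDGQPI", "b7-FDGQPIN", "b8-FDGQPINE",
             "b10-FDGQPINETD", "b11-FDGQPINETDT", "b13-FDGQPINETDTPA",
             "b14-FDGQPINETDTPAQ", "b15-FDGQPINETDTPAQL",
             "b16-FDGQPINETDTPAQLE"],
        ),
        _remnant(
            "trypsin_variant2", "trypsin",
            "FRFDGQPINETDTPAQLEMEDEDTIDVFQQQTGG", "H239C161N41O60S1",
            3738.6632,
            ["b32-FRFDGQPINETDTPAQLEMEDEDTIDVFQQQT"],
            ["b6-FRFDGQ", "b12-FRFDGQPINETD", "b13-FRFDGQPINETDT",
             "b16-FRFDGQPINETDTPAQ", "b17-FRFDGQPINETDTPAQL",
             "b18-FRFDGQPINETDTPAQLE", "b24-FRFDGQPINETDTPAQLEMEDEDT",
             "b25-FRFDGQPINETDTPAQLEMEDEDTI",
             "b26-FRFDGQPINETDTPAQLEMEDEDTID",
             "b27-FRFDGQPINETDTPAQLEMEDEDTIDV"],
        ),
        RemnantDefinition(
            name="walp_diglycine",
            protease="walp",
            sequence="GG",
            composition=residue_composition("GG"),
            monoisotopic_mass=residue_mass_sum("GG"),
            neutral_losses=[],
            diagnostic_ions=[],
        ),
    ]


def get_remnant(name: str) -> RemnantDefinition:
    """Look up a builtin remnant by name."""
    for remnant in builtin_remnants():
        if remnant.name == name:
            return remnant
    raise KeyError(f"no builtin remnant named {name!r}")
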