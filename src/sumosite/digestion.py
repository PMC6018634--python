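"""In-silico protein digestion under the workflow's five protease rules.

Cleavage specificities used for the SUMO site searches:

========  ==========================  ===========  ============
protease  C-terminal to               N-terminal   max missed
========  ==========================  ===========  ============
lysc      K                           --           8
aspn      K                           D, E         8
gluc      K, D, E                     --           8
trypsin   K, R                        --           4
walp      K, V, A, T, S, L, G         --           10
========  ==========================  ===========  ============

Lys-C is the first-stage enzyme of the serial digestion (it preserves the
8A2 antibody epitope within the SUMO2/3 C-terminus, unlike trypsin which
cuts inside it); the other four are second-stage search enzymes.  Digestion
here is a pure combinatorial operation — the minimum-length (7 aa) and
maximum-mass limits belong to the filtering stage.

Coordinates are 0-based half-open throughout.  A cut at position ``i``
severs the bond between residues ``i-1`` and ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping

__all__ = [
    "ProteaseRule",
    "DigestPeptide",
    "PROTEASES",
    "MAX_PEPTIDE_MASS",
    "get_protease",
    "cleavage_sites",
    "digest",
    "epitope_intact",
    "derive_remnant",
]


@dataclass(frozen=True)
class ProteaseRule:
    """Cleavage specificity of one protease."""

    name: str
    cterm_residues: FrozenSet[str]
    nterm_residues: FrozenSet[str]
    max_missed: int

    def __post_init__(self) -> None:
        if not self.cterm_residues and not self.nterm_residues:
            raise ValueError(f"{self.name}: no cleavage residues at all")
        if self.max_missed < 0:
            raise ValueError(f"{self.name}: negative max_missed")


PROTEASES: Mapping[str, ProteaseRule] = {
    "lysc": ProteaseRule("lysc", frozenset("K"), frozenset(), 8),
    "aspn": ProteaseRule("aspn", frozenset("K"), frozenset("DE"), 8),
    "gluc": ProteaseRule("gluc", frozenset("KDE"), frozenset(), 8),
    "trypsin": ProteaseRule("trypsin", frozenset("KR"), frozenset(), 4),
    "walp": ProteaseRule("walp", frozenset("KVATSLG"), frozenset(), 10),
}

#: maximum peptide mass (Da) per second-stage search, applied by filtering
MAX_PEPTIDE_MASS: Mapping[str, float] = {
    "aspn": 6000.0,
    "gluc": 7000.0,
    "trypsin": 9000.0,
    "walp": 3200.0,
}


def get_protease(name: str) -> ProteaseRule:
    try:
        return PROTEASES[name]
    except KeyError:
        raise KeyError(
            f"unknown protease {name!r}; known: {sorted(PROTEASES)}"
        ) from None


@dataclass(frozen=True)
class DigestPeptide:
    """One digest product with parent-protein coordinates."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int


def cleavage_sites(seq: str, rule: ProteaseRule) -> List[int]:
    """Ordered 0-based cut positions of ``rule`` in ``seq``.

    Cuts after C-terminal-specificity residues and before N-terminal ones;
    positions 0 and ``len(seq)`` are never reported; coincident cuts from
    the two specificities are deduplicated.  Unknown residues are simply
    non-cleavable.
    """
    if not seq:
        raise ValueError("empty sequence")
    cuts = set()
    for i, aa in enumerate(seq):
        if aa in rule.cterm_residues:
            cuts.add(i + 1)
        if aa in rule.nterm_residues:
            cuts.add(i)
    cuts.discard(0)
    cuts.discard(len(seq))
    return sorted(cuts)


def digest(seq: str, rule: ProteaseRule, max_missed: int | None = None) -> List[DigestPeptide]:
    """All digest peptides of ``seq`` with up to ``max_missed`` missed cleavages.

    Returns every maximal fragment between consecutive cuts plus every
    concatenation of up to ``max_missed + 1`` adjacent fragments, without
    duplicate coordinate spans, ordered by (start, end).
    """
    if max_missed is None:
        max_missed = rule.max_missed
    if not 0 <= max_missed <= rule.max_missed:
        raise ValueError(
            f"max_missed {max_missed} outside [0, {rule.max_missed}] for {rule.name}"
        )
    if not seq:
        return []
    bounds = [0] + cleavage_sites(seq, rule) + [len(seq)]
    peptides: List[DigestPeptide] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for m in range(max_missed + 1):
            j = i + m + 1
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            peptides.append(DigestPeptide(seq[start:end], start, end, m))
    return peptides


def epitope_intact(protein_seq: str, epitope: str, rule: ProteaseRule) -> bool:
    """True iff no cleavage site falls strictly inside any epitope occurrence.

    This is the antibody-survival check: the 8A2 epitope (IRFRFDGQPI within
    the SUMO2/3 C-terminus) is destroyed by trypsin, which cuts after its
    internal arginines, but survives Lys-C digestion.
    """
    starts = []
    pos = protein_seq.find(epitope)
    while pos != -1:
        starts.append(pos)
        pos = protein_seq.find(epitope, pos + 1)
    if not starts:
        raise ValueError(f"epitope {epitope!r} not found in protein")
    cuts = cleavage_sites(protein_seq, rule)
    for start in starts:
        end = start + len(epitope)
        if any(start < cut < end for cut in cuts):
            return False
    return True


def derive_remnant(mature_sumo_cterm: str, rule: ProteaseRule) -> str:
    """The SUMO remnant that ``rule`` leaves on a modified substrate lysine.

    ``mature_sumo_cterm`` is the C-terminal region of mature SUMO ending in
    the diglycine that is isopeptide-linked to the substrate.  The remnant is
    the suffix downstream of the protease's last cleavage site (fully
    cleaved; the longer missed-cleavage variants follow from earlier cuts).
    """
    if not mature_sumo_cterm.endswith("GG"):
        raise ValueError("mature SUMO C-terminus must end in GG")
    cuts = cleavage_sites(mature_sumo_cterm, rule)
    if not cuts:
        return mature_sumo_cterm
    return mature_sumo_cterm[cuts[-1]:]
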