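"""Trident residue-conservation scores over MSAs and the delta-RCS analysis.

The trident score of an alignment column combines three ingredients:

* ``t`` — symbol diversity: weighted Shannon entropy over the 21-symbol
  alphabet (20 residues + gap), normalized by log(min(N, 21));
* ``r`` — stereochemical diversity: mean pairwise distance between the
  column's non-gap residues, where the distance between residues a,b is
  1 - s(a,b)/sqrt(s(a,a) s(b,b)) under a substitution matrix (BLOSUM62 by
  default), rescaled so the most dissimilar residue pair has distance 1;
* ``g`` — weighted gap fraction.

The column score is (1-t)^alpha (1-r)^beta (1-g)^gamma with the exponents
diversity alpha = 1, chemistry beta = 0.5 and gap penalty gamma = 2 by
default; multiplied by 100 it is the Residue Conservation Score (RCS).

Sequences are weighted position-wise (Henikoff & Henikoff); uniform weights
are available.  The delta-RCS analysis pairs every SUMOylated lysine with
every non-SUMOylated lysine of the same protein and structural class
(disordered / globular-exposed / globular-buried; disordered lysines count
as exposed) and runs a two-tailed paired t-test on the pairwise RCS
differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "GAP",
    "ALPHABET",
    "TridentParams",
    "MSAProfile",
    "DeltaRcsClassResult",
    "henikoff_weights",
    "trident_column_score",
    "rcs_profile",
    "classify_lysine",
    "delta_rcs",
]

logger = logging.getLogger(__name__)

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + GAP  # 21 symbols


@dataclass(frozen=True)
class TridentParams:
    matrix: str = "blosum62"
    alpha_diversity: float = 1.0
    beta_chemistry: float = 0.5
    gamma_gap: float = 2.0

    def __post_init__(self) -> None:
        if min(self.alpha_diversity, self.beta_chemistry, self.gamma_gap) < 0:
            raise ValueError("trident exponents must be >= 0")


@lru_cache(maxsize=4)
def _distance_matrix(name: str) -> Dict[Tuple[str, str], float]:
    """Residue-pair distances in [0, 1] derived from a substitution matrix."""
    from Bio.Align import substitution_matrices

    sub = substitution_matrices.load(name.upper())
    raw: Dict[Tuple[str, str], float] = {}
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            raw[(a, b)] = 1.0 - sub[a, b] / math.sqrt(sub[a, a] * sub[b, b])
    max_d = max(raw.values())
    return {k: v / max_d for k, v in raw.items()}


@dataclass(frozen=True)
class MSAProfile:
    """Aligned orthologous sequences with a designated reference row."""

    sequences: Tuple[str, ...]
    reference_row: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal alignment row lengths {sorted(lengths)}")
        if not 0 <= self.reference_row < len(self.sequences):
            raise ValueError("reference_row out of range")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def column(self, j: int) -> List[str]:
        return [s[j] for s in self.sequences]

    def column_map(self) -> Dict[int, int]:
        """1-based ungapped reference position -> 0-based alignment column."""
        ref = self.sequences[self.reference_row]
        mapping = {}
        pos = 0
        for j, aa in enumerate(ref):
            if aa != GAP:
                pos += 1
                mapping[pos] = j
        if not mapping:
            raise ValueError("reference row is entirely gaps")
        return mapping

    @classmethod
    def from_fasta(cls, path, reference_id: Optional[str] = None) -> "MSAProfile":
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        ref = 0
        if reference_id is not None:
            ids = [r.id for r in records]
            ref = ids.index(reference_id)
        return cls(
            sequences=tuple(str(r.seq).upper() for r in records),
            reference_row=ref,
            name=str(path),
        )


def henikoff_weights(sequences: Sequence[str]) -> np.ndarray:
    """Position-based sequence weights, normalized to sum to 1.

    Each column contributes 1/(r*s) to each sequence, where r is the number
    of distinct symbols in the column and s the count of the sequence's own
    symbol; gaps count as a symbol.
    """
    n = len(sequences)
    if n == 0:
        raise ValueError("no sequences")
    weights = np.zeros(n)
    for j in range(len(sequences[0])):
        column = [s[j] for s in sequences]
        counts: Dict[str, int] = {}
        for aa in column:
            counts[aa] = counts.get(aa, 0) + 1
        r = len(counts)
        for i, aa in enumerate(column):
            weights[i] += 1.0 / (r * counts[aa])
    total = weights.sum()
    if total == 0:
        return np.full(n, 1.0 / n)
    return weights / total


def trident_column_score(
    column: Sequence[str],
    weights: Optional[Sequence[float]] = None,
    params: TridentParams = TridentParams(),
) -> float:
    """Trident conservation score of one alignment column, in [0, 1]."""
    if len(column) == 0:
        raise ValueError("empty column")
    n = len(column)
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != n:
            raise ValueError("weights/column length mismatch")
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError(f"weights sum to {w.sum():.8f}, not 1")

    symbols = [aa if aa in ALPHABET else GAP for aa in (c.upper() for c in column)]

    # t: weighted symbol entropy over the 21-letter alphabet
    freq: Dict[str, float] = {}
    for aa, wi in zip(symbols, w):
        freq[aa] = freq.get(aa, 0.0) + wi
    entropy = -sum(p * math.log(p) for p in freq.values() if p > 0)
    lam = math.log(min(n, len(ALPHABET)))
    t = entropy / lam if lam > 0 else 0.0
    t = min(t, 1.0)

    # r: mean pairwise stereochemical distance of the non-gap residues
    residues = [aa for aa in symbols if aa != GAP]
    if len(residues) >= 2:
        dist = _distance_matrix(params.matrix)
        total, pairs = 0.0, 0
        for i in range(len(residues)):
            for j in range(i + 1, len(residues)):
                total += dist[(residues[i], residues[j])]
                pairs += 1
        r = total / pairs
    else:
        r = 0.0

    # g: weighted gap fraction
    g = sum(wi for aa, wi in zip(symbols, w) if aa == GAP)

    return (
        (1.0 - t) ** params.alpha_diversity
        * (1.0 - r) ** params.beta_chemistry
        * (1.0 - g) ** params.gamma_gap
    )


def rcs_profile(
    msa: MSAProfile,
    params: TridentParams = TridentParams(),
    weighting: str = "henikoff",
) -> Dict[int, float]:
    """RCS (percent) for every ungapped reference position of ``msa``."""
    if weighting == "henikoff":
        weights = henikoff_weights(msa.sequences)
    elif weighting == "uniform":
        weights = np.full(len(msa.sequences), 1.0 / len(msa.sequences))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    if len(msa.sequences) == 1:
        logger.info("single-sequence MSA %s: all positions score 100", msa.name)
    return {
        pos: 100.0 * trident_column_score(msa.column(j), weights, params)
        for pos, j in msa.column_map().items()
    }


def classify_lysine(disordered: bool, exposed: bool) -> str:
    """Structural class of a lysine; disordered residues count as exposed."""
    if disordered:
        return "disordered"
    return "globular_exposed" if exposed else "globular_buried"


@dataclass(frozen=True)
class DeltaRcsClassResult:
    structural_class: str
    mean_delta: float
    sd_delta: float
    n_pairs: int
    t_statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.001


def delta_rcs(
    sumo_lysines: Set[Tuple[str, int]],
    all_lysines_rcs: Mapping[Tuple[str, int], float],
    classes: Mapping[Tuple[str, int], str],
) -> Dict[str, DeltaRcsClassResult]:
    """Pairwise RCS differences of SUMOylated vs other lysines, per class.

    Every SUMOylated lysine is paired with every non-SUMOylated lysine of
    the same protein and same structural class; delta = RCS(SUMOylated) -
    RCS(other).  A negative mean means modified lysines are less conserved.
    Classes without any pair are omitted (with a logged notice).  The key
    ``"all"`` carries the result pooled over the three classes.
    """
    by_class: Dict[str, List[float]] = {}
    by_protein: Dict[Tuple[str, str], List[Tuple[int, float]]] = {}
    for (protein, pos), rcs in all_lysines_rcs.items():
        cls = classes.get((protein, pos))
        if cls is None:
            raise KeyError(f"no structural class for ({protein!r}, {pos})")
        by_protein.setdefault((protein, cls), []).append((pos, rcs))

    for protein, pos in sorted(sumo_lysines):
        if (protein, pos) not in all_lysines_rcs:
            raise KeyError(f"no RCS for SUMOylated lysine ({protein!r}, {pos})")
        cls = classes[(protein, pos)]
        rcs_s = all_lysines_rcs[(protein, pos)]
        for other_pos, rcs_n in by_protein.get((protein, cls), ()):
            if other_pos == pos or (protein, other_pos) in sumo_lysines:
                continue
            by_class.setdefault(cls, []).append(rcs_s - rcs_n)

    pooled = [d for deltas in by_class.values() for d in deltas]
    if pooled:
        by_class["all"] = pooled
    results: Dict[str, DeltaRcsClassResult] = {}
    for cls in ("disordered", "globular_exposed", "globular_buried", "all"):
        deltas = by_class.get(cls)
        if not deltas:
            logger.info("structural class %s has no pairs; omitted", cls)
            continue
        arr = np.asarray(deltas)
        if len(arr) > 1 and arr.std(ddof=1) > 0:
            t, p = stats.ttest_1samp(arr, 0.0)
        else:
            t, p = 0.0, 1.0
        results[cls] = DeltaRcsClassResult(
            structural_class=cls,
            mean_delta=float(arr.mean()),
            sd_delta=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            n_pairs=len(arr),
            t_statistic=float(t),
            p_value=float(p),
        )
    return results
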