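"""Quantification of the SUMO2/3 pool equilibrium and SUMO chain topology.

Because the enrichment captures the C-terminus of SUMO2/3 whether or not it
is conjugated, the evidence table carries signal from every cellular pool of
SUMO: conjugated SUMO (split into chain-forming SUMO on SUMO itself, SUMO on
the E1 subunits SAE1/UBA2, on the E2 UBC9, on E3 ligases, or on any other
target), free mature SUMO (peptides ending in QQTGG, predominantly
DVFQQQTGG), and the immature precursors whose C-terminal extension is still
present.  Internal SUMO-derived peptides could originate from any pool and
are excluded from the denominators.

Chain topology is quantified from SUMO-remnant-modified peptides that map to
a SUMO isoform itself: per replicate, each modified lysine accumulates the
full intensity of every peptide carrying it (multiply modified peptides
count fully toward each of their sites) and the per-lysine sums are
normalized to fractions.

Only evidence from the Lys-C/Asp-N workflow enters these quantifications.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .evidence import EvidenceRow, StudyDesign

__all__ = [
    "POOL_LABELS",
    "SumoSequenceConstants",
    "HUMAN_CONSTANTS",
    "MOUSE_CONSTANTS",
    "SUMO1_HUMAN",
    "SUMO2_HUMAN",
    "SUMO3_HUMAN",
    "EquilibriumResult",
    "ChainProfile",
    "classify_row",
    "equilibrium_fractions",
    "chain_topology",
    "compare_organ_fraction",
]

logger = logging.getLogger(__name__)

POOL_LABELS = (
    "chain", "e1", "e2", "e3", "other_target",
    "free_mature", "immature_sumo2", "immature_sumo3", "internal_excluded",
)

#: pools that enter the per-replicate fraction denominator
QUANTIFIED_LABELS = tuple(l for l in POOL_LABELS if l != "internal_excluded")

# Human SUMO precursor sequences (canonical UniProt isoforms).  SUMO2's only
# KxE-motif lysine is K11; the 8A2 epitope IRFRFDGQPI lies in the C-terminal
# half shared by SUMO2 and SUMO3.
SUMO1_HUMAN = (
    "MSDQEAKPSTEDLGDKKEGEYIKLKVIGQDSSEIHFKVKMTTHLKKLKESYCQRQGVPMNSLRFLFEGQR"
    "IADNHTPKELGMEEEDVIEVYQEQTGGHSTV"
)
SUMO2_HUMAN = (
    "MADEKPKEGVKTENNDHINLKVAGQDGSVVQFKIKRHTPLSKLMKAYCERQGLSMRQIRFRFDGQPINET"
    "DTPAQLEMEDEDTIDVFQQQTGGVY"
)
SUMO3_HUMAN = (
    "MSEEKPKEGVKTENDHINLKVAGQDGSVVQFKIKRHTPLSKLMKAYCERQGLSMRQIRFRFDGQPINETD"
    "TPAQLEMEDEDTIDVFQQQTGGVPESSLAGHSF"
)


@dataclass(frozen=True)
class SumoSequenceConstants:
    """Sequence constants used to sub-class SUMO-derived peptides."""

    mature_suffix: str = "QQTGG"
    immature_sumo2: Tuple[str, ...] = ("DVFQQQTGGVY",)
    immature_sumo3: Tuple[str, ...] = ("DVFQQQTGGVP", "DVFQQQTGGVPESSLAGHSF")
    e1_names: Tuple[str, ...] = ("SAE1", "UBA2")
    e2_names: Tuple[str, ...] = ("UBC9",)
    e3_name_pattern: str = "E3 SUMO ligase"
    sumo_protein_ids: Tuple[str, ...] = ("SUMO1", "SUMO2", "SUMO3")


HUMAN_CONSTANTS = SumoSequenceConstants()
MOUSE_CONSTANTS = SumoSequenceConstants(
    immature_sumo2=("DVFQQQTGGVY",),
    immature_sumo3=("DVFQQQTGGSASRGSVPTPNRCP",),
)


def classify_row(
    row: EvidenceRow,
    constants: SumoSequenceConstants = HUMAN_CONSTANTS,
    protein_names: Optional[Mapping[str, str]] = None,
) -> str:
    """Assign one pool label to a SUMO-related evidence row.

    SUMO-remnant-modified rows are classed by their leading protein with
    precedence chain > e1 > e2 > e3 > other_target.  Unmodified rows must
    derive from a SUMO protein and are classed free mature / immature /
    internal by their relation to the QQTGG C-terminus.

    ``protein_names`` optionally maps protein ids to descriptive names, used
    for the "E3 SUMO ligase" substring match; the id itself is always
    checked too.
    """
    names = protein_names or {}
    leading = row.leading_protein
    descriptive = names.get(leading, leading)

    def matches(candidates: Sequence[str]) -> bool:
        return any(c in leading or c in descriptive for c in candidates)

    if row.is_sumo_modified:
        if matches(constants.sumo_protein_ids):
            return "chain"
        if matches(constants.e1_names):
            return "e1"
        if matches(constants.e2_names):
            return "e2"
        if constants.e3_name_pattern in descriptive:
            return "e3"
        return "other_target"

    if not matches(constants.sumo_protein_ids):
        raise ValueError(
            f"row is neither SUMO-modified nor SUMO-derived "
            f"(leading protein {leading!r})"
        )
    peptide = row.peptide_sequence
    suffix = constants.mature_suffix
    if peptide.endswith(suffix):
        return "free_mature"
    if suffix in peptide:
        if any(peptide.endswith(s) or peptide == s for s in constants.immature_sumo2):
            return "immature_sumo2"
        if any(peptide.endswith(s) or peptide == s for s in constants.immature_sumo3):
            return "immature_sumo3"
        # fall back on the residue following the mature C-terminus
        tail = peptide[peptide.rindex(suffix) + len(suffix):]
        return "immature_sumo2" if tail.startswith("VY") else "immature_sumo3"
    return "internal_excluded"


@dataclass
class EquilibriumResult:
    """Per-replicate pool fractions plus per-condition summaries."""

    #: (condition, replicate) -> label -> fraction
    per_replicate: Dict[Tuple[str, int], Dict[str, float]]
    #: condition -> label -> (mean, dispersion, n)
    summary: Dict[str, Dict[str, Tuple[float, float, int]]]
    error_type: str  # "sd" or "sem"
    #: replicates excluded for zero total intensity
    excluded_replicates: List[Tuple[str, int]] = field(default_factory=list)
    #: free-mature intensity restricted to the DVFQQQTGG peptide, per
    #: replicate, reported alongside the all-QQTGG total
    free_dvfqqqtgg_fraction: Dict[Tuple[str, int], float] = field(
        default_factory=dict
    )

    def condition_fractions(self, condition: str, label: str) -> np.ndarray:
        return np.array(
            [
                fractions.get(label, 0.0)
                for (cond, _), fractions in sorted(self.per_replicate.items())
                if cond == condition
            ]
        )


_LYSC_ASPN = ("lysc", "aspn")


def equilibrium_fractions(
    rows: Sequence[EvidenceRow],
    design: StudyDesign,
    constants: SumoSequenceConstants = HUMAN_CONSTANTS,
    protein_names: Optional[Mapping[str, str]] = None,
    error_type: str = "sd",
) -> EquilibriumResult:
    """Pool fractions per replicate, summarized per condition.

    Intensities are summed per pool within each (condition, replicate) and
    divided by the replicate's total over all non-excluded pools.
    ``error_type`` selects SD (cell-culture style) or SEM (organ style)
    for the per-condition dispersion.
    """
    if error_type not in ("sd", "sem"):
        raise ValueError("error_type must be 'sd' or 'sem'")
    sums: Dict[Tuple[str, int], Dict[str, float]] = {}
    free_dvf: Dict[Tuple[str, int], float] = {}
    for row in rows:
        if row.protease not in _LYSC_ASPN:
            continue
        if row.intensity is None:
            continue
        label = classify_row(row, constants, protein_names)
        if label == "internal_excluded":
            continue
        key = (row.condition, row.replicate)
        bucket = sums.setdefault(key, {})
        bucket[label] = bucket.get(label, 0.0) + row.intensity
        if label == "free_mature" and row.peptide_sequence == "DVFQQQTGG":
            free_dvf[key] = free_dvf.get(key, 0.0) + row.intensity

    per_replicate: Dict[Tuple[str, int], Dict[str, float]] = {}
    excluded: List[Tuple[str, int]] = []
    free_fraction: Dict[Tuple[str, int], float] = {}
    for key, bucket in sorted(sums.items()):
        total = sum(bucket.values())
        if total <= 0:
            excluded.append(key)
            logger.warning("replicate %s has zero usable intensity; excluded", key)
            continue
        per_replicate[key] = {
            label: bucket.get(label, 0.0) / total for label in QUANTIFIED_LABELS
        }
        free_fraction[key] = free_dvf.get(key, 0.0) / total

    summary: Dict[str, Dict[str, Tuple[float, float, int]]] = {}
    for condition in design.conditions:
        values = {
            label: [
                fr[label]
                for (cond, _), fr in sorted(per_replicate.items())
                if cond == condition
            ]
            for label in QUANTIFIED_LABELS
        }
        n = len(next(iter(values.values()))) if values else 0
        if n == 0:
            continue
        cond_summary = {}
        for label, vals in values.items():
            arr = np.asarray(vals, dtype=float)
            disp = arr.std(ddof=1) if len(arr) > 1 else 0.0
            if error_type == "sem" and len(arr) > 1:
                disp /= np.sqrt(len(arr))
            cond_summary[label] = (float(arr.mean()), float(disp), len(arr))
        summary[condition] = cond_summary

    return EquilibriumResult(
        per_replicate=per_replicate,
        summary=summary,
        error_type=error_type,
        excluded_replicates=excluded,
        free_dvfqqqtgg_fraction=free_fraction,
    )


@dataclass
class ChainProfile:
    """Per-lysine chain-linkage fractions for one SUMO isoform."""

    isoform: str
    #: (condition, replicate) -> lysine position -> fraction
    per_replicate: Dict[Tuple[str, int], Dict[int, float]]
    #: condition -> lysine position -> (mean, dispersion, n)
    summary: Dict[str, Dict[int, Tuple[float, float, int]]]
    error_type: str = "sd"


def chain_topology(
    rows: Sequence[EvidenceRow],
    design: StudyDesign,
    isoform: str,
    proteins: Mapping[str, str],
    error_type: str = "sd",
) -> ChainProfile:
    """Fractional SUMO-SUMO linkage usage over the lysines of ``isoform``.

    Considers Lys-C/Asp-N evidence whose leading protein is ``isoform``;
    remnant-modified peptides shared between isoforms (C-terminal homology of
    SUMO2/SUMO3) should already carry an isoform-set leading protein and are
    skipped unless unique to ``isoform``.
    """
    if isoform not in proteins:
        raise KeyError(f"isoform {isoform!r} absent from protein sequences")
    seq = proteins[isoform]
    sums: Dict[Tuple[str, int], Dict[int, float]] = {}
    for row in rows:
        if row.protease not in _LYSC_ASPN or row.leading_protein != isoform:
            continue
        if not row.is_sumo_modified or row.intensity is None:
            continue
        offset = seq.find(row.peptide_sequence)
        if offset == -1:
            raise ValueError(
                f"peptide {row.peptide_sequence!r} not found in {isoform}"
            )
        key = (row.condition, row.replicate)
        bucket = sums.setdefault(key, {})
        # a multiply modified peptide contributes its full intensity to
        # every one of its modified lysines
        for mod in row.sumo_mods:
            pos = offset + mod.position
            bucket[pos] = bucket.get(pos, 0.0) + row.intensity

    per_replicate = {}
    for key, bucket in sorted(sums.items()):
        total = sum(bucket.values())
        if total > 0:
            per_replicate[key] = {k: v / total for k, v in sorted(bucket.items())}

    lysines = sorted({k for fr in per_replicate.values() for k in fr})
    summary: Dict[str, Dict[int, Tuple[float, float, int]]] = {}
    for condition in design.conditions:
        cond_reps = [
            fr for (cond, _), fr in sorted(per_replicate.items())
            if cond == condition
        ]
        if not cond_reps:
            continue
        cond_summary = {}
        for k in lysines:
            vals = np.array([fr.get(k, 0.0) for fr in cond_reps])
            disp = vals.std(ddof=1) if len(vals) > 1 else 0.0
            if error_type == "sem" and len(vals) > 1:
                disp /= np.sqrt(len(vals))
            cond_summary[k] = (float(vals.mean()), float(disp), len(vals))
        summary[condition] = cond_summary
    if not per_replicate:
        logger.info("no %s chain evidence; empty profile", isoform)
    return ChainProfile(
        isoform=isoform, per_replicate=per_replicate, summary=summary,
        error_type=error_type,
    )


def compare_organ_fraction(
    result: EquilibriumResult, organ: str, label: str
) -> Tuple[float, float]:
    """Two-sample two-tailed t-test of one organ against six reference organs.

    The reference set is the remaining organs minus the single one whose
    mean fraction is most extreme relative to the rest (largest |z|),
    leaving six "median" organs whose replicate-level fractions are pooled.
    Returns (t statistic, two-tailed P).
    """
    conditions = sorted({cond for cond, _ in result.per_replicate})
    if len(conditions) < 8:
        raise ValueError(
            f"need >= 8 conditions for the six-median-organ reference, "
            f"got {len(conditions)}"
        )
    if organ not in conditions:
        raise KeyError(f"organ {organ!r} not among conditions")
    others = [c for c in conditions if c != organ]
    means = {c: float(np.mean(result.condition_fractions(c, label))) for c in others}

    def extremeness(c: str) -> float:
        rest = np.array([means[o] for o in others if o != c])
        sd = rest.std(ddof=1)
        if sd == 0:
            return abs(means[c] - rest.mean())
        return abs(means[c] - rest.mean()) / sd

    most_extreme = max(others, key=lambda c: (extremeness(c), c))
    reference = [c for c in others if c != most_extreme]
    ref_values = np.concatenate(
        [result.condition_fractions(c, label) for c in reference]
    )
    organ_values = result.condition_fractions(organ, label)
    if len(organ_values) < 2:
        raise ValueError(f"organ {organ!r} has < 2 replicates")
    t, p = stats.ttest_ind(organ_values, ref_values)
    return float(t), float(p)
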