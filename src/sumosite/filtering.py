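"""Site-level quality filtering of SUMO evidence and SUMO-phospho co-modification.

MaxQuant's automatic FDR control is complemented by a manual filtering
ledger: decoy removal, score and localization thresholds, the requirement of
diagnostic remnant fragment ions, and protease-specific rules about SUMO
sites on peptide C-terminal lysines (a site on a C-terminal K of a
trypsin/Glu-C/WALP peptide is chemically implausible because the modified
lysine resists cleavage; for Asp-N it is only plausible when the following
protein residue provides the Asp-N cut).  Every dropped row is attributed to
the first rule that rejects it, so the per-rule counts always add up.

Rule order (fixed): reverse, length, mass, score, delta_multi, loc,
diagnostic, cterm, duplicate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import chem
from .digestion import MAX_PEPTIDE_MASS
from .evidence import EvidenceRow, extract_window

__all__ = [
    "FilterParams",
    "FilterReport",
    "ComodRecord",
    "filter_sites",
    "site_level_fdr",
    "find_comod",
    "RULE_ORDER",
]

logger = logging.getLogger(__name__)

RULE_ORDER = (
    "reverse", "length", "mass", "score", "delta_multi", "loc",
    "diagnostic", "cterm", "duplicate",
)

#: canonical remnant modification mass per search protease (Da), used when
#: checking the per-protease maximum peptide mass
_REMNANT_MASS = {
    "aspn": 960.4301,
    "gluc": 731.3602,
    "trypsin": 3435.4936,
    "walp": 114.0429,
    "lysc": 0.0,
}


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the manual filtering ledger (defaults are the workflow standards)."""

    min_delta_multi: float = 40.0
    min_loc_delta: float = 6.0
    min_andromeda: float = 40.0
    min_delta_single: float = 20.0
    require_diagnostic: bool = True
    min_peptide_length: int = 7
    max_peptide_mass: Mapping[str, float] = field(
        default_factory=lambda: dict(MAX_PEPTIDE_MASS)
    )


@dataclass
class FilterReport:
    counts_dropped: Dict[str, int]
    survivors: int
    input_size: int

    @property
    def fraction_discarded(self) -> float:
        if self.input_size == 0:
            return 0.0
        return 1.0 - self.survivors / self.input_size


def _peptide_mass(row: EvidenceRow) -> float:
    base = chem.residue_mass_sum(row.peptide_sequence) + chem.WATER_MASS
    remnant = _REMNANT_MASS.get(row.protease, 0.0)
    return base + remnant * len(row.sumo_mods)


def _first_violated_rule(
    row: EvidenceRow,
    params: FilterParams,
    proteins: Optional[Mapping[str, str]],
) -> Optional[str]:
    if row.reverse:
        return "reverse"
    if len(row.peptide_sequence) < params.min_peptide_length:
        return "length"
    max_mass = params.max_peptide_mass.get(row.protease)
    if max_mass is not None and _peptide_mass(row) > max_mass:
        return "mass"
    if not (
        row.andromeda_score >= params.min_andromeda
        and row.delta_score > params.min_delta_single
    ):
        return "score"
    if len(row.modifications) >= 2 and not row.delta_score > params.min_delta_multi:
        return "delta_multi"
    if any(m.loc_delta <= params.min_loc_delta for m in row.sumo_mods):
        return "loc"
    if (
        params.require_diagnostic
        and row.protease in ("aspn", "gluc", "trypsin")
        and not row.has_diagnostic_ions
    ):
        return "diagnostic"
    cterm_pos = len(row.peptide_sequence)
    if row.peptide_sequence.endswith("K") and any(
        m.position == cterm_pos for m in row.sumo_mods
    ):
        if row.protease in ("trypsin", "gluc", "walp"):
            return "cterm"
        if row.protease == "aspn":
            if proteins is None:
                raise ValueError(
                    "Asp-N C-terminal lysine rule needs protein sequences"
                )
            seq = proteins.get(row.leading_protein)
            if seq is None:
                raise KeyError(
                    f"leading protein {row.leading_protein!r} absent from FASTA"
                )
            offset = seq.find(row.peptide_sequence)
            if offset == -1:
                raise ValueError(
                    f"peptide {row.peptide_sequence!r} not found in "
                    f"{row.leading_protein!r}"
                )
            nxt = offset + len(row.peptide_sequence)
            if nxt >= len(seq) or seq[nxt] not in "DE":
                return "cterm"
    return None


def _dup_keys(
    row: EvidenceRow, proteins: Optional[Mapping[str, str]]
) -> List[Tuple]:
    """Collapse keys: per-sample MS/MS scan ids, then per-sample 51-mer windows."""
    keys: List[Tuple] = [
        ("scan", row.sample_id, scan) for scan in row.msms_scan_ids
    ]
    for mod in row.sumo_mods:
        if proteins is not None and row.leading_protein in proteins:
            seq = proteins[row.leading_protein]
            offset = seq.find(row.peptide_sequence)
            if offset != -1:
                window = extract_window(seq, offset + mod.position)
                keys.append(("window", row.sample_id, window))
                continue
        keys.append(
            ("window", row.sample_id, row.leading_protein,
             row.peptide_sequence, mod.position)
        )
    return keys


def _row_rank(row: EvidenceRow) -> Tuple:
    loc_max = max((m.loc_delta for m in row.sumo_mods), default=0.0)
    # deterministic tie-break on content, so input order never matters
    return (
        row.delta_score, row.andromeda_score, loc_max,
        row.peptide_sequence, row.sample_id, row.msms_scan_ids,
    )


def filter_sites(
    rows: Sequence[EvidenceRow],
    params: FilterParams = FilterParams(),
    proteins: Optional[Mapping[str, str]] = None,
) -> Tuple[List[EvidenceRow], FilterReport]:
    """Apply the manual filtering ledger; returns (survivors, report)."""
    counts: Dict[str, int] = {rule: 0 for rule in RULE_ORDER}
    passed: List[EvidenceRow] = []
    for row in rows:
        rule = _first_violated_rule(row, params, proteins)
        if rule is None:
            passed.append(row)
        else:
            counts[rule] += 1

    # duplicate collapse: any shared scan id or duplicate window keeps only
    # the best-scoring row
    claimed: Dict[Tuple, EvidenceRow] = {}
    ranked = sorted(passed, key=_row_rank, reverse=True)
    survivors_set = []
    for row in ranked:
        keys = _dup_keys(row, proteins)
        if any(k in claimed for k in keys):
            counts["duplicate"] += 1
            continue
        for k in keys:
            claimed[k] = row
        survivors_set.append(row)
    # content-keyed ordering keeps the output independent of input row order
    survivors = sorted(
        survivors_set,
        key=lambda r: (r.leading_protein, r.peptide_sequence, r.sample_id,
                       r.msms_scan_ids),
    )

    counts = {k: v for k, v in counts.items() if v}
    report = FilterReport(
        counts_dropped=counts, survivors=len(survivors), input_size=len(rows)
    )
    for rule, n in counts.items():
        logger.info("filter rule %-12s dropped %d rows", rule, n)
    logger.info(
        "filtering kept %d/%d rows (%.1f%% discarded)",
        report.survivors, report.input_size, 100 * report.fraction_discarded,
    )
    return survivors, report


def site_level_fdr(
    sites_with_decoys: Sequence[Tuple[float, bool]],
    decoy_fraction_target: float,
) -> float:
    """Smallest accept-above score threshold with decoy/target ratio <= target.

    ``sites_with_decoys`` is (score, is_decoy) per candidate.  Returns
    ``math.inf`` when no threshold attains the target fraction.
    """
    targets = sorted(s for s, d in sites_with_decoys if not d)
    decoys = sorted(s for s, d in sites_with_decoys if d)
    if not targets:
        raise ValueError("no target sites")
    import bisect

    best = math.inf
    for threshold in sorted({s for s, _ in sites_with_decoys}):
        n_t = len(targets) - bisect.bisect_left(targets, threshold)
        n_d = len(decoys) - bisect.bisect_left(decoys, threshold)
        if n_t == 0:
            continue
        if n_d / n_t <= decoy_fraction_target:
            best = min(best, threshold)
    return best


@dataclass(frozen=True)
class ComodRecord:
    """A SUMO-phospho co-modified peptide passing the combined-score filter."""

    peptide_sequence: str
    leading_protein: str
    sumo_position: int
    phospho_position: int
    sumo_loc_delta: float
    phospho_loc_delta: float
    andromeda: float
    delta: float
    combined_score: float
    sumo_window: str
    phospho_window: str


def find_comod(
    rows: Sequence[EvidenceRow],
    proteins: Mapping[str, str],
    min_combined: float = 20.0,
    min_loc_delta: float = 6.0,
    min_andromeda: float = 40.0,
) -> List[ComodRecord]:
    """SUMO-phospho co-modified peptides with combined score > ``min_combined``.

    Only direct MS/MS evidence is considered.  The combined score is
    ``delta / 2`` (so the >20 cutoff is equivalent to a delta score >40),
    with the Andromeda and localization thresholds applied as hard gates.
    Per unique modified peptide (sequence plus modification positions) the
    highest-scoring record is kept.
    """
    best: Dict[Tuple, ComodRecord] = {}
    for row in rows:
        if row.identification_type != "msms":
            continue
        sumos = row.sumo_mods
        phosphos = row.mods_of("phospho")
        if not sumos or not phosphos:
            continue
        if row.andromeda_score - min_andromeda < 0:
            continue
        combined = row.delta_score / 2.0
        if not combined > min_combined:
            continue
        seq = proteins.get(row.leading_protein)
        if seq is None:
            raise KeyError(
                f"leading protein {row.leading_protein!r} absent from FASTA"
            )
        offset = seq.find(row.peptide_sequence)
        if offset == -1:
            raise ValueError(
                f"peptide {row.peptide_sequence!r} not found in "
                f"{row.leading_protein!r}"
            )
        for smod in sumos:
            for pmod in phosphos:
                if min(smod.loc_delta, pmod.loc_delta) - min_loc_delta <= 0:
                    continue
                key = (row.peptide_sequence, smod.position, pmod.position)
                record = ComodRecord(
                    peptide_sequence=row.peptide_sequence,
                    leading_protein=row.leading_protein,
                    sumo_position=smod.position,
                    phospho_position=pmod.position,
                    sumo_loc_delta=smod.loc_delta,
                    phospho_loc_delta=pmod.loc_delta,
                    andromeda=row.andromeda_score,
                    delta=row.delta_score,
                    combined_score=combined,
                    sumo_window=extract_window(seq, offset + smod.position),
                    phospho_window=extract_window(seq, offset + pmod.position),
                )
                prev = best.get(key)
                if prev is None or (record.combined_score, record.andromeda) > (
                    prev.combined_score, prev.andromeda
                ):
                    best[key] = record
    return [best[k] for k in sorted(best)]
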