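"""Synthetic study data with known ground truth for every pipeline stage.

The generator emulates the tables a MaxQuant search of the Lys-C/Asp-N SUMO
enrichment workflow would produce: a proteome FASTA with planted SUMO
acceptor lysines (a configurable fraction in the KxE consensus context),
an evidence table whose rows cover every SUMO pool (substrate conjugates,
SUMO-SUMO chain linkages, SUMO on the E1/E2/E3 enzymes, free mature and
immature SUMO peptides, internal SUMO peptides), decoy and deliberately
rule-violating rows for auditing the filter ledger, SUMO-phospho co-modified
rows, and ortholog alignments in which SUMO-modified lysine columns carry a
planted conservation offset.

Defaults mirror the study conditions: a cell-culture-like design of three
conditions in triplicate, pool fractions with ~93% of SUMO conjugated, the
SUMO2 chain profile concentrated on K11, and 36% KxE adherence.  Intensities
are log-normal per peptide with mean-preserving multiplicative replicate
noise; missingness, when enabled, preferentially removes low intensities.

Everything is deterministic per seed (numpy PCG64).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import digestion
from .conservation import AMINO_ACIDS, GAP, MSAProfile, TridentParams, trident_column_score
from .equilibrium import (
    HUMAN_CONSTANTS,
    SUMO1_HUMAN,
    SUMO2_HUMAN,
    SUMO3_HUMAN,
    SumoSequenceConstants,
)
from .evidence import EvidenceRow, Modification, StudyDesign

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "HEK_LIKE_POOLS",
    "ORGAN_LIKE_POOLS",
    "SUMO2_CHAIN_PROFILE",
    "make_design",
    "generate_proteome",
    "generate_evidence",
    "generate_msa_set",
    "generate_null_matrix",
    "generate_shifted_matrix",
]

#: cell-culture-like pool fractions (93.2% conjugated)
HEK_LIKE_POOLS: Mapping[str, float] = {
    "chain": 0.06,
    "e1": 0.002,
    "e2": 0.01,
    "e3": 0.03,
    "other_target": 0.83,
    "free_mature": 0.06,
    "immature_sumo2": 0.001,
    "immature_sumo3": 0.007,
}

#: organ-like pool fractions (~52% conjugated, large free pool)
ORGAN_LIKE_POOLS: Mapping[str, float] = {
    "chain": 0.05,
    "e1": 0.005,
    "e2": 0.02,
    "e3": 0.01,
    "other_target": 0.43,
    "free_mature": 0.47,
    "immature_sumo2": 0.012,
    "immature_sumo3": 0.003,
}

#: chain-linkage fractions over SUMO2 lysines (1-based positions)
SUMO2_CHAIN_PROFILE: Mapping[int, float] = {11: 0.35, 7: 0.25, 21: 0.20, 33: 0.20}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study; defaults are the emulated conditions."""

    seed: int = 0
    n_proteins: int = 60
    protein_length_range: Tuple[int, int] = (200, 500)
    n_sites: int = 400
    kxe_adherence: float = 0.36
    pool_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(HEK_LIKE_POOLS)
    )
    chain_profile: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {"SUMO2": dict(SUMO2_CHAIN_PROFILE)}
    )
    conditions: Tuple[str, ...] = ("control", "heat", "mg132")
    replicates: int = 3
    base_log2_mean: float = 20.0
    base_log2_sd: float = 1.0
    intensity_cv: float = 0.2
    missing_rate: float = 0.0
    decoy_rate: float = 0.05
    low_score_rate: float = 0.05
    comod_rate: float = 0.05
    #: evidence entries per chain linkage (charge states / cleavage forms)
    chain_peptide_multiplicity: int = 6
    planted_violations: Mapping[str, int] = field(default_factory=dict)
    # MSA generation
    msa_n_proteins: int = 15
    msa_protein_length: int = 100
    msa_n_orthologs: int = 24
    msa_lysines_per_protein: int = 12
    msa_sumo_per_protein: int = 3
    msa_base_rcs_mean: float = 75.0
    msa_base_rcs_sd: float = 5.0
    msa_rcs_offset: float = 10.0  # planted deficit at SUMOylated lysines

    def __post_init__(self) -> None:
        total = sum(self.pool_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pool fractions sum to {total}, not 1")
        for isoform, profile in self.chain_profile.items():
            if abs(sum(profile.values()) - 1.0) > 1e-9:
                raise ValueError(f"chain profile of {isoform} does not sum to 1")
        if not 0.0 <= self.kxe_adherence <= 1.0:
            raise ValueError("kxe_adherence must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    sites: List[Tuple[str, int, bool]]  # (protein, position, is_kxe)
    realized_adherence: float
    pool_fractions: Dict[str, float]
    chain_profile: Dict[str, Dict[int, float]]
    row_pools: Dict[int, str] = field(default_factory=dict)  # row index -> pool
    planted_violations: Dict[str, int] = field(default_factory=dict)
    msa_offset: float = 0.0
    sumo_lysines: List[Tuple[str, int]] = field(default_factory=list)
    lysine_classes: Dict[Tuple[str, int], str] = field(default_factory=dict)


def make_design(
    conditions: Sequence[str] = ("control", "heat", "mg132"), replicates: int = 3
) -> StudyDesign:
    """A sample table of ``conditions`` x ``replicates``."""
    return StudyDesign(
        tuple(
            (f"{cond}_r{rep}", cond, rep)
            for cond in conditions
            for rep in range(1, replicates + 1)
        )
    )


# residues used for random protein backbones; K excluded so every planted
# lysine position is deliberate, keeping site bookkeeping exact
_BACKBONE = "ADEFGHILNPQRSTVWY"
_NON_E_D = "AFGHILNPQRSTVWY"

_ENZYME_PROTEINS = ("SAE1", "UBA2", "UBC9", "E3L1", "E3L2")
PROTEIN_NAMES: Mapping[str, str] = {
    "SAE1": "SUMO-activating enzyme subunit SAE1",
    "UBA2": "SUMO-activating enzyme subunit UBA2",
    "UBC9": "SUMO-conjugating enzyme UBC9",
    "E3L1": "E3 SUMO ligase RanBP2-like protein 1",
    "E3L2": "E3 SUMO ligase PIAS-like protein 2",
}


def _random_protein(rng: np.random.Generator, length: int) -> List[str]:
    return list(rng.choice(list(_BACKBONE), size=length))


def generate_proteome(
    config: GeneratorConfig,
) -> Tuple[Dict[str, str], List[Tuple[str, int, bool]]]:
    """Random proteome with planted SUMO sites; returns (proteins, site plan).

    The site plan lists (protein id, 1-based lysine position, is_kxe).  The
    SUMO paralogs and the conjugation enzymes are always present.  The
    backbone alphabet excludes lysine, so planted positions are the only
    lysines; a KxE site gets E at +2, a non-KxE site a non-E/D residue.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protein_length_range
    # ~1 plantable site per 14 residues given the 10-residue spacing rule
    if config.n_sites > config.n_proteins * lo // 14:
        raise ValueError("site plan infeasible: too many sites per protein")
    proteins: Dict[str, List[str]] = {}
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        proteins[f"P{i:04d}"] = _random_protein(rng, length)

    site_plan: List[Tuple[str, int, bool]] = []
    ids = sorted(proteins)
    per_protein = {pid: 0 for pid in ids}
    for s in range(config.n_sites):
        pid = ids[s % len(ids)]
        seq = proteins[pid]
        # keep planted sites >= 10 residues apart and clear of the termini
        for _ in range(200):
            pos = int(rng.integers(6, len(seq) - 6))
            if all(abs(pos - (p - 1)) >= 10 for q, p, _ in site_plan if q == pid):
                break
        else:
            continue
        is_kxe = bool(rng.random() < config.kxe_adherence)
        seq[pos] = "K"
        seq[pos + 2] = "E" if is_kxe else str(rng.choice(list(_NON_E_D)))
        # flanking aspartates bound the Asp-N fragment containing the site,
        # keeping site peptides short of the per-protease mass limits
        seq[pos - 5] = "D"
        seq[pos + 4] = "D"
        site_plan.append((pid, pos + 1, is_kxe))
        per_protein[pid] += 1

    out = {pid: "".join(seq) for pid, seq in proteins.items()}
    for pid in _ENZYME_PROTEINS:
        seq = _random_protein(rng, 150)
        for pos in (40, 90):
            seq[pos] = "K"
            seq[pos + 2] = str(rng.choice(list(_NON_E_D)))
            seq[pos - 5] = "D"
            seq[pos + 4] = "D"
        out[pid] = "".join(seq)
    # spare proteins reserved for planted filter violations, so their
    # windows never collide with baseline evidence
    n_spare = max(16, sum(config.planted_violations.values()) + 2)
    for k in range(n_spare):
        seq = _random_protein(rng, 120)
        seq[59] = "K"
        seq[61] = str(rng.choice(list(_NON_E_D)))
        seq[54] = "D"
        seq[63] = "D"
        out[f"SPARE{k:03d}"] = "".join(seq)
    out["SUMO1"] = SUMO1_HUMAN
    out["SUMO2"] = SUMO2_HUMAN
    out["SUMO3"] = SUMO3_HUMAN
    return out, site_plan


def _site_peptide(seq: str, position: int) -> Tuple[str, int]:
    """An Asp-N peptide covering 1-based ``position``; (peptide, pos in peptide).

    Fragments are merged forward/backward until the peptide is >= 7 residues
    and the site is not the C-terminal residue.
    """
    rule = digestion.PROTEASES["aspn"]
    bounds = [0] + digestion.cleavage_sites(seq, rule) + [len(seq)]
    i = position - 1
    frag = next(k for k in range(len(bounds) - 1) if bounds[k] <= i < bounds[k + 1])
    start, end = frag, frag + 1
    while bounds[end] - bounds[start] < 7 or bounds[end] == i + 1:
        can_fwd = bounds[end] < len(seq)
        can_bwd = bounds[start] > 0
        if bounds[end] == i + 1:  # site must not be the C-terminal residue
            if not can_fwd:
                break
            end += 1
        elif can_fwd and can_bwd:
            # extend whichever side adds the shorter fragment
            fwd = bounds[end + 1] - bounds[end]
            bwd = bounds[start] - bounds[start - 1]
            if fwd <= bwd:
                end += 1
            else:
                start -= 1
        elif can_fwd:
            end += 1
        elif can_bwd:
            start -= 1
        else:
            break
    s, e = bounds[start], bounds[end]
    return seq[s:e], i - s + 1


def _lognormal_noise(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with mean 1 and the given CV."""
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size=size)


class _RowFactory:
    """Bookkeeping for evidence rows: scan ids, score draws, intensities."""

    def __init__(self, config: GeneratorConfig, design: StudyDesign):
        self.config = config
        self.design = design
        self.rng = np.random.default_rng(config.seed + 1)
        self.next_scan = 100000
        self.rows: List[EvidenceRow] = []
        self.row_pools: Dict[int, str] = {}

    def scores(self, multi: bool = False) -> Tuple[float, float, float]:
        rng = self.rng
        andromeda = float(np.clip(rng.normal(130, 25), 45, None))
        lo = 45.0 if multi else 25.0
        delta = float(np.clip(rng.normal(85, 15), lo, None))
        loc = float(np.clip(rng.normal(30, 10), 6.5, None))
        return andromeda, delta, loc

    def add(
        self,
        pool: Optional[str],
        sample_id: str,
        condition: str,
        replicate: int,
        peptide: str,
        mods: Tuple[Modification, ...],
        leading: str,
        intensity: Optional[float],
        *,
        reverse: bool = False,
        andromeda: Optional[float] = None,
        delta: Optional[float] = None,
        identification_type: str = "msms",
        protease: str = "aspn",
        has_diagnostic_ions: bool = True,
    ) -> EvidenceRow:
        a, d, _ = self.scores(multi=len(mods) >= 2)
        row = EvidenceRow(
            peptide_sequence=peptide,
            modifications=mods,
            protein_ids=(leading,),
            leading_protein=leading,
            andromeda_score=a if andromeda is None else andromeda,
            delta_score=d if delta is None else delta,
            reverse=reverse,
            msms_scan_ids=(self.next_scan,),
            identification_type=identification_type,
            sample_id=sample_id,
            condition=condition,
            replicate=replicate,
            intensity=intensity,
            protease=protease,
            has_diagnostic_ions=has_diagnostic_ions,
        )
        self.next_scan += 1
        if pool is not None:
            self.row_pools[len(self.rows)] = pool
        self.rows.append(row)
        return row


def _base_intensities(
    rng: np.random.Generator, n: int, config: GeneratorConfig
) -> np.ndarray:
    return 2.0 ** rng.normal(config.base_log2_mean, config.base_log2_sd, size=n)


def generate_evidence(
    config: GeneratorConfig,
    proteome: Tuple[Dict[str, str], List[Tuple[str, int, bool]]],
) -> Tuple[List[EvidenceRow], StudyDesign, GroundTruth]:
    """Evidence rows for the full design, plus the planted ground truth.

    Per replicate, expected summed intensity of each pool equals its
    configured fraction of the total; replicate intensities carry
    mean-preserving log-normal noise so realized fractions scatter around
    the truth.
    """
    proteins, site_plan = proteome
    design = make_design(config.conditions, config.replicates)
    factory = _RowFactory(config, design)
    rng = np.random.default_rng(config.seed + 2)
    constants = HUMAN_CONSTANTS

    # --- peptide inventories per pool, with base intensities scaled so each
    # pool's expected sum matches its configured fraction
    total_budget = 2.0 ** (config.base_log2_mean + 10)

    inventory: List[Tuple[str, str, Tuple[Modification, ...], str, float]] = []
    # (pool, peptide, mods, leading protein, base intensity)

    # substrate conjugates
    base = _base_intensities(rng, len(site_plan), config)
    base *= config.pool_fractions["other_target"] * total_budget / base.sum()
    for (pid, pos, _), b in zip(site_plan, base):
        peptide, pep_pos = _site_peptide(proteins[pid], pos)
        loc = float(np.clip(rng.normal(30, 10), 6.5, None))
        inventory.append(
            ("other_target", peptide, (Modification("sumo", pep_pos, loc),), pid, b)
        )

    # SUMO chains, split per isoform profile; several evidence entries per
    # linkage (charge states / missed-cleavage forms) for stable fractions
    chain_total = config.pool_fractions["chain"] * total_budget
    chain_multiplicity = config.chain_peptide_multiplicity
    for isoform, profile in config.chain_profile.items():
        seq = proteins[isoform]
        for lys_pos, frac in sorted(profile.items()):
            if seq[lys_pos - 1] != "K":
                raise ValueError(f"{isoform} has no lysine at {lys_pos}")
            peptide, pep_pos = _site_peptide(seq, lys_pos)
            share = chain_total * frac / len(config.chain_profile)
            for _ in range(chain_multiplicity):
                loc = float(np.clip(rng.normal(30, 10), 6.5, None))
                inventory.append(
                    (
                        "chain",
                        peptide,
                        (Modification("sumo", pep_pos, loc),),
                        isoform,
                        share / chain_multiplicity,
                    )
                )

    # SUMO on the conjugation machinery
    for pool, leads in (("e1", ("SAE1", "UBA2")), ("e2", ("UBC9",)),
                        ("e3", ("E3L1", "E3L2"))):
        share = config.pool_fractions[pool] * total_budget / len(leads)
        for lead in leads:
            peptide, pep_pos = _site_peptide(proteins[lead], 41)
            loc = float(np.clip(rng.normal(30, 10), 6.5, None))
            inventory.append(
                (pool, peptide, (Modification("sumo", pep_pos, loc),), lead, share)
            )

    # free mature SUMO: predominantly DVFQQQTGG (several charge states /
    # evidence entries), plus a minor longer QQTGG-terminated peptide
    free_total = config.pool_fractions["free_mature"] * total_budget
    for _ in range(5):
        inventory.append(
            ("free_mature", "DVFQQQTGG", (), "SUMO2", free_total * 0.9 / 5)
        )
    inventory.append(("free_mature", "TIDVFQQQTGG", (), "SUMO2", free_total * 0.1))
    # immature precursors
    inventory.append(
        ("immature_sumo2", constants.immature_sumo2[0], (), "SUMO2",
         config.pool_fractions["immature_sumo2"] * total_budget)
    )
    inventory.append(
        ("immature_sumo3", constants.immature_sumo3[0], (), "SUMO3",
         config.pool_fractions["immature_sumo3"] * total_budget)
    )
    # internal SUMO peptides: excluded from quantification by definition
    inventory.append(
        ("internal_excluded", "DGSVVQFKIKRHTPLSK", (), "SUMO2",
         0.05 * total_budget)
    )

    truth_fractions = dict(config.pool_fractions)

    # --- emit per-sample rows with replicate noise
    for sample_id, condition, replicate in design.samples:
        noise = _lognormal_noise(rng, config.intensity_cv, size=len(inventory))
        for (pool, peptide, mods, lead, b), eps in zip(inventory, noise):
            intensity: Optional[float] = b * eps
            if config.missing_rate > 0:
                # low intensities go missing preferentially
                logit = (config.base_log2_mean - math.log2(intensity)) / 2.0
                p_missing = config.missing_rate * 2.0 / (1.0 + math.exp(-logit))
                if rng.random() < min(p_missing, 0.95):
                    intensity = None
            factory.add(
                pool, sample_id, condition, replicate, peptide, mods, lead,
                intensity,
            )

    # --- decoys and sub-threshold rows (dropped by the filter ledger)
    n_decoy = int(round(config.decoy_rate * len(site_plan)))
    n_low = int(round(config.low_score_rate * len(site_plan)))
    sample0 = design.samples[0]
    for k in range(n_decoy):
        pid, pos, _ = site_plan[k % len(site_plan)]
        peptide, pep_pos = _site_peptide(proteins[pid], pos)
        factory.add(
            None, sample0[0], sample0[1], sample0[2], peptide[::-1],
            (Modification("sumo", len(peptide) - pep_pos + 1, 20.0),),
            f"REV__{pid}", 2.0 ** config.base_log2_mean, reverse=True,
        )
    for k in range(n_low):
        pid, pos, _ = site_plan[(k + 7) % len(site_plan)]
        peptide, pep_pos = _site_peptide(proteins[pid], pos)
        factory.add(
            None, sample0[0], sample0[1], sample0[2], peptide,
            (Modification("sumo", pep_pos, 15.0),), pid,
            2.0 ** config.base_log2_mean,
            andromeda=float(rng.uniform(10, 35)), delta=float(rng.uniform(2, 15)),
        )

    # --- SUMO-phospho co-modified rows
    n_comod = int(round(config.comod_rate * len(site_plan)))
    for k in range(n_comod):
        pid, pos, _ = site_plan[(3 * k) % len(site_plan)]
        peptide, pep_pos = _site_peptide(proteins[pid], pos)
        sty = [i + 1 for i, aa in enumerate(peptide)
               if aa in "STY" and i + 1 != pep_pos]
        if not sty:
            continue
        ppos = int(sty[int(rng.integers(len(sty)))])
        factory.add(
            None, sample0[0], sample0[1], sample0[2], peptide,
            (
                Modification("sumo", pep_pos, float(rng.uniform(8, 40))),
                Modification("phospho", ppos, float(rng.uniform(8, 40))),
            ),
            pid, 2.0 ** config.base_log2_mean,
            delta=float(rng.uniform(46, 90)),
        )

    # --- planted single-rule violations, for auditing the filter ledger.
    # Each planted row lives on its own spare protein so its window never
    # collides with baseline evidence; every row passes all rules preceding
    # the one it violates, so attribution is exact.
    violations = dict(config.planted_violations)
    spares = iter(sorted(p for p in proteins if p.startswith("SPARE")))
    for rule, count in sorted(violations.items()):
        for _ in range(count):
            pid = next(spares)
            peptide, pep_pos = _site_peptide(proteins[pid], 60)
            mods = (Modification("sumo", pep_pos, 25.0),)
            kw: Dict = {}
            if rule == "reverse":
                kw["reverse"] = True
            elif rule == "length":
                peptide, mods = "AAKAGA", (Modification("sumo", 3, 25.0),)
            elif rule == "mass":
                # ~7.4 kDa before the remnant: over the 6 kDa Asp-N limit
                peptide, mods = "K" + "W" * 39, (Modification("sumo", 1, 25.0),)
            elif rule == "score":
                kw["andromeda"] = 30.0
            elif rule == "delta_multi":
                sty = [i + 1 for i, aa in enumerate(peptide)
                       if aa in "STY" and i + 1 != pep_pos]
                ppos = sty[0] if sty else (1 if pep_pos != 1 else 2)
                kind = "phospho" if sty else "other"
                mods = mods + (Modification(kind, ppos, 25.0),)
                kw["delta"] = 35.0
            elif rule == "loc":
                mods = (Modification("sumo", pep_pos, 5.0),)
            elif rule == "diagnostic":
                kw["has_diagnostic_ions"] = False
            elif rule == "cterm":
                peptide = peptide[:pep_pos]
                if len(peptide) < 7:
                    peptide = ("A" * (7 - len(peptide))) + peptide
                mods = (Modification("sumo", len(peptide), 25.0),)
                kw["protease"] = "trypsin"
            elif rule == "duplicate":
                row = factory.add(
                    None, sample0[0], sample0[1], sample0[2], peptide, mods,
                    pid, 2.0 ** config.base_log2_mean,
                )
                # the same MS/MS scan assigned twice: one row must go
                dup = replace(row, delta_score=row.delta_score - 1.0)
                factory.rows.append(dup)
                continue
            else:
                raise ValueError(f"unknown filter rule {rule!r}")
            factory.add(
                None, sample0[0], sample0[1], sample0[2], peptide, mods, pid,
                2.0 ** config.base_log2_mean, **kw,
            )

    realized = (
        sum(1 for _, _, kxe in site_plan if kxe) / len(site_plan)
        if site_plan else 0.0
    )
    truth = GroundTruth(
        sites=list(site_plan),
        realized_adherence=realized,
        pool_fractions=truth_fractions,
        chain_profile={k: dict(v) for k, v in config.chain_profile.items()},
        row_pools=factory.row_pools,
        planted_violations=violations,
    )
    return factory.rows, design, truth


# ---------------------------------------------------------------------------
# MSA generation with a planted conservation offset


def _column_for_target(
    rng: np.random.Generator,
    consensus: str,
    n_rows: int,
    target: float,
    params: TridentParams,
) -> List[str]:
    """A column whose trident score is as close as possible to ``target``.

    Row 0 (the reference) always carries the consensus residue; the
    remaining rows carry either the consensus or decoy residues drawn once
    per column.  The number of consensus rows is chosen by scanning all
    counts for the best match (uniform weights).
    """
    decoys = [str(a) for a in rng.choice(list(AMINO_ACIDS.replace(consensus, "")),
                                         size=n_rows - 1)]
    best: Tuple[float, List[str]] = (float("inf"), [consensus] * n_rows)
    for k in range(1, n_rows + 1):
        column = [consensus] * k + decoys[: n_rows - k]
        score = 100.0 * trident_column_score(column, None, params)
        gap = abs(score - target)
        if gap < best[0]:
            best = (gap, column)
    column = best[1]
    # reference stays consensus; shuffle the rest deterministically
    tail = column[1:]
    rng.shuffle(tail)
    return [column[0]] + list(tail)


def generate_msa_set(
    config: GeneratorConfig,
    params: TridentParams = TridentParams(),
) -> Tuple[Dict[str, MSAProfile], GroundTruth]:
    """Ortholog alignments with a planted RCS deficit at SUMOylated lysines.

    Every protein gets ``msa_lysines_per_protein`` lysine columns whose
    target RCS is drawn from Normal(base mean, base sd); the SUMOylated
    subset is targeted ``msa_rcs_offset`` points lower.  Structural classes
    (disordered / globular-exposed / globular-buried) are assigned uniformly
    at random per lysine.  Column construction is calibrated against the
    trident score with uniform weights.
    """
    rng = np.random.default_rng(config.seed + 4)
    msas: Dict[str, MSAProfile] = {}
    sumo_lysines: List[Tuple[str, int]] = []
    lysine_classes: Dict[Tuple[str, int], str] = {}
    classes = ("disordered", "globular_exposed", "globular_buried")
    n = config.msa_n_orthologs
    length = config.msa_protein_length

    for p in range(config.msa_n_proteins):
        pid = f"OG{p:03d}"
        positions = sorted(
            rng.choice(
                np.arange(2, length - 2), size=config.msa_lysines_per_protein,
                replace=False,
            ).tolist()
        )
        sumo_set = set(
            rng.choice(positions, size=config.msa_sumo_per_protein, replace=False)
            .tolist()
        )
        columns: List[List[str]] = []
        for j in range(length):
            if j in positions:
                base = float(rng.normal(config.msa_base_rcs_mean,
                                        config.msa_base_rcs_sd))
                target = base - (config.msa_rcs_offset if j in sumo_set else 0.0)
                target = float(np.clip(target, 5.0, 99.0))
                columns.append(_column_for_target(rng, "K", n, target, params))
            else:
                consensus = str(rng.choice(list(_BACKBONE)))
                target = float(rng.uniform(30, 95))
                columns.append(
                    _column_for_target(rng, consensus, n, target, params)
                )
        rows = ["".join(col[i] for col in columns) for i in range(n)]
        msas[pid] = MSAProfile(sequences=tuple(rows), reference_row=0, name=pid)
        for j in positions:
            key = (pid, j + 1)  # 1-based reference positions (row 0 ungapped)
            lysine_classes[key] = str(rng.choice(classes))
            if j in sumo_set:
                sumo_lysines.append(key)

    truth = GroundTruth(
        sites=[],
        realized_adherence=float("nan"),
        pool_fractions={},
        chain_profile={},
        msa_offset=-config.msa_rcs_offset,
        sumo_lysines=sumo_lysines,
        lysine_classes=lysine_classes,
    )
    return msas, truth


# ---------------------------------------------------------------------------
# quantification matrices for differential-test calibration


def generate_null_matrix(
    n_entities: int, design: StudyDesign, seed: int = 0
) -> "pd.DataFrame":
    """Log2 intensity matrix with no true differences (standard normal)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    data = rng.normal(20.0, 1.0, size=(n_entities, len(design.samples)))
    return pd.DataFrame(
        data,
        index=[f"site{i:05d}" for i in range(n_entities)],
        columns=design.sample_ids,
    )


def generate_shifted_matrix(
    n_entities: int,
    design: StudyDesign,
    shifted_condition: str,
    fraction_shifted: float = 0.05,
    effect_sd: float = 4.0,
    seed: int = 0,
) -> Tuple["pd.DataFrame", List[str]]:
    """Null matrix plus a ``effect_sd``-sigma shift in a subset of entities.

    Returns the matrix and the ids of the truly shifted entities.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    frame = generate_null_matrix(n_entities, design, seed)
    n_shift = int(round(fraction_shifted * n_entities))
    shifted = list(frame.index[:n_shift])
    cols = design.samples_of(shifted_condition)
    frame.loc[shifted, cols] += effect_sd * 1.0
    return frame, shifted


# ---------------------------------------------------------------------------
# full simulated-study emission


def generate_annotations(
    config: GeneratorConfig, proteins: Mapping[str, str],
    target_ids: Sequence[str],
) -> Dict[str, set]:
    """Random protein -> term annotations with one planted enriched term.

    The term ``planted_nuclear`` covers 60% of SUMO target proteins but only
    15% of the rest, so enrichment analysis has a true positive to find;
    terms ``T00``..``T09`` are assigned uniformly at random.
    """
    rng = np.random.default_rng(config.seed + 5)
    targets = set(target_ids)
    annotations: Dict[str, set] = {}
    for pid in sorted(proteins):
        terms = {f"T{int(t):02d}" for t in rng.choice(10, size=2, replace=False)}
        p = 0.6 if pid in targets else 0.15
        if rng.random() < p:
            terms.add("planted_nuclear")
        annotations[pid] = terms
    return annotations


def write_simulation(config: GeneratorConfig, outdir) -> None:
    """Emit a complete simulated study directory.

    Writes proteome.fasta, evidence.tsv, design.tsv, annotations.tsv,
    ground_truth.tsv and msa/*.fasta under ``outdir``.
    """
    from pathlib import Path

    import pandas as pd

    from .evidence import write_design, write_evidence, write_fasta

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    proteome = generate_proteome(config)
    proteins, site_plan = proteome
    rows, design, truth = generate_evidence(config, proteome)
    write_fasta(proteins, out / "proteome.fasta")
    write_evidence(rows, out / "evidence.tsv")
    write_design(design, out / "design.tsv")

    target_ids = sorted({pid for pid, _, _ in site_plan})
    annotations = generate_annotations(config, proteins, target_ids)
    pd.DataFrame(
        [(pid, term) for pid, terms in annotations.items()
         for term in sorted(terms)],
        columns=["entity", "term"],
    ).to_csv(out / "annotations.tsv", sep="\t", index=False)

    pd.DataFrame(
        [(pid, pos, "+" if kxe else "") for pid, pos, kxe in truth.sites],
        columns=["protein", "position", "kxe"],
    ).to_csv(out / "ground_truth.tsv", sep="\t", index=False)

    msas, msa_truth = generate_msa_set(config)
    msa_dir = out / "msa"
    msa_dir.mkdir(exist_ok=True)
    for name, msa in sorted(msas.items()):
        with open(msa_dir / f"{name}.fasta", "w") as fh:
            for i, seq in enumerate(msa.sequences):
                fh.write(f">{name}_{'ref' if i == 0 else f'ortho{i:02d}'}\n")
                fh.write(seq + "\n")
    pd.DataFrame(
        [
            (pid, pos, cls,
             "+" if (pid, pos) in set(msa_truth.sumo_lysines) else "")
            for (pid, pos), cls in sorted(msa_truth.lysine_classes.items())
        ],
        columns=["protein", "position", "structural_class", "sumoylated"],
    ).to_csv(out / "msa_lysines.tsv", sep="\t", index=False)
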