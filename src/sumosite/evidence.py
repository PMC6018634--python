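"""Domain model and TSV readers/writers for MaxQuant-dialect tables.

The pipeline consumes a simplified dialect of MaxQuant's ``evidence.txt``:
one row per identified (possibly modified) peptide per sample, with
Andromeda/delta scores, a decoy flag, MS/MS scan ids and an LFQ intensity.
Modifications are encoded in a single column as
``kind@position:localization_delta`` entries separated by ``;`` (positions
are 1-based within the peptide), e.g. ``sumo@3:45.2;phospho@7:12.1``.

Intensity semantics follow MaxQuant: a zero or empty cell means "not
quantified" and is represented as ``None``.  Unrecognized columns are
preserved opaquely and written back on round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "Modification",
    "EvidenceRow",
    "SiteRecord",
    "ProteinGroupRecord",
    "StudyDesign",
    "SchemaError",
    "read_design",
    "write_design",
    "read_evidence",
    "write_evidence",
    "read_site_table",
    "write_site_table",
    "read_protein_groups",
    "write_protein_groups",
    "read_fasta",
    "write_fasta",
    "assemble_sites",
    "extract_window",
    "WINDOW_FLANK",
    "WINDOW_PAD",
]

WINDOW_FLANK = 25  #: residues either side of the modified lysine
WINDOW_PAD = "_"  #: padding character at protein termini


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


@dataclass(frozen=True)
class Modification:
    kind: str  # sumo | phospho | other
    position: int  # 1-based within the peptide
    loc_delta: float

    def encode(self) -> str:
        return f"{self.kind}@{self.position}:{self.loc_delta:g}"


def _parse_modifications(text: str, line: object = "?") -> Tuple[Modification, ...]:
    if not text or (isinstance(text, float) and pd.isna(text)):
        return ()
    mods = []
    for chunk in str(text).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            kind, rest = chunk.split("@", 1)
            pos, loc = rest.split(":", 1)
            mods.append(Modification(kind.strip(), int(pos), float(loc)))
        except ValueError:
            raise SchemaError(
                f"line {line}: unparseable modification entry {chunk!r}"
            ) from None
    return tuple(mods)


@dataclass(frozen=True)
class EvidenceRow:
    """One identified peptide in one sample."""

    peptide_sequence: str
    modifications: Tuple[Modification, ...]
    protein_ids: Tuple[str, ...]
    leading_protein: str
    andromeda_score: float
    delta_score: float
    reverse: bool
    msms_scan_ids: Tuple[int, ...]
    identification_type: str  # msms | matched
    sample_id: str
    condition: str
    replicate: int
    intensity: Optional[float]
    protease: str
    has_diagnostic_ions: bool = True
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mod in self.modifications:
            if not 1 <= mod.position <= len(self.peptide_sequence):
                raise ValueError(
                    f"modification position {mod.position} outside peptide "
                    f"{self.peptide_sequence!r}"
                )
        if self.intensity is not None and self.intensity < 0:
            raise ValueError("negative intensity")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    def mods_of(self, kind: str) -> Tuple[Modification, ...]:
        return tuple(m for m in self.modifications if m.kind == kind)

    @property
    def sumo_mods(self) -> Tuple[Modification, ...]:
        return self.mods_of("sumo")

    @property
    def is_sumo_modified(self) -> bool:
        return bool(self.sumo_mods)


@dataclass(frozen=True)
class StudyDesign:
    """Sample -> (condition, replicate) bookkeeping."""

    samples: Tuple[Tuple[str, str, int], ...]

    def __post_init__(self) -> None:
        ids = [s[0] for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in design")

    @property
    def conditions(self) -> List[str]:
        seen: Dict[str, None] = {}
        for _, cond, _ in self.samples:
            seen.setdefault(cond, None)
        return list(seen)

    @property
    def sample_ids(self) -> List[str]:
        return [s[0] for s in self.samples]

    def lookup(self, sample_id: str) -> Tuple[str, int]:
        for sid, cond, rep in self.samples:
            if sid == sample_id:
                return cond, rep
        raise KeyError(f"unknown sample id {sample_id!r}")

    def samples_of(self, condition: str) -> List[str]:
        return [s for s, c, _ in self.samples if c == condition]


def read_design(path: str | Path) -> StudyDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "condition", "replicate"):
        if col not in df.columns:
            raise SchemaError(f"design table lacks required column {col!r}")
    return StudyDesign(
        tuple(
            (row["sample"], row["condition"], int(row["replicate"]))
            for _, row in df.iterrows()
        )
    )


def write_design(design: StudyDesign, path: str | Path) -> None:
    pd.DataFrame(
        list(design.samples), columns=["sample", "condition", "replicate"]
    ).to_csv(path, sep="\t", index=False)


_EVIDENCE_COLUMNS = {
    "Sequence": "peptide_sequence",
    "Modifications": "modifications",
    "Proteins": "protein_ids",
    "Leading razor protein": "leading_protein",
    "Score": "andromeda_score",
    "Delta score": "delta_score",
    "Reverse": "reverse",
    "MS/MS scan number": "msms_scan_ids",
    "Type": "identification_type",
    "Experiment": "sample_id",
    "Intensity": "intensity",
    "Protease": "protease",
    "Diagnostic ions": "has_diagnostic_ions",
}


def _opt_float(cell) -> Optional[float]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return None
    value = float(cell)
    return None if value == 0 else value  # MaxQuant: 0 intensity == missing


def read_evidence(path: str | Path, design: StudyDesign) -> List[EvidenceRow]:
    """Read an evidence TSV, resolving sample labels against ``design``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"evidence table lacks required column(s) {missing}")
    extra_cols = [c for c in df.columns if c not in _EVIDENCE_COLUMNS]
    rows: List[EvidenceRow] = []
    for i, rec in enumerate(df.to_dict("records"), start=2):  # 1 = header line
        sample_id = rec["Experiment"]
        condition, replicate = design.lookup(sample_id)
        scans = tuple(
            int(s) for s in str(rec["MS/MS scan number"]).split(";") if s.strip()
        )
        rows.append(
            EvidenceRow(
                peptide_sequence=rec["Sequence"],
                modifications=_parse_modifications(rec["Modifications"], line=i),
                protein_ids=tuple(
                    p for p in rec["Proteins"].split(";") if p.strip()
                ),
                leading_protein=rec["Leading razor protein"],
                andromeda_score=float(rec["Score"]),
                delta_score=float(rec["Delta score"]),
                reverse=rec["Reverse"].strip() == "+",
                msms_scan_ids=scans,
                identification_type=(
                    "msms" if rec["Type"].upper().endswith("MSMS") else "matched"
                ),
                sample_id=sample_id,
                condition=condition,
                replicate=replicate,
                intensity=_opt_float(rec["Intensity"]),
                protease=rec["Protease"],
                has_diagnostic_ions=rec["Diagnostic ions"].strip() == "+",
                extra={c: rec[c] for c in extra_cols},
            )
        )
    return rows


def write_evidence(rows: Sequence[EvidenceRow], path: str | Path) -> None:
    extra_cols: Dict[str, None] = {}
    for row in rows:
        for c in row.extra:
            extra_cols.setdefault(c, None)
    records = []
    for row in rows:
        rec = {
            "Sequence": row.peptide_sequence,
            "Modifications": ";".join(m.encode() for m in row.modifications),
            "Proteins": ";".join(row.protein_ids),
            "Leading razor protein": row.leading_protein,
            "Score": f"{row.andromeda_score:g}",
            "Delta score": f"{row.delta_score:g}",
            "Reverse": "+" if row.reverse else "",
            "MS/MS scan number": ";".join(str(s) for s in row.msms_scan_ids),
            "Type": "MULTI-MSMS" if row.identification_type == "msms" else "MATCH",
            "Experiment": row.sample_id,
            "Intensity": "" if row.intensity is None else f"{row.intensity:.10g}",
            "Protease": row.protease,
            "Diagnostic ions": "+" if row.has_diagnostic_ions else "",
        }
        for c in extra_cols:
            rec[c] = row.extra.get(c, "")
        records.append(rec)
    columns = list(_EVIDENCE_COLUMNS) + list(extra_cols)
    pd.DataFrame(records, columns=columns).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SiteRecord:
    """One SUMO-modified lysine mapped to protein coordinates."""

    protein_id: str
    site_position: int  # 1-based in the protein
    window: str  # 51-mer, '_'-padded at termini
    best_andromeda: float
    best_delta: float
    best_loc_delta: float
    msms_count: int
    intensities: Mapping[str, Optional[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.window) != 2 * WINDOW_FLANK + 1:
            raise ValueError(
                f"window must be {2 * WINDOW_FLANK + 1} residues, "
                f"got {len(self.window)}"
            )
        if self.msms_count < 0:
            raise ValueError("negative msms_count")


@dataclass(frozen=True)
class ProteinGroupRecord:
    protein_ids: Tuple[str, ...]
    gene_name: str
    peptide_count: int
    intensities: Mapping[str, Optional[float]] = field(default_factory=dict)
    is_sumo_target: bool = False

    def __post_init__(self) -> None:
        if self.peptide_count < 1:
            raise ValueError("peptide_count must be >= 1")


def _intensity_columns(records) -> List[str]:
    samples: Dict[str, None] = {}
    for rec in records:
        for s in rec.intensities:
            samples.setdefault(s, None)
    return list(samples)


def write_site_table(sites: Sequence[SiteRecord], path: str | Path) -> None:
    samples = _intensity_columns(sites)
    rows = []
    for s in sites:
        rec = {
            "Protein": s.protein_id,
            "Position": s.site_position,
            "Sequence window": s.window,
            "Score": f"{s.best_andromeda:g}",
            "Delta score": f"{s.best_delta:g}",
            "Localization delta": f"{s.best_loc_delta:g}",
            "MS/MS count": s.msms_count,
        }
        for sample in samples:
            v = s.intensities.get(sample)
            rec[f"Intensity {sample}"] = "" if v is None else f"{v:.10g}"
        rows.append(rec)
    columns = [
        "Protein", "Position", "Sequence window", "Score", "Delta score",
        "Localization delta", "MS/MS count",
    ] + [f"Intensity {s}" for s in samples]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> List[SiteRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [
        "Protein", "Position", "Sequence window", "Score", "Delta score",
        "Localization delta", "MS/MS count",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"site table lacks required column(s) {missing}")
    sample_cols = [c for c in df.columns if c.startswith("Intensity ")]
    sites = []
    for rec in df.to_dict("records"):
        sites.append(
            SiteRecord(
                protein_id=rec["Protein"],
                site_position=int(rec["Position"]),
                window=rec["Sequence window"],
                best_andromeda=float(rec["Score"]),
                best_delta=float(rec["Delta score"]),
                best_loc_delta=float(rec["Localization delta"]),
                msms_count=int(rec["MS/MS count"]),
                intensities={
                    c[len("Intensity "):]: _opt_float(rec[c]) for c in sample_cols
                },
            )
        )
    return sites


def write_protein_groups(groups: Sequence[ProteinGroupRecord], path: str | Path) -> None:
    samples = _intensity_columns(groups)
    rows = []
    for g in groups:
        rec = {
            "Protein IDs": ";".join(g.protein_ids),
            "Gene names": g.gene_name,
            "Peptides": g.peptide_count,
            "SUMO target": "+" if g.is_sumo_target else "",
        }
        for sample in samples:
            v = g.intensities.get(sample)
            rec[f"Intensity {sample}"] = "" if v is None else f"{v:.10g}"
        rows.append(rec)
    columns = ["Protein IDs", "Gene names", "Peptides", "SUMO target"] + [
        f"Intensity {s}" for s in samples
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_protein_groups(path: str | Path) -> List[ProteinGroupRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["Protein IDs", "Gene names", "Peptides", "SUMO target"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"proteinGroups table lacks required column(s) {missing}")
    sample_cols = [c for c in df.columns if c.startswith("Intensity ")]
    return [
        ProteinGroupRecord(
            protein_ids=tuple(rec["Protein IDs"].split(";")),
            gene_name=rec["Gene names"],
            peptide_count=int(rec["Peptides"]),
            intensities={
                c[len("Intensity "):]: _opt_float(rec[c]) for c in sample_cols
            },
            is_sumo_target=rec["SUMO target"].strip() == "+",
        )
        for rec in df.to_dict("records")
    ]


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Protein id -> sequence (first whitespace-delimited token as id)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(proteins: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def extract_window(protein_seq: str, position: int, flank: int = WINDOW_FLANK) -> str:
    """±``flank`` residue window centred on 1-based ``position``, '_'-padded."""
    if not 1 <= position <= len(protein_seq):
        raise ValueError(f"position {position} outside protein of length {len(protein_seq)}")
    i = position - 1
    left = protein_seq[max(0, i - flank):i]
    right = protein_seq[i + 1:i + 1 + flank]
    return (
        WINDOW_PAD * (flank - len(left)) + left + protein_seq[i]
        + right + WINDOW_PAD * (flank - len(right))
    )


def assemble_sites(
    rows: Sequence[EvidenceRow], proteins: Mapping[str, str]
) -> List[SiteRecord]:
    """Map SUMO-modified peptides back to protein coordinates.

    Rows are grouped by (leading protein, protein site position); per-site
    scores are maxima over supporting rows, MS/MS counts tally rows with
    direct fragmentation evidence, and intensities are summed per sample.
    Duplicate rows therefore collapse onto one site.
    """
    buckets: Dict[Tuple[str, int], Dict] = {}
    for row in rows:
        if not row.sumo_mods:
            continue
        protein = row.leading_protein
        if protein not in proteins:
            raise KeyError(f"leading protein {protein!r} absent from FASTA")
        seq = proteins[protein]
        offset = seq.find(row.peptide_sequence)
        if offset == -1:
            raise ValueError(
                f"peptide {row.peptide_sequence!r} not found in protein {protein!r}"
            )
        for mod in row.sumo_mods:
            site_pos = offset + mod.position  # 1-based protein coordinate
            key = (protein, site_pos)
            bucket = buckets.setdefault(
                key,
                {
                    "andromeda": row.andromeda_score,
                    "delta": row.delta_score,
                    "loc": mod.loc_delta,
                    "msms": 0,
                    "intensities": {},
                },
            )
            bucket["andromeda"] = max(bucket["andromeda"], row.andromeda_score)
            bucket["delta"] = max(bucket["delta"], row.delta_score)
            bucket["loc"] = max(bucket["loc"], mod.loc_delta)
            if row.identification_type == "msms":
                bucket["msms"] += 1
            if row.intensity is not None:
                prev = bucket["intensities"].get(row.sample_id)
                bucket["intensities"][row.sample_id] = (
                    row.intensity if prev is None else prev + row.intensity
                )
    sites = []
    for (protein, pos), b in sorted(buckets.items()):
        sites.append(
            SiteRecord(
                protein_id=protein,
                site_position=pos,
                window=extract_window(proteins[protein], pos),
                best_andromeda=b["andromeda"],
                best_delta=b["delta"],
                best_loc_delta=b["loc"],
                msms_count=b["msms"],
                intensities=b["intensities"],
            )
        )
    return sites
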