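"""Shared fixtures: a miniature study that exercises every pipeline stage."""

from __future__ import annotations

import pytest

from sumosite.evidence import EvidenceRow, Modification, StudyDesign


@pytest.fixture(scope="session")
def design3() -> StudyDesign:
    return StudyDesign(
        (
            ("control_r1", "control", 1),
            ("control_r2", "control", 2),
            ("control_r3", "control", 3),
            ("heat_r1", "heat", 1),
            ("heat_r2", "heat", 2),
            ("heat_r3", "heat", 3),
        )
    )


@pytest.fixture
def tiny_proteins() -> dict:
    # P1 has K at position 12 (0-based 11) with E at +2 (KxE), K at 30;
    # P2 has K at 5 followed by D (Asp-N C-terminal-K case)
    p1 = "MASTDLGHWRFAKLEQPDNVITYWGHLFAKDSPQRLVNEW"
    p2 = "AQWLKDSTRGHPLMNEYFVA"
    assert p1[12] == "K" and p1[14] == "E"
    return {"P1": p1, "P2": p2}


def make_row(
    peptide="DLGHWRFAKLEQPDNVITYWGHLFA",
    mods=(Modification("sumo", 9, 30.0),),
    protein="P1",
    andromeda=120.0,
    delta=60.0,
    reverse=False,
    scans=(1,),
    id_type="msms",
    sample="control_r1",
    condition="control",
    replicate=1,
    intensity=1e6,
    protease="aspn",
    diagnostic=True,
) -> EvidenceRow:
    return EvidenceRow(
        peptide_sequence=peptide,
        modifications=tuple(mods),
        protein_ids=(protein,),
        leading_protein=protein,
        andromeda_score=andromeda,
        delta_score=delta,
        reverse=reverse,
        msms_scan_ids=tuple(scans),
        identification_type=id_type,
        sample_id=sample,
        condition=condition,
        replicate=replicate,
        intensity=intensity,
        protease=protease,
        has_diagnostic_ions=diagnostic,
    )


@pytest.fixture
def row_factory():
    return make_row
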