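"""Consensus-motif adherence and annotation-term enrichment statistics.

The canonical SUMO acceptor motif is KxE: the modified lysine followed, one
residue on, by glutamate (KxD is the weaker aspartate variant).  The
inverted motif places E/D two residues before the lysine; in mouse tissue
the inverted motif followed by a proline ([ED]xKP) is specifically enriched.
Motif classes are read off the 51-residue sequence window centred on the
modified lysine (flank positions -25..+25).

Term enrichment is the Perseus-style two-tailed Fisher exact test with
Benjamini-Hochberg correction; for visualization-grade ranking of enriched
terms the relative score (log2(enrichment)^3 x -log10(P))^0.25, batch
normalized so the best term scores 100, is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .evidence import SiteRecord, WINDOW_FLANK

__all__ = [
    "MotifCall",
    "EnrichmentRow",
    "motif_class",
    "kxe_adherence",
    "fisher_enrichment",
    "relative_score",
    "positional_enrichment",
]


@dataclass(frozen=True)
class MotifCall:
    window: str
    classes: frozenset  # subset of {"KxE","KxD","inverted_ExK","ED_x_K_P"}
    intensity_weight: Optional[float] = None

    @property
    def is_kxe(self) -> bool:
        return "KxE" in self.classes


def _flank(window: str, offset: int) -> Optional[str]:
    """Residue at signed ``offset`` from the central lysine, None if padded."""
    i = WINDOW_FLANK + offset
    if not 0 <= i < len(window):
        return None
    aa = window[i]
    return None if aa == "_" else aa


def motif_class(window: str) -> MotifCall:
    """Classify the SUMO consensus context of a 51-mer window.

    Classes are not mutually exclusive; a window matching none of them gets
    an empty class set.
    """
    if len(window) != 2 * WINDOW_FLANK + 1:
        raise ValueError(
            f"window must be {2 * WINDOW_FLANK + 1} residues, got {len(window)}"
        )
    classes = set()
    if _flank(window, +2) == "E":
        classes.add("KxE")
    if _flank(window, +2) == "D":
        classes.add("KxD")
    if _flank(window, -2) in ("E", "D"):
        classes.add("inverted_ExK")
        if _flank(window, +1) == "P":
            classes.add("ED_x_K_P")
    return MotifCall(window=window, classes=frozenset(classes))


def kxe_adherence(
    sites: Sequence[SiteRecord],
    intensities: Optional[Mapping[Tuple[str, int], float]] = None,
) -> Tuple[float, float]:
    """(site fraction, intensity fraction) of sites in the KxE motif.

    The site fraction counts KxE windows among all sites; the intensity
    fraction weights each site by its total intensity (summed over samples
    unless ``intensities`` supplies one number per (protein, position)).
    Sites with no intensity are excluded from the intensity ratio only.
    """
    if not sites:
        raise ValueError("no sites given")
    n_kxe = 0
    total_int = 0.0
    kxe_int = 0.0
    for site in sites:
        call = motif_class(site.window)
        if intensities is not None:
            weight = intensities.get((site.protein_id, site.site_position))
        else:
            observed = [v for v in site.intensities.values() if v is not None]
            weight = sum(observed) if observed else None
        if call.is_kxe:
            n_kxe += 1
        if weight is not None:
            total_int += weight
            if call.is_kxe:
                kxe_int += weight
    site_fraction = n_kxe / len(sites)
    intensity_fraction = kxe_int / total_int if total_int > 0 else float("nan")
    return site_fraction, intensity_fraction


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    category: str
    fg_hits: int
    fg_size: int
    bg_hits: int
    bg_size: int
    p: float
    fdr: float
    enrichment: float
    relative_score: Optional[float] = None


def fisher_enrichment(
    fg: Set[str],
    bg: Set[str],
    annotations: Mapping[str, Set[str]],
    fdr_cutoff: float = 0.02,
    categories: Optional[Mapping[str, str]] = None,
) -> List[EnrichmentRow]:
    """Two-tailed Fisher term enrichment of ``fg`` against ``bg``.

    Per term the 2x2 table is foreground hit/miss vs background-minus-
    foreground hit/miss.  P-values are BH-corrected over all tested terms;
    rows passing ``fdr < fdr_cutoff`` are returned sorted by relative score
    (enriched terms) then P.  Depleted terms (enrichment <= 1) carry no
    relative score.
    """
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    terms: Dict[str, Tuple[int, int]] = {}
    all_terms = sorted({t for e in bg for t in annotations.get(e, ())})
    fg_size, bg_size = len(fg), len(bg)
    rest = bg - fg
    results = []
    for term in all_terms:
        fg_hits = sum(1 for e in fg if term in annotations.get(e, ()))
        rest_hits = sum(1 for e in rest if term in annotations.get(e, ()))
        bg_hits = fg_hits + rest_hits
        table = [
            [fg_hits, fg_size - fg_hits],
            [rest_hits, len(rest) - rest_hits],
        ]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        fg_rate = fg_hits / fg_size if fg_size else 0.0
        bg_rate = bg_hits / bg_size if bg_size else 0.0
        enr = fg_rate / bg_rate if bg_rate > 0 else math.inf
        results.append((term, fg_hits, bg_hits, float(p), enr))
    if not results:
        return []
    pvals = [r[3] for r in results]
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")

    rows: List[EnrichmentRow] = []
    raw_scores: Dict[str, float] = {}
    for (term, fg_hits, bg_hits, p, enr), fdr in zip(results, fdrs):
        if fdr >= fdr_cutoff:
            continue
        if enr > 1 and 0 < p:
            raw_scores[term] = _raw_relative_score(enr, p)
        rows.append(
            EnrichmentRow(
                term=term,
                category=(categories or {}).get(term, ""),
                fg_hits=fg_hits,
                fg_size=fg_size,
                bg_hits=bg_hits,
                bg_size=bg_size,
                p=p,
                fdr=float(fdr),
                enrichment=enr,
            )
        )
    max_raw = max(raw_scores.values(), default=0.0)
    final = []
    for row in rows:
        score = None
        if row.term in raw_scores and max_raw > 0:
            score = 100.0 * raw_scores[row.term] / max_raw
        final.append(
            EnrichmentRow(**{**row.__dict__, "relative_score": score})
        )
    final.sort(
        key=lambda r: (
            -(r.relative_score if r.relative_score is not None else -1.0),
            r.p,
            r.term,
        )
    )
    return final


def _raw_relative_score(enrichment: float, p: float) -> float:
    if not math.isfinite(enrichment):
        raise ValueError("enrichment must be finite")
    return (math.log2(enrichment) ** 3 * -math.log10(p)) ** 0.25


def relative_score(
    enrichments: Sequence[float], pvalues: Sequence[float]
) -> List[float]:
    """(log2(enrichment)^3 x -log10(P))^0.25, normalized so the max is 100.

    Defined for enriched terms only (enrichment > 1, 0 < P < 1).
    """
    if len(enrichments) != len(pvalues):
        raise ValueError("length mismatch")
    raws = []
    for enr, p in zip(enrichments, pvalues):
        if enr <= 1:
            raise ValueError(f"relative score undefined for enrichment {enr} <= 1")
        if not 0 < p < 1:
            raise ValueError(f"P-value {p} outside (0, 1)")
        raws.append(_raw_relative_score(enr, p))
    top = max(raws)
    return [100.0 * r / top for r in raws]


def positional_enrichment(
    windows: Sequence[str],
    reference_composition: Mapping[str, float],
) -> Dict[int, Dict[str, float]]:
    """Per-position binomial z-scores of residue usage vs a reference.

    An iceLogo-style summary: for each flank position (-25..+25, 0 skipped)
    and residue, z = (observed - n p) / sqrt(n p (1 - p)) with p the
    reference frequency of that residue.  Padded positions are ignored.
    """
    out: Dict[int, Dict[str, float]] = {}
    for offset in range(-WINDOW_FLANK, WINDOW_FLANK + 1):
        if offset == 0:
            continue
        counts: Dict[str, int] = {}
        n = 0
        for window in windows:
            aa = _flank(window, offset)
            if aa is None:
                continue
            counts[aa] = counts.get(aa, 0) + 1
            n += 1
        if n == 0:
            continue
        scores = {}
        for aa, p in reference_composition.items():
            if not 0 < p < 1:
                continue
            observed = counts.get(aa, 0)
            scores[aa] = (observed - n * p) / math.sqrt(n * p * (1 - p))
        out[offset] = scores
    return out
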