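"""Label-free quantification filters and permutation-FDR differential tests.

Mirrors the Perseus-style downstream treatment of MaxQuant LFQ intensities:
detection filtering (an entity must be quantified in enough replicates of at
least one condition; proteins additionally need >= 2 peptides), log2
transform, per-sample median normalization, global imputation of missing
values from a down-shifted normal distribution, and SAM-style moderated
tests with permutation-based FDR.

The moderated two-sample statistic is d = (mean_A - mean_B) / (s + s0),
where s is the pooled standard error and s0 a variance-stabilization
constant (the study ran Perseus with this constant set to 1).  For >= 2
conditions an F-like analogue sqrt(SS_between/(k-1)) / (sqrt(MS_within)+s0)
is used; at s0 = 0 and two conditions it is a monotone transform of |t|, so
both tests rank entities identically there.

q-values are estimated Perseus-style: for a threshold |d|, the expected
number of false positives is the average count of permutation statistics
exceeding it, divided by the observed count, then made monotone.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .evidence import StudyDesign

__all__ = [
    "QuantMatrix",
    "DiffTestResult",
    "RankScore",
    "quant_filter",
    "median_normalize",
    "impute_downshift",
    "perm_two_sample",
    "perm_anova",
    "rank_entities",
    "zscore_rows",
]


@dataclass
class QuantMatrix:
    """Entities x samples intensity matrix (NaN = missing)."""

    values: pd.DataFrame  # index: entity ids, columns: sample ids
    log2_transformed: bool = False
    peptide_counts: Optional[Mapping[str, int]] = None

    def log2(self) -> "QuantMatrix":
        if self.log2_transformed:
            return self
        with np.errstate(divide="ignore", invalid="ignore"):
            logged = np.log2(self.values.where(self.values > 0))
        return QuantMatrix(logged, True, self.peptide_counts)

    @property
    def has_missing(self) -> bool:
        return bool(self.values.isna().any().any())


def quant_filter(
    matrix: QuantMatrix,
    design: StudyDesign,
    min_detected: int,
    min_peptides: int = 0,
) -> QuantMatrix:
    """Keep entities detected in >= ``min_detected`` replicates of >= 1 condition.

    When ``min_peptides`` > 0 the matrix must carry peptide counts and
    entities below the count are removed (the protein-level rule).
    """
    keep = pd.Series(False, index=matrix.values.index)
    for condition in design.conditions:
        cols = [c for c in design.samples_of(condition) if c in matrix.values.columns]
        if not cols:
            continue
        detected = matrix.values[cols].notna().sum(axis=1)
        keep |= detected >= min_detected
    if min_peptides > 0:
        if matrix.peptide_counts is None:
            raise ValueError("min_peptides requires peptide counts on the matrix")
        counts = pd.Series(dict(matrix.peptide_counts)).reindex(matrix.values.index)
        keep &= counts.fillna(0) >= min_peptides
    return QuantMatrix(
        matrix.values.loc[keep], matrix.log2_transformed, matrix.peptide_counts
    )


def median_normalize(matrix: QuantMatrix) -> QuantMatrix:
    """Shift each sample column so its median equals the grand median."""
    if not matrix.log2_transformed:
        raise ValueError("median normalization expects log2-transformed values")
    medians = matrix.values.median(axis=0, skipna=True)
    if medians.isna().any():
        empty = list(medians.index[medians.isna()])
        raise ValueError(f"column(s) entirely missing: {empty}")
    grand = float(np.median(medians))
    shifted = matrix.values.sub(medians - grand, axis=1)
    return QuantMatrix(shifted, True, matrix.peptide_counts)


def impute_downshift(
    matrix: QuantMatrix,
    width: float = 0.3,
    shift: float = 1.8,
    seed: int = 0,
) -> QuantMatrix:
    """Globally impute missing values from a down-shifted normal.

    Missing entries are drawn from Normal(mu - shift*sigma, (width*sigma)^2)
    where mu and sigma are the mean and SD of all observed values in the
    matrix.  Deterministic for a fixed seed.
    """
    values = matrix.values.to_numpy(dtype=float, copy=True)
    mask = np.isnan(values)
    if not mask.any():
        return QuantMatrix(
            matrix.values.copy(), matrix.log2_transformed, matrix.peptide_counts
        )
    observed = values[~mask]
    if observed.size == 0:
        raise ValueError("cannot impute a matrix with no observed values")
    mu, sigma = float(observed.mean()), float(observed.std(ddof=1))
    rng = np.random.default_rng(seed)
    values[mask] = rng.normal(mu - shift * sigma, width * sigma, size=mask.sum())
    out = pd.DataFrame(values, index=matrix.values.index, columns=matrix.values.columns)
    return QuantMatrix(out, matrix.log2_transformed, matrix.peptide_counts)


@dataclass
class DiffTestResult:
    """Per-entity effect, moderated statistic and permutation q-value."""

    table: pd.DataFrame  # columns: effect, statistic, q_value, significant
    fdr: float

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def _two_sample_stat(
    data: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, s0: float
) -> Tuple[np.ndarray, np.ndarray]:
    a, b = data[:, idx_a], data[:, idx_b]
    na, nb = a.shape[1], b.shape[1]
    effect = a.mean(axis=1) - b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    return effect, effect / (se + s0)


def _perm_q_values(
    observed: np.ndarray, perm_stats: np.ndarray, n_perm: int
) -> np.ndarray:
    """Perseus-style permutation q-values on |statistic|."""
    obs = np.abs(observed)
    perm = np.sort(np.abs(perm_stats).ravel())
    order = np.argsort(-obs)
    q = np.empty_like(obs)
    n = len(obs)
    for rank, i in enumerate(order):
        n_obs_ge = rank + 1
        n_perm_ge = len(perm) - np.searchsorted(perm, obs[i], side="left")
        expected_false = n_perm_ge / n_perm
        q[i] = min(1.0, expected_false / n_obs_ge)
    # enforce monotonicity in the ranking statistic (BH-style cumulative
    # minimum taken from the least significant entity upward)
    running = 1.0
    for i in order[::-1]:
        running = min(running, q[i])
        q[i] = running
    return q


def _label_permutations(
    n_samples: int, n_a: int, n_perm: int, rng: np.random.Generator
) -> List[np.ndarray]:
    """Distinct group-A index sets, exhaustively if few enough else sampled.

    The observed labeling and (for equal group sizes) its mirror are
    excluded — they carry the unpermuted signal and would floor the
    attainable q-values.
    """
    from math import comb

    identity = tuple(range(n_a))
    mirror = tuple(range(n_samples - n_a, n_samples))
    skip = {identity, mirror if len(mirror) == n_a else identity}
    total = comb(n_samples, n_a)
    if total - len(skip) <= n_perm:
        return [
            np.array(c)
            for c in combinations(range(n_samples), n_a)
            if c not in skip
        ]
    seen = set(skip)
    perms: List[np.ndarray] = []
    while len(perms) < n_perm:
        pick = tuple(sorted(rng.choice(n_samples, size=n_a, replace=False)))
        if pick not in seen:
            seen.add(pick)
            perms.append(np.array(pick))
    return perms


def perm_two_sample(
    matrix: QuantMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    s0: float = 1.0,
    fdr: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> DiffTestResult:
    """SAM-style moderated two-sample test with permutation FDR."""
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    if matrix.has_missing:
        raise ValueError("matrix contains missing values; impute first")
    cols = list(group_a) + list(group_b)
    data = matrix.values[cols].to_numpy(dtype=float)
    n_a = len(group_a)
    idx_a = np.arange(n_a)
    idx_b = np.arange(n_a, len(cols))
    effect, stat = _two_sample_stat(data, idx_a, idx_b, s0)

    rng = np.random.default_rng(seed)
    perms = _label_permutations(len(cols), n_a, n_perm, rng)
    perm_stats = []
    for pick in perms:
        other = np.setdiff1d(np.arange(len(cols)), pick)
        _, d = _two_sample_stat(data, pick, other, s0)
        perm_stats.append(d)
    q = _perm_q_values(stat, np.array(perm_stats), len(perms))
    table = pd.DataFrame(
        {
            "effect": effect,
            "statistic": stat,
            "q_value": q,
            "significant": q <= fdr,
        },
        index=matrix.values.index,
    )
    return DiffTestResult(table=table, fdr=fdr)


def _anova_stat(
    data: np.ndarray, groups: Sequence[np.ndarray], s0: float
) -> Tuple[np.ndarray, np.ndarray]:
    grand = data.mean(axis=1)
    k = len(groups)
    n_total = data.shape[1]
    ss_between = np.zeros(data.shape[0])
    ss_within = np.zeros(data.shape[0])
    for idx in groups:
        g = data[:, idx]
        gm = g.mean(axis=1)
        ss_between += len(idx) * (gm - grand) ** 2
        ss_within += ((g - gm[:, None]) ** 2).sum(axis=1)
    ms_within = ss_within / (n_total - k)
    effect = ss_between / (k - 1)  # F numerator (between-group mean square)
    stat = np.sqrt(effect) / (np.sqrt(ms_within) + s0)
    return effect, stat


def perm_anova(
    matrix: QuantMatrix,
    design: StudyDesign,
    s0: float = 1.0,
    fdr: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> DiffTestResult:
    """Multi-condition moderated F-like test with permutation FDR."""
    conditions = [
        c for c in design.conditions
        if any(s in matrix.values.columns for s in design.samples_of(c))
    ]
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions")
    if matrix.has_missing:
        raise ValueError("matrix contains missing values; impute first")
    cols: List[str] = []
    groups: List[np.ndarray] = []
    for condition in conditions:
        samples = [s for s in design.samples_of(condition) if s in matrix.values.columns]
        if len(samples) < 2:
            raise ValueError(f"condition {condition!r} has < 2 replicates")
        groups.append(np.arange(len(cols), len(cols) + len(samples)))
        cols.extend(samples)
    data = matrix.values[cols].to_numpy(dtype=float)
    effect, stat = _anova_stat(data, groups, s0)

    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    perm_stats = []
    for _ in range(n_perm):
        perm = rng.permutation(len(cols))
        shuffled, start = [], 0
        for size in sizes:
            shuffled.append(perm[start:start + size])
            start += size
        _, d = _anova_stat(data, shuffled, s0)
        perm_stats.append(d)
    q = _perm_q_values(stat, np.array(perm_stats), n_perm)
    table = pd.DataFrame(
        {
            "effect": effect,
            "statistic": stat,
            "q_value": q,
            "significant": q <= fdr,
        },
        index=matrix.values.index,
    )
    return DiffTestResult(table=table, fdr=fdr)


@dataclass(frozen=True)
class RankScore:
    entity_id: str
    components: Mapping[str, float]
    score: float


def rank_entities(
    components: Mapping[str, Mapping[str, float]],
    weights: Optional[Mapping[str, float]] = None,
) -> List[RankScore]:
    """Rank entities by the mean of min-max-normalized score components.

    ``components`` maps entity id -> component name -> non-negative value
    (intensity components should already be log-transformed).  Ties are
    broken by entity id.  Equal weights unless ``weights`` given.
    """
    if not components:
        return []
    names = sorted({n for comps in components.values() for n in comps})
    w = {n: (weights or {}).get(n, 1.0) for n in names}
    mins = {n: min(c.get(n, 0.0) for c in components.values()) for n in names}
    maxs = {n: max(c.get(n, 0.0) for c in components.values()) for n in names}
    scored = []
    for entity, comps in components.items():
        parts = []
        for n in names:
            lo, hi = mins[n], maxs[n]
            v = comps.get(n, 0.0)
            parts.append(w[n] * ((v - lo) / (hi - lo) if hi > lo else 0.0))
        score = sum(parts) / sum(w.values())
        scored.append(RankScore(entity, dict(comps), score))
    return sorted(scored, key=lambda r: (-r.score, r.entity_id))


def zscore_rows(matrix: QuantMatrix) -> QuantMatrix:
    """Per-entity z-scoring, a visualization helper."""
    values = matrix.values
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1).replace(0, np.nan)
    return QuantMatrix(
        values.sub(mu, axis=0).div(sd, axis=0),
        matrix.log2_transformed,
        matrix.peptide_counts,
    )
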