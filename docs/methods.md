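# Methods

This note documents the models, parameter choices and numerical decisions
behind `sumosite`, and what the synthetic-data tests do and do not
establish about real data.

## Remnant chemistry

Remnant masses are *modification* masses: the tag is attached to the
substrate lysine through an isopeptide bond, so a remnant's mass is the
bare sum of its residue monoisotopic masses with no terminal water. With
standard element masses (C 12, H 1.0078250319, N 14.0030740052,
O 15.9949146221, S 31.97207069) the residue sum of DVFQQQTGG reproduces
960.4301 Da exactly, which fixes both conventions.

The built-in remnant catalogue stores, for each definition, the sequence,
the elemental composition, the monoisotopic mass, neutral losses and
diagnostic ions. For the Glu-C and trypsin variants the recorded
composition corresponds to the sequence truncated before its C-terminal
GG, whereas the Asp-N composition covers the full sequence. The two are
deliberately kept as recorded — the composition is authoritative for the
mass, the `composition_matches_sequence` flag surfaces the situation, and
nothing is silently reconciled.

Diagnostic ions follow the standard conventions: a b-type prefix ion at
charge z has m/z = (Σ residue masses + z·m_proton)/z; internal fragments
(QQ, FQ, FQQ) are computed the same way; `-H2O`/`-CO` suffixes subtract the
corresponding neutral mass. Masses printed at four decimals are compared at
5·10⁻⁴ Da.

## Digestion

Cleavage rules: Asp-N cuts C-terminal to K and N-terminal to D/E (8 missed
cleavages); Glu-C C-terminal to K/D/E (8); trypsin C-terminal to K/R (4, no
proline suppression); WALP C-terminal to K/V/A/T/S/L/G (10). Lys-C, the
first-stage enzyme, is modelled as C-terminal to K with 8 missed cleavages —
the workflow only fixes its specificity, not a missed-cleavage limit, so the
limit matches the other high-missed-cleavage searches. Coordinates are
0-based half-open; coincident cuts from the two specificities deduplicate to
one. Digestion itself is purely combinatorial; the minimum peptide length
(7 aa) and the per-protease maximum peptide mass (Asp-N 6000, Glu-C 7000,
trypsin 9000, WALP 3200 Da, *including* the remnant modification mass) are
applied by the filtering module.

The remnant a protease leaves is the suffix of the mature SUMO C-terminus
downstream of the last cleavage site; missed-cleavage variants (e.g. the
FR-prefixed trypsin variant 2) arise from earlier cuts.

## Evidence model and site assembly

The evidence dialect is a documented subset of MaxQuant's `evidence.txt`:
one row per identified peptide per sample with Andromeda score, delta score
(margin over the next-best candidate), per-modification localization delta
scores, decoy flag, MS/MS scan ids, an identification type (direct MS/MS vs
matched between runs) and an LFQ intensity. A zero or empty intensity cell
means "not quantified" (`None`), matching MaxQuant semantics. Unknown
columns round-trip opaquely.

Sites are 1-based protein coordinates. Windows are 51-mers (±25 residues)
centred on the modified lysine, padded with `_` at protein termini. Site
records aggregate supporting rows: best scores are maxima, MS/MS counts
tally direct-fragmentation rows, intensities sum per sample.

## Filtering ledger

Rules apply in a fixed order, and each dropped row is attributed to the
first rule that rejects it, so per-rule counts always sum to input −
survivors: (1) reverse-database hits; (2) peptide length < 7; (3) modified
peptide mass above the protease limit; (4) Andromeda < 40 or delta ≤ 20;
(5) delta ≤ 40 for peptides with ≥ 2 variable modifications; (6) any SUMO
localization delta ≤ 6; (7) missing diagnostic remnant ions (Asp-N, Glu-C
and trypsin rows; diagnostic presence is consumed as a per-row flag —
spectrum matching is upstream of this package); (8) SUMO sites on peptide
C-terminal lysines for trypsin/Glu-C/WALP always, and for Asp-N unless the
next protein residue is D or E (a modified lysine resists cleavage, so such
assignments are chemically implausible); (9) duplicate MS/MS scan
assignments and duplicate per-sample 51-mer windows collapse to the
best-scoring row (lexicographic max over delta, Andromeda, localization,
then content keys, making the outcome independent of row order).

Site-level decoy FDR returns the smallest accept-above threshold whose
decoy/target ratio stays at or below the target fraction, +∞ when
unattainable.

SUMO-phospho co-modification considers direct MS/MS rows with ≥ 1 SUMO and
≥ 1 phospho site, both localization deltas > 6 and Andromeda ≥ 40. The
combined score is defined as delta/2 so that the > 20 cutoff coincides
exactly with delta > 40; the source material prints only this equivalence
and the ingredients, not the arithmetic, so the formula here is the
package's own choice with the auxiliary score excesses retained as hard
gates. The highest-scoring record per unique modified peptide is kept, and
both 51-mer windows are assigned.

## Pool equilibrium and chain topology

Only Lys-C/Asp-N evidence enters these quantifications, and intensities are
taken from the evidence table directly (not from the filtered site table).
SUMO-remnant-modified rows are classed by leading protein with precedence
chain (SUMO itself) > E1 (SAE1/UBA2) > E2 (UBC9) > E3 (descriptive name
containing "E3 SUMO ligase") > other target. Unmodified SUMO-derived
peptides ending in QQTGG are free mature SUMO; peptides containing but not
ending in QQTGG are immature SUMO2 or SUMO3 according to the species
constants (human SUMO2 precursor tail VY; SUMO3 VP/VPESSLAGHSF; mouse SUMO3
SASRGSVPTPNRCP); all other SUMO-internal peptides are excluded from the
denominators because they could originate from any pool. Since "free
mature" is dominated by but not limited to DVFQQQTGG, the fraction carried
by that peptide alone is reported alongside the all-QQTGG total.

Fractions are ratios of summed intensities within each (condition,
replicate); they are invariant to scaling a replicate and sum to 1 over
non-excluded pools. Condition summaries use SD (cell-culture style) or SEM
(organ style). For organ-vs-rest tests, the reference set is the remaining
organs minus the single one with the most extreme mean fraction (largest
|z| against the others), leaving six "median" organs whose replicate
fractions are pooled into a two-sample two-tailed t-test; this construction
is one concrete reading of a reference set described only loosely, and is
flagged as an interpretation.

Chain topology bins SUMO-remnant-modified peptides mapping to a SUMO
isoform by modified lysine; a multiply modified peptide contributes its
full intensity to each of its sites; per-replicate sums are normalized to
fractions. Peptides consistent with both SUMO2 and SUMO3 (their C-termini
are homologous) should carry an isoform-set leading protein and are only
counted in profiles they are unique to.

## Quantification statistics

Entities must be detected in at least `min_detected` replicates of at least
one condition (3/3 for the cell-culture design, 4/5 for the organ design);
proteins additionally need ≥ 2 peptides. Median normalization shifts each
log2 sample column to the grand median. Missing values are imputed globally
from Normal(μ − 1.8σ, (0.3σ)²) of the observed log2 values — the
conventional down-shifted-normal defaults — with a mandatory seed.

The two-sample statistic is d = (mean_A − mean_B)/(s + s0) with pooled
standard error s and stabilization constant s0. The upstream analysis names
a "p0 value of 1" for its permutation tests; that parameter is read here as
s0 = 1 (the moderation constant those tests expose); the alternative
reading as a p-value floor is noted but not implemented. The multi-condition
analogue is sqrt(SS_between/(k−1))/(sqrt(MS_within) + s0), which at s0 = 0
and two conditions is a monotone transform of |t| and therefore ranks
entities identically to the two-sample test.

q-values are permutation-based: for each entity's |d|, the expected false
count is the mean number of permutation statistics at or above it, divided
by the observed count, then made monotone by a cumulative minimum from the
least significant entity upward. Group-label permutations are exhaustive
when few enough (e.g. 18 usable at 3 vs 3), otherwise sampled without
replacement; the observed labeling and its mirror are excluded, since they
carry the unpermuted signal and would floor the attainable q-values.

Ranking scores combine the stated components (MS/MS counts, intensities,
scores — intensities log-transformed) as an equal-weight mean of
min-max-normalized values with configurable weights; the exact weighting of
the original ranking is not printed, so this is the package's documented
choice. Ties break by entity id.

## Motifs and enrichment

Motif classes are read off the 51-mer: KxE iff the +2 residue is E, KxD iff
D, inverted iff −2 ∈ {E, D}, and [ED]xKP additionally requires P at +1;
classes are not mutually exclusive, and `_` padding never matches.
Adherence is reported both per site and weighted by site intensity (sites
without intensity drop out of the weighted ratio only).

Term enrichment uses the two-tailed Fisher exact test (sum of all table
probabilities at or below the observed table's) on foreground-vs-rest 2×2
tables, BH correction across all tested terms, and a default corrected-P
cutoff of 0.02. Enriched terms get the relative score
(log₂(enrichment)³ × −log₁₀(P))^0.25, batch-normalized so the maximum is
100; depleted terms are reported without a relative score since the formula
is only defined for enrichment > 1. A per-position binomial z-score helper
provides sequence-logo-style summaries against a reference composition.

## Conservation

The trident column score is (1−t)^α (1−r)^β (1−g)^γ with defaults α = 1,
β = 0.5, γ = 2: t is the weighted Shannon entropy over the 21-symbol
alphabet (20 residues + gap) normalized by log(min(N, 21)); r is the
unweighted mean pairwise distance between the column's non-gap residues,
where d(a,b) = 1 − s(a,b)/√(s(a,a)·s(b,b)) under BLOSUM62, rescaled so the
most dissimilar pair has distance 1 (this keeps d(a,a) = 0, so a fully
conserved column scores exactly 1); g is the weighted gap fraction.
Sequence weights are position-based (Henikoff–Henikoff, gaps counting as a
symbol), with uniform weights available. RCS is the column score × 100 at
each ungapped reference position.

A property worth knowing: because the entropy normalization log(min(N, 21))
grows with the number of rows, adding gap rows to a maximally diverse
column can slightly *raise* the score even though the gap penalty grows.
This is inherent to the trident definition; monotone degradation holds for
conserved columns, which is what the tests assert.

Structural classes: disordered lysines are always "exposed", giving three
classes (disordered, globular-exposed, globular-buried); per-residue
disorder/accessibility flags are consumed as annotations, not computed.
Delta-RCS pairs every SUMOylated lysine with every non-SUMOylated lysine of
the same protein and class, and tests the pairwise differences with a
two-tailed paired (one-sample) t-test; P < 0.001 is the significance bar.
A negative mean delta means modified lysines are less conserved — the sign
convention is fixed by construction and verified on synthetic data.

## Synthetic data

The generator emulates the study conditions, and its defaults were chosen
once from them: a cell-culture-like design (3 conditions × 3 replicates;
recovery tests use 5), pool fractions with 93.2% conjugated (chain 6%, E1
0.2%, E2 1%, E3 3%, other targets 83%, free 6%, immature 0.1%/0.7%), an
organ-like profile with 52% conjugated, the SUMO2 chain profile
{K11 0.35, K7 0.25, K21 0.20, K33 0.20}, and 36% KxE adherence. Protein
backbones exclude lysine so every planted site is deliberate; flanking
aspartates bound the Asp-N fragment containing each site so baseline
peptides respect the mass limits. Intensities are log-normal per peptide
(CV 0.2, mean-preserving multiplicative replicate noise); missingness, when
enabled, preferentially removes low intensities to exercise imputation
realistically. Chain linkages and the dominant free peptide are emitted as
several evidence entries each (charge states / cleavage forms), as in real
tables. Canonical human SUMO1/2/3 precursor sequences ship as constants.

Filter-rule violations can be planted one rule at a time on reserved spare
proteins (so their windows never collide with baseline evidence), each
constructed to pass all preceding rules — making the per-rule drop counts
exactly auditable. MSA generation targets per-column conservation levels by
scanning the number of consensus rows against the trident score itself
(uniform weights, 24 orthologs), planting a configurable RCS deficit
(default 10 points) at SUMOylated lysine columns; the recovery test then
exercises the independent scoring/pairing/t-test path.

What passing these tests shows: the estimators are unbiased and correctly
calibrated under log-normal intensity noise, clean peptide-to-protein
mapping and known ground truth. What they do not show: robustness to
chimeric spectra, mis-localized sites, shared peptides across paralogs,
retention-time-dependent intensity bias, or annotation errors — all of
which real MaxQuant tables contain.

## Problem sizes

Default test and acceptance runs use 400 planted sites on 60 proteins with
3-5 replicates, 15 alignments of 24 orthologs × 100 columns, 20-seed null
calibration at 1000 entities, and oracle comparisons on sequences ≤ 30
residues and tables with margins ≤ 50 — sizes at which every recovery
tolerance (±0.02 pools, ±0.03 chains, ±0.04 adherence, ±3 points delta-RCS)
is met with comfortable sampling margins.
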