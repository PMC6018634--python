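"""Permutation-FDR differential testing and consensus-motif statistics.

Simulates a site intensity matrix in which 5% of sites respond to a
treatment, flags responders with the SAM-style moderated test, then
measures KxE-motif adherence of a planted site set.
"""

from sumosite import QuantMatrix, kxe_adherence, motif_class, perm_two_sample
from sumosite.evidence import SiteRecord, extract_window
from sumosite.synthetic import (
    GeneratorConfig, generate_proteome, generate_shifted_matrix, make_design,
)

design = make_design(("control", "heat"), 3)
frame, shifted = generate_shifted_matrix(
    500, design, "heat", fraction_shifted=0.05, effect_sd=4.0, seed=3
)
result = perm_two_sample(
    QuantMatrix(frame, log2_transformed=True),
    design.samples_of("heat"), design.samples_of("control"),
    s0=1.0, fdr=0.05, seed=0,
)
flagged = set(result.significant)
print(f"flagged {len(flagged)} of 500 sites at 5% permutation FDR")
print(f"  true responders recovered: {len(flagged & set(shifted))}/{len(shifted)}")
print(f"  false flags: {len(flagged - set(shifted))}")

config = GeneratorConfig(seed=3, n_sites=600, n_proteins=60, kxe_adherence=0.36)
proteins, plan = generate_proteome(config)
sites = [
    SiteRecord(pid, pos, extract_window(proteins[pid], pos),
               0.0, 0.0, 0.0, 0)
    for pid, pos, _ in plan
]
site_fraction, _ = kxe_adherence(sites)
print(f"\nKxE adherence of {len(sites)} planted sites: "
      f"{100 * site_fraction:.1f}% (configured 36%)")
call = motif_class(sites[0].window)
print(f"example window classes: {sorted(call.classes) or 'none'}")

# The moderated statistic with s0=1 suppresses low-variance false positives,
# so nearly all flags are true responders; adherence recovers the planted
# consensus-motif rate.
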