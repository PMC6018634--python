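"""Why the workflow digests with Lys-C first and Asp-N second.

The 8A2 antibody recognizes IRFRFDGQPI inside the SUMO2/3 C-terminus.
Trypsin cuts within that epitope (it contains arginines), destroying the
binding site before enrichment; Lys-C does not.  After enrichment, Asp-N
trims the conjugated SUMO down to the short DVFQQQTGG tag.
"""

from sumosite import PROTEASES, derive_remnant, epitope_intact
from sumosite.equilibrium import SUMO2_HUMAN

EPITOPE = "IRFRFDGQPI"
mature = SUMO2_HUMAN[:93]

for protease in ("trypsin", "lysc"):
    intact = epitope_intact(SUMO2_HUMAN, EPITOPE, PROTEASES[protease])
    print(f"{protease:8s} leaves the 8A2 epitope intact: {intact}")

for protease in ("lysc", "trypsin", "aspn"):
    remnant = derive_remnant(mature, PROTEASES[protease])
    print(f"{protease:8s} remnant: {len(remnant):2d} residues "
          f"({remnant if len(remnant) < 35 else remnant[:12] + '...'})")

# Lys-C leaves the epitope intact but a ~5.6 kDa remnant; trypsin leaves a
# 32-residue tag but no epitope; Asp-N (after Lys-C enrichment) leaves the
# 9-residue DVFQQQTGG tag that makes site-level MS practical.
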