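"""Remnant masses and diagnostic ions for the SUMO2/3 search definitions.

Each protease leaves a different C-terminal SUMO fragment on the modified
lysine; its monoisotopic mass is what the search engine adds as a variable
modification, and the b-type/internal fragment ions are what confirms a
spectrum really carries the remnant.
"""

from sumosite import builtin_remnants

for remnant in builtin_remnants():
    print(f"{remnant.name:26s} {remnant.protease:8s} "
          f"{remnant.monoisotopic_mass:10.4f} Da  {remnant.sequence}")
print()

aspn = next(r for r in builtin_remnants() if r.protease == "aspn")
print(f"diagnostic ions of {aspn.sequence} (1+):")
for label, mz in aspn.ion_table(charge=1):
    print(f"  {label:14s} m/z {mz:9.4f}")

# The printed masses mean: a peptide whose lysine carries the Asp-N remnant
# is 960.4301 Da heavier than its unmodified form; the b2-DV ion at
# m/z 215.1026 is one of the fragments that certifies the remnant.
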