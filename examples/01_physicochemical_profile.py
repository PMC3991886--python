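"""Physicochemical profile of an SSB from its printed composition row.

Raw sequences are often not republished alongside characterization tables,
but a one-decimal composition row plus the chain length pins down the
integer residue counts almost completely. This example rebuilds the counts
for DpsSSB (the 142-residue SSB of Desulfotalea psychrophila) and derives
monomer mass, isoelectric point, aliphatic index and the cold-adaptation
group statistics from them.
"""

from ssbkit import load_reference_composition, reconstruct_counts
from ssbkit.composition import arg_lys_ratio, group_fractions
from ssbkit.physchem import physchem_report

table = load_reference_composition()
counts = reconstruct_counts(table.row("DpsSSB"), table.lengths["DpsSSB"])
report = physchem_report(counts)

print(f"DpsSSB ({counts.length} residues)")
print(f"  monomer mass     : {report.monomer_mass_kda} kDa")
print(f"  isoelectric point: {report.pI}")
print(f"  aliphatic index  : {report.aliphatic_index}")
print(f"  cysteines        : {report.cys_count}")

groups = group_fractions(counts)
print(f"  charged (DEKHR)  : {groups['charged']}%")
print(f"  polar (NQSTY)    : {groups['polar']}%")
print(f"  hydrophobic      : {groups['hydrophobic']}%")
print(f"  Arg/(Arg+Lys)    : {arg_lys_ratio(counts)}")

# The low hydrophobic content and the acidic pI are typical of bacterial
# SSBs; a depressed Arg/(Arg+Lys) ratio is a psychrophilic hallmark
# (DpsSSB, at 0.63, is the panel's exception).
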