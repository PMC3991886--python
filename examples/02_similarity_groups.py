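"""Identity vs similarity under residue similarity groups.

Percent identity counts only exact matches; percent similarity also counts
conservative substitutions — residues sharing a similarity group such as
{K,R} or {V,L,I,M}. The same groups drive the conservation shading of an
alignment column.
"""

from ssbkit import global_align, shade_msa

# Two toy OB-fold fragments differing by conservative substitutions.
a = "MKRGWNEVILM"
b = "MRKGWDELIVM"

res = global_align(a, b)
print("aligned:", res.aligned_a)
print("        ", res.aligned_b)
print(f"identity  {res.identity_pct}%   (exact matches per alignment column)")
print(f"similarity {res.similarity_pct}%  (adding co-group substitutions)")

# Column conservation bands of a small pre-aligned MSA: 100% = every
# sequence similar, >=80% / >=60% = largest similarity cluster reaching
# that fraction.
msa = ["KDWA", "RDWA", "KEWC", "REYS", "KDFG"]
print("MSA shading:", shade_msa(msa))
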