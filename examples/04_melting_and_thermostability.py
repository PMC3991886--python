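"""Duplex destabilization (dTm) and thermal-inactivation half-life.

SSBs bind ssDNA only, so they pull the duplex<->single-strand equilibrium
toward melting: the apparent Tm of a reporter duplex drops. Separately,
the protein's own heat tolerance is scored by how long it keeps binding
activity at a fixed temperature (half-life).
"""

from ssbkit import delta_tm, extract_tm, half_life
from ssbkit.synth import generate_melting, generate_timecourse

# The PtoSSB scenario: free 44-bp duplex melts at 75 C; with PtoSSB at 58 C.
free = extract_tm(generate_melting(75.0, noise_sd=0.01, seed=1))
bound = extract_tm(generate_melting(58.0, noise_sd=0.01, seed=2))
print(f"Tm free duplex : {free.value:.1f} C")
print(f"Tm with SSB    : {bound.value:.1f} C")
print(f"destabilization: {delta_tm(free, bound):.1f} C"
      " (largest shift in the panel)")

# Inactivation at 100 C sampled on the standard 0-60 min grid.
tc = generate_timecourse(half_life_min=15.0, temperature_label=100.0)
print(f"half-life at {tc.temperature_label:.0f} C: {half_life(tc)}")

# A censored course: activity never falls below 50% within the grid.
tc_stable = generate_timecourse(half_life_min=200.0, temperature_label=60.0)
print(f"half-life at {tc_stable.temperature_label:.0f} C: {half_life(tc_stable)}")
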