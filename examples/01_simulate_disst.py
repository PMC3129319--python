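"""Simulate a dynamic insulin sensitivity test for a virtual participant.

A 10 g glucose bolus at t = 7.5 min and a 1 U insulin bolus at t = 17.5
min over a 60 min test; the participant starts at their basal steady
state.  Prints the basal state and the excursion extrema: plasma insulin
peaks right after the bolus, and for a normally glucose tolerant (NGT)
participant glucose dips below basal late in the test — the feature that
makes glucose-dependent clearance identifiable.
"""

from practident import NGT, disst_protocol, simulate

protocol = disst_protocol(sample_spacing=5.0)
profiles = simulate(NGT.kin, NGT.secretion, NGT.pd, protocol)

b = profiles.basal
print(f"basal state: I = {b.I:.2f} mU/L, Q = {b.Q:.2f} mU/L, G = {b.G:.2f} mmol/L")
print(f"plasma insulin peak: {profiles.I.max():.1f} mU/L")
print(f"glucose peak: {profiles.G.max():.2f} mmol/L, "
      f"minimum: {profiles.G.min():.2f} mmol/L (basal {NGT.pd.Gb:.1f})")
print(f"glucose below basal after t = "
      f"{profiles.grid[profiles.G < NGT.pd.Gb].min():.1f} min")
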