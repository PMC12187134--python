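"""Equilibrium speciation of the LC8-bridged assembly ladder.

Speciates 10 uM 53BP1 trimer against increasing LC8-dimer equivalents with
the QT2-like affinity pair (intratrimer 0.3 uM, bridging 1.1 uM) for the
wild-type-like q = 3 architecture, and prints the bridged fraction and
weight-average mass at each point.  The weight-average mass climbs from the
free-trimer 51 kDa toward the region between the 114.6 kDa trimer complex
and the 292.8 kDa fully occupied dimer-of-trimers — the heterogeneous
mixture seen by SEC-MALS.
"""

from lc8bridge import LadderModel, mass_profile, titration_profile

model = LadderModel(q=3, kd_intra=0.3e-6, kd_bridge=1.1e-6)
equivalents = [0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0]
states = titration_profile(equivalents, 10e-6, model)

print(f"{'LC8 eq':>7} {'bridged frac':>13} {'Mw (kDa)':>9}  dominant species")
for eq, st in zip(equivalents, states):
    rows, mw = mass_profile(st)
    top = max(rows, key=lambda r: r[2])
    print(f"{eq:>7.2f} {st.bridged_fraction():>13.3f} {mw:>9.1f}  "
          f"{top[0].ratio} ({top[1]:.1f} kDa, w = {top[2]:.2f})")
print("\nBridged fraction rises with added LC8; with excess LC8 the "
      "weight-average mass approaches the fully occupied bridged complex.")
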