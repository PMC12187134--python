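"""Expected complex masses of the trimer and bridged 53BP1/LC8 assemblies.

For each number q of intact LC8-recognition (QT) sites per chain, prints the
mass of the fully occupied single-trimer complex (1 trimer : q LC8 dimers)
and bridged dimer-of-trimers (2 trimers : 3q LC8 dimers), computed from the
default monomer masses (LBD-OD protomer 17.0 kDa, LC8 dimer 21.2 kDa).
These are the reference values against which SEC-MALS peak masses are
interpreted.
"""

from lc8bridge import expected_mass_table

print(f"{'q':>2} {'trimer':>8} {'kDa':>6} {'bridged':>8} {'kDa':>6} {'free trimer kDa':>16}")
for q in (1, 2, 3):
    row = expected_mass_table(q)
    print(
        f"{q:>2} {row['trimer_ratio']:>8} {row['trimer_mass_kDa']:>6} "
        f"{row['bridged_ratio']:>8} {row['bridged_mass_kDa']:>6} "
        f"{row['free_trimer_mass_kDa']:>16}"
    )
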