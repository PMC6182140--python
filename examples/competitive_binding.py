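"""Competitive occupancy of a sliding clamp by two PIP-box ligands.

Solves the mutually exclusive binding equilibrium for a translesion
polymerase (40 nM, Kd 0.4 μM) and a clamp-channel peptide (400 nM,
Kd 1.1 μM) competing for 400 nM of clamp protomer sites — the
concentration regime of a primer-extension bypass assay with the clamp
in 10-fold excess over the polymerase.
"""

from clampdyn.binding_equilibria import (
    EquilibriumSystem,
    Ligand,
    solve_competitive,
    stoich_ratios,
)

system = EquilibriumSystem(
    receptor_total=400.0,  # nM clamp protomer sites (one PIP pocket each)
    ligands=[
        Ligand("pol_eta", total=40.0, Kd=400.0),  # 0.4 μM in nM units
        Ligand("p15", total=400.0, Kd=1100.0),  # 1.1 μM
    ],
    unit="nM",
)
result = solve_competitive(system)

print(f"free clamp sites : {result.receptor_free:.1f} nM")
for name in ("pol_eta", "p15"):
    print(f"{name:8s}: {result.bound[name]:6.1f} nM bound "
          f"({100 * result.fraction_bound[name]:.1f}% of its total)")
print("molar ratio clamp:p15 =", stoich_ratios([400.0, 400.0]))
# About 43% of the polymerase is clamp-bound even with an equimolar
# competitor present: competition alone cannot switch the polymerase off,
# so any inhibition must come from a co-occupied (ternary) clamp.
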