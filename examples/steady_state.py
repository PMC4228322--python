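"""Closed-form equilibrium of the ODE granulopoiesis model.

All cell counts are in units of the equilibrium stem-cell number (C_S = 1).
The equilibrium follows directly from the parameter table: stem efflux
a_S^nor/tau_S feeds the progenitor chain, each amplified stage holds
influx x A^in x T / a, and the maturing chains hold influx x transit time.
"""

from myelosim import compute_steady_state

steady = compute_steady_state()

print("equilibrium compartment contents (units of stem-cell number):")
for name in ("S", "CG", "PGB", "G4", "G5", "G6", "MGB", "GRA",
             "GM_CSF", "G_CSF"):
    print(f"  {name:8s} {steady.nor[name]:12.4f}")
print(f"stem efflux into CG: {steady.S_out:.5f} per hour")
print()
print("The stem compartment exports 1.875% of its size per hour; after a")
print("~64-fold amplification in CG and ~32-fold in PGB this sustains the")
print("~80x stem-cell-number pool of circulating granulocytes, which turn")
print("over with a 5 h life-time.")
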