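"""Recovery after acute loss of circulating granulocytes.

Granulocytes are initialised at 1e-15 of normal (all other compartments at
equilibrium).  The loss is sensed only through G-CSF, which shortens
maturation and raises amplification; the compartment refills from the intact
marrow within hours and overshoots briefly.
"""

from myelosim.scenarios import ScenarioRunner

runner = ScenarioRunner()
sc = runner.depletion(["GRA"], 1e-15, engine="ode", t_end_days=4.0,
                      dt_out=0.25)

print("granulocyte depletion (ODE engine):")
print(f"  50% recovery: {sc.markers['GRA_recovery_50']*24:5.1f} h")
print(f"  99% recovery: {sc.markers['GRA_recovery_99']*24:5.1f} h")
print(f"  peak overshoot: {sc.result.rel('GRA').max():.3f} x normal")
print()
print("Because the stem compartment is never signalled, the hybrid engine")
print("produces the same trajectory (see tests/test_hybrid.py).")
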