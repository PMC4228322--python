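"""Six cycles of CHOP-21 chemotherapy on both engines.

The drug block (cyclophosphamide + doxorubicin + vincristine) kills marrow
stages at first-order rates for one day per application, with a 1.3-fold
first-cycle effect; prednisone on days 1-5 of each cycle prolongs the
granulocyte life-time, producing the initial leukocytosis.  In the hybrid
engine the stem-cell kill only reaches proliferating cells in GE Omega, so
the quiescent niche population shields the stem pool.
"""

from myelosim.scenarios import ScenarioRunner, leukocytes_per_ul

runner = ScenarioRunner()

hyb = runner.regimen("CHOP-21", engine="hybrid")
ode = runner.regimen("CHOP-21", engine="ode")

print("CHOP-21, hybrid engine:")
print(f"  minimum total stem number: {100*hyb.markers['N_S_min']:.1f}% "
      f"(quiescent pool protected)")
v = hyb.markers["GRA_cycle1_nadir_value"]
print(f"  cycle-1 leukocyte nadir: {100*v:.1f}% of normal "
      f"({leukocytes_per_ul(v):.0f}/ul) on day "
      f"{hyb.markers['GRA_cycle1_nadir_day']:.1f}")

print("CHOP-21, ODE engine:")
print(f"  minimum stem number: {100*ode.markers['S_min']:.3f}% "
      f"(homogeneous pool nearly eliminated)")
print(f"  cycle-1 leukocyte nadir: "
      f"{100*ode.markers['GRA_cycle1_nadir_value']:.1f}% on day "
      f"{ode.markers['GRA_cycle1_nadir_day']:.1f}")
print()
print("Both engines produce similar circulating-cell dynamics, but the")
print("hidden stem-cell dynamics differ radically - the cell-cycle-specific")
print("kill of the hybrid model spares the dormant niche population.")
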