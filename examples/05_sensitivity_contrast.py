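"""Mouse-versus-human OAT sensitivity contrast.

Builds time-integrated sensitivity matrices of every organ concentration
with respect to the eight PK parameters (seven partition coefficients
plus hepatic clearance). In the mouse, clearance dominates every row; in
the human, tissue partitioning dominates and clearance is secondary —
the central interspecies conclusion of the analysis.
"""

from nanopbpk import (DoseEvent, load_physiology, load_pk_parameters,
                      rank_parameters, sensitivity_matrix)
from nanopbpk.sensitivity import DEFAULT_PK_PARAMETERS, FLOW_PARAMETERS

taxol = load_pk_parameters("taxol")

mouse = sensitivity_matrix(load_physiology("mouse"), taxol, DoseEvent(400.0),
                           horizon=3.0)
human = sensitivity_matrix(load_physiology("human"),
                           taxol.with_overrides(CL=25.81),
                           DoseEvent(316000.0), horizon=3.0)

print("mouse matrix (3 h, raw sensitivities):")
print(mouse.table.round(2).to_string())
print("\ntop-ranked parameter per organ (|integrated sensitivity|):")
print(f"{'organ':>6} {'mouse':>8} {'human':>8}")
for organ in mouse.table.index:
    print(f"{organ:>6} {rank_parameters(mouse, organ)[0]:>8} "
          f"{rank_parameters(human, organ)[0]:>8}")

flows = sensitivity_matrix(load_physiology("mouse"), taxol, DoseEvent(400.0),
                           parameters=DEFAULT_PK_PARAMETERS + FLOW_PARAMETERS,
                           outputs=("tu",), horizon=24.0)
print("\nmouse tumor accumulation over 24 h, parameters ranked:")
print("  " + " > ".join(rank_parameters(flows, "tu")[:5]) + " > ...")
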