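"""Build the two kinetic schemes and look at their transition matrices.

The channel chain's forward rates grow with depolarization; the buffer
grid's binding probabilities are proportional to free calcium.
"""

import numpy as np

from presynmc import (Environment, build_calbindin_scheme, build_vdcc_scheme,
                      export_edge_list, max_admissible_dt, transition_matrix)

vdcc = build_vdcc_scheme()
print("VDCC scheme:", vdcc.s, "states,", len(vdcc.transitions), "edges, max branch",
      vdcc.max_branch)
print(export_edge_list(vdcc))

for V in (-70.0, 0.0, 30.0):
    P = transition_matrix(vdcc, Environment(V, 1e-7), 1e-6)
    print(f"V = {V:+.0f} mV   P(C0->C1) = {P[0, 1]:.2e}   P(O->C3) = {P[4, 3]:.2e}")
print("-> opening probability grows with V, closing probability shrinks\n")

calb = build_calbindin_scheme()
print("Calbindin scheme:", calb.s, "states,", len(calb.transitions), "edges")
for ca in (1e-7, 1e-6, 1e-5):
    P = transition_matrix(calb, Environment(0.0, ca), 1e-6)
    i, j = calb.index_of("H0M0"), calb.index_of("H1M0")
    print(f"[Ca] = {ca:.0e} M   P(H0M0->H1M0) = {P[i, j]:.2e}")
print("-> binding probability is linear in free calcium")

env = Environment(30.0, 1e-5)
print(f"\nlargest admissible timestep at +30 mV: "
      f"{max_admissible_dt(vdcc, env):.2e} s (1 us default is safely below)")
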