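"""Multi-state mobility decomposition of a trajectory ensemble.

Simulates particles switching between a near-immobile state
(D = 0.001 um^2/s) and a mobile one (D = 0.1 um^2/s) and infers the
states, their weight fractions, the transition probabilities and the
weighted mean diffusion constant with the Gibbs sampler.
"""

import numpy as np

from ssmic import states, synth

model = synth.SwitchingModel(D=[0.001, 0.1], pi=[0.6, 0.4],
                             T=[[0.95, 0.05], [0.075, 0.925]])
trajs, _ = synth.simulate_trajectories(model, 400, 50, seed=3)
st = states.decompose(trajs, K_max=5, n_iter=2000, burn_in=600, seed=4)

print(f"states found: {st.n_states}")
for k in range(st.n_states):
    print(f"  state {k}: D = {st.D[k]:.4f} um^2/s, weight pi = {st.pi[k]:.3f}")
print(f"weighted mean D-bar = {st.D_bar:.4f} um^2/s (truth 0.0406)")
print("transitions (from, to, probability):")
for i, j, p in states.transition_summary(st):
    print(f"  {i} -> {j}: {p:.3f}")
print("The weight fractions say how much of the time complexes spend nearly")
print("immobile (actin-bound) versus freely mobile on the cell surface.")
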