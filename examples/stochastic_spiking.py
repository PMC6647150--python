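"""Channel noise turns the silent excitable neuron into a spiking one.

Simulates the stochastic model at increasing noise amplitudes and counts
threshold crossings (v = 0, re-armed below rest) over a fixed horizon.
"""

import numpy as np

import fhnlif as F

params = F.REFERENCE_PARAMS
cfg = F.SimConfig(dt=0.01, T=1000.0)

print("sigma0   spikes in T=1000")
for i, sigma0 in enumerate([0.005, 0.008, 0.01, 0.02]):
    traj = F.simulate_fhn(params, F.NoiseSpec("additive", sigma0), cfg,
                          rng=np.random.default_rng(40 + i))
    spikes = F.detect_spikes(traj)
    print(f"{sigma0:6.3f}   {spikes.count}")

print()
print("Below sigma0 ~ 0.005 the neuron spikes rarely, if at all; the")
print("spike count grows with the amplitude because noise pushes the")
print("state across the separatrix more often.")
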