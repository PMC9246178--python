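"""Finite-size input variability: RMF versus thermodynamic mean field.

A neuron receives a fixed total drive split across K channels (total
excitation E = 20 or inhibition I = -20, 50 Hz per channel).  The TMF
limit replaces the discrete input stream by its deterministic mean and so
erases input variability; the RMF calculation keeps the finite jump sizes.
The fewer/stronger the synapses, the larger the gap in Std(x).
"""

import math

from rmfnet.baselines import tmf_rate_and_moments
from rmfnet.network import NeuronParams, PoissonDrive
from rmfnet.rmf import moments

neuron = NeuronParams(h=1.0, a=math.log(100.0) / 20.0, tau=0.01)

print(f"{'inputs':>14} {'K':>4} {'RMF std(x)':>11} {'TMF std(x)':>11} {'ratio':>6}")
for sign, label in ((+1.0, "excitatory"), (-1.0, "inhibitory")):
    for K in (7, 20):
        mu = sign * 20.0 / K
        drive = PoissonDrive(channels=tuple((50.0, mu) for _ in range(K)))
        ms = moments(drive, neuron, n_max=2)
        tm = tmf_rate_and_moments(drive, neuron, variant="with_relaxation")
        print(f"{label:>14} {K:>4} {ms.std_x:>11.3f} {tm.std_x:>11.3f} "
              f"{ms.std_x / tm.std_x:>6.2f}")

print("\nThe TMF approximation underestimates the stationary variability of"
      "\nthe internal variable, most strongly for a few large inhibitory"
      "\nsynapses (about seventeenfold at K = 7), because long silent periods"
      "\nintegrate the full discreteness of the input stream.")
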