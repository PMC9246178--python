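"""Divergence of the resolvent series and its Padé resummation.

The stationary rate is the sum of a perturbative series in -h*tau whose
coefficients Q_m(-a) grow superexponentially under strong excitation (zero
radius of convergence), while inhibition keeps them bounded.  Direct
Taylor summation therefore fails exactly where excitation dominates; the
zigzag diagonal chain of Padé approximants still converges there.
"""

import numpy as np

from rmfnet.network import NeuronParams, PoissonDrive
from rmfnet.rmf import iterate_kernels, rate_transfer

neuron = NeuronParams(h=1.0, a=0.1, tau=0.01)

for mu in (3.0, -3.0):
    drive = PoissonDrive(channels=((500.0, mu),))
    table = iterate_kernels(drive, neuron, M=40)
    lr = table.log_inv_radius()
    kind = "excitatory" if mu > 0 else "inhibitory"
    print(f"{kind} input (mu = {mu:+.0f}): log10(1/r_m) at m = 5, 20, 40: "
          f"{lr[4] / np.log(10):8.2f} {lr[19] / np.log(10):8.2f} "
          f"{lr[39] / np.log(10):8.2f}")

print("\n1/r_m estimates the inverse radius of convergence: growth without"
      "\nbound (excitation) means a divergent series; a plateau (inhibition)"
      "\nmeans a finite radius.\n")

for be, mu in ((500.0, -3.0), (500.0, 3.0), (1000.0, 3.0)):
    drive = PoissonDrive(channels=((be, mu),))
    rp = rate_transfer(drive, neuron, method="pade")
    rt = rate_transfer(drive, neuron, method="taylor")
    print(f"beta_e = {be:6.0f} Hz, mu = {mu:+.0f}:  Pade beta = {rp.beta:8.4f} Hz "
          f"(converged={rp.converged})   "
          f"Taylor beta = {rt.beta:8.4g} Hz (converged={rt.converged})")

print("\nFor inhibition both summations agree.  At 500 Hz of strong"
      "\nexcitation the divergent series is still asymptotic enough that its"
      "\nsmallest term meets the stopping rule (optimal truncation); at 1 kHz"
      "\ndirect summation blows up and only the Padé chain converges.")
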