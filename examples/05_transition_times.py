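"""Predicting metastable transition times from RMF moments alone.

For a bistable circuit, an effective double-well potential is built from
the equal-weight two-Gaussian mixture of the up/down conditional moments
of the group-mean internal variable (computed purely from the RMF
solution), and an Eyring-Kramers escape time is read off.  The absolute
scale is heuristic, but the prediction rank-orders the simulated
transition times across coupling strengths.
"""

import math

import numpy as np

from rmfnet.metastability import (cluster_observable, detect_states,
                                  predict_transition_time, rmf_cluster_moments)
from rmfnet.network import bistable_clusters, make_bistable_network
from rmfnet.simulate import simulate
from rmfnet.solver import find_solutions, reduce_clusters

print(f"{'mu_e':>5} {'mu_i':>5} {'T_pred (s)':>12} {'T_sim (s)':>10} {'n_trans':>8}")
for mu_e, mu_i in ((1.2, -4.0), (1.3, -6.0), (1.4, -8.0)):
    net = make_bistable_network(10, mu_e, mu_i, 1500.0)
    red = reduce_clusters(net)
    sols = find_solutions(net, n_starts=2, seed=0, reduction=red)
    mom = rmf_cluster_moments(red, sols[0].beta)
    n = 10
    up = (mom[0].mean_x, mom[0].std_x / math.sqrt(n))
    dn = (mom[2].mean_x, mom[2].std_x / math.sqrt(n))
    pred = predict_transition_time(up, dn, tau=0.01)
    rec, tr = simulate(net, duration=25.0, seed=3, trace_dt=1e-3)
    st = detect_states(cluster_observable(tr, bistable_clusters(10)[0]),
                       dt=1e-3, seed=0, tau=0.01)
    print(f"{mu_e:>5} {mu_i:>5} {pred.time:>12.3g} "
          f"{st.mean_transition_time:>10.3g} {st.n_transitions:>8}")

print("\nStronger coupling deepens the effective wells: both the predicted"
      "\nand the simulated transition times grow, in the same order.")
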