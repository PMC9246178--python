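# Methods

## Model

An LER (linear-exponential-reset) neuron carries an internal variable
`x(t)` — a caricature of the membrane potential — with three dynamical
components:

* **interaction**: when presynaptic neuron `j` spikes, `x_i` jumps by the
  synaptic weight `mu_ij` (any sign, dimensionless in x-units);
* **relaxation**: between events `x_i` decays exponentially to zero with
  time constant `tau_i`;
* **reset**: when neuron `i` itself spikes, `x_i` resets to zero.

Spikes are emitted by a point process with stochastic intensity
`lambda_i(t) = h_i exp(a_i x_i(t))`: `h_i` is the spontaneous rate of the
isolated neuron, `a_i` its excitability. The exponential rectification
admits inhibition naturally (negative `x` only suppresses the rate) while
the reset implements a refractory feedback that precludes rate explosion.
Finite `tau` guarantees ergodicity of the finite network.

Default parameters follow common biophysical choices: `tau = 10 ms`
(membrane time constant), `h = 1 Hz` (spontaneous rate), `a = 0.1`, or
`a = ln(100)/20 ~ 0.23` for the two-group circuit where a single large
synaptic event moves `x` by ~2% of its dynamic range.

## Replica-mean-field calculation

In the replica-mean-field (RMF) limit — infinitely many copies of the
network with uniformly randomized cross-replica routing — every neuron
receives its inputs as independent Poisson streams whose rates must be
solved for self-consistently. The stationary law of one neuron under
Poisson drive is encoded by the moment-generating function
`L(u) = E[exp(u x)]`, which satisfies a delay differential equation with
*negative* delay `a` and no natural initial condition; the physically
meaningful solution is pinned down by regularity and the normalization
`L(0) = 1`, `h L(a) = beta`.

`rmfnet.rmf` solves it by a resolvent expansion: with the
exponential-moment drive `V(u) = sum_j beta_j (e^{mu_j u} - 1) + c u`
(`c` is the mean background drive) and the homogeneous solution
`q(u) = exp(tau int_a^u V(v)/v dv)`, iterated kernels are built by

    Q_0(u) = (q(u+a) - 1)/u,
    Q_m(u) = q(u+a) (1/u) int_a^{u+a} Q_{m-1}(v)/q(v) dv,

and the output rate solves `h/beta = 1 - a sum_m (-h tau)^m Q_m(-a)`.
The series is divergent (zero radius) whenever excitation dominates —
`h` is a singular perturbation parameter — and is resummed by walking the
zigzag diagonal chain `[m,m] -> [m,m+1] -> [m+1,m+1]` of Padé
approximants until two successive values agree to a relative `delta`
(default `1e-6`). Nonconvergence is a first-class result: it is flagged
and never silently returned.

### Numerical choices

* **Mesh**: uniform with `n_per_a = 200` points per unit of `a`, spanning
  `u in [-3a/2, (M - m)a]` per kernel order (the sub-`-a` margin supports
  moment extraction); removable singularities (`V(v)/v` at 0, `Q_m` at
  `u = 0`) are replaced by their explicit limits, never by mesh offsets.
* **Signed-log arithmetic**: `q` and the kernels span thousands of orders
  of magnitude on the nested mesh (exponents ~1e4 for `mu_e = 3`), so the
  whole kernel pipeline carries sign and log-magnitude arrays.
  Per-interval integrals use exponential-fit quadrature (exact for
  locally exponential integrands, trapezoid across sign changes), and
  cumulative sums use `np.logaddexp.accumulate` on the positive and
  negative parts separately. Low-order coefficients agree with an
  arbitrary-precision quadrature oracle to ~1e-7 relative.
* **Padé tables** are solved with mpmath at 40 significant digits after
  rescaling the terms to `d_m = c_m y^m` (evaluation at 1), because the
  coefficients overflow doubles far below the default order cap
  (`M_cap = 40`). Singular tables are skipped along the chain. When the
  chain settles into a two-cycle whose amplitude is at the
  coefficient-noise level, both interleaved subsequences having
  stabilized is accepted as convergence (value: their average).
  Kernel tables are built lazily at orders 12 -> 24 -> 40, since the
  chain typically stops near order 10 and table cost is quadratic in the
  order.
* **Moments**: `M_n(x)` are derivatives of `L` at 0, extracted by a
  degree-`n_max + 4` least-squares polynomial fit on the window
  `[-a/2, a/2]` of the *cumulant* generating function `ln L` (far closer
  to a low-degree polynomial than `L` when the mean drift is large;
  cumulants are then converted to raw moments). Intensity moments use
  the exact identity `M_n(lambda) = h^n E[e^{n a x}] = h^n L(n a)`,
  evaluating the resummed profile directly — this is the fully summed
  form of the series `h^n sum_k (a n)^k / k! M_k(x)`; a truncated-series
  variant driven by the fitted moments is kept as a diagnostic
  (`lambda_cutoff`), but fitted moments beyond small `k` amplify fit
  noise by `(2/a)^k k!` and are not usable quantitatively.

## Exact simulation

`rmfnet.simulate` samples the finite network's continuous-time Markov
chain exactly by Ogata thinning with the piecewise bound
`sum_i h_i exp(a_i max(x_i, 0)) + (total external rate)`, valid until the
next accepted event because `|x_i|` decays monotonically between events.
At a spike the spiking neuron resets first, then targets receive their
jumps; the recorded post-spike value is 0. The mean background drive
`c_i` is realized as a discrete Poisson stream of weak excitatory jumps
(`mu_bg = 0.1` by default, i.e. 15 kHz of events for a 1.5 kHz drive),
matching a dense cloud of weak synapses; the RMF engine treats the same
drive as the exact linear term `c u` in `V`. Both descriptions coincide
as `mu_bg -> 0`; at `mu_bg = 0.1` the residual discreteness is well below
Monte-Carlo resolution in the comparisons we run. Inner loops are
numba-compiled; every chunk draws all randomness (waiting times, thinning
uniforms, routing addresses) from one seeded generator in a fixed order,
so runs are exactly reproducible from their seed.

The R-replica simulator implements randomized routing: each delivery from
a spike of `(j, r)` picks an independent uniform replica per postsynaptic
type. Pooled deliveries to a fixed unit pass a Poisson dispersion test at
moderate R, which is the mechanism behind the Poisson hypothesis.

## Network solver

`rmfnet.solver` iterates the full rate vector through the rate-transfer
map (`beta <- F(beta)`, optional damping). Neurons that are exchangeable
by a transposition fixing everyone else (identical parameters, in- and
out-weights) are merged into clusters, and `F` is evaluated once per
cluster with channel multiplicities as rate multipliers — the two-group
circuit reduces from `K` neurons to 4 clusters at any size. Within-group
excitatory multiplicity is `n - 1` (no autapse); only excitatory clusters
carry self-coupling.

Naive iteration is locally convergent (rate-transfer functions are weakly
sublinear at large rates) but its contraction ratio approaches 1 near the
pitchfork bifurcation (~400 iterations at `mu_e = 1.7`). The solver
therefore wraps the naive map in short-memory Anderson mixing, engaged
only once the residual history contracts cleanly and geometrically —
before that the iterate may still be escaping an unstable symmetric
fixed point along its unstable manifold, and a Newton-like accelerator
would converge onto the saddle. Found fixed points are classified by the
spectral radius of the finite-difference Jacobian of `F` (cluster space);
saddles are discarded and re-seeded along their unstable eigenvector so
the flanking stable solutions are always recovered. `find_solutions`
starts from `beta_0 = h + eps` with two deterministic group-biased starts
plus uniform random ones, and merges limits within relative distance
`1e-3` (iteration tolerance `5e-6` relative keeps fixed-point error well
below that threshold).

## Baselines

* **Linear Hawkes**: stationary rates solve `beta = h + diag(tau) W beta`
  (nonnegative weights only); the RMF intensity variance follows
  Campbell's formula `V[lambda_i] = (tau_i/2) sum_j mu_ij^2 beta_j`.
* **No-reset first order**: `beta = h exp(sum_j beta_j w_j + c tau a)`
  with effective weights `w_j = tau int_0^a (e^{mu_j v} - 1)/v dv`
  (`w_j -> tau mu_j a` for weak synapses). This is exactly the `M = 0`
  truncation `h/q(0)` of the resolvent series and is valid while
  `beta tau << 1`.
* **TMF approximations**: the input stream is replaced by its
  deterministic mean drive `D = sum_j beta_j mu_j + c`. With relaxation,
  `x` follows `x' = -x/tau + D` from 0 after each reset, making the
  dynamics a renewal process: `beta = 1/int_0^inf S(t) dt` and
  `E[x^n] = beta int x(t)^n S(t) dt` with survival
  `S = exp(-int lambda)`. The survival integral runs on a grid of
  `tau/200` up to `25 tau`, with the constant-hazard tail beyond the
  drift plateau handled analytically. The no-relaxation variant uses
  `x = D t` (divergent, and reported as such, for `D <= 0`); the
  high-rate closed form is `beta = aD / ln(1 + aD/h)`.

The TMF construction deliberately erases input variability; comparing its
`Std(x)` with the RMF value quantifies finite-size effects (about
seventeenfold underestimation for 7 inhibitory channels at total drive
-20, about twofold for the excitatory mirror case).

## Metastability toolkit

The two-group cross-inhibition circuit turns bistable above a critical
excitatory weight; in the RMF limit the transition appears as a pitchfork
of the self-consistent rate system. The bifurcation observable
`Delta = (sum of up-state rates - sum of down-state rates) / (total)`,
computed per (Exc, Inh) cluster pair, is 0 for the symmetric solution and
approaches 1 at strong silencing; by construction it lies in `[0, 1]`.
Phase diagrams evaluate `Delta` cell-by-cell; the critical-weight scaling
study bisects `mu_e` (co-varying `mu_i = -5 mu_e` and the background
drive `1500 mu_e` Hz, i.e. 1000 synapses at 15 Hz with
`mu_TMF = mu_e/10`) to the smallest value with `Delta > 0.01`. Because
the bistable band is an interval in `mu_e` whose top shrinks with `K`
(up-state drives leave the resummable regime), the onset search scans a
geometric grid upward before bisecting rather than escalating a failed
upper probe.

Simulated dominance periods are segmented with a 2-state Gaussian-emission
HMM (hmmlearn, EM with quantile initialization and fixed seed, Viterbi
decoding) on the Exc-cluster mean of `x` sampled at 1 ms — the
lowest-variance scalar summary of group dominance; label runs shorter
than `5 tau` are merged (debounce). Degenerate fits (one state empty, or
means closer than half the summed stds) are reported as monostable. When
conditioning statistics on the state, samples within 0.25 s of a label
change are excluded: boundary samples mix the two states and would
contaminate a ~1 Hz down-state rate with a ~40 Hz up-state one.

Transition times are predicted from RMF moments alone: the equal-weight
two-Gaussian mixture of the up/down conditional `(mean, std)` of the
group-mean observable defines an effective potential `U = -ln p` (unit
effective temperature), and the standard overdamped double-well estimate
`T = 2 pi / sqrt(U''(well) |U''(barrier)|) exp(U(barrier) - U(well))`,
scaled by `tau` as the attempt timescale, gives the escape time per
direction. The absolute scale of this one-dimensional heuristic is not
meaningful — predicted times exceed simulated ones by orders of
magnitude — but it rank-orders the simulated transition times across
coupling strengths (Spearman > 0.9 on a 3x3 grid of
`mu_e in {1.2, 1.3, 1.4}`, `mu_i in {-4, -6, -8}`).

## What the tests do and do not show

The package's master oracle is exactness for feedforward neurons: for a
single neuron under true Poisson drive the event-driven simulation and
the RMF calculation describe the same process, and the suite verifies
rate, `E[x]`, `Std(x)` and `Std(lambda)` agree to 3 Monte-Carlo standard
errors across excitatory and inhibitory sweeps. For recurrent networks
the RMF limit is an approximation that neglects activity correlations;
agreement there (bistable conditional moments, inhomogeneous-network
rates) is a property of the regimes tested — strong recurrent inhibition
or dominant feedforward structure — not a general guarantee.

Problem sizes in the test suite and acceptance script are scaled to run
in minutes on one core as the package's own default protocols: the
estimator-precision experiment uses the printed 32x400-event protocol
unchanged; oracle sweeps use 8 repeats of 2500 events (or 400 s for
near-silent inhibitory points); the bistable comparison uses 6 repeats of
8 s; the scaling study uses K = 24..240 with onset bisection to 2%
relative; the transition-time grid uses 30 s per cell. Larger runs
tighten the Monte-Carlo bars but do not change any qualitative outcome.

## Known limitations

* Rate-transfer evaluations can genuinely fail to converge (flagged, per
  the convergence-region structure of the resummation); network solves
  propagate the failure with the offending neuron rather than guessing.
* The critical-scaling exponent measured over K = 24..240 is -0.39,
  slightly flatter than -1/2, with local slopes steepening toward small
  K; the fitted value depends mildly on the K window.
* The Kramers predictor's absolute timescale is heuristic (see above);
  only orderings should be interpreted.
* The cluster reduction requires exact exchangeability; nearly-symmetric
  networks must be solved at full size.
* Conductance-based coupling, propagation delays, and synaptic adaptation
  are outside the model class.
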