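# Methods

## The model

`presynmc` simulates the first stages of presynaptic transmission in a
well-mixed compartment as a discrete-state, discrete-time Markov process.
Two kinetic schemes are built in:

**Voltage-dependent calcium channel (VDCC), 5 states.** A linear chain
C0 ↔ C1 ↔ C2 ↔ C3 ↔ O with Hodgkin–Huxley-style exponential voltage
dependence per step,

    α_i(V) = α_i° · exp(+V / V_αi)      (forward, grows with depolarization)
    β_i(V) = β_i° · exp(−V / V_βi)      (backward, grows with repolarization)

The sign convention is encoded per edge: a `voltage_exp` rate law stores a
*signed* voltage scale, positive for α-type and negative for β-type edges,
so that channels open on depolarization and close on repolarization. The
default constants (α°, β° in 1/s, V scales in mV) are the calyx-type P/Q
channel gating parameters of Bischofberger & Jonas (2002), as used in the
MCell presynaptic reconstructions of Nadkarni et al. (2010) and Bartol et
al. (2015); they ship as a versioned YAML file
(`src/presynmc/data/vdcc5.yaml`). Nothing in the engines, oracles, or
benchmarks depends on the specific values.

**Calbindin-D28k buffer, 9 states.** Four binding sites — two high-affinity
(H) and two medium-affinity (M) — give a 3×3 occupancy grid HaMb,
a, b ∈ {0, 1, 2}, with 24 edges. Association edges are first order in free
calcium (`mass_action` laws, 1/(M·s)); dissociation edges are constant
(1/s). Statistical multiplicity for two identical sites is applied by the
builder (2× on-rate for the first site bound, 1× for the second; 1× off-rate
from single, 2× from double occupancy), so that with independent sites the
grid satisfies detailed balance and has the product-form equilibrium

    P(a, b) = C(2,a) θ_H^a (1−θ_H)^{2−a} · C(2,b) θ_M^b (1−θ_M)^{2−b},
    θ = c / (c + K),  K = k_off / k_on.

Default per-site rates are the Nägerl et al. (2000) constants
(`src/presynmc/data/calbindin9.yaml`): k_on = 1.1×10⁷ /M/s, k_off = 2.6 /s
(high); k_on = 8.7×10⁷ /M/s, k_off = 35.8 /s (medium).

**One-step transition matrix.** For timestep Δt (default 1 μs) the matrix is
P_ij = k_ij(env)·Δt on each edge, P_ii = 1 − Σ_j P_ij, zero elsewhere.
Adjacency is the scheme's edge list, so the same operation serves the
channel chain and the buffer grid. The construction is valid only while
every row's exit probability stays below 1; violating that raises an error
reporting the offending state and the largest admissible Δt. It is never
silently renormalized, because renormalization would change the stochastic
process. Time-varying drivers (voltage, calcium) are held piecewise-constant
within a step.

## The four engines

All engines advance the same occupancy vector under the same matrix:

- **standard** — discrete inverse-transform sampling: one uniform per
  particle per step, mapped through the cumulative partition of its row.
  Exactly n draws per step; time O(b·n·t); per-particle semantics.
- **multinomial** — one multinomial draw per *occupied* state per step
  distributes that state's n_i particles over its destinations
  (X_i ~ Multi(n_i, P_i·)). Summing per destination gives the next
  occupancy. Identical in law to the standard engine (multinomial thinning
  of i.i.d. categorical draws) at O(b·s·t) time, independent of n.
- **gaussian** — the stochastic-ODE / AWGN approximation: deterministic mean
  update x′ = xP plus zero-mean normal noise per state, s draws per step.
  The per-state spread is taken as sqrt(n_i(n−n_i))/n · scale (default
  scale 1): the literal variance-units form n_i(n−n_i) is dimensionally
  inconsistent as a standard deviation, so the square-root form — which
  preserves the boundary behavior (no noise at n_i = 0 or n) — is the
  default, with the literal reading available via `literal_variance=True`.
  Results are clamped to [0, n] and renormalized to conserve the total;
  clamp events are tallied because their frequency is the observable
  signature of the central-limit approximation failing at small n (common
  at n = 5, < 10⁻⁴ per state-step at n = 10⁵).
- **ode** — deterministic forward Euler through the same matrix, x′ = xP;
  zero random draws.

**PRNG accounting.** Every run carries exact draw counters by category. The
multinomial convention: a multinomial over m possible outcomes costs m − 1
binomial component draws (the last bucket is fixed by conservation), i.e.
b_i per occupied state and at most Σ_i b_i = |edges| ≤ b·s per step. This
makes the worst-case bounds b·s·t (10⁵ for the channel case, 3.6×10⁵ for the
buffer case at t = 10⁴) testable contracts, alongside the exact n·t law of
the standard engine. Unoccupied states cost nothing.

**Seeding.** A single base seed; ensemble runs derive per-run generators via
`numpy.random.SeedSequence(base).spawn(n_runs)`, making ensembles
bit-reproducible.

## Calcium coupling

The coupled cascade (`run_presynaptic_cascade`) joins the two schemes
through one integer pool of free calcium in the canonical 0.5 × 0.5 × 4 μm
box (10⁻¹⁵ L). Defaults: 65 channels all starting in C0, 45 μM calbindin
(2.71×10⁴ molecules), 100 nM resting free calcium, 10 ms horizon at 1 μs
steps.

- **Influx.** Each open channel admits ions at a GHK-flux rate
  k_Ca(V) = p_s·N_A·u·([Ca]ₒ − [Ca]ᵢe^u)/(e^u − 1), u = zFV/RT, with
  single-channel permeability p_s = 10⁻¹⁶ L/s (≈ 0.2 pA at −70 mV, 2 mM
  external calcium — a physiological single-channel scale; the literature
  I–V parameterizations vary, so this is the package's own choice). Entries
  per step are Poisson(open·k_Ca·Δt), drawn as one variate. Outward flux is
  clipped at zero; efflux pathways (pumps) are out of scope.
- **Operator splitting**, fixed per step: (1) channel transitions under the
  instantaneous voltage, (2) influx through the now-open channels, (3)
  buffer transitions against the updated pool. At 1 μs steps the splitting
  error is second order and negligible against sampling noise.
- **Exact ledger.** Buffer transitions are sampled as per-edge flows, so
  each binding/unbinding event moves exactly one ion. If sampled binding
  demand exceeds the pool (vanishingly rare at 1 μs), excess events are
  cancelled in randomized edge order and those molecules stay put. The
  invariant free + bound − cumulative influx = initial holds as an exact
  integer identity at every step of every stochastic run.
- The **gaussian** engine is not accepted in the coupled cascade: it does
  not produce integer per-edge events, so the exact ledger cannot be kept.
  A deterministic mean-field cascade (`engine="ode"`) is provided, with a
  real-valued ledger conserved to floating-point accuracy.
- **Buffer initialization**: molecules are placed at the product-form
  equilibrium of a configured calcium level (largest-remainder rounding by
  default, multinomial sampling optionally). The initialization level can
  differ from the pool's starting concentration to study the buffering of a
  calcium bolus by resting calbindin.

## Stimulus

The action-potential template is a difference of exponentials,
A·(e^(−t′/τ_fall) − e^(−t′/τ_rise)) after onset, normalized to the requested
peak. Defaults: rest −70 mV, peak +30 mV, onset 1 ms, τ_rise 0.2 ms,
τ_fall 0.5 ms, 10 ms at 1 μs — a ~1 ms-wide spike typical of hippocampal
boutons. No published waveform is reproduced; only the qualitative response
(channels open around the voltage peak and close on repolarization) is
meaningful. Arbitrary two-column time/voltage files are loaded with linear
resampling to the simulation step.

## Validation strategy

Because particles are independent and identically distributed given the
environment, the single-particle chain law is an exact oracle: the state
distribution after T steps is p₀·Pᵀ (matrix power). The test suite and the
`validate` subcommand compare empirical occupancies from both stochastic
engines against it by chi-square (α = 0.01) on 2-, 5-, and 9-state schemes
with 10⁴ replicates, compare the engines against *each other* by two-sample
chi-square over 1,000-run ensembles, check the multinomial ensemble mean
against the Euler trajectory (within 4 standard errors per timepoint), and
check Euler itself against the two-state analytic relaxation
(½ + ½e^(−2kt), < 1% at 1 μs steps). For very small systems (n ≤ 8, s ≤ 4)
the full joint occupancy distribution is enumerated exactly and compared to
engine frequencies. Oracles are restricted to frozen-environment windows;
time-varying runs are validated piecewise.

## What the built-in conditions do and do not show

The default conditions reproduce the canonical study setting: a single
action potential, 65 channels, 2.7×10⁴ buffer molecules, 10⁴ steps of 1 μs,
ensembles of 1,000 runs. Passing tests demonstrate correctness of the
sampling laws, the complexity/draw-count claims, and the qualitative
physiology (C0 emptying and recovering, transient C1–C3 humps, open-state
peak tracking the voltage peak, non-decreasing influx, near-complete
buffering of free calcium with a small fully-bound plateau). They do not
calibrate absolute transient amplitudes against experimental recordings:
the influx parameterization and AP waveform are generic, the compartment is
spatially unresolved (no diffusion, no channel–sensor distance), and pumps,
calcium sensors, and release machinery are absent by design.

## Numerical choices and problem sizes

- Row-stochasticity is asserted to 10⁻⁹ additive tolerance on entry to every
  engine step; matrix construction guarantees 10⁻¹² internally.
- Deterministic trajectories conserve mass to < 10⁻⁹ over 10⁴ steps.
- Chi-square tests merge bins with expected count < 5.
- Draw-count benchmarks run the population engines in full; the
  constant-draw-per-step engines (standard: n/step, gaussian: s/step) are
  measured on a 200-step window and scaled exactly by the step ratio, which
  is an identity, not an approximation — the records carry
  `extrapolated=True`. The scaling experiment uses n ∈ {10², 10³, 10⁴} over
  10³ steps.
- The acceptance script and test ensembles use 1 ms windows where only
  per-timepoint statistics are needed, and the full 10 ms / 10⁴-step runs
  wherever a claim is about an entire trajectory (conservation, ledger,
  transient shapes).

## Known limitations

- Well-mixed compartment only; no spatial gradients or diffusive kernels.
- No PMCA pumps, calcium sensors, or vesicle release; the cascade ends at
  buffered calcium.
- The Gaussian engine is an approximation by construction and is excluded
  from the exact-ledger cascade.
- Fixed-timestep formulation throughout; no event-driven (Gillespie-style)
  exact-time sampling. The timestep validity check makes the tradeoff
  explicit rather than hiding it.
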