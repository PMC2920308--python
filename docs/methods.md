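# Methods

## Model

The network has three conserved signaling species. Species *i* carries
`x_i` inactive and `x_i*` active copies with `x_i + x_i* = x_i⁰` fixed; all
active counts start at zero. A constant stimulus `x₀` (never consumed — all
activators act catalytically) drives four irreversible mass-action channels:

    A :  x₀ + X3  → x₀ + X3*      a_A  = k_a  · x₀  · x₃
    B1:  x₀ + X1  → x₀ + X1*      a_B1 = k_b1 · x₀  · x₁
    B2:  X1* + X2 → X1* + X2*     a_B2 = k_b2 · x₁* · x₂
    B3:  X2* + X3 → X2* + X3*     a_B3 = k_b3 · x₂* · x₃

Channels A and B3 both produce X3*, joining the one-step (type A) and
three-step (type B) pathways in a loop. There is no degradation, synthesis,
or reversibility; each species can fire at most `x_i⁰` activation events, so
every cell reaches an absorbing fully-determined end state. Units are
dimensionless counts and an arbitrary simulation time unit; rate constants
are per activator copy per substrate copy per time.

Structural assumptions (enforced as validator *warnings*, since zeroing
constants to isolate one pathway is a supported use): `k_b2 ≪ k_b3` (the
slow–fast combination that makes type B all-or-none) and `k_b1 > k_a` (the
entry step must outrun the direct pathway so weak stimuli engage the cascade).

## Regime classification

Comparing the type A coefficient `k_a·x₀` against the type B coefficient
`k_b3·x₂*` — with the early-time approximations `x₁* ≈ x₁⁰` (the entry step
is fast) and `x₂*` replaced by its stochastic activation scale
`√(k_b2·x₁⁰·x₂⁰)` (evaluated at unit time, as the coefficient comparison
implies) — gives the two thresholds used by `classify_regime_analytic`:

* type A dominates at all times when `x₀ > k_b3·√(k_b2·x₁⁰·x₂⁰)/k_a`;
* type B dominates from the beginning when `x₀ < k_b2·x₁⁰·x₂⁰/(k_a·x₃⁰)`.

Between them the response is MIXED, kept as an explicit third label rather
than forcing a binary call. When `k_a = 0` both thresholds are unbounded and
every stimulus is TYPE_B. If an (unphysical) parameter set makes the bounds
cross, the type A relation is checked first, preserving monotonicity of the
label in `x₀`. These are order-of-magnitude boundaries, not sharp
transitions: simulated pathway dominance a factor ~2 beyond a threshold is
still partial (see *Pathway attribution* below).

## Exact stochastic simulation

`simulate_cell` implements the Gillespie direct method: waiting time
`τ ~ Exp(a₀)`, channel chosen with probability `a_c/a₀`, chosen here over
first-reaction or tau-leaping variants because the network has only four
channels and the oracle tests require exactness. States are sampled
piecewise-constant onto a user grid (the value at grid time τ is the state
immediately after the last event at or before τ); the simulation ends early
at the absorbing state and remaining grid points copy it. Propensities are
computed in double precision over integer states. Event counts per cell are
bounded by the totals (≤ Σ x_i⁰ events), which keeps even 2·10⁴-replicate
oracle runs cheap without approximate accelerations.

Populations derive per-cell seeds as
`SeedSequence(master_seed, spawn_key=(cell_id,))`, making ensembles
reproducible and order-independent; identical seeds give bitwise-identical
trajectories. Cumulative per-channel firing counters ride along in the state,
giving exact conservation identities (`x₃* = fireA + fireB3`, etc.) and exact
pathway attribution.

The one-step subnetwork admits a closed-form master-equation solution used as
an independent oracle: with a constant catalytic activator each substrate
copy converts independently at hazard `k·x₀`, so the activated count at time
t is Binomial(n, 1 − e^{−k·x₀·t}).

## Chemical-Langevin treatment

The diffusion approximation assigns each channel drift `−r` on its consumed
(inactive) abundance and an independent Gaussian noise of amplitude `√r`
(Itô interpretation, as obtained from the master equation via Fokker–Planck);
y₃ receives both the A and B3 contributions. The relative noise on a channel
is `√r/r = 1/√r`: for the one-step channel `1/√(k·x₀·y₃)`, which stays
order-one at small rate constants regardless of copy number — the model's
central point about noise at large molecule counts.

`euler_maruyama_ensemble` integrates the coupled system explicitly with
independent `N(0, dt)` increments per channel and *reflecting clamps* onto
`[0, total]` after every step (boundary handling is otherwise unconstrained;
clamping preserves positivity and conservation). The default step is
`dt = 0.01/(k_b3·max total)`, an order of magnitude below the fastest
per-molecule hazard; a validator warns when a user-chosen dt is coarse.

The one-step equation `dx = −k_eff·x dt + √(k_eff·x) dW` (`k_eff = k·x₀`)
linearizes under `u = √x` to an Ornstein–Uhlenbeck equation
`du = −(k_eff/2)u dt + (√k_eff/2) dW`, dropping the Itô correction
`−k_eff/(8u) dt`, which is O(1/x) relative to the drift. `one_step_analytic_path`
integrates the OU part *exactly* between grid points
(`u' = u·e^{−k_eff Δ/2} + η`, `η ~ N(0, (1 − e^{−k_eff Δ})/4)`, the exact
covariance of the stochastic convolution) and returns `x = u²` clamped onto
`[0, x_init]`. The dropped correction is not assumed negligible: the tests
compare the analytic ensemble against the Euler–Maruyama ensemble (10⁴ paths,
`k_eff·dt = 10⁻³`) and the observed moment discrepancies are 2–4%, within
the 5% band asserted.

## Population analysis

* **Activation times** — first grid time with `x₃* ≥ θ·x₃⁰`; θ = 0.5 defines
  an "activated cell" for the population fraction n/N (the trajectory
  normalization gives no printed cut; half-maximum is the natural choice).
* **Moments** — cross-cell mean and unbiased (ddof = 1) variance per record
  time; Fano = variance/mean, reported as *missing* (NaN, not 0 or ∞) where
  the mean is zero.
* **Sharp-rising estimates** — treating each cell as fully off or on:
  mean = (n/N)·x₃⁰, second moment = (n/N)·(x₃⁰)², hence
  variance = (n/N)(1 − n/N)(x₃⁰)² and Fano = (1 − n/N)·x₃⁰. Only the
  Fano > 1 bound and the linear x₃⁰ scaling are asserted in tests; the
  formula's time direction (Fano falls as n grows) is reported as-is, and
  the empirical Fano is computed independently rather than inferred from it.
* **Snapshots and modality** — equal-width histograms of x₃* over
  `[0, x₃⁰]` (default 20 bins). Modality is a transparent threshold-mass
  rule rather than a kernel-density or dip test: with p_low the mass below
  0.1·x₃⁰ and p_high above 0.9·x₃⁰, a snapshot is *bimodal* when both tails
  hold ≥ 0.05 and together ≥ 0.8; *unimodal_low/high* when one tail alone
  holds ≥ 0.8; else *transitional*. Adequate and exactly testable for
  all-or-none distributions; cutoffs are arguments.
* **Pathway attribution** — pooled `Σ fireA / Σ(fireA + fireB3)` from the
  event counters, an operational stand-in for "which pathway dominates";
  the empirical phase-diagram label uses cuts ≥ 0.9 (TYPE_A) / ≤ 0.1
  (TYPE_B).

## Study conditions, what holds where, and problem sizes

The base preset pins totals 100/100/100, `k_a = 10⁻⁵`, `k_b3 = 1` (the
values behind the 10⁵/10³ thresholds), with the documented choices
`k_b1 = 1` (only `k_b1 > k_a` is constrained; equal to k_b3 keeps one fast
scale) and `k_b2 = 10⁻⁴` (mid-range of the slow-constant sweep axis). The
stimulus presets weak/intermediate/strong (50, 5·10⁴, 2·10⁵) are placed by
the analytic thresholds — below, between, above.

A measured subtlety worth stating plainly: sharp all-or-none activation and
the resulting bimodal snapshots require the *aggregate* slow-step rate
`k_b2·x₁⁰·x₂⁰` to sit far below the per-molecule fast hazard `k_b3`. At the
base `k_b2 = 10⁻⁴` with 100×100 molecules the aggregate slow rate is 1.0 =
k_b3, so onset and rise share one time scale: the weak preset shows strongly
super-Poissonian variability (Fano 8–30 through mid-activation) but a
*transitional*, not bimodal, half-activated snapshot, and a spread/rise
ratio near 1.7. One hundred times deeper in the type B regime
(`k_b2 = 10⁻⁶`, `x₀ = 5`) the canonical phenomenology is fully developed —
spread/rise ≈ 10², outer-decile mass ≈ 0.98, and the modality sequence
unimodal_low → bimodal → unimodal_high with crossing peaks — and that is the
parameter set the all-or-none and bimodality property tests use. Similarly,
pathway attribution at `x₀ = 2·10⁵` (2× the type A threshold) is ~0.85–0.88
rather than ≈ 1: the threshold is an order-of-magnitude boundary, and full
(≥ 0.99) dominance appears a decade beyond it, as the phase-diagram tests
exercise at `x₀ = 10⁶`.

Default problem sizes — 100-cell populations on 151–201-point grids, 200
cells for the k_b2 sweep, 2·10⁴ replicates for the master-equation oracle,
10⁴ paths for the CLE cross-checks — keep every statistic's sampling error
well inside its asserted tolerance while the whole suite stays cheap; event
counts per cell are bounded by the totals, so these sizes run in seconds.

## What the simulations do and do not show

All data are generated by the model itself; there is no external data path.
The simulator demonstrates the *mechanism* — a slow stochastic step followed
by a fast one yields all-or-none activation with large cell-to-cell
variability, switching to deterministic response under strong stimuli — in a
network whose species are effective groupings, not individual proteins.
Passing tests say nothing about rate-constant values in real apoptotic
cells, about time-varying or noisy stimuli (x₀ is constant), about
degradation/synthesis or reversible steps (absent by design), or about
extrinsic variability in initial copy numbers (totals are identical across
cells; real populations vary them, which would widen the distributions
further).

## Known limitations

* The CLE integrator is first-order (Euler–Maruyama with reflecting clamps);
  no Milstein or higher-order schemes, and clamping slightly biases paths
  that graze the boundaries.
* The analytic one-step path drops the O(1/x) Itô correction; its moments
  are validated against the CLE integrator, not exact for small x.
* The modality classifier is tuned to all-or-none shapes; it will call a
  broad central distribution "transitional" rather than counting modes.
* `phase_diagram_scan` re-simulates every grid cell; large grids scale
  linearly in cells × grid points.
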