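# minsig — minimal two-pathway stochastic signaling network simulator

`minsig` simulates and analyzes a four-reaction minimal model of
stimulus-driven cell signaling whose response switches from deterministic to
stochastic as the stimulus weakens — the behavior seen in apoptosis (programmed
cell death) signaling, where strong death stimuli kill cells quickly and
uniformly while weak ones produce slow activation with large cell-to-cell
variability. It is written for systems biologists who want an exact, seeded,
scriptable sandbox for studying that transition: single-cell trajectories,
population distributions, Fano factors, and phase diagrams, all from the
command line or Python.

## The model

Three signaling species X1, X2, X3 start fully inactive (totals x₁⁰, x₂⁰,
x₃⁰); a constant external stimulus x₀ drives four irreversible mass-action
activation reactions, each catalytic in its activator:

| channel | reaction            | propensity          |
|---------|---------------------|---------------------|
| A       | x₀ activates X3     | k_a · x₀ · x₃       |
| B1      | x₀ activates X1     | k_b1 · x₀ · x₁      |
| B2      | X1\* activates X2   | k_b2 · x₁\* · x₂    |
| B3      | X2\* activates X3   | k_b3 · x₂\* · x₃    |

Channel A is the one-step *type A* (deterministic) pathway; B1→B2→B3 is the
fast–slow–fast *type B* (stochastic) pathway; both converge on activated X3,
joining the pathways in a loop. With k_b1 > k_a and k_b2 ≪ k_b3, a strong
stimulus activates X3 rapidly through A, while a weak one funnels through the
slow step B2: activation becomes a rare event per cell, followed by an abrupt
fast completion — all-or-none activation with a bimodal population
distribution of X3\*.

Two closed-form thresholds separate the regimes: type A dominates at all
times when x₀ > k_b3·√(k_b2·x₁⁰·x₂⁰)/k_a, and type B dominates from the
start when x₀ < k_b2·x₁⁰·x₂⁰/(k_a·x₃⁰). With the built-in base parameters
(totals 100, k_a = 10⁻⁵, k_b1 = k_b3 = 1, k_b2 = 10⁻⁴) these evaluate to
1 × 10⁵ and 1 × 10³.

The package provides:

* **exact Gillespie SSA** (direct method) for single cells and seeded
  populations, with per-channel firing counters;
* **chemical-Langevin integration** (Euler–Maruyama, plus an exactly
  integrated solution of the one-step equation via the square-root change of
  variable) — notable because the relative noise 1/√(k·x₀·x) is set by the
  *rate*, not the copy number, so fluctuations persist at large molecule
  counts;
* **population analysis**: first-passage activation times, cross-cell
  moments and Fano factor (variance/mean), sharp-rising (all-or-none) moment
  estimates, snapshot histograms with a modality classifier, pathway
  attribution, and a (k_b2, x₀) phase-diagram scan.

## Worked example

Simulate 100 cells under a weak stimulus (x₀ = 50, firmly below the type B
threshold of 1000) and summarize the population:

```sh
$ minsig simulate --preset weak --cells 100 --seed 7 --t-max 10 --records 201 --out weak.tsv
minsig: wrote 100 cells to weak.tsv
$ minsig analyze weak.tsv --out summary.tsv
minsig: pooled channel-A attribution = 0.0012
```

The attribution line says that only 0.12% of X3-activation events went
through the deterministic channel A — this population signals almost purely
through the stochastic type B cascade. The summary table holds per-time
cross-cell moments:

```
 time  mean    variance      fano  fraction_activated
  1.0 28.16  774.499394 27.503530                0.32
  1.5 47.75 1224.391414 25.641705                0.57
  2.0 65.83 1161.233434 17.639882                0.76
```

A Fano factor of ~26 while half the cells are past half-activation is far
above the Poisson value of 1: cell-to-cell variability, not molecular
shot noise, dominates. A phase-diagram scan compares the analytic thresholds
against simulated pathway dominance:

```sh
$ minsig sweep --k-b2-grid 1e-5,1e-4 --x0-grid 10,1e6 --cells 50 --t-max 500 --seed 1 --out phase.tsv
$ cat phase.tsv
k_b2    x0         analytic  empirical  attribution
1e-05   10.0       TYPE_B    TYPE_B     0.002
1e-05   1000000.0  TYPE_A    TYPE_A     1.0
0.0001  10.0       TYPE_B    TYPE_B     0.0004
0.0001  1000000.0  TYPE_A    TYPE_A     0.988
```

The same machinery is available as a library (`minsig.simulate_population`,
`minsig.ensemble_moments`, `minsig.phase_diagram_scan`, ...); `minsig sde`
runs the chemical-Langevin integrator through the identical TSV schema.

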