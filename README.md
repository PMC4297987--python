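# catchbond

Kinetic Monte Carlo simulation of **two-state catch bonds** — receptor–ligand
bonds whose lifetime counter-intuitively *grows* with tensile force over a
range before falling — and of adhesion clusters built from them.

Catch bonds (P-selectin/PSGL-1, FimH/mannose, fibronectin/integrin α5β1, …)
are modelled with two bound conformations, a weak and a strong adhesive
state, plus a dissociated state.  Every transition rate follows Bell's law

    k(F) = k0 · exp(F / Fb)

with a sign-carrying force scale `Fb`.  Two built-in designs realize the two
known "catching" strategies: `type1` forms in the weak state and force
drives it into the strong state; `type2` forms in the strong state and force
keeps it there.  Both produce similar lifetime-versus-clamped-force
profiles, but they respond very differently to *time-dependent* loads —
ramps of different rates, load/unload cycles, steady ramps to rupture, and
periodically oscillating forces — which is what this package simulates:

* exact (in distribution) kinetic Monte Carlo for a single bond under any
  piecewise linear/constant/sinusoidal force protocol, with closed-form
  Markov oracles (mean first-passage time, survival function) at constant
  force;
* lifetime statistics in the two conventions used for force-clamp
  experiments (`T0`: all ruptures, timed from force onset; `T1`: pre-clamp
  ruptures excluded, timed from the clamp instant);
* rupture-force spectra, pathway-aware mode counting, bond strength (the
  most likely rupture force of the dominant pathway) versus loading rate,
  and detection of the critical loading rate where the strength jumps;
* a coupled finite-element / Monte Carlo model of an elastic fiber bonded
  to a rigid substrate by 40 receptors with force-history-carrying state
  memory and velocity-suppressed rebinding, under an oscillating load.

See `docs/methods.md` for the model equations, numerical schemes, and
design decisions.

## Worked example

Simulate 2000 lifetimes of a `type1` bond under the classic force-clamp
protocol (ramp at 500 pN/s, clamp at 20 pN):

```bash
$ catchbond simulate single --model type1 \
    --protocol '{"type":"clamp","ramp_rate":500,"clamp_force":20}' \
    --n-reps 2000 --seed 3
{
  "T0_s": 7.844203313849593,
  "T0_se": 0.33819062900856406,
  "T1_s": 10.438769640665933,
  "T1_se": 0.43131093598750286,
  "n_total": 2000,
  "n_excluded_preclamp": 504,
  "switch_probability": 0.4195
}
```

Reading this: 504 of 2000 bonds broke during the 0.04 s ramp and are
excluded from `T1`; the survivors last 10.4 ± 0.4 s at the 20 pN clamp —
near the catch-bond optimum (the same bond lives only ~0.9 s at zero
force, `mean_lifetime_constant_force(builtin_model("type1"), 0.0)` ≈
0.934 s).  42 % of all trajectories visited the strong state before
rupturing.

The same from Python:

```python
from catchbond import (builtin_model, clamp_after_ramp,
                       simulate_ensemble, lifetime_stats)

protocol = clamp_after_ramp(500.0, 20.0)
samples = simulate_ensemble(builtin_model("type1"), protocol,
                            n_reps=2000, seed=3)
stats = lifetime_stats(samples, protocol.clamp_start_time)
print(stats.T1_mean, stats.switch_probability)   # 10.44  0.4195
```

Whole experiments are packaged as recipes (reduced ensembles by default,
`--full` for study scale), each writing a tidy CSV plus a JSON metadata
sidecar:

```bash
catchbond recipe fig1b --out results/      # lifetime vs clamped force
catchbond recipe fig3c --out results/      # strength vs loading rate
catchbond recipe fig8  --out results/      # cluster lifetime vs alpha, f
catchbond recipe --help                    # the full list
```

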