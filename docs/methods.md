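# Methods

## The two-state catch-bond model

A bound receptor–ligand complex is described by two bound conformations —
State 1 and State 2 — plus an absorbing dissociated State 0.  Every
transition rate obeys Bell's law,

    k(F) = k0 · exp(F / Fb),

with a sign-carrying force scale `Fb` (pN): positive `Fb` means the rate
grows with tensile force, negative `Fb` that it is suppressed.  A newly
formed bond always starts in State 1.

Two built-in parameter sets implement the two canonical "catching"
strategies, distinguished by which bound state is mechanically strong:

| transition | type1 (State 2 strong) | type2 (State 1 strong) |
|---|---|---|
| 1→0 | 3.0 /s, +12.0 pN | 0.012 /s, +14.0 pN |
| 2→0 | 0.01 /s, +12.0 pN | 1.0 /s, +4.0 pN |
| 1→2 | 0.02 /s, +3.0 pN | 1.3 /s, −6.0 pN |
| 2→1 | 0.001 /s, −1.0 pN | 0.001 /s, +1.0 pN |

The switching signs encode one principle: **force tilts the 1↔2
conformational landscape toward the strong state.**  For type1 the weak
initial state is driven into the strong State 2 (1→2 accelerated, 2→1
suppressed); for type2 the strong initial state is protected (1→2
suppressed, 2→1 — the rescue back to strength — accelerated).  Under an
instantaneous clamp both designs then produce closely similar catch-bond
profiles, with the mean lifetime rising from ≈1–2 s at zero force to a peak
of ≈9–20 s near 20 pN before decaying — which is the designed behaviour,
and the reason the signs must be as tabulated: flipping the 2→1 sign of
type1 turns it into a monotone slip bond, and flipping type2's moves its
strength jump (below) far from its designed place.

Closed-form constant-force oracles back the stochastic engine: the mean
lifetime from State 1 is the Markov mean first-passage time

    τ1 = (b + c + d) / ((a + b)(c + d) − b·d),

with a = k1→0(F), b = k1→2(F), c = k2→0(F), d = k2→1(F), and the survival
function is the row sum of the 2×2 transient matrix exponential, evaluated
by eigendecomposition (both eigenvalues are real and non-positive; the
exponentials of `μ ± δ` are combined directly so no overflowing
cosh/sinh intermediates appear).

## Force protocols

Deterministic piecewise force histories built from linear, constant and
sinusoidal segments, always continuous and non-negative: instant clamp,
ramp-then-clamp (force-clamp), unbounded steady ramp (force spectroscopy),
peak–unload–clamp, repeated load/unload triangles before a clamp at the
peak (cyclic reinforcement history), and a periodic oscillation about a
homeostatic force.

The oscillating load models a contractile stress fiber that remodels toward
its homeostatic tension F0 at rate γ (1/s, default 10) while a cyclic
substrate stretch of amplitude α and frequency f drives it.  The
first-order relaxation dynamics give the steady periodic force

    F(t) = F0 · [1 + α·β(f)·sin(2πf·t + φ)],
    β = ω/√(ω² + γ²),  φ = arctan(γ/ω),  ω = 2πf,

so slow stretches are absorbed by remodelling (β→0) and fast ones
transmitted in full (β→1), with crossover near f ≈ γ/2π ≈ 1.6 Hz.  The
period average equals F0 exactly.  Construction fails if the parameters
would ever drive F(t) < 0 — silently clamping to zero would change the
kinetics of the unloading phase, which is precisely where type2 switching
happens.

## Kinetic Monte Carlo engine

The default `segment_exact` sampler is exact in distribution.  Within each
constant or linear segment the next event time solves Λ(Δt) = E for a unit
exponential E, where Λ is the total integrated hazard; per-transition
integrals along a linear segment are closed-form,

    ∫ k0 e^{(F0+ṙu)/Fb} du = k0 (Fb/ṙ) e^{F0/Fb} (e^{ṙΔt/Fb} − 1),

inverted analytically when one transition is active and by bracketed Brent
root-finding otherwise.  Because the exponential clock is memoryless, the
variate is redrawn at segment boundaries and after state switches without
bias.  On sinusoidal segments events are drawn by thinning against a
dominating constant rate; the bound is taken over 1/32-period sub-intervals
(each transition bounded at whichever force extreme its `Fb` sign favours),
because with pN-scale force scales (Fb = ±1 pN) rates vary by many orders
of magnitude over one cycle and a whole-cycle bound would reject
essentially every proposal.  At constant force the scheme reduces exactly
to the Gillespie algorithm.

A second, deliberately different `fixed_step` sampler (at most one event
per step, step capped so total rate × Δt ≤ 0.005 by default) is retained
purely as a cross-check; agreement of the two samplers is itself asserted
in the tests.

Ensembles use one `SeedSequence` spawn per replicate, so results are
bit-reproducible for a fixed (seed, n_reps, options) and replicates are
independent.  The censoring horizon defaults to 10⁴ s, far above any mean
lifetime the built-in parameters imply; for clamp protocols a censoring
fraction above 0.1 % is treated as an error because every lifetime there
must be finite.

A note on lifetime dispersion: at its catch optimum (20 pN) the type1
lifetime is a designed *mixture* — about half of bonds die from the weak
state within ~0.03 s, the rest switch and live ~19 s — so its coefficient
of variation is ≈1.7 rather than the 1 of an exponential holding time, and
the relative error of a 10⁴-replicate mean is ≈2 % rather than 1 %.  Type2
at the same clamp is near-exponential (its weak-state excursions are
transient) and shows the textbook 1 %.

## Lifetime conventions and observables

* **T0** — all ruptures counted, timed from force onset.
* **T1** — ruptures before the clamp instant excluded, timed from the clamp
  instant (the convention of force-clamp experiments).
* **switch probability** — fraction of trajectories that ever visited
  State 2 before rupture.  The alternative reading ("in State 2 at
  rupture") was rejected because the cumulative reading is the natural
  meaning of a switching probability and is monotone under nesting of
  observation windows.

**Rupture-force spectra** are 1-pN histograms smoothed by a 3-bin moving
average.  Mode detection treats a mode as a *rupture pathway*: candidate
local maxima (≥3 smoothed counts, ≥3 pN apart) are first merged by a dip
rule (a valley shallower than half the smaller peak does not separate two
pathways), then any basin carrying <0.5 % of all ruptures is absorbed into
its neighbour — a sparse pathway fragmented by sampling noise pools into
one mode, a negligible pathway is not reported.  The 0.5 % floor makes the
count insensitive to ensemble size: at the smallest ensembles used for
mode counting (10⁴–2×10⁴) it corresponds to ≥50 events.  A 10 %-of-maximum
height rule was considered and rejected: at 5 pN/s the type1 secondary
(strong-state) pathway carries ≈1 % of ruptures spread over ~40 pN, so its
peak height is ~0.1 % of the primary peak, yet it is a real, reproducible
pathway.

**Bond strength** is the modal rupture force of the *dominant* pathway:
basins are split at the smoothed minima between modes and the strength is
the peak of the heaviest basin, refined to sub-bin precision by fitting the
log-counts of the peak region with the extreme-value shape
log p = const + z − e^z, z = (f − μ)/b (exact for a slip bond under a
steady ramp).  For unimodal spectra this is the classic most-likely rupture
force; for bimodal spectra it jumps where the dominant pathway changes.
The raw global density mode was rejected because it compares a narrow
low-force peak against a broad high-force peak by height alone: the type2
low-force pathway then keeps the "strength" pinned near ~5 pN until loading
rates ~4× above the designed critical rate, regardless of bin width.

**Jump detection** reports the geometric mean of the adjacent rate pair
with the largest strength increment, if that increment is ≥5 pN and ≥3×
the median absolute adjacent increment; a pure slip bond's smooth
log-linear rise never qualifies.

With these conventions the critical loading rates come out at ≈350 pN/s
(type1) and ≈9 pN/s (type2) on 10-point-per-decade scans — a separation of
a factor ≈40.  The strength jump marks where bonds stop dying through the
weak-state channel: for type2, the expected number of lethal weak-state
excursions during the low-force transit is ≈6/r, placing the crossover
near r ≈ 6–9 pN/s; for type1 it is where survivors of the weak initial
state first reach the switching region in numbers.

## The adhesion cluster

Geometry is 1-D and axial: n = 40 receptors at spacing l0 = 32 nm on an
elastic fiber (tensional modulus EA = 46 nN), N = 160 ligand sites on a
rigid substrate, left-aligned so 120 free sites extend beyond the loaded
(right) end.  Closed bonds are springs of stiffness k_LR = 0.25 pN/nm; the
external force acts on the rightmost node.  The quasi-static equilibrium is
a tridiagonal solve (rod elements EA/l0 plus bond springs); for a fixed
topology the solution is affine in the applied force, so per-step mechanics
costs O(n) and full solves occur only when a bond breaks or forms.

Kinetics advance by adaptive Bernoulli steps: the step shrinks from the
base dt (0.005 s, and at most 1/50 of the oscillation period) until every
entity's event probability is ≤0.05, with a floor of 10⁻⁷ s; an entity
whose rate outruns even the floor step fires with probability ≈1, which
only occurs during the terminal rupture cascade, where those bonds are
physically gone within nanoseconds anyway.  Closed bonds sample competing
rupture/switch events from their current tension via the same Bell-law
kinetics as a single bond.  Receptors carry their conformational state
across unbind/rebind cycles; a re-formed bond starts in the receptor's
remembered state.  The cluster is dead at the first instant every receptor
is simultaneously open.

**Rebinding.**  An open receptor i rebinds a free ligand j with rate

    k_rebind = k0 · v0/(v0 + |v|) · exp(−k_LR·max(d_ij − l_bind, 0)²/(2 kBT)),

k0 = 0.1 /s, v0 = a/τ0 = 400 nm/s (a = 10 nm, τ0 = 0.025 s), kBT = 4.14
pN·nm.  The velocity factor compares the encounter duration a/|v| with the
intrinsic association time; the Boltzmann factor charges the elastic cost
of forming a bond across the residual gap.  Two deliberate choices:

* the gap d_ij is measured on the **reference lattice** (|i − j|·l0), not
  between elastically displaced positions.  The k_LR springs are a
  mesoscale idealization whose stretch under load (≈40 nm at 10 pN — larger
  than the molecular scale, and larger than l0) is not a physical
  receptor–ligand separation; charging it to the binding reaction would
  make every rebinding rate ≲0.02/s, rebinding would never matter, and
  cluster stability would be insensitive to the relative velocity — whereas
  velocity-suppressed rebinding is precisely the mechanism that makes an
  oscillating load destabilize the cluster.  In practice the lattice decay
  restricts rebinding to the receptor's own site.
* l_bind defaults to the encounter length a = 10 nm (its literature value
  is not fixed by the sources at hand); it is config-overridable and
  recorded in output metadata.

Simultaneous rebinding proposals are resolved in uniformly random receptor
order with ligand exclusivity enforced, so no ligand is ever double-booked.

The production path is a numba-compiled loop (~3 µs/step) with a tridiagonal
Thomas solver; a plain-Python reference stepper with identical dynamics
(different random stream) is kept for unit tests and is statistically
cross-checked against the compiled path.

### What the cluster model does and does not reproduce

At F0 = 400 pN the oscillating load destabilizes both cluster types:
mean lifetime decreases with stretch amplitude α and with frequency f,
saturating once the stress fiber transmits the full stretch (β→1) and
rebinding is strongly velocity-suppressed — all driven by the rebinding
velocity factor, and all reproduced here.  Lifetime distributions in the
marginal regimes are broad (CV near 1), consistent with
fluctuation-driven extinction of a quasi-stationary bond population; the
relative error of the mean from 100 runs is then ~10 %.

The *ordering* of the two types is not reproduced: in this implementation
the type2 cluster generally outlives the type1 cluster at matched
settings.  The mechanism is robust under the tabulated parameters: a type1
receptor must survive a weak-state churn phase (state-1 death ≈7/s at the
10 pN initial per-bond tension, versus switching ≈0.6/s) before the
strong-state ratchet engages, and with the rebinding rate constant
k0 = 0.1/s this initial attrition cannot be repaid, while type2 starts
strong and loses bonds only through transient weak-state flickers
(≈0.1/s per bond).  The per-bond tension (F0/n = 10 pN) and k0 are fixed
by the stated parameters, and uniform load sharing follows from the stated
EA, so no faithful parameter reading was found that flips the ordering;
the corresponding acceptance check is expected to fail and is left
failing.

## Synthetic-data / study-condition defaults

Ensemble sizes follow the study conditions: 10⁴ replicates per force-clamp
point (relative SE of the mean lifetime ≈1 %), 5×10³ per loading-rate
point in strength scans, 100 cluster runs (relative SE ≈10 %).  Grids not
fixed by the sources were chosen once for visibility of the effect and
recorded in recipe metadata: strength scans at 10 points per decade
(10–10⁴ pN/s for type1, 1–10² pN/s for type2); cluster α-sweeps
{0.3, 0.5, 0.7, 0.9} at f = 2 Hz (where lifetimes are finite for all
points within the 2000 s horizon) and f-sweeps {0.25, 1, 2, 4, 8} Hz at
α = 0.6; single-bond oscillation grids at F0 = 20 pN.  Recipes default to
reduced ensembles (2000 single-bond replicates, 20 cluster runs) so each
completes in minutes; `--full` restores study scale.

## Known limitations

* Single-bond rebinding is not modelled (steady-ramp strength therefore
  vanishes at very low loading rates).
* Cluster loads are restricted to constant or single-sinusoid protocols.
* The cyclic-reinforcement saturation scale at peak force 10 pN is
  ~16–24 cycles in this model; over the 0–8-cycle grid the last step still
  contributes ≈20–40 % of the total T1 rise, so a strict "flat by 8
  cycles" check fails even though the reinforcement itself is strong and
  monotone.
* Initial bond-state mixtures other than 100 % State 1 are expressible via
  a custom model but are untested against any quantitative claim.
* Mode counting and jump detection are operationalized heuristics
  (documented above); their thresholds are design choices, not fitted
  quantities.
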