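# Methods

## Model

Cells are cylinders of constant diameter d whose state is (length l, cycle
age a, uptake state q_S).  The population evolves by three mechanisms:

* **Elongation.**  dl/dt = (q_S / Y_SX) · l · (1 − l/l̄)^η, with q_S the
  specific substrate-uptake rate (g substrate per g biomass per hour) and
  Y_SX the substrate-to-biomass yield.  With η close to zero this is
  near-exponential single-cell growth over most of the cycle; the
  (1 − l/l̄)^η factor shuts elongation off smoothly at the hard maximum
  length l̄.  Equivalently, writing the total per-cell uptake
  Q = q_S·ρV(l) with V(l) = πd²/4·l, the law reads
  dl/dt = Q/(ρ V Y_SX) · l · (1 − l/l̄)^η — this per-biomass reading is
  the dimensionally consistent one (a per-cell Q in g/hr divided by ρV
  yields hr⁻¹, not m/hr) and keeps lengthening almost linear in l.
* **Division.**  Length-dependent hazard
  γ(l) = (1/T)·[(l̄−l)^κ − (l̄−l_inf)^κ] / [(l̄−l_c)^κ − (l̄−l_inf)^κ]
  on [l_inf, l̄), zero below the minimal rupture length l_inf, equal to
  1/T at the characteristic length l_c, and (κ < 0) divergent at l̄.  The
  well-posedness condition −κ + η > 1 makes the cumulative hazard along a
  growth trajectory diverge before l̄, so every cell divides at a length
  strictly below l̄.  At division the mother's length is split by a
  fraction x ~ Beta(α, α); daughters' lengths sum exactly to the mother's
  and both daughters restart at cycle age 0.
* **Washout (chemostat only).**  A perfectly mixed vessel at dilution rate
  D removes cells uniformly: each newborn draws a deadline from
  Exponential(mean 1/D) and is removed when its cycle age exceeds it.
  Because the exponential is memoryless, redrawing the clock at each
  division is statistically identical to one residence clock per physical
  trajectory; a per-step removal trial with probability 1 − e^{−D·dt} is
  offered as an equivalent option.

### Baseline parameters

| parameter | value | meaning |
|---|---|---|
| D | 0.15 hr⁻¹ | dilution rate |
| l_inf | 7 µm | minimal length at rupture |
| l_c | 11 µm | characteristic division length (γ = 1/T there) |
| l̄ | 18 µm | maximal length |
| T | 2 hr | division-rate time scale |
| Y_SX | 1/0.42 g/g | substrate-to-biomass ratio |
| τ₁, τ₂ | 25 s, 5 s | uptake adaptation times (dynamic mode) |
| d | 1 µm | cell diameter |
| η | 0.05 | elongation shape exponent |
| κ | −0.96 | division-law exponent |
| α | 20 | Beta kernel concentration (daughter CV ≈ 8%) |

All lengths are metres and times hours internally; the config accepts τ₁,
τ₂ in seconds via `tau1_s`/`tau2_s`.

### The uptake rate and the "auto" calibration

The uptake machinery is modelled as two components relaxing toward Monod
laws, q̇_S1 = (f1(S) − q_S1)/τ₁ and q̇_S2 = (f2(S)f3(q_S1) − q_S2)/τ₂,
with f3 an inhibition factor 1/(1 + q/K_I).  Because τ₁, τ₂ are seconds
while the cell cycle is hours, the uptake state is glued to its
equilibrium at any population time scale; for steady-state work the
package therefore defaults to `qS_mode: constant-saturating`, a single
constant q_S per cell.  (In dynamic mode the relaxation is integrated by
its exact exponential update over dt, since dt is not small against τ₂.)

The numeric value of q_S is not a free stylistic choice.  With uniform
washout the normalized population structure evolves exactly as a closed
culture, so a chemostat admits a steady state **iff** the Malthusian rate
of the kinetic model equals D — in a real vessel the substrate
concentration settles wherever this holds.  `qS: auto` enforces that
self-consistency: the specific uptake rate is root-found so the renewal
eigenproblem (below) has Malthusian rate D (chemostat) or the measured
log-phase growth rate ν_m (batch; default target 0.276 hr⁻¹, the observed
rate for this parameter set).  All other reported statistics — ⟨a⟩,
τ_obs, the divide-again fraction — are then predictions of the model, not
inputs.

## The renewal eigenproblem

A cell born at length x grows deterministically, so along the length axis
the survival against division is exp(−(G(y) − G(x))) with
G(l) = ∫ γ/v dl, and the age accumulated from x to y is A(y) − A(x) with
A(l) = ∫ dl/v.  Discounting each division by e^{−ν·age} and applying the
Beta split defines a positive operator on birth-length densities whose
leading eigenvalue ρ(ν) is decreasing; the population growth rate is the
root ρ(ν) = 1.  At the root, the discounted-offspring integral per
division equals 1/2 — the deterministic form of Powell's
∫ e^{−Da} h da = 1/2.  The operator is discretized on ~1000 length nodes
(linear plus geometric refinement near l̄, where γ diverges but survival
vanishes), and the eigenpair found by power iteration; ρ is accurate to
~1e−4 against a doubled grid.  This model has no sampling error and is
used (a) to calibrate q_S, (b) as an independent oracle for the
Monte-Carlo engine's growth rate and τ_obs.

## Monte-Carlo engine

Struct-of-arrays time stepping at dt = 0.01 hr: Euler for length (the
rates are ≤ ~0.3 hr⁻¹, so the O(dt) bias is negligible; a runtime warning
fires if the 99th percentile of γ·dt exceeds 0.05), division with
probability 1 − e^{−γ(l)dt} per cell per step, washout by deadline.
Lineage bookkeeping follows the convention that one daughter continues
the mother's lineage id and the other opens a new one; `generation_index`
counts recorded divisions along a lineage.  Determinism: a config plus a
seed reproduces the event log bit for bit.

**Chemostat runs** burn in for t_record_start (≥ 5/D recommended; the
slowest relaxation time is 1/D ≈ 6.7 hr at the baseline D) and record
events and hourly snapshots afterwards.  Stationarity is diagnosed from
the drift between the two halves of the recorded count series; because a
calibrated chemostat is a *critical* branching process, its count
fluctuates by a few percent without drifting, so the diagnostic accepts
either a drift below 1% or one within 3 SE of the between-subwindow
Monte-Carlo noise (8 subwindows).

**Batch runs** stop when the population has multiplied by
`growth_factor` (default 100, from 10³ to 10⁵ cells).  Self-similarity is
diagnosed by the Kolmogorov (sup) distance between the scaled age CDFs of
checkpoints a few hours apart, threshold 0.02; a sup-CDF distance was
chosen over a histogram L1 because its noise floor (~0.006 at 2×10⁴
subsampled ages) sits well below the threshold, whereas binned-density L1
noise does not.  The growth rate ν_m is estimated from the count series
by the two-point log formula over the detected log phase (longest
trailing window with a stable local slope of ln N), with a log-linear
regression supplying r².

**Problem sizes.**  Reference statistics use ~3–4×10³ steady-state cells
recorded for ~60 hr (≥ 3×10⁴ division events, giving sub-percent standard
errors on the means) and batch growth to 10⁵ cells; both complete in
seconds, and the estimates are comfortably inside the few-percent bands
the tests assert.

## Analytics on age grids

Densities live on uniform age grids (default span 6·ln2/rate, 2000–20001
nodes); cumulative integrals use the trapezoid rule, and the e^{Da}
weighting in f-from-g is assembled from decaying exponentials of age
*differences*, so no overflow occurs on sane grids (a truncation warning
fires if rate·a_max > 700).  Numerical conventions worth noting:

* The normalization theorem — f built from any normalized g with
  ∫e^{Da} g ≤ 2 carries unit mass — holds on the half-line; on a
  truncated grid [0, A] the identity reads ∫₀^A f + f(A)/D = 1, since
  beyond the support of g the density decays as a pure exponential.  When
  ∫e^{Da} g = 2 exactly (λ = 0), the grid integral itself is 1 to 1e−6.
* A (g, D) pair whose f would go negative (∫e^{Da}g > 2) is *flagged*
  (`meta["steady_state_consistent"] = False`), not raised: measured g's
  are noisy and the flag is the useful diagnostic.
* h_from_g / g_from_h renormalize on the grid and report the
  pre-normalization mass deficit as `meta["consistency_residual"]`; for a
  steady-state-consistent pair it vanishes, and g and h then cross at
  exactly a = ln2/D.
* The λ diagnostic (the limit of e^{Da} f(a), provably ≥ 0 and equal to
  2D − D∫e^{Da}g) is reported as the median of e^{Da}f over the last 5%
  of the grid, never asserted to be zero.
* Moments are always computed from raw samples, never from histograms, so
  they are invariant to binning.  Relation checks use tolerance 1e−6 for
  analytic inputs, ~2% (configurable) for measured/simulated ones;
  inequalities get zero slack on analytic inputs.

## Synthetic data

The generators emulate the study conditions, not real experiments:
clipped-Gaussian initial populations (rejection-sampled truncation —
clamping would put unphysical atoms on the bounds; defaults: length
9 ± 1.5 µm clipped to [2, 16] µm, age 0, erased by burn-in), closed-form
age laws (Dirac, exponential, gamma/Pearson type-III — the shape
historically fitted to interdivision-time histograms — and truncated
Gaussian), and the deliberately mis-attributed datasets: interdivision
times sampled from h but analysed as g.  What passing tests show is
internal consistency of simulator, eigenproblem and closed forms under
the model's assumptions; they do not validate the kinetic laws against
any organism.  Real data additionally carry measurement bias against old
(long) cells, finite observation windows, and mother/daughter
correlations that the independent-Beta kernel deliberately omits.

## Design choices and limitations

* The division hazard depends on length only ("sizer"); adder/timer
  criteria and age-dependent hazards are out of scope.
* Substrate is exogenous: no feedback mass balance for S.  The `auto`
  calibration stands in for that feedback at steady state.
* The uptake state is split at division by an independent symmetric Beta
  on the extensive quantity (specific rates transform as q·y/x); in
  constant-saturating mode the split is a no-op.
* No closed form for the length PDF is attempted (the division source
  integral has no specific shape); lengths are observed only through the
  simulator.
* The printed step rule "divide if 1 − e^{−γδt} < u" fires with the
  complementary probability; the engine implements u < 1 − e^{−γδt}, the
  standard survival-process discretization consistent with γ being a
  frequency.
* Batch growth-factor runs cap memory via `n_cap` (hard error, advising a
  smaller n_init) rather than by resampling, keeping the recorded process
  unweighted.
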