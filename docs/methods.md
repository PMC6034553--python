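# Methods

`humanl23` models human layer-2/3 (L2/L3) cortical pyramidal neurons from
their dendritic spines up to their somatic output spikes.  This note
documents the models, the numerical machinery, the synthetic-data
conditions, and the design choices made where the problem was genuinely
open.

## Passive cable model

Neurons are trees of cylindrical sections read from 7-column SWC files (or
generated synthetically).  Each section is discretized into compartments of
at most 0.02 AC space constants at 100 Hz (`d_lambda` rule; minimum one
compartment per section), each carrying membrane capacitance
C = C_m·area and leak conductance g = area/R_m, and coupled to its parent
through the axial resistance of the connecting half-segments.  A
multi-point SWC soma is collapsed to a single isopotential compartment of
equivalent sphere area; neurites attach at the soma center.

Defaults reflect the human L2/L3 estimates: C_m = 0.5 μF/cm² (half the
textbook value — a distinctive property of these cells), R_m = 15 kΩ·cm²,
R_a = 200 Ω·cm, resting potential −86 mV.

Spine membrane is folded in globally through the area factor

    F_spines = (dendritic area + total spine area) / dendritic area = 1.9,

applied as C_m → C_m·F and R_m → R_m/F on every dendritic compartment at
least 60 μm (path distance) from the soma; the product R_m·C_m — the
membrane time constant — is untouched, and soma, axon and proximal
dendrites are never corrected.

Integration is backward Euler with a Hines-ordered tree solve
(parents-before-children array layout; one leaf-to-root elimination and one
back-substitution per step), unconditionally stable, with fixed
dt = 0.025 ms by default.  Voltage-dependent synaptic conductances enter
the implicit matrix with their magnesium-block factor frozen at the
previous step's voltage (semi-implicit), keeping each step linear.  The
kernels are JIT-compiled with numba.  Accuracy guards in the test suite:
halving dt moves EPSP peaks by < 0.5%; a sealed cylinder of one space
constant reproduces the cosh attenuation closed form within 1%; the
transfer-resistance matrix (computed by a sparse steady-state solve) is
symmetric to 1e-6.

Choices the source problem leaves open, made here: dt and the spatial
resolution (free numerical settings with refinement tests); path distance
measured along the centerline from the soma center; heavy sweep analyses
use a coarser 0.1-λ discretization, which the refinement tests show is
adequate for the peak/threshold quantities those sweeps measure.

## Synapses and spines

Both AMPA and NMDA conductances follow a two-state kinetic scheme

    g(t, V) = B(V)·g_max·N·(e^(−t/τ_decay) − e^(−t/τ_rise)),

with N normalizing the peak to exactly B·g_max at
t_peak = τ_r·τ_d/(τ_d−τ_r)·ln(τ_d/τ_r).  AMPA: τ 0.3/1.8 ms,
g_max 0.88 nS per contact, B ≡ 1.  NMDA: τ 8.02/34.99 ms, g_max 1.31 nS,
and the Jahr–Stevens magnesium block

    B(V) = 1 / (1 + n·[Mg²⁺]·e^(−γV)),

with n = 0.28 mM⁻¹, [Mg²⁺] = 1 mM and steepness γ = 0.0771 mV⁻¹ (γ's unit
follows from the exponent being dimensionless).  Both reversal potentials
are 0 mV.

Spines are explicit two-compartment devices: a neck cylinder (1.35 μm ×
0.25 μm prototype) and an isopotential head (2.8 μm²), both carrying
membrane with the host dendrite's passive parameters.  The neck's axial
resistance R_neck = 4·R_a·L/(π·d²) ≈ 55–82.5 MΩ at R_a = 200–300 Ω·cm is
split: half links shaft to neck center, half neck to head.  Synapses
activate on the head membrane only.  Explicit spines are *not* also
spine-area corrected — the correction stands in for the unmodeled spine
population, whereas explicit spines carry their own membrane.

## EPSP analysis

* **Shape index**: (rise time, half-width) of a somatic EPSP; rise time is
  10–90% of peak (the classical shape-index literature's convention — the
  underlying study never defines it; configurable), half-width the time
  above 50% of peak, baseline the pre-onset mean.
* **Peeling**: the slowest membrane time constant from the least-squares
  slope of ln(V) over a tail window.
* **Localization**: a synapse's putative locations are the compartments of
  the model's shape-index curve within a Euclidean radius (default 1 ms —
  the source describes both a 1 ms radius and a 1 ms diameter; the radius
  reading is the default and the parameter is exposed) of the experimental
  shape index.
* **Connection fitting**: assuming five contacts per connection, each
  repeat draws five sites from the putative pool and fits one shared peak
  AMPA conductance by bounded derivative-free least squares (Brent) on the
  full somatic waveform (not peak-only: the whole transient carries the
  information), reporting mean ± SD across repeats.
* **NMDA kinetics, two stages**: stage 1 fits (τ_rise, τ_decay, γ, g_NMDA,
  g_AMPA_blocked) to the AMPA-blocked composite EPSP by Nelder–Mead within
  bounds τ_r ∈ [1, 20] ms, τ_d ∈ [20, 100] ms, γ ∈ [0.03, 0.12] mV⁻¹ (the
  bounds bracket the reported human values and the rodent literature);
  a residual AMPA conductance is allowed because the blocker is
  competitive.  Stage 2 freezes stage 1 and fits the unblocked g_AMPA,
  constrained to ≥ 5× the blocked value; a fit pinned at that bound with
  no residual improvement is flagged, not dropped.  Candidates (random
  synapse counts 15–30 and placements) are ranked by summed RMSD against
  both targets; the *best typical* fit is the high-ranked candidate
  nearest the mean of the top 100 in bound-normalized parameter space.
  The full-scale search (60,000 seeds, 20,000 carried to stage 2) is a
  configuration default; tests and the acceptance run use a handful of
  seeds, which the closed-loop recovery shows is already sufficient on
  noiseless synthetic targets.

## NMDA spikes and independent subunits

An NMDA spike is a local plateau: dendritic voltage above −40 mV for at
least 20 ms (both configurable).  The minimal cluster size on a branch is
found by bracketing + bisection over a fixed spine placement (positions
drawn uniformly within a 20 μm stretch, one synapse per spine, AMPA+NMDA),
exploiting monotonicity in synapse count; the placement seed is recorded.

Independent subunits: clusters at the minimal size are activated
simultaneously (t = 0 for all) at a set of terminals; a configuration is
valid when every activated terminal sustains its own plateau *and* the
peak voltage at the lowest-common-ancestor branch point of every activated
pair stays below −40 mV over the whole window.  The search adds terminals
most-distal-first in electrotonic terms, with a bounded swap pass
("greedy-backtrack", never worse than pure greedy) or an exhaustive
subset search for small trees.  The exact search used originally is
unspecified; this strategy is a documented stand-in whose optimality is
guaranteed only for small terminal counts.

## Active soma/axon model

Active conductances live only at the soma and a 60 μm axonal stub —
dendritic excitability in human cells is experimentally unconstrained, so
the dendrites stay passive(+NMDA).  Nine HH-style channel archetypes
(transient/persistent Na⁺, fast/slow/M-type K⁺, Ca-gated SK, high- and
low-threshold Ca²⁺, Ih) are expressed in a generic gating scheme —
Boltzmann steady states, bell-shaped τ(V), Hill-type calcium gates, a
single-pool calcium concentration with influx scale and decay time — whose
parameters are configuration data.  The identities and kinetics are this
package's own literature-style archetype set, tuned to give tonic,
adapting ~10 Hz firing with ~0.7 ms spikes on the small reference cell;
the original channel set is unnamed in the underlying study, so no attempt
is made to replicate specific published kinetics.

The 29 free parameters: per region (soma, axon) nine maximal conductance
densities, two Na gate voltage shifts plus one Na time-constant scale, the
calcium influx scale and decay time; plus one shared leak reversal.

### The 17 features and I-F normalization

Twelve features come from the step-response trace (baseline and
steady-state voltage, mean rate, first-spike latency, first ISI, ISI
"CV" computed as ISI_mean/ISI_SD exactly as the target convention prints
it (the reciprocal is available via a switch), adaptation index
(normalized mean consecutive-ISI difference), AP height, AP-begin voltage
at the 20 mV/ms upstroke crossing, AHP depth and latency, spike
half-width between the AP-begin voltage and the peak).  Spikes are
bookkept by peaks above 0 mV.  Features undefined for too few spikes are
NaN, never fabricated; in fitting they become infinite distances.

The five I-F features are read from a normalized reference I-F curve
(piecewise linear, abscissa scaled by the 10-Hz current): the trace's mean
rate is inverted through the curve to a normalized input u, and the
features are the curve's rates at 0.75u, 1.25u, 1.5u, 2u and 3u.  Both
targets and candidates go through the same map, so these objectives are a
deterministic function of the candidate's rate — they tie the fit to the
population I-F behaviour without extra simulations per candidate.

### Multi-objective fit

Objective i is |feature_i − mean_i|/SD_i.  The evolutionary search keeps a
population of parameter vectors under non-dominated sorting; because with
17 objectives essentially everything is mutually non-dominated, selection
ties are broken by a *graded worst-case distance*: models with fewer
undefined objectives always win, equally-undefined models compare on the
(always finite) rate mismatch, fully-defined models on their worst
objective.  Offspring mix SBX crossover + polynomial mutation with an
exploitation stream around the incumbent best (sparse coordinate steps,
success-adapted size); while the incumbent still misses a full spike train
the exploitation stream alternates fresh uniform draws (tonic firing
occupies ~2% of the bound volume, so global restarts are the fastest way
into the basin).  The first 40% of generations score only six core
objectives (baseline, rate, AP height, AP-begin, AHP depth, half-width) so
the search finds plausible spikes before the timing and I-F statistics
join.  In the test profile (population 20, 15 generations) the returned
best is refined by a momentum-assisted coordinate hill climb (default 55
evaluations per parameter; accepted steps are re-extended along the same
direction, which threads the correlated-objective valleys that defeat
axis-aligned moves) on a worst-case-plus-mean score; the full profile
(population 1000, 500 generations) relies on its own length.  Validation
runs follow the standard practice of a few independent optimizations with
the best model selected.

## Synthetic data: what it emulates, what it does not

The generators replace unreleased experimental inputs and define the
package's study conditions:

* **Trees**: random leaf-splitting topology hitting a drawn basal-terminal
  count (human 44.5 ± 8.1, rat 31.4 ± 8.6), with terminal branches
  elongated (human ×1.7) — the two gross statistics that drive terminal
  decoupling — plus an apical trunk with obliques and a small tuft.  No
  attempt at anatomically realistic branch angles, taper profiles or 3D
  space filling; only terminal counts, lengths and diameters matter to the
  electrotonic analyses here.
* **Spines**: truncated-normal draws around the measured 2.88 ± 1.37 μm²
  head area, 1.34 ± 0.50 μm neck length, 0.24 ± 0.08 μm neck diameter.
* **Pair EPSPs**: five contacts planted 140 ± 78 μm from the soma
  (truncated to the tree), simultaneous activation, additive Gaussian
  noise.  No electrode artifacts, dendritic filtering of noise, or
  synaptic failures.
* **NMDA targets**: 15–30 spinous synapses in an apical region with the
  reported kinetics planted; the blocked trace keeps the residual AMPA
  conductance.  Composite somatic EPSPs come out at the few-mV
  experimental scale.
* **Spike-train targets**: the reference active model, stimulated at the
  titrated ~10 Hz current for 1 s from 100 ms baseline; each repeat
  jitters densities by 15%, the leak reversal by ~2 mV and the stimulus
  amplitude by 5%, calibrated so the feature dispersions match the
  published ones (AP height ~±3 mV, half-width ~±15%, voltage base
  ~±1.5–3 mV).  The five I-F feature SDs come from an emulated 25-cell
  population scattered multiplicatively (±18%) around the reference curve,
  mirroring how the experimental I-F spread is a population quantity.  An
  SD floor of 1e-3 (feature units) keeps SD-normalized distances finite.

Because every generated dataset ships its planted ground truth, all fit
tests are closed-loop recoveries.  Passing them shows the estimation
machinery is consistent — it does not show that the archetype channels or
the random trees are faithful to real human cells; the extended suite in
`tests/test_modeldb_extended.py` covers the published six-cell numbers
when the deposited reconstructions are available locally.

## Problem sizes in tests and the acceptance run

Simulation-heavy analyses run at stated reduced sizes: synthetic trees at
0.1-λ discretization (~400 compartments); connection fits with 2–3 repeats
over 8–12 noise seeds; NMDA fits with ~6 candidate seeds; probability
curves with 20–25 trials per count over 5–6 counts; independence counts
with the greedy strategy; the spiking fit in the documented test profile
with two independent optimizations.  The full-scale defaults (100 repeats,
60,000 seeds, 1,000 trials, population 1,000 × 500 generations) remain the
function defaults or documented configuration.

## Known limitations

* Channel archetypes are generic; absolute fitted densities are not
  comparable to published per-cell values.
* The independence search is heuristic beyond small trees; counts are
  lower bounds on what an exhaustive search might certify.
* The synthetic morphology model ignores 3D embedding; analyses that
  depend on physical (not electrotonic) geometry beyond path length should
  not rely on it.
* The clustered spike-threshold curve can fail to bracket 50% within a
  swept range; the threshold then comes from flagged linear extrapolation.
* No background synaptic state: all thresholds refer to a quiescent,
  in-vitro-like resting cell.
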