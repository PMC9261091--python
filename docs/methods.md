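# Methods

`assrnet` simulates how common ion-channel gene variants and GABAergic
synaptic alterations change the 40 Hz auditory steady-state response (ASSR)
of a cortical microcircuit.  This note records the models, the parameters
that matter, the numerical choices, and the limits of what the desk-scale
tests demonstrate.

## Channel kinetics and the modifier layer

Every voltage-gated conductance is written as

    g(V, t) = ḡ · Π_i x_i(t)^{p_i},      ẋ = (x_∞(V) − x) / τ(V)
    x_∞(V) = 1 / (1 + exp((V_½ − V)/k)),  τ(V) = τ_b + τ_a · exp(−((V−V_p)/σ)²)

with signed slope `k` (negative for inactivation-like and for the
hyperpolarization-activated gate of Ih).  This sigmoid-plus-Gaussian-τ form
was chosen over raw α/β rate pairs because a variant in this framework *is*
a change to (V_½, k, τ, ḡ): the `KineticModifier` layer applies an additive
offset shift (translating both x_∞ and τ along the voltage axis), a slope
factor, a τ factor and a conductance factor, per gate.  Modifiers compose
(shifts add, factors multiply), the identity modifier is bit-exact, and
translation by `d` equals evaluating the unmodified gate at `V − d` exactly;
these identities are property-tested.

Eleven conductance classes are parameterised (transient/persistent Na⁺;
transient, persistent, Kv3-like and M-type K⁺; SK; Ih; high- and low-voltage
activated Ca²⁺; leak), with kinetics stored in versioned TSV files.  The
class list and the numerical values follow the thick-tufted layer-5
pyramidal-cell (L5PC) model family this circuit descends from, adjusted by
hand so the reduced cells below behave qualitatively correctly; they are
data, not code.  Ca²⁺ channels use a Nernst reversal recomputed each step
from the intracellular pool ([Ca²⁺]_o = 2 mM, 37 °C); SK activation is a
Hill function of [Ca²⁺] (exponent 4, half-activation 4.3·10⁻⁴ mM).  The Ca²⁺
pool is first-order with an exact exponential update
(d[Ca]/dt = −γ·i_Ca − ([Ca]−rest)/τ_Ca; defaults rest 10⁻⁴ mM, τ_Ca 80 ms,
γ 5·10⁻³ mM·cm²/(ms·mA)).  No temperature correction is applied (all
kinetics are 37 °C-equivalent).

## Cell models

The pyramidal cell is a four-compartment reduction (basal — soma — apical
trunk — apical tuft chain).  The soma carries all eleven channels; dendrites
carry leak and an Ih gradient increasing toward the tuft.  Geometry and
densities were fitted by hand to reproduce qualitative L5PC behaviour:
resting potential ≈ −75 mV, input resistance ≈ 56 MΩ, adapting regular
spiking (SK- and M-current mediated), and an Ih sag of several mV on
hyperpolarizing steps.  The fast-spiking PV⁺ basket cell is a single
compartment with fast Na⁺ (rapid inactivation recovery), a Kv3-like
rectifier and leak; it fires > 100 Hz with essentially no adaptation.

Feature extraction uses somatic steps of {0.3, 0.5, 0.7} × 1.5 nA plus a
−0.05 nA subthreshold step, 1 s each: spike counts (upward 0 mV crossings
merged within 2 ms), first-spike latency, resting potential from the
pre-stimulus window, input resistance from the subthreshold steady-state
deflection.  Integration: exponential Euler for gates via lookup tables
(0.05 mV grid), backward-Euler cable update solved by the Thomas algorithm
along the compartment chain; dt = 0.025 ms for single-cell protocols
(0.05 ms for the downscaling search and network runs).  Spike counts are
verified to be unchanged when dt is halved.

## Variants

A model variant is a named set of full-effect deltas on one channel
(offset shifts in mV; slope/τ/ḡ factors).  Attenuation by coefficient
c ∈ (0, 1] is linear for shifts (c·Δv) and logarithmic for factors
(f^c) — the natural split between additive and multiplicative parameters.
`downscale` finds the largest c keeping all features of the modified cell
inside an acceptance band around the unmodified cell (defaults: spike counts
±10 % with a ±1 floor, resting potential ±2 mV, input resistance ±10 %);
since pass/fail need not be monotone in c, an 8-point descending coarse scan
locates the largest passing point and bisection refines the boundary to
10⁻³.  The search accepts a pluggable evaluator so it can be verified
against an exhaustive grid scan with cheap analytic criteria; the
simulation-backed version is additionally checked on exemplars.
Combination is linear superposition per (channel, gate): shifts add, factors
multiply — commutative and associative by construction, with same-gene
variants merging on the same gates.

The bundled 86-variant library is **synthetic**: the original literature
tables are not redistributed here, so
`synthesize_variant_library` draws representative full effects (offsets
2–15 mV, slope factors 0.6–1.8, τ factors 0.5–2.5, ḡ factors 0.5–2.0)
across the CACNA1C/CACNA1D/CACNB2 → CaHVA, CACNA1I → CaLVA, SCN1A →
NaT/NaP and HCN1 → Ih families, with four fixed named exemplars.  Ca7
(CaHVA activation left-shift −10 mV, ḡ × 1.4) is the strong
excitability-reducing Ca²⁺ exemplar: the left shift increases Ca²⁺ influx
per spike, recruiting SK and damping firing.  HCN1-1/-2 shift the Ih
activation offset negative and increase its slope factor (HCN1-2 stronger).
A blank schema template is provided for transcribing real tables; with such
a table in place no code changes.

## Microcircuit

256 pyramidal and 64 basket cells (4:1), Erdős–Rényi connectivity per
projection, AMPA (0.5/2 ms) + NMDA (2/100 ms, Jahr–Stevens Mg²⁺ block,
1 mM) for excitation and GABA_A (0.5/8 ms, −75 mV) for inhibition, all
perisomatic; bi-exponential conductances normalised to unit peak per event;
1 ms synaptic delay (3 ms in the resonance configuration below).  All cells
receive Poisson background; the 40 Hz drive is one input spike per cell per
bout, bouts every 25 ms for 1 s after a 200 ms settling period.  35 % of
interneurons (22 of 64; round-to-nearest) receive no drive, and the
remaining interneurons receive the drive at 0.1 × the pyramidal weight —
both choices make the interneuron response follow the pyramidal volley
rather than the stimulus directly, which is what lets prolonged inhibition
express coherent beat-skipping.  Conditions are alternatives applied to a
control network: a scaled variant on every pyramidal cell, `Gmax`
(GABA_A weights × 0.75) or `IPSC` (GABA_A decay 8 → 25 ms); stacking is
rejected.

Connectivity probabilities, weights and background rates are calibrated
stand-ins (the modelled system's exact values are not available here).  Two
operating points of the same circuit are shipped, because the position on
the axis between feed-forward and recurrent dynamics is not determined by
the information available, and different measures are informative at
different points:

* **Drive-dominated** (`config.forced_fixture`, quarter scale 64E/16I;
  `default_config` is its full-size 1/N-scaled form): every bout forces a
  pyramidal volley whose size tracks excitability.  Used for the evoked
  power measures.  Here IPSC produces textbook beat-skipping (alternating
  volleys; 20 Hz subharmonic up several-fold, 40 Hz power roughly halved),
  Gmax reduces 40 Hz power without a beta shift, and excitability-reducing
  variants scale the volley down.
* **Resonance-dominated** (`config.resonant_fixture`, half scale 128E/32I):
  strong tonic background sustains an intrinsic pyramidal–interneuron gamma
  rhythm near 40 Hz (period set by the strong, delayed perisomatic
  inhibition) which the click train entrains.  Used for inter-trial
  coherence: phase locking now depends on intact GABAergic timing, so Gmax
  and IPSC collapse ITC (≈ 0.6–0.7 vs ≈ 0.98 control) while a downscaled
  Ca²⁺-channel variant produces no coherence deficit (it slightly
  *increases* ITC by damping tonic spike noise — consistent with the claim
  that variant effects are amplitude effects, not desynchronization).

Test fixtures at reduced size densify connection probabilities and scale
per-connection weights as 1/N so the mean total conductance per cell is
preserved; the 4:1 E:I ratio is always kept.

## Simulation pipeline

A *virtual subject* is one structural realization (connectivity + drive-free
mask) drawn from `SeedSequence([base_seed, subject])`; trials reuse the
subject's structure and differ only in the noise realization
(`SeedSequence([base_seed, subject, trial])`), so subjects are paired across
conditions and trials are paired across conditions too.  The default cohort
is 20 subjects × 10 trials = 200 simulations per condition; scaled
experiments in the tests use 5 × 5 (coherence, additivity) and 5 × 3
(power contrasts), sizes at which the qualitative contrasts are stable
across seeds.  Trials run 1200 ms (200 ms settling + 1000 ms drive);
the LFP is boxcar-averaged over each 1 ms window and stored at 1 kHz
(anti-aliased decimation: instantaneous sampling would fold volley
harmonics near the Nyquist rate back onto the 40 Hz band).

The model LFP is the sum over pyramidal cells of |I_AMPA| + |I_GABA_A| at
the soma, counting recurrent network synapses (the stereotyped feed-forward
click current is excluded by default, since its identical contribution in
every condition masks circuit effects); external-inclusive, EPSC-only and
summed-membrane-potential proxies are selectable per configuration, so an
alternative LFP definition can be swapped in without code changes.  The
proxy is linear in population size; scaled fixtures compare per-cell
normalised values.

Two integration backends produce the dynamics: a vectorized numpy reference
and a numba kernel implementing the identical update equations (table-driven
exponential-Euler gates, backward-Euler cable step, same synapse-state
recursion); they agree to single precision and the kernel is ~20× faster.
Cohorts persist to HDF5 with per-trial SHA-256 checksums; interrupted runs
resume from the store.

## Analysis

*4040* is the evoked power at 40 Hz under 40 Hz drive; *2040* the power in
the 20 Hz subharmonic band under the same drive.  Evoked power averages the
trials first (suppressing non-phase-locked components — verified against
random-phase surrogates), then takes a Welch PSD (Hann, 500 ms segments,
50 % overlap) integrated over ±2 Hz bands.  ITC uses a 7-cycle Morlet
wavelet at 40 Hz: ITC(t) is the modulus of the across-trial mean unit
phasor, time-averaged outside one wavelet support of the window edges; the
estimator is validated against the Rayleigh null E[ITC] = √π/(2√n).
Group comparisons are estimation statistics: mean difference against the
shared control with a percentile bootstrap CI (default 5000 resamples,
seeded; fewer than 1000 resamples records a warning).  No multiple-testing
correction is applied across the variant screen, matching the estimation
(not hypothesis-testing) framing.

## What the desk-scale tests do and do not show

The synthetic cohort generator reproduces the *structure* of the study —
paired virtual subjects, trial noise, conditions, downscaled variants — and
the tests demonstrate the qualitative mechanism chain: entrainment at the
drive frequency, beat-skipping under prolonged IPSCs, gamma reduction under
reduced inhibition, additive combination of variant effects, and the
power/coherence dissociation.  They do not show that the *printed* effect
magnitudes are reproduced: those depend on the original literature-derived
variant tables and network constants, which are not part of this
repository.  With a transcribed variant table dropped into
`assrnet/data/variants_transcribed.tsv` and the corresponding constants
in a config file, the same pipeline runs the full-scale screen unchanged.

## Known limitations

* Single interneuron class (PV⁺ basket); no SST⁺/VIP⁺ populations, no
  NMDA-hypofunction or neuromodulatory conditions.
* Reduced morphology: no axonal initiation zone, no stochastic gating; the
  four-compartment geometry is a qualitative fit, not a morphological
  reconstruction.
* The bundled variant library is synthetic and representative, not
  literature-derived; per-variant results are therefore illustrative.
* The two operating points bracket, rather than pin down, the circuit's
  true drive/recurrence balance.
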