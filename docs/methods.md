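# Model and methods

`hippotrial` simulates randomized, placebo-controlled virtual trials of
memantine on a small hippocampal microcircuit carrying graded
Alzheimer-type pathology. This note documents the model, its
assumptions, the calibration constants and their rationale, and the
limits of what the simulations show.

## Circuit

The network contains 33 integrated cells: dentate gyrus (8 granule
cells, 2 basket cells, 1 mossy cell), CA3 (8 pyramidal cells, 2 basket
cells, 1 O-LM cell) and CA1 (8 pyramidal cells, 2 basket cells, 1 O-LM
cell). Entorhinal cortex layers 2 and 3 (10 fibres each) and nine
septal (MS-DB) pacemaker cells are external spike sources. Projections
follow the canonical trisynaptic loop: EC2 → DG granule cells, DG
interneurons and CA3 pyramidal cells (perforant path; 10 synapses per
stated projection per target, so 9%/18% pruning has integer
resolution); granule cells → CA3 (mossy fibres) and the hilar mossy
cell; CA3 recurrent collaterals; CA3 → CA1 (Schaffer collaterals);
EC3 → CA1 (temporoammonic); basket cells inhibit principal somata,
O-LM cells inhibit principal dendrites, and the septum rhythmically
inhibits all interneurons (theta-paced disinhibition). Topology is
deterministic (round-robin fibre and fan-in assignment).

Each cell is a chain of 16 leaky-integrator compartments
(soma = index 0). The soma carries the reference leak (time constant
20 ms for principal cells, 10 ms for interneurons); dendritic
compartments have 2% of the somatic leak and inter-compartment
coupling of 20 leak units. Spiking is somatic threshold-reset
(−50 mV threshold, −70 mV reset, 5 ms absolute refractory period).
Conductances are expressed relative to the somatic leak; reversal
potentials are 0 mV (AMPA/NMDA), −75 mV (GABA), −70 mV (leak).

**Synapse placement.** All excitatory afferents attach to proximal
apical compartments 2–7 (mossy fibres most proximally, 1–3). With a
passive unbranched cable and a somatic reset, distal compartments
escape the somatic voltage clamp and sit near 0 mV whenever they are
driven, which is outside the voltage window in which memantine block
and Mg²⁺ gating operate; the proximal input zone keeps synaptic
membrane potential in the −70…−45 mV range where the published
voltage dependence of the drug is meaningful. This placement is a
deliberate design choice of this model.

## Receptor registers

Each excitatory synapse carries an AMPA and an NMDA register, each
inhibitory synapse a GABA register: activation variables in [0, 1]
that decay exponentially (AMPA 5 ms, NMDA 100 ms, GABA 10 ms) and jump
on presynaptic spikes (increments 0.7, 0.15, 0.7; the small NMDA
increment keeps NMDA activation rate-coding rather than saturating).
Synaptic current is conductance-based: weight × activation ×
driving force.

## NMDA gating and memantine

The NMDA conductance is closed below the calcium-channel opening
threshold of −68 mV (Mg²⁺ block). Above it, memantine blocks the open
channel with Langmuir occupancy c/(c + IC50(V)); IC50(V) interpolates
linearly from 0.5 µM at −70 mV to 30 µM at −30 mV (clamped outside)
and the block is fully relieved above −20 mV — strong depolarization
expels the blocker, so phasic transmission is spared.

A virtual dose acts through two thresholds:

* the **electrical opening threshold** rises by
  k·c/(c + K) with k = 10.0 mV, K = 16.5 µM (+1.5 / +3.8 / +6.5 mV at
  3/10/30 µM), trimming near-rest NMDA current;
* the **calcium opening threshold** — the potential above which
  channel current counts toward the excitotoxic calcium load — rises
  much more steeply, by k·cʰ/(cʰ + Kʰ) with k = 80 mV, K = 10 µM,
  h = 1.5 (+11 / +40 / +67 mV), so therapeutic doses abolish tonic
  calcium entry (the neuroprotective action) while charge transfer
  degrades only gradually.

Splitting the electrical and calcium gates is the central modelling
choice of the package: dose-dependent control of the calcium opening
threshold is the stated mechanism of the virtual therapy, and it is
what lets memantine *increase* spike output in an over-driven
pathological network.

## Pathology

Severity has two printed components. (1) *Synaptic decay*: EC2
synapses (onto DG granule cells, DG interneurons and CA3 pyramidal
cells; 200 in the default build) are disabled one by one in a seeded
random order to a 9% (moderate) or 18% (severe) loss fraction.
(2) *Excitotoxicity*: the drive law power = powerA·(M − ReP) with
powerA = 9 and synaptic-function targets ln 9 / ln 63 / ln 135 enters
the engine as a multiplicative NMDA-weight gain
exp(M)/exp(M_control) = 1/7/15.

**Calcium-overload closure.** The consequence of over-stimulation is
modelled with one per-cell state: a calcium load that integrates the
NMDA current entering above the (dose-shifted) calcium threshold,
with influx rate χ = 0.0575 per current unit, clearance time constant
600 ms, and saturation of influx at 350 current units in CA1
(transporter/buffer capacity; effectively unsaturated elsewhere).
When the load crosses 6.0 the cell's NMDA conductance inactivates
(excitotoxic shutdown) and recovers only when the load falls below
0.15 — a long hysteresis producing seconds-long silent periods.
Granule cells and interneurons are resistant (strong calcium
buffering); CA3 pyramidal cells have unit vulnerability and CA1
pyramidal cells 2.6× — the classic gradient of delayed excitotoxic
neuronal death. Under placebo the 7× / 15× glutamate gain keeps
pyramidal cells duty-cycling between bursts and overload silence;
effective doses cut calcium entry, lengthen the active phase, and
raise spike output, while at 30 µM in moderate disease the combined
electrical block leaves CA3 below its firing threshold entirely.

## Drive

EC afferents are inhomogeneous Poisson processes with a theta
envelope (default 8 Hz, midpoint of the 4–12 Hz band) carrying nested
gamma amplitude modulation (40 Hz, depth 0.5). EC2 and EC3 envelopes
are in antiphase. Per-fibre peak rate is 120 Hz. Septal cells fire
Poisson trains peaking at the theta phase at which interneurons are
inhibited, disinhibiting principal cells half a cycle out of phase
with the EC2 drive.

## Virtual subjects and the trial

A virtual hippocampus is a (pruning pattern, afferent noise stream,
drive factor, susceptibility factor) tuple derived from one master
seed. The two lognormal subject factors — afferent drive scale
(σ = 0.03) and excitotoxic susceptibility scale (σ = 0.15,
multiplying χ) — supply the between-subject variability implied by
the width of the reported arm confidence intervals, and, because the
susceptibility factor moves CA3 and CA1 together and CA1 rides on
CA3's output, they produce the strongly positive CA3–CA1 spike-count
correlations seen across placebo subjects.

The default design: 80 hippocampi, 40 moderate and 40 severe, each
severity randomized into four arms of 10 (placebo, 3, 10, 30 µM).
Every hippocampus is simulated untreated (80 baselines); each
non-placebo hippocampus is simulated again at its dose with identical
noise (60 treated runs; 140 simulations). Placebo comparisons use the
placebo arm's baselines; the other 70 baselines are retained as each
treated subject's own untreated reference.

Each simulation integrates 12 s of biological time at dt = 0.1 ms
(forward Euler, single thread, bitwise reproducible); the first 2 s
are a burn-in during which the calcium loads reach their working
regime and are not recorded. Endpoints are computed over the 10
recorded seconds and over the principal cells of each region (8
granule / 8 CA3 pyramidal / 8 CA1 pyramidal): total spikes per
region; CA1 mean ISI (mean over cells of the within-cell mean
interval); CA1 frequency (mean per-cell rate). The statistical
battery is the standard parametric workup: means with 95% t
intervals, Shapiro–Wilk, Brown–Forsythe, one-way ANOVA with Tukey
HSD, Pearson correlation; box plots use mean / ±SE box / 95% CI
whiskers.

## Numerical and practical notes

* The compiled kernel (numba) is verified spike-for-spike against a
  pure-Python re-implementation of the same update rule in the test
  suite.
* A full default trial (140 × 12 s, 33 cells, dt 0.1 ms) takes about
  1–2 minutes on one CPU core.
* Degenerate inputs: silent regions report frequency 0 and an
  undefined (NaN) ISI; ANOVA groups with fewer than two finite values
  are dropped from a comparison; zero-variance inputs to the
  correlation raise an error.
* The median-centred Levene (Brown–Forsythe) test is noticeably
  conservative for very small groups; its type-I calibration is
  checked at a moderate group size (n = 30).

## What the defaults were calibrated to, and limitations

The membrane formalism behind the published endpoint tables is not
fully specified anywhere, so the constants above (weights, cable
parameters, overload parameters, dose–threshold maps, subject
variability) are this package's own calibration, fixed once so that
the default trial reproduces the study-level pattern: placebo CA1
output near 1.5 k spikes/10 s at ~19 Hz with ~46 ms ISI in moderate
disease, slightly lower in severe disease; 3 and 10 µM raising
moderate CA3 output and 10 µM raising CA1; complete CA3 collapse at
30 µM in moderate disease; no effect of 3 µM but clear effects of 10
and 30 µM in severe disease; and CA3–CA1 count correlations above
0.9 in placebo arms.

Known limitations:

* In the shipped calibration the moderate 3 µM arm raises CA3 but
  not CA1 spike counts; the reported study found a CA1 rise at 3 µM
  as well. The CA1 effect of the lowest dose is the one qualitative
  feature this model does not reproduce.
* A healthy (gain-1) control network fires far less than the AD
  networks here, because regional output is dominated by the
  amplified NMDA drive; the virtual trial contains no healthy arm,
  so this has no bearing on its endpoints, but the model should not
  be used to compare healthy and diseased absolute rates.
* DG spike counts run higher than the other regions and respond only
  weakly to dose; DG endpoints were not part of the calibration
  surface.
* No pharmacokinetics (doses are bath concentrations), no plasticity,
  no morphological detail, no within-run disease progression; the
  synthetic subjects differ only along the two documented axes, not
  in connectivity or cell counts.

Passing tests on this synthetic population demonstrate internal
reproduction of the study-level statistics under the model's
assumptions; they are not evidence about biological hippocampi beyond
those assumptions.
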