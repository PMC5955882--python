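# Methods

`bulbnet` is a desk-scale biophysical model of the olfactory-bulb
microcircuit formed by mitral cells (MC), middle tufted cells (mTC),
superficial and deep granule cells (sGC/dGC) and deep short-axon cells
(dSAC). This note documents the model, its assumptions, the parameters
that matter, and the known limitations. Every empirical statement here is
recomputed by the test suite or by `scripts/acceptance.py`.

## Morphologies

Cells are trees of cylindrical sections with path-based geometry; no 3-D
embedding is kept, so all distances (Sholl radii, synapse positions,
lateral reach) are path distances from the soma. Reduced cells use the
canonical dimensions: a 20-um spherical soma; an apical dendrite 4 um
thick and 400 um (MC) or 250 um (mTC) long, ending in four 0.8 x 80 um
tuft branches; two lateral dendrites of 3 x 800 um (MC) or 2.5 x 600 um
(mTC); and a thin axon (1.5 x 100 um, our choice — only its Na/K_A
content matters). The dSAC is a ball-and-stick with a 1,400-um dendrite
(doubled when no slice correction is applied). The granule cell is a soma
plus an apical shaft bearing gemmule (spine) compartments where the
reciprocal synapses attach; the packaged fixture uses 50 gemmules, network
runs use 12 for speed (the gemmule count only sets how many distinct
synaptic sites a GC offers).

Synthetic populations grow the lateral dendrites from `BranchStats`: the
number of stems, a per-segment branch-length distribution, and per-order
bifurcation probabilities; diameters taper by 0.8 per order with a 0.3-um
floor. The stored terminal path-length distribution is *descriptive*: it
is regenerated by brute-force resampling from the growth rule and used
only for validation. Default statistics were calibrated once so that (i)
the synthetic-mTC total-lateral-length distribution peaks near 8,500 um
and (ii) the population input resistances land on the full-morphology
targets (65.2 MOhm mTC, 27.4 MOhm MC); the free knobs were mean branch
length, stem count and stem diameter (mTC 2.2 um, MC 3.2 um).

## Membrane model and solver

The cable equation is integrated by backward Euler on the compartment
tree (Hines-ordered elimination, one up/down sweep per step), with channel
gates advanced by a Rush-Larsen exponential step using steady states and
time constants tabulated on a 0.5-mV grid per time step. The scheme is
unconditionally stable for the passive subsystem; accuracy is verified
against the RC closed form, the sealed-end-cable input conductance
`G_soma + G_inf tanh(L/lambda)`, and a dense matrix-exponential solution
on small trees (all to better than 1%, most to 0.1%). Default
discretization is 20 um per compartment (25 um in network runs); default
dt is 0.025 ms for single-cell work and 0.05 ms for networks. The dt
refinement bound (< 0.5 mV on halving dt) is asserted on subthreshold
responses: once spikes occur, any solver shows O(10 mV) pointwise
differences from infinitesimal spike-time shifts.

Channels are Hodgkin-Huxley style with Boltzmann steady states: fast Na
(m^3 h), delayed rectifier K_DR (n^2), A-type K_A (a^4 b, incomplete
inactivation), and a slow potassium current K_S whose time constant is
~250 ms above -58 mV and ~25 ms below. MCs carry Na + K_A + K_DR and fire
tonically at every suprathreshold step. mTCs carry Na + K_A + K_S, with
K_S (and extra Na) concentrated in the apical/tuft region: the apical
region then acts as a slow burst terminator — a few spikes charge K_S,
the cell falls silent, K_S discharges slowly near -50 mV, and the cycle
repeats. This yields clustered bursting at low drive, high-frequency tonic
firing at high drive, and — because K_S deactivates quickly below -58 mV —
rebound clusters within tens of ms after 50-ms pauses in depolarization.
Replacing K_S by K_DR at the same densities abolishes bursting. The axon
carries only Na (30x the somatodendritic density) and K_A, so spikes
initiate near the soma. dGCs have 25% more K_DR and 25% less Na than
sGCs. Granule cells and dSACs carry comparatively high K_DR (0.08-0.1
S/cm^2): this is what lets them fire persistently under sustained
synaptic conductance instead of entering depolarization block, which
matters because the dendrodendritic excitation decays slowly.

Passive parameters are shared between MC and mTC (Ra 278 Ohm cm, Cm 1.2
uF/cm^2, g_L 63.4 uS/cm^2) and were solved — two unknowns, two targets —
so the reduced morphologies give exactly 91.5 and 125.3 MOhm somatic
input resistance; GC and dSAC leak were calibrated likewise (603.2 and
278.3 MOhm). Input resistance is computed from the steady state of the
passive linear system (channels disabled), which the linearity of the
passive cable makes exact for any small probe current.

## Synapses and odor drive

Reciprocal dendrodendritic synapses pair an excitatory principal-to-GC
component (AMPA+NMDA-like composite, tau 2/50 ms, reversal 0 mV) and an
inhibitory GC-to-principal component (GABA-A-like, tau 1/18 ms, reversal
-75 mV) at the same site on a lateral dendrite. Release is event-driven:
a local dV/dt threshold crossing (20 mV/ms, 2-ms lockout) at the
presynaptic compartment increments a double-exponential conductance in
the postsynaptic compartment. Weights are dimensionless in [0, 1] and
scale fixture maxima (1 nS excitatory, 4 nS inhibitory per synapse). The
dSAC is excited by mTC axon terminals through 2/200-ms synapses and,
while firing above 10 Hz, imposes a 10-nS tonic hyperpolarizing
conductance on its target GCs — enough to block their spiking.

Odor input is a per-glomerulus activation S from a Hill dose-response
(S = c^n / (c^n + K^n), default n = 1.5, affinities log-uniform per
glomerulus), normalized by an abstract glomerular-layer winners-take-all:
residuals below theta times the bulb mean (theta = 0.75) are zeroed and
survivors pass through a narrow sigmoid gate, so the surviving set is
invariant to uniform concentration scaling and identical drive reaches
the MC and mTC tufts of each glomerulus. theta = 0.75 (not 1.0) so that
two equally strong co-active glomeruli survive normalization. The drive
becomes an excitatory tuft conductance (0.8 nS per tuft compartment at
S = 1) modulated by a raised-cosine sniff cycle (3 Hz default; at the
default depth 0.3 the waveform's CV is 0.125, i.e. almost constant) or by
a pulse mode with onsets exactly 350 ms apart.

## Plasticity and columns

Learning alternates 50-ms simulation windows with batch weight updates
from local spike counts. The excitatory component potentiates when the
principal-side dendritic compartment fires more than theta_LTP = 1.5
spikes per window (backpropagating action potentials) and depresses below
theta_LTD = 1. The inhibitory component potentiates when the GC exceeds
theta_LTP *and* the principal-side site is locally active, and depresses
when either is silent; this local gate is what confines columns to active
glomeruli and, combined with inhibition-hindered backpropagation,
produces the selective depression of distal synapses (potentiated
inhibition on an MC falls from ~1.0 near the soma to 0 beyond ~350 um).
Increments are 0.1/0.01 of w_max per window; column formation is robust
to halving or doubling both (tested), as it relies only on potentiation
and depression having different thresholds. theta_LTP = 1.5 (not higher)
because desk-scale mTC bursts are 3-spike clusters which straddle window
boundaries. A column is the set of GCs with any inhibitory weight at or
above half of w_max onto a unit's principal cells; its depth extent is the
member soma depth range over the GCL depth.

## Desk-scale experiments

Problem sizes were chosen so every runner completes in minutes on one
core: pairs or quadruplets of glomerular units with 1 MC + 2 mTC each,
160-260 granule cells, 2.4-4.2 s of simulated time, learning runs of
10-26 sniffs.

*Two-cell synchronization.* Two principal cells and two GCs under weak
~3-Hz drive (period 350 ms, depth 0.4), with a 12% drive asymmetry and
40-Hz background synaptic noise per cell providing the heterogeneity that
real morphological diversity provides in the full model. In the
`reciprocal` wiring each GC has reciprocal contacts with both cells (weak
0.5-nS excitatory contacts, so the GC integrates joint activity; strong
16-nS compound inhibitory contacts); in `common_external` the GCs receive
identical external volleys timed near the sniff trough and inhibit their
own cell only. Shared inhibition resets both mTC bursters together —
hyperpolarization discharges K_S in both cells — so burst clusters
realign on release: synchrony (sigma = 5 ms reliability) rises from ~0.05
to ~0.4-0.5. MC pairs, lacking the slow-K reset, stay at their baseline in
every wiring.

*Lateral inhibition vs distance.* Learned two-unit networks at 100-600 um
separation with laterals aligned on the separation axis; the probe cell
is voltage-clamped at -60 mV while the other unit is driven, and the peak
outward clamp current is normalized per cell type. The decay with
distance arises from the stimulated unit's dendritic reach and the
distance-depressed excitatory weights; MC curves decay more slowly than
mTC curves at 0% co-connectivity (longer laterals), the gap closes at
100%, and uniformizing the learned weights flattens the profile.

*Column formation.* Strong (S = 1) and weak (S = 0.35) units; the control
normalizes both (weak -> 0), the ablation routes raw drive to the mTC
tufts only. Control: full-depth column (extent >= 0.9) under the strong
unit only. Ablation: an additional shallow, purely superficial column
(extent ~0.4) under the weak unit.

*Cluster gating.* Four units in two clusters (within-cluster separation
160 um, between 220 um), lateral stems aimed at the nearest within- and
between-cluster units, 100-um synapse reach, learned columns, and two
dSACs that fire persistently (~270 Hz) on mTC-axon input and silence the
cluster-bridging GCs. Outputs are per-unit pooled mTC rate series (10-ms
bins, exposed as a parameter), rate comparisons with cluster 2 ON vs OFF,
and the pooled-rate Pearson correlation matrix.

## Known limitations

* The cluster-gating experiment reproduces the circuit machinery but not
  the full-scale correlation magnitudes: with two mTCs per unit, learned
  coupling that is distance-depressed by design, and burst oscillators
  that entrain weakly under distributed inhibition, within-cluster
  pooled-rate correlations stay far below the full model's values, and
  between-unit rate coupling beyond ~300 um is negligible. The full-scale
  result rests on hundreds of cells per unit and millimetre-scale
  dendrites that desk scale cannot emulate; the acceptance suite asserts
  the full-scale values and reports this gap rather than masking it.
* The glomerular layer is an abstract normalization, not a PGC/ETC
  circuit; drive is a rate-derived conductance, not OSN spikes.
* Channel kinetics are calibrated stand-ins: they reproduce the
  phenotypes (tonic MC, burster mTC with rebound, persistent dSAC), not
  voltage-clamp data for specific channels.
* Synthetic-morphology statistics are fixtures constrained only by the
  lateral-length mode and population input resistances, not fits to
  reconstructions; no 3-D embedding exists, so SWC exports use synthetic
  directions that preserve lengths and topology only.
* Passing tests show the mechanisms work under the generator's idealized
  drive (Hill activation, raised-cosine sniff, Poisson background); real
  odor dynamics, correlated noise and gap junctions are out of scope.
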