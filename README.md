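# bulbnet

A desk-scale biophysical model of the olfactory-bulb microcircuit formed
by its two principal-cell pathways — mitral cells (MC) and middle tufted
cells (mTC) — together with superficial and deep granule cells (sGC/dGC)
and deep short-axon cells (dSAC).

The olfactory bulb turns odorant-evoked glomerular activation into
spatiotemporal spike patterns. The two principal-cell types read the same
glomerular input but diverge in the deeper layers: they connect to largely
separate granule-cell populations through reciprocal dendrodendritic
synapses on their lateral dendrites. `bulbnet` implements this circuit at
a scale that runs in minutes on one core and reproduces its key in-silico
phenomena:

* **Cell models.** Compartmental cable models (backward Euler on the
  dendritic tree, Rush–Larsen channel gating) with Hodgkin–Huxley-style
  conductances: MCs (Na, K_A, K_DR) fire tonically; mTCs (Na, K_A and a
  slow potassium current K_S) fire clustered bursts at low drive, tonic
  trains at high drive, and rebound clusters after brief pauses in
  depolarization. Somatic input resistance is the steady state of the
  passive cable, `R_in = ΔV/ΔI`; the calibrated models give 91.5 MΩ (MC),
  125.3 MΩ (mTC), 278.3 MΩ (dSAC) and 603.2 MΩ (GC).
* **Morphologies.** Reduced canonical cells plus a statistical generator
  (per-order branching probabilities, branch-length distributions,
  diameter taper) whose default fixtures put the mode of the synthetic-mTC
  total-lateral-dendrite length near 8,500 μm; SWC read/write, Sholl and
  branch-order analysis.
* **Network.** Glomerular units on a 2-D surface, granule cells in a 3-D
  slab, reciprocal synapses placed as a Poisson process along lateral
  dendrites (0.1 syn/μm) with depth-stratified GC pairing and configurable
  MC/mTC co-connectivity; dSACs excited by mTC axons that silence
  cluster-bridging granule cells.
* **Glomerular layer.** Hill dose–response per glomerulus, raised-cosine
  sniff modulation, and a winners-take-all normalization
  `drive_i = S_i · gate(S_i − θ·mean(S))` delivering identical drive to
  the MC and mTC tufts of each glomerulus.
* **Plasticity.** Activity-dependent modification of each synaptic
  component from local spike counts, which grows granule-cell *columns*
  beneath strongly activated glomeruli.
* **Analysis.** Gaussian-kernel spike-time reliability (for two trials
  with one spike offset by Δ it equals `exp(−Δ²/4σ²)`), pooled rate
  series, zero-lag Pearson correlation matrices, voltage-clamp IPSC
  lateral-inhibition curves and firing-rate-change maps.

## Worked example

```
$ python examples/01_single_cells.py
MC: input resistance 91.5 MOhm
     300 pA step ->  33 spikes ( 23.6 Hz), tonic
    1200 pA step -> 126 spikes ( 90.0 Hz), tonic
  rebound clusters after 50 ms pauses: False, first-spike latency ~8 ms
mTC: input resistance 125.3 MOhm
     300 pA step ->  24 spikes ( 17.1 Hz), bursting
    1200 pA step ->  69 spikes ( 49.3 Hz), tonic
  rebound clusters after 50 ms pauses: True, first-spike latency ~15 ms
```

The input resistances are the calibration anchors of the two cell models.
The step responses show the central phenotype split: the MC fires tonic
trains at every suprathreshold current, while the mTC fires clusters of
spikes separated by silent gaps at 300 pA and converts to fast tonic
firing at 1200 pA. Only the mTC produces rebound spike clusters when a
depolarizing current is interrupted by 50-ms pauses — the signature of its
slow potassium conductance, and the cellular basis of granule-cell-mediated
mTC synchronization (`examples/03_two_cell_synchronization.py`).

The other examples build synthetic morphology populations, synchronize an
mTC pair through shared granule cells, form columns under a strong
glomerulus, map lateral inhibition against inter-glomerular distance, and
run the two-cluster dSAC-gating experiment. A thin CLI wraps the same
runners: `bulbnet rin --cell mTC`, `bulbnet simulate --cell mTC
--amplitude 300`, `bulbnet run two-cell-sync`, `bulbnet make-fixtures`.

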