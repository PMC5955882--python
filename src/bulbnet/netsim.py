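"""Network simulation: maps a NetworkModel onto the compartmental engine.

Each principal cell, granule cell and dSAC becomes a compartment subtree in
one flat simulation group.  Reciprocal synapses become paired
event-triggered double-exponential conductances (AMPA-like principal->GC,
GABA-A-like GC->principal) gated by local presynaptic dV/dt threshold
crossings.  Odor drive is an excitatory tuft conductance proportional to
the per-glomerulus activation waveform.  dSACs are excited by mTC axons
(2/200 ms kinetics) and, while firing above 10 Hz, impose a tonic
hyperpolarizing conductance on their target GCs strong enough to block
spiking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import SimGroup
from .glomin import GlomerularDrive
from .membrane import SpikeTrain, Subtype, load_biophys, make_cell
from .morpho import SectionKind
from .netbuild import NetworkModel

DSAC_EXC_W_US = 0.001  # mTC axon -> dSAC synaptic weight
DSAC_RATE_THRESHOLD_HZ = 10.0


def constant_drive(amplitudes) -> GlomerularDrive:
    """Unmodulated drive at the given per-glomerulus amplitudes."""
    return GlomerularDrive(np.asarray(amplitudes, dtype=float), modulation_depth=0.0)


@dataclass
class SpikeData:
    """Per-cell spike times collected from a network run."""

    trains: dict[int, np.ndarray]

    def train(self, cell_id: int) -> SpikeTrain:
        return SpikeTrain(self.trains.get(cell_id, np.zeros(0)), cell_id)

    def pooled(self, cell_ids) -> np.ndarray:
        arrs = [self.trains.get(c, np.zeros(0)) for c in cell_ids]
        return np.sort(np.concatenate(arrs)) if arrs else np.zeros(0)

    def rate(self, cell_ids, t_start: float, t_stop: float) -> float:
        """Mean per-cell firing rate (spikes/s) over a window."""
        ids = list(cell_ids)
        if not ids:
            return 0.0
        n = sum(
            int(((self.trains.get(c, np.zeros(0)) >= t_start)
                 & (self.trains.get(c, np.zeros(0)) < t_stop)).sum())
            for c in ids
        )
        return float(n) / len(ids) / ((t_stop - t_start) / 1000.0)


class NetSim:
    """Simulation state for one NetworkModel."""

    def __init__(
        self,
        net: NetworkModel,
        dt: float = 0.05,
        max_seg_length: float = 25.0,
        drive_row_of=None,
        n_drive_rows: int | None = None,
        noise_rate_hz: float = 0.0,
        noise_w_uS: float = 0.0005,
        noise_seed: int = 0,
    ):
        """``drive_row_of(cell_info) -> int`` maps principal cells to rows of
        the drive waveform (default: the cell's glomerulus id)."""
        self.net = net
        self.dt = dt
        bio = load_biophys()
        self.bio = bio
        self.grp = SimGroup(bio["kinetics"], dt)
        self.handles = {}
        for cid in sorted(net.cells):
            info = net.cells[cid]
            st = info.subtype
            if st in (Subtype.MC, Subtype.MTC):
                cm = make_cell(st, morphology=info.morphology)
            elif st is Subtype.DSAC:
                cm = make_cell(st)
            else:
                cm = make_cell(st, n_gemmule=net.n_gemmule)
            self.handles[cid] = self.grp.add_cell(cm, max_seg_length)

        syn_cfg = bio["synapse"]
        self.w_exc_max_uS = syn_cfg["w_exc_max_uS"]
        self.w_inh_max_uS = syn_cfg["w_inh_max_uS"]
        self.exc_idx = np.zeros(0, dtype=np.int64)
        self.inh_idx = np.zeros(0, dtype=np.int64)
        self.syn_pcomp = np.zeros(0, dtype=np.int64)
        self.syn_gc_soma = np.zeros(0, dtype=np.int64)
        if net.synapses is not None and len(net.synapses):
            tab = net.synapses
            ampa, gaba = syn_cfg["ampa"], syn_cfg["gaba"]
            exc_idx, inh_idx, pcomp, gsoma = [], [], [], []
            gem_cache: dict[int, np.ndarray] = {}
            for k in range(len(tab)):
                pid = int(tab.principal_id[k])
                gid = int(tab.gc_id[k])
                hp, hg = self.handles[pid], self.handles[gid]
                pc = hp.offset + hp.tree.comp_at(
                    int(tab.section_id[k]), float(tab.sec_frac[k])
                )
                if gid not in gem_cache:
                    gem_cache[gid] = np.flatnonzero(
                        np.asarray([kk is SectionKind.TUFT for kk in hg.tree.kind])
                    )
                gems = gem_cache[gid]
                gc = hg.offset + int(gems[int(tab.gc_slot[k]) % len(gems)])
                exc_idx.append(self.grp.add_synapse(
                    pc, gc, ampa["e_rev"], ampa["tau_rise"], ampa["tau_decay"],
                    float(tab.w_exc[k]) * self.w_exc_max_uS,
                ))
                inh_idx.append(self.grp.add_synapse(
                    gc, pc, gaba["e_rev"], gaba["tau_rise"], gaba["tau_decay"],
                    float(tab.w_inh[k]) * self.w_inh_max_uS,
                ))
                pcomp.append(pc)
                gsoma.append(hg.soma)
            self.exc_idx = np.asarray(exc_idx, dtype=np.int64)
            self.inh_idx = np.asarray(inh_idx, dtype=np.int64)
            self.syn_pcomp = np.asarray(pcomp, dtype=np.int64)
            self.syn_gc_soma = np.asarray(gsoma, dtype=np.int64)

        # dSAC wiring: mTC axon -> dSAC excitation; targets gated tonically
        ds = syn_cfg["dsac_exc"]
        self.dsac_soma: dict[int, int] = {}
        self.dsac_targets: dict[int, list[int]] = {}
        for w in net.dsacs:
            hd = self.handles[w.dsac_id]
            self.dsac_soma[w.dsac_id] = hd.soma
            self.dsac_targets[w.dsac_id] = list(w.inhibitory_targets)
            for mtc in w.excitatory_inputs:
                hm = self.handles[mtc]
                axon = [
                    i for i, kk in enumerate(hm.tree.kind) if kk is SectionKind.AXON
                ]
                pre = hm.offset + axon[-1]  # distal axon compartment
                self.grp.add_synapse(
                    pre, hd.soma, ds["e_rev"], ds["tau_rise"], ds["tau_decay"],
                    DSAC_EXC_W_US,
                )
        self.dsac_gc_tonic = syn_cfg["dsac_gc_tonic_uS"]
        self.dsacs_enabled = bool(net.dsacs)

        # per-principal background synaptic noise (independent Poisson
        # trains onto the soma), emulating the stochastic synaptic
        # bombardment that decorrelates unconnected cells in vivo
        self.noise_rate = noise_rate_hz
        self._noise_rng = np.random.default_rng(noise_seed)
        self.noise_syn: list[int] = []
        if noise_rate_hz > 0:
            for cid in sorted(net.cells):
                if net.cells[cid].subtype in (Subtype.MC, Subtype.MTC):
                    h = self.handles[cid]
                    self.noise_syn.append(
                        self.grp.add_synapse(-1, h.soma, 0.0, 0.5, 5.0, noise_w_uS)
                    )

        self.grp.finalize(v_init=bio["passive"]["principal"]["e_l"])

        # odor drive rows on tuft compartments of principal cells
        g_unit = bio["drive"]["g_per_unit_uS"]
        row_of = drive_row_of or (lambda info: info.glom_id)
        self.n_drive_rows = n_drive_rows or len(net.units)
        for cid, info in net.cells.items():
            if info.subtype not in (Subtype.MC, Subtype.MTC):
                continue
            row = row_of(info)
            if row is None or row < 0:
                continue
            h = self.handles[cid]
            for i, kk in enumerate(h.tree.kind):
                if kk is SectionKind.TUFT:
                    self.grp.drive_idx[h.offset + i] = row
                    self.grp.drive_g[h.offset + i] = g_unit
        # record spikes at every soma
        self.soma_of = {cid: h.soma for cid, h in self.handles.items()}
        for c in self.soma_of.values():
            self.grp.spk_flag[c] = True
        self._comp_to_cell = {h.soma: cid for cid, h in self.handles.items()}

    # -- weights ------------------------------------------------------------

    def set_weights(self, w_exc: np.ndarray, w_inh: np.ndarray) -> None:
        """Load dimensionless weights (0..1) into the live synapse tables."""
        self.grp.syn_w_a[self.exc_idx] = np.asarray(w_exc) * self.w_exc_max_uS
        self.grp.syn_w_a[self.inh_idx] = np.asarray(w_inh) * self.w_inh_max_uS

    def sync_weights_from_net(self) -> None:
        if self.net.synapses is not None and len(self.net.synapses):
            self.set_weights(self.net.synapses.w_exc, self.net.synapses.w_inh)

    # -- clamping -------------------------------------------------------------

    def clamp_soma(self, cell_id: int, holding: float = -60.0) -> None:
        self.grp.set_clamp([self.handles[cell_id].soma], [holding])

    # -- main loop -------------------------------------------------------------

    def run(
        self,
        drive: GlomerularDrive | np.ndarray,
        duration: float,
        window_ms: float = 50.0,
        on_window=None,
    ):
        """Advance the network under a drive for ``duration`` ms.

        ``on_window(sim, window_index, spike_count_delta)`` runs after each
        window with that window's per-compartment spike counts (used by the
        plasticity rule).  Returns (SpikeData, clamp_current_trace_nA).
        """
        if isinstance(drive, np.ndarray):
            drive = constant_drive(drive)
        nwin = max(1, int(round(duration / window_ms)))
        steps_per_win = max(1, int(round(window_ms / self.dt)))
        spikes: dict[int, list] = {}
        clamp_all = []
        for w in range(nwin):
            base = self.grp.spike_count.copy()
            wave = drive.waveform(steps_per_win, self.dt, t0=self.grp.t)
            if wave.shape[0] < self.n_drive_rows:
                pad = np.zeros((self.n_drive_rows - wave.shape[0], steps_per_win))
                wave = np.vstack([wave, pad])
            ext = None
            if self.noise_syn:
                ev = []
                for k in self.noise_syn:
                    n_ev = self._noise_rng.poisson(self.noise_rate * window_ms / 1000.0)
                    steps = np.sort(self._noise_rng.integers(0, steps_per_win, n_ev))
                    ev.extend((int(s), k) for s in steps)
                ev.sort()
                ext = (
                    np.asarray([a for a, _ in ev], dtype=np.int64),
                    np.asarray([b for _, b in ev], dtype=np.int64),
                )
            _, clamp, (spk_c, spk_t) = self.grp.run(
                steps_per_win, wave=wave, ext_events=ext
            )
            if clamp.shape[0]:
                clamp_all.append(clamp)
            for c, t in zip(spk_c, spk_t):
                cid = self._comp_to_cell.get(int(c))
                if cid is not None:
                    spikes.setdefault(cid, []).append(t)
            delta = self.grp.spike_count - base
            self._update_dsac_gating(delta, window_ms)
            if on_window is not None:
                on_window(self, w, delta)
        data = SpikeData({cid: np.asarray(ts) for cid, ts in spikes.items()})
        clamp_trace = np.concatenate(clamp_all, axis=1)[0] if clamp_all else None
        return data, clamp_trace

    def _update_dsac_gating(self, delta: np.ndarray, window_ms: float) -> None:
        if not self.dsacs_enabled:
            return
        gate = np.zeros_like(self.grp.g_tonic)
        for did, soma in self.dsac_soma.items():
            rate = delta[soma] / (window_ms / 1000.0)
            if rate > DSAC_RATE_THRESHOLD_HZ:
                for gcid in self.dsac_targets[did]:
                    h = self.handles[gcid]
                    gate[h.soma] += self.dsac_gc_tonic
        self.grp.g_tonic = gate


# ---------------------------------------------------------------------------
# probe measurements used by the analysis and experiments modules
# ---------------------------------------------------------------------------


def _probe_cell(net: NetworkModel, probe_unit: int, cell_type: str) -> int:
    u = net.unit(probe_unit)
    ids = u.mc_ids if cell_type == "MC" else u.mtc_ids
    if not ids:
        raise ValueError(f"unit {probe_unit} has no {cell_type} cells")
    return ids[0]


def measure_ipsc_peak(
    net: NetworkModel,
    probe_unit: int,
    cell_type: str = "MC",
    holding: float = -60.0,
    stim_unit: int | None = None,
    stim_amp: float = 1.0,
    duration: float = 500.0,
    onset: float = 100.0,
    dt: float = 0.05,
) -> float:
    """Peak outward somatic clamp current (nA) evoked by driving another GU.

    The probe principal cell is voltage-clamped at ``holding``; the
    stimulated unit is driven at ``stim_amp`` from ``onset`` onward; the
    IPSC peak is the maximum outward deviation of the clamp current from
    its pre-stimulus baseline.  Returns 0 when no synaptic path exists.
    """
    gloms = [u.glom_id for u in net.units]
    if stim_unit is None:
        stim_unit = next(g for g in gloms if g != probe_unit)
    sim = NetSim(net, dt=dt)
    sim.sync_weights_from_net()
    pid = _probe_cell(net, probe_unit, cell_type)
    sim.clamp_soma(pid, holding)
    amps = np.zeros(len(gloms))
    _, base_trace = sim.run(constant_drive(amps), onset, window_ms=onset)
    amps[gloms.index(stim_unit)] = stim_amp
    _, stim_trace = sim.run(constant_drive(amps), duration, window_ms=50.0)
    if base_trace is None or stim_trace is None:
        return 0.0
    # engine clamp output is g*(V_hold - V): an outward synaptic current
    # drags V below holding, so the clamp output goes positive; subtract the
    # baseline and keep the outward direction
    baseline = float(np.median(base_trace))
    dev = stim_trace - baseline
    return float(max(dev.max(), 0.0))


def measure_rate_change(
    net: NetworkModel,
    s_probe: float,
    s_co: float,
    cell_type: str = "MC",
    probe_unit: int | None = None,
    duration: float = 1200.0,
    settle: float = 200.0,
    dt: float = 0.05,
    sniff_rate: float = 3.0,
) -> float:
    """Percent firing-rate change of the probe unit when a co-unit is active.

    Runs the network twice (probe alone; probe + co-unit) under
    sniff-modulated drive and compares the mean per-cell rate of the probe
    unit's principal cells of ``cell_type``.
    """
    gloms = [u.glom_id for u in net.units]
    if probe_unit is None:
        probe_unit = gloms[0]
    u = net.unit(probe_unit)
    ids = u.mc_ids if cell_type == "MC" else u.mtc_ids

    def run_with(amp_vec):
        sim = NetSim(net, dt=dt)
        sim.sync_weights_from_net()
        drv = GlomerularDrive(amp_vec, sniff_rate=sniff_rate, modulation_depth=0.3)
        data, _ = sim.run(drv, duration)
        return data.rate(ids, settle, duration)

    alone = np.zeros(len(gloms))
    alone[gloms.index(probe_unit)] = s_probe
    both = alone.copy()
    for g in gloms:
        if g != probe_unit:
            both[gloms.index(g)] = s_co
    r_alone = run_with(alone)
    r_both = run_with(both)
    if r_alone == 0:
        return 0.0
    return 100.0 * (r_both - r_alone) / r_alone
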