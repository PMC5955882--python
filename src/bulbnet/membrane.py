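"""Cell models, stimulation protocols and firing-phenotype analysis.

Five cell subtypes are provided: mitral (MC), middle tufted (mTC),
superficial and deep granule (sGC/dGC) and deep short-axon (dSAC) cells.
MCs carry fast Na, A-type K and delayed-rectifier K conductances and fire
tonically; mTCs replace the delayed rectifier with a slow K conductance
(K_S), which yields clustered bursting at low drive, tonic firing at high
drive, and rebound clusters after brief pauses in depolarization.  dGCs
have a higher K_DR and lower Na density than sGCs (they are less
excitable).  Channel gating parameters and densities are calibrated
against the target input resistances and firing phenotypes and ship in a
versioned fixture file (``fixtures/biophys.yaml``).

Passive properties are uniform over the somatodendritic membrane; the axon
leak is scaled by a fixed factor and its Na density is 30-fold the
somatodendritic one, so action potentials initiate near the soma.
"""

from __future__ import annotations

import copy
import functools
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources

import numpy as np
import yaml

from . import engine
from .engine import SimGroup, passive_linear_system
from .morpho import (
    CellType,
    Morphology,
    SectionKind,
    gc_fixture_morphology,
    make_reduced_morphology,
)

REGIONS = ("soma", "apical", "tuft", "lateral", "axon")


@dataclass
class PassiveProps:
    """Passive membrane parameters (Ra in Ohm*cm, Cm in uF/cm^2, g_l in S/cm^2)."""

    ra: float
    cm: float
    g_l: float
    e_l: float
    axon_gl_scale: float = 1.0

    def __post_init__(self):
        if self.ra <= 0 or self.cm <= 0 or self.g_l < 0:
            raise ValueError("Ra and Cm must be positive, g_l non-negative")


@dataclass
class ChannelSpec:
    """One conductance: kind in {Na, K_A, K_DR, K_S}, densities per region."""

    kind: str
    gbar: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("Na", "K_A", "K_DR", "K_S"):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if any(v < 0 for v in self.gbar.values()):
            raise ValueError("gbar must be >= 0")


class Subtype(str, Enum):
    MC = "MC"
    MTC = "mTC"
    SGC = "sGC"
    DGC = "dGC"
    DSAC = "dSAC"


@dataclass
class CellModel:
    morphology: Morphology
    passive: PassiveProps
    channels: list[ChannelSpec]
    subtype: Subtype

    def channel(self, kind: str) -> ChannelSpec | None:
        for ch in self.channels:
            if ch.kind == kind:
                return ch
        return None


@dataclass
class Protocol:
    """Piecewise-constant somatic stimulation.

    segments: list of (duration ms, injected current pA); clamp_mode
    'current' or 'voltage' (holding used in voltage mode).
    """

    segments: list[tuple[float, float]]
    site: str | tuple[int, float] = "soma"
    clamp_mode: str = "current"
    holding: float = -60.0

    def __post_init__(self):
        if any(d <= 0 for d, _ in self.segments):
            raise ValueError("segment durations must be > 0")

    @property
    def duration(self) -> float:
        return sum(d for d, _ in self.segments)

    @classmethod
    def step(cls, amplitude_pA: float, onset: float = 100.0, length: float = 1000.0,
             tail: float = 100.0) -> "Protocol":
        return cls([(onset, 0.0), (length, amplitude_pA), (tail, 0.0)])


@dataclass
class VoltageTrace:
    dt: float
    site: int
    values: np.ndarray
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * (np.arange(self.values.shape[0]) + 1)


@dataclass
class SpikeTrain:
    times: np.ndarray
    cell_id: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and (np.any(np.diff(self.times) <= 0) or self.times[0] < 0):
            raise ValueError("spike times must be non-negative and strictly increasing")

    def __len__(self):
        return self.times.shape[0]


@dataclass
class SimResult:
    trace: VoltageTrace
    spikes: SpikeTrain
    traces: dict[str, VoltageTrace] = field(default_factory=dict)
    clamp_current: np.ndarray | None = None  # nA, positive = outward


# ---------------------------------------------------------------------------
# biophysics fixture
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=1)
def load_biophys() -> dict:
    with resources.files("bulbnet.fixtures").joinpath("biophys.yaml").open() as fh:
        return yaml.safe_load(fh)


def _passive_from(cfg: dict) -> PassiveProps:
    return PassiveProps(
        ra=cfg["ra"], cm=cfg["cm"], g_l=cfg["g_l"], e_l=cfg["e_l"],
        axon_gl_scale=cfg.get("axon_gl_scale", 1.0),
    )


def _channels_from(cfg: dict) -> list[ChannelSpec]:
    return [ChannelSpec(kind, dict(dens)) for kind, dens in cfg.items()]


def make_cell(
    subtype: Subtype | str,
    morphology: Morphology | None = None,
    slice_corrected: bool = True,
    n_gemmule: int | None = None,
) -> CellModel:
    """Build a calibrated cell model of the given subtype.

    A custom ``morphology`` (e.g. a synthetic tree) may be supplied for
    principal cells; the granule-cell variants accept ``n_gemmule`` to
    trade spine count for speed in large networks.
    """
    st = Subtype(subtype)
    bio = load_biophys()
    if st in (Subtype.MC, Subtype.MTC):
        m = morphology or make_reduced_morphology(
            CellType.MC if st is Subtype.MC else CellType.MTC
        )
        return CellModel(
            m,
            _passive_from(bio["passive"]["principal"]),
            _channels_from(bio["channels"][st.value]),
            st,
        )
    if st is Subtype.DSAC:
        m = morphology or make_reduced_morphology(CellType.DSAC, slice_corrected)
        return CellModel(
            m, _passive_from(bio["passive"]["dsac"]),
            _channels_from(bio["channels"]["dSAC"]), st,
        )
    # granule cells: +-25% contrast on K_DR and Na around the common mean
    m = morphology or gc_fixture_morphology(
        n_gemmule if n_gemmule is not None else 50
    )
    chans = _channels_from(bio["channels"]["GC"])
    contrast = bio["channels"].get("gc_contrast", 0.25)
    sign = -1.0 if st is Subtype.SGC else 1.0  # dGC: more K_DR, less Na
    out = []
    for ch in chans:
        dens = dict(ch.gbar)
        if ch.kind == "K_DR":
            dens = {k: v * (1 + sign * contrast) for k, v in dens.items()}
        if ch.kind == "Na":
            dens = {k: v * (1 - sign * contrast) for k, v in dens.items()}
        out.append(ChannelSpec(ch.kind, dens))
    return CellModel(m, _passive_from(bio["passive"]["gc"]), out, st)


def swap_channel(cell: CellModel, old_kind: str, new_kind: str) -> CellModel:
    """Replace one conductance kind by another at the same densities.

    Used for the channel-swap ablation: giving the mTC model a delayed
    rectifier in place of its slow K conductance abolishes bursting.
    """
    new = copy.deepcopy(cell)
    for ch in new.channels:
        if ch.kind == old_kind:
            ch.kind = new_kind
    return new


# ---------------------------------------------------------------------------
# simulation protocols
# ---------------------------------------------------------------------------


def _site_comp(handle, protocol_site) -> int:
    if protocol_site == "soma":
        return handle.soma
    sec, frac = protocol_site
    return handle.offset + handle.tree.comp_at(sec, frac)


def simulate(
    cell: CellModel,
    protocol: Protocol,
    dt: float = 0.025,
    synaptic_inputs: list[dict] | None = None,
    record_sites: dict[str, tuple[int, float]] | None = None,
    max_seg_length: float = 20.0,
) -> SimResult:
    """Run a protocol on one cell and return soma trace plus spike train.

    ``synaptic_inputs`` is an optional event schedule: a list of dicts with
    keys times (ms), site ((section, frac) or 'soma'), weight_uS, e_rev,
    tau_rise, tau_decay.
    """
    bio = load_biophys()
    grp = SimGroup(bio["kinetics"], dt)
    h = grp.add_cell(cell, max_seg_length)
    ext_sched = []
    if synaptic_inputs:
        for spec in synaptic_inputs:
            comp = _site_comp(h, spec.get("site", "soma"))
            k = grp.add_synapse(
                -1, comp, spec.get("e_rev", 0.0), spec.get("tau_rise", 0.5),
                spec.get("tau_decay", 5.0), spec["weight_uS"],
            )
            for tm in np.atleast_1d(spec["times"]):
                ext_sched.append((float(tm), k))
    grp.finalize(v_init=cell.passive.e_l)
    site = _site_comp(h, protocol.site)
    rec = [h.soma]
    names = ["soma"]
    if record_sites:
        for name, loc in record_sites.items():
            rec.append(_site_comp(h, loc))
            names.append(name)
    grp.spk_flag[h.soma] = True

    if protocol.clamp_mode == "voltage":
        grp.set_clamp([site], [protocol.holding])

    values = []
    clamp = []
    t_cursor = 0.0
    for dur, amp in protocol.segments:
        nsteps = max(1, int(round(dur / dt)))
        if protocol.clamp_mode == "current":
            grp.i_inj[:] = 0.0
            grp.i_inj[site] = amp * 1e-3  # pA -> nA
        ev = [(tm, k) for tm, k in ext_sched if t_cursor <= tm < t_cursor + nsteps * dt]
        ev.sort()
        ext = (
            np.asarray([int((tm - t_cursor) / dt) for tm, _ in ev], dtype=np.int64),
            np.asarray([k for _, k in ev], dtype=np.int64),
        )
        out, cl, _ = grp.run(nsteps, dt, record=np.asarray(rec), ext_events=ext)
        values.append(out)
        if cl.shape[0]:
            clamp.append(cl[0])
        t_cursor += nsteps * dt
    allv = np.concatenate(values, axis=1)
    traces = {
        name: VoltageTrace(dt, rec[i], allv[i]) for i, name in enumerate(names)
    }
    soma_trace = traces["soma"]
    spikes = detect_spikes(soma_trace)
    clamp_current = -np.concatenate(clamp) if clamp else None  # outward positive
    return SimResult(soma_trace, spikes, traces, clamp_current)


def input_resistance(
    cell: CellModel,
    probe_current_pA: float = -20.0,
    max_seg_length: float = 20.0,
) -> float:
    """Steady-state somatic input resistance in MOhm.

    Computed from the steady state of the passive system (channels
    disabled): the linearity of the passive cable makes the steady-state
    ratio dV/dI exact for any small probe current.
    """
    G, _C, _tree = passive_linear_system(cell, max_seg_length)
    i = np.zeros(G.shape[0])
    i[0] = probe_current_pA * 1e-3  # nA
    v = np.linalg.solve(G, i)
    return float(v[0] / i[0])  # mV/nA = MOhm


def detect_spikes(trace: VoltageTrace, dvdt_threshold: float = 20.0) -> SpikeTrain:
    """Threshold upward dV/dt crossings with a 2 ms refractory lockout."""
    if dvdt_threshold <= 0:
        raise ValueError("threshold must be > 0")
    v = trace.values
    if v.shape[0] < 2:
        return SpikeTrain(np.zeros(0))
    dvdt = np.diff(v) / trace.dt
    above = dvdt >= dvdt_threshold
    times = []
    last = -1e9
    t = trace.t0 + trace.dt * (np.arange(dvdt.shape[0]) + 1)
    for i in np.flatnonzero(above):
        if t[i] - last >= 2.0:
            times.append(t[i])
            last = t[i]
    return SpikeTrain(np.asarray(times))


# burst rule: a cluster is >= 2 spikes with inter-spike intervals < 15 ms;
# bursting requires >= 2 clusters separated by > 50 ms
CLUSTER_ISI = 15.0
CLUSTER_GAP = 50.0


def spike_clusters(times: np.ndarray) -> list[np.ndarray]:
    """Split a spike train into maximal groups with ISIs < CLUSTER_ISI."""
    if len(times) == 0:
        return []
    cuts = np.flatnonzero(np.diff(times) >= CLUSTER_ISI) + 1
    return np.split(np.asarray(times), cuts)


def classify_firing(train: SpikeTrain, trace: VoltageTrace | None = None) -> str:
    """'silent', 'tonic' or 'bursting' for a step-protocol response."""
    if len(train) == 0:
        return "silent"
    groups = [g for g in spike_clusters(train.times) if g.shape[0] >= 2]
    for g1, g2 in zip(groups, groups[1:]):
        if g2[0] - g1[-1] > CLUSTER_GAP:
            return "bursting"
    return "tonic"


def rebound_response(
    cell: CellModel,
    base_current_pA: float,
    pause_ms: float = 50.0,
    pause_rate_hz: float = 4.0,
    duration_ms: float = 2000.0,
    onset_ms: float = 300.0,
    dt: float = 0.025,
) -> tuple[bool, list[float]]:
    """Inject a step current with periodic pauses to 0 pA.

    Returns (fires_rebound, first-spike latencies): fires_rebound is true
    when a spike cluster (>= 2 spikes, ISIs < 15 ms) begins within 60 ms
    after at least half of the repolarizations.
    """
    if pause_ms <= 0:
        raise ValueError("pause_ms must be > 0")
    period = 1000.0 / pause_rate_hz
    segments: list[tuple[float, float]] = [(onset_ms, base_current_pA)]
    t = onset_ms
    repolarizations = []
    while t + period <= duration_ms:
        segments.append((pause_ms, 0.0))
        repolarizations.append(t + pause_ms)
        segments.append((period - pause_ms, base_current_pA))
        t += period
    res = simulate(cell, Protocol(segments), dt=dt)
    times = res.spikes.times
    clusters = [g for g in spike_clusters(times) if g.shape[0] >= 2]
    starts = np.asarray([g[0] for g in clusters]) if clusters else np.zeros(0)
    latencies: list[float] = []
    hits = 0
    for rt in repolarizations:
        sel = starts[(starts >= rt) & (starts <= rt + 60.0)]
        after = times[(times >= rt) & (times <= rt + 60.0)]
        if after.size:
            latencies.append(float(after[0] - rt))
        if sel.size:
            hits += 1
    fires = bool(repolarizations) and hits >= 0.5 * len(repolarizations)
    return fires, latencies
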