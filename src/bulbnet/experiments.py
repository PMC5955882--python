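"""Scripted, seeded reproductions of the model's in-silico experiments.

Four experiment families:

* two-cell synchronization: two principal cells (MC or mTC) and two granule
  cells under weak ~3 Hz drive; separate, reciprocal, or common-external GC
  wiring.  Shared granule-cell inhibition synchronizes mTC burst clusters
  but leaves tonically firing MCs unaffected.
* lateral inhibition vs distance: pairs of glomerular units at increasing
  separation; after column formation the somatic IPSC evoked in a probe
  cell by driving the other unit decays with distance, more steeply for
  mTCs (shorter lateral dendrites) than MCs; co-connectivity of GCs with
  both cell types removes the difference, and uniformly redistributed
  weights destroy the columnar profile.
* column formation: a strongly and a weakly driven unit; glomerular-layer
  normalization silences the weak unit so only the strong unit grows a
  full-depth column; disconnecting mTCs from the glomerular inhibition
  leaves a shallow superficial column under the weak unit.
* cluster gating: four units in two clusters; granule-cell columns couple
  all units, and dSACs (driven by mTC axons, silencing cluster-bridging
  GCs) restore independence between clusters while preserving coupling
  within them.

All experiments are deterministic given their seed.  Desk-scale defaults
(cell counts, drive amplitudes, durations) are chosen so each runner
completes in minutes on one core.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .analysis import cross_correlation, rate_series, reliability
from .engine import SimGroup
from .glomin import GlomerularDrive, glomerular_inhibition
from .membrane import Subtype, load_biophys, make_cell
from .morpho import CellType, SectionKind, default_branch_stats, gc_fixture_morphology, write_swc
from .netbuild import (
    Geometry,
    NetworkModel,
    assign_clusters,
    build_network,
    connect_reciprocal,
    wire_dsacs,
)
from .netsim import NetSim, measure_ipsc_peak
from .plasticity import ColumnMap, PlasticityRule, extract_column, run_learning, uniformize_weights


@dataclass
class ExperimentConfig:
    """Serializable description of one experiment run."""

    name: str
    seed: int = 0
    params: dict = field(default_factory=dict)
    out_dir: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# two-cell synchronization
# ---------------------------------------------------------------------------

SYNC_DEFAULTS = dict(
    amp=0.55,            # drive amplitude (activation units)
    depth=0.4,           # sniff modulation depth; period 350 ms
    period_ms=350.0,
    asym=0.12,           # deterministic drive asymmetry between the cells
    noise_rate=40.0,     # Hz, per-cell background synaptic noise
    noise_w=0.0004,      # uS
    exc_contacts=6,
    inh_contacts=8,
    w_exc_contact=0.0005,  # uS: GCs fire volleys on joint bursts
    w_inh_contact=0.016,   # uS: potentiated compound dendrodendritic contact
    ext_w=0.01,          # uS, common-external volley onto GC somas
    ext_tau_decay=30.0,
    ext_phase_ms=330.0,  # volley time within the cycle (near the trough)
    duration=4200.0,
    dt=0.05,
)


def exp_two_cell_sync(
    cell_type: str = "mTC",
    wiring: str = "separate",
    seed: int = 0,
    **overrides,
) -> dict:
    """Paired-cell microcircuit: two principal cells + two granule cells.

    wiring: 'separate' (each GC reciprocally connected to its own cell),
    'reciprocal' (each GC has reciprocal contacts with both cells), or
    'common_external' (no principal->GC links; both GCs receive the same
    external excitatory volleys).  Returns the pairwise spike-time
    synchrony (sigma = 5 ms reliability between the two somatic trains).
    """
    if wiring not in ("separate", "reciprocal", "common_external"):
        raise ValueError(f"unknown wiring {wiring!r}")
    p = dict(SYNC_DEFAULTS, **overrides)
    rng = np.random.default_rng(seed)
    bio = load_biophys()
    grp = SimGroup(bio["kinetics"], p["dt"])
    cells = [grp.add_cell(make_cell(cell_type)) for _ in range(2)]
    gcs = [grp.add_cell(make_cell("sGC", n_gemmule=12)) for _ in range(2)]
    ampa, gaba = bio["synapse"]["ampa"], bio["synapse"]["gaba"]
    w_inh = p["w_inh_contact"]

    def lat(h, n):
        idx = [i for i, k in enumerate(h.tree.kind)
               if k is SectionKind.LATERAL and h.tree.path_dist[i] < 400]
        return [h.offset + idx[s] for s in np.linspace(0, len(idx) - 1, n).astype(int)]

    def gem(h, n):
        idx = [i for i, k in enumerate(h.tree.kind) if k is SectionKind.TUFT]
        return [h.offset + idx[s] for s in np.linspace(0, len(idx) - 1, n).astype(int)]

    ext_syn = []
    for i, (pc_h, g) in enumerate(zip(cells, gcs)):
        if wiring == "reciprocal":
            exc_srcs, inh_tgts = cells, cells
        elif wiring == "separate":
            exc_srcs, inh_tgts = [pc_h], [pc_h]
        else:
            exc_srcs, inh_tgts = [], [pc_h]
        for src in exc_srcs:
            for pc, gc in zip(lat(src, p["exc_contacts"]), gem(g, p["exc_contacts"])):
                grp.add_synapse(pc, gc, ampa["e_rev"], ampa["tau_rise"],
                                ampa["tau_decay"], p["w_exc_contact"])
        gsites = gem(g, p["inh_contacts"])
        for tgt in inh_tgts:
            for pc, gc in zip(lat(tgt, p["inh_contacts"]), gsites):
                grp.add_synapse(gc, pc, gaba["e_rev"], gaba["tau_rise"],
                                gaba["tau_decay"], w_inh)
        if wiring == "common_external":
            ext_syn.append(grp.add_synapse(-1, g.soma, 0.0, 0.5,
                                           p["ext_tau_decay"], p["ext_w"]))
    noise_syn = [grp.add_synapse(-1, c.soma, 0.0, 0.5, 5.0, p["noise_w"]) for c in cells]
    grp.finalize()
    g_drive = bio["drive"]["g_per_unit_uS"]
    for i, c in enumerate(cells):
        for k in range(c.offset, c.offset + c.ncomp):
            if c.tree.kind[k - c.offset] is SectionKind.TUFT:
                grp.drive_idx[k] = i
                grp.drive_g[k] = g_drive
    for x in cells + gcs:
        grp.spk_flag[x.soma] = True

    amps = p["amp"] * np.array([1 + p["asym"], 1 - p["asym"]])
    amps = amps * (1 + 0.03 * rng.uniform(-1, 1, 2))
    dt, dur = p["dt"], p["duration"]
    nsteps = int(dur / dt)
    t = dt * (np.arange(nsteps) + 1)
    wave = np.vstack([
        a * (1 - p["depth"] * 0.5 * (1 + np.cos(2 * np.pi * t / p["period_ms"])))
        for a in amps
    ])
    ev = []
    for k in noise_syn:
        n_ev = rng.poisson(p["noise_rate"] * dur / 1000.0)
        for tt in np.sort(rng.uniform(0, dur, n_ev)):
            ev.append((int(tt / dt), k))
    for base in np.arange(p["ext_phase_ms"], dur, p["period_ms"]):
        for k in ext_syn:
            ev.append((int(base / dt), k))
    ev.sort()
    ext_events = (
        np.asarray([a for a, _ in ev], dtype=np.int64),
        np.asarray([b for _, b in ev], dtype=np.int64),
    )
    _, _, (sc, st) = grp.run(nsteps, wave=wave, ext_events=ext_events)
    trains = [st[sc == c.soma] for c in cells]
    sync = reliability(trains, sigma=5.0)
    return {
        "cell_type": cell_type,
        "wiring": wiring,
        "synchrony": float(sync),
        "n_spikes": [int(len(tr)) for tr in trains],
        "gc_spikes": [int((sc == g.soma).sum()) for g in gcs],
        "trains": trains,
    }


def sync_summary(cell_type: str, seeds=range(4), **overrides) -> dict:
    """Mean synchrony per wiring plus gains over the separate baseline."""
    out = {}
    for wiring in ("separate", "reciprocal", "common_external"):
        vals = [exp_two_cell_sync(cell_type, wiring, s, **overrides)["synchrony"]
                for s in seeds]
        out[wiring] = float(np.mean(vals))
    out["gain_reciprocal"] = out["reciprocal"] - out["separate"]
    out["gain_common_external"] = out["common_external"] - out["separate"]
    return out


# ---------------------------------------------------------------------------
# paired-unit networks (lateral inhibition, column formation)
# ---------------------------------------------------------------------------


def build_pair_network(
    distance: float,
    co_connectivity: float = 0.0,
    seed: int = 0,
    n_sniffs: int = 12,
    gc_per_um: float = 0.35,
    learned: bool = True,
    drive_amps=None,
) -> NetworkModel:
    """Two glomerular units at the given separation, laterals aligned on x.

    Learning (both units strongly driven unless ``drive_amps`` overrides)
    forms the columns used by the lateral-inhibition probes.
    """
    width = distance + 900.0
    net = build_network(
        2, 1, 2, n_gc=int(gc_per_um * width),
        geometry=Geometry((width, 600.0), 400.0), seed=seed,
        glom_positions=[(400.0, 300.0), (400.0 + distance, 300.0)],
        aligned_axis=True,
    )
    net = connect_reciprocal(net, density=0.1, co_connectivity=co_connectivity,
                             seed=seed + 1)
    if learned:
        amps = glomerular_inhibition(np.asarray(drive_amps if drive_amps is not None
                                                else [1.0, 1.0], dtype=float))
        drive = GlomerularDrive(amps, sniff_rate=3.0, modulation_depth=0.3,
                                amp_jitter=0.05, phase_jitter_ms=10, seed=seed + 2)
        net = run_learning(net, drive, PlasticityRule(), n_sniffs=n_sniffs)
    return net


def half_decay_distance(distances, curve) -> float:
    """First distance at which a normalized curve falls below 0.5."""
    d = np.asarray(distances, dtype=float)
    c = np.asarray(curve, dtype=float)
    below = np.flatnonzero(c < 0.5)
    if below.size == 0:
        return float(d[-1])
    i = below[0]
    if i == 0:
        return float(d[0])
    # linear interpolation between the bracketing grid points
    f = (c[i - 1] - 0.5) / (c[i - 1] - c[i])
    return float(d[i - 1] + f * (d[i] - d[i - 1]))


def exp_lateral_inhibition(
    co_connectivity_grid=(0.0, 1.0),
    weight_layout: str = "columnar",
    seed: int = 0,
    distances=(100.0, 250.0, 400.0, 600.0),
    n_sniffs: int = 12,
) -> dict:
    """Normalized IPSC-vs-distance curves for MC and mTC probes.

    Builds a learned pair network per distance and co-connectivity level,
    voltage-clamps the probe cell while driving the other unit, and
    normalizes the peak outward current per cell type.  'uniform' layout
    redistributes each unit's learned weights evenly before probing.
    """
    if weight_layout not in ("columnar", "uniform"):
        raise ValueError(f"unknown weight layout {weight_layout!r}")
    out = {"distances": list(distances), "curves": {}, "half_decay": {}}
    for co in co_connectivity_grid:
        peaks = {"MC": [], "mTC": []}
        for d in distances:
            net = build_pair_network(d, co, seed=seed, n_sniffs=n_sniffs)
            if weight_layout == "uniform":
                for g in (0, 1):
                    uniformize_weights(net, g)
            for ct in ("MC", "mTC"):
                peaks[ct].append(
                    measure_ipsc_peak(net, probe_unit=0, cell_type=ct, stim_unit=1)
                )
        for ct in ("MC", "mTC"):
            arr = np.asarray(peaks[ct])
            mx = arr.max()
            curve = arr / mx if mx > 0 else arr
            out["curves"][(co, ct)] = curve
            out["half_decay"][(co, ct)] = half_decay_distance(distances, curve)
    return out


COLUMN_DEFAULTS = dict(weak=0.35, n_sniffs=26, n_gc=240, distance=350.0)


def exp_column_formation(
    glomerular_inhibition_on_mtc: bool = True,
    seed: int = 0,
    **overrides,
) -> dict[int, ColumnMap]:
    """Strong + weak unit; returns the column map per glomerulus.

    With glomerular inhibition acting on both cell types (control), only
    the strongly driven unit grows a column and it spans the full GCL
    depth.  With mTCs disconnected from the glomerular circuitry
    (ablation), the weak unit's un-suppressed mTCs grow a shallow column
    confined to the superficial (sGC) stratum.
    """
    p = dict(COLUMN_DEFAULTS, **overrides)
    net = build_network(
        2, 1, 2, n_gc=p["n_gc"], geometry=Geometry((800.0, 600.0), 400.0),
        seed=seed, glom_positions=[(150.0, 300.0), (150.0 + p["distance"], 300.0)],
        aligned_axis=True,
    )
    net = connect_reciprocal(net, density=0.1, co_connectivity=0.0, seed=seed + 1)
    raw = np.array([1.0, p["weak"]])
    norm = glomerular_inhibition(raw)
    if glomerular_inhibition_on_mtc:
        amps, rows, nrows = norm, None, 2
    else:
        # mTC tufts bypass the glomerular-layer suppression (ablation)
        amps = np.concatenate([norm, raw])
        rows = lambda info: info.glom_id + (2 if info.subtype is Subtype.MTC else 0)
        nrows = 4
    drive = GlomerularDrive(amps, sniff_rate=3.0, modulation_depth=0.3,
                            amp_jitter=0.05, phase_jitter_ms=10, seed=seed + 2)
    net = run_learning(net, drive, PlasticityRule(), n_sniffs=p["n_sniffs"],
                       drive_row_of=rows, n_drive_rows=nrows)
    return {g: extract_column(net, g) for g in (0, 1)}


# ---------------------------------------------------------------------------
# cluster gating (4 GUs, 2 clusters, dSACs)
# ---------------------------------------------------------------------------

GLOM_NAMES = ("GL5", "GL37", "GL32", "GL78")
CLUSTER_OF = {0: 0, 1: 0, 2: 1, 3: 1}
CLUSTER_POSITIONS = [(300.0, 300.0), (460.0, 300.0), (300.0, 520.0), (460.0, 520.0)]
#: per-unit drive scaling: the units do not receive exactly the same input
CLUSTER_AMP_FACTORS = np.array([1.12, 0.88, 1.18, 0.94])
CLUSTER_DEFAULTS = dict(
    n_gc=240, reach=100.0, learn_sniffs=10, amp=0.45, depth=0.4,
    duration=2400.0, settle=300.0, bin_ms=10.0, noise_rate=40.0,
    noise_w=0.0004, n_dsac=2, inh_gain=4.0,
)


def build_cluster_network(seed: int = 0, **overrides) -> NetworkModel:
    """Four glomerular units in two clusters with learned GC columns.

    The two lateral stems of every principal cell are aimed at the nearest
    within-cluster and between-cluster units, preserving at desk scale the
    dense dendritic overlap of the full system.
    """
    p = dict(CLUSTER_DEFAULTS, **overrides)
    net = build_network(4, 1, 2, n_gc=p["n_gc"],
                        geometry=Geometry((760.0, 860.0), 400.0), seed=seed,
                        glom_positions=CLUSTER_POSITIONS)
    nearest_within = {0: 1, 1: 0, 2: 3, 3: 2}
    nearest_across = {0: 2, 1: 3, 2: 0, 3: 1}
    for u in net.units:
        my = np.asarray(CLUSTER_POSITIONS[u.glom_id])
        w = CLUSTER_POSITIONS[nearest_within[u.glom_id]]
        a = CLUSTER_POSITIONS[nearest_across[u.glom_id]]
        a1 = float(np.arctan2(w[1] - my[1], w[0] - my[0]))
        a2 = float(np.arctan2(a[1] - my[1], a[0] - my[0]))
        for cid in u.principal_ids:
            stems = sorted(net.cells[cid].stem_angle)
            net.cells[cid].stem_angle = {stems[0]: a1, stems[1]: a2}
    net = connect_reciprocal(net, density=0.1, co_connectivity=0.0,
                             seed=seed + 1, reach_radius=p["reach"])
    net = assign_clusters(net, [[0, 1], [2, 3]])
    S = glomerular_inhibition(np.ones(4))
    drive = GlomerularDrive(S, sniff_rate=3.0, modulation_depth=0.3,
                            amp_jitter=0.05, phase_jitter_ms=10, seed=seed + 2)
    return run_learning(net, drive, PlasticityRule(), n_sniffs=p["learn_sniffs"])


def exp_cluster_gating(
    net: NetworkModel | None = None,
    config: str = "columns",
    population: str = "mTC",
    cluster2_state: str = "ON",
    seed: int = 0,
    **overrides,
) -> dict:
    """Run one network configuration of the two-cluster experiment.

    config: 'no_columns' (weights zeroed), 'columns' (learned weights), or
    'columns_dsacs' (learned weights plus dSACs silencing cluster-bridging
    GCs).  Emits per-GU pooled rate series, mean rates, the spike rasters
    and the correlation matrix over the drive window.
    """
    if config not in ("no_columns", "columns", "columns_dsacs"):
        raise ValueError(f"unknown configuration {config!r}")
    p = dict(CLUSTER_DEFAULTS, **overrides)
    if net is None:
        net = build_cluster_network(seed, **overrides)
    tab = net.synapses
    saved = (tab.w_exc.copy(), tab.w_inh.copy())
    if config == "no_columns":
        tab.w_exc = np.zeros_like(saved[0])
        tab.w_inh = np.zeros_like(saved[1])
    net.dsacs = []
    added = []
    if config == "columns_dsacs":
        net = wire_dsacs(net, n_dsac=p["n_dsac"], seed=seed + 3)
        added = [w.dsac_id for w in net.dsacs]
    try:
        rng = np.random.default_rng(seed + 4)
        amps = p["amp"] * CLUSTER_AMP_FACTORS * (1 + 0.03 * rng.uniform(-1, 1, 4))
        if cluster2_state.upper() == "OFF":
            amps = amps.copy()
            amps[2:] = 0.0
        sim = NetSim(net, dt=0.05, noise_rate_hz=p["noise_rate"],
                     noise_w_uS=p["noise_w"], noise_seed=seed + 9)
        sim.sync_weights_from_net()
        # gating runs probe the mature network: potentiated dendrodendritic
        # inhibition acts as a compound conductance (inh_gain contacts)
        sim.grp.syn_w_a[sim.inh_idx] *= p["inh_gain"]
        drive = GlomerularDrive(amps, sniff_rate=3.0, modulation_depth=p["depth"],
                                seed=seed + 5)
        data, _ = sim.run(drive, p["duration"])
        settle, dur = p["settle"], p["duration"]
        series, rates = [], {}
        for g, u in enumerate(net.units):
            ids = u.mtc_ids if population == "mTC" else u.mc_ids
            pooled = data.pooled(ids)
            pooled = pooled[pooled > settle] - settle
            series.append(rate_series([pooled], p["bin_ms"], t_stop=dur - settle,
                                      label=GLOM_NAMES[g]))
            rates[GLOM_NAMES[g]] = data.rate(ids, settle, dur)
        cm = cross_correlation(series)
        dsac_rates = {d: data.rate([d], settle, dur) for d in added}
    finally:
        tab.w_exc, tab.w_inh = saved
        for d in added:
            del net.cells[d]
        net.dsacs = []
    m = cm.matrix
    within = float((m[0, 1] + m[2, 3]) / 2)
    between = float(np.mean([m[i, j] for i in (0, 1) for j in (2, 3)]))
    return {
        "config": config,
        "population": population,
        "cluster2_state": cluster2_state.upper(),
        "rates": rates,
        "rate_series": series,
        "correlations": cm,
        "within_mean": within,
        "between_mean": between,
        "dsac_rates": dsac_rates,
        "spikes": data,
    }


# ---------------------------------------------------------------------------
# fixture regeneration
# ---------------------------------------------------------------------------


def make_fixtures(seed: int = 20260926, out_dir: str | None = None) -> dict[str, Path]:
    """Deterministically regenerate the packaged fixture files.

    Rebuilds the default BranchStats (with the brute-force resampled
    terminal path-length distribution), the granule-cell SWC morphology,
    and the demo experiment configuration.  Byte-identical across runs for
    a fixed seed.
    """
    import yaml

    from .morpho import BranchStats, Distribution

    if out_dir is None:
        out = Path(__file__).parent / "fixtures"
    else:
        out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def make_stats(mu, probs, nlat, nlat_p, stem):
        bl = Distribution("lognormal", {"mean": float(np.log(mu)), "sd": 0.45})
        nl = Distribution("choice", {"values": nlat, "probs": nlat_p})
        st = BranchStats(bl, probs, nl, stem_diameter=stem)
        rng = np.random.default_rng(seed)
        pl = st.implied_path_lengths(rng, 400)
        q = np.quantile(pl, np.linspace(0.005, 0.995, 199))
        st.path_length_dist = Distribution(
            "empirical", {"values": [round(float(v), 2) for v in q]}
        )
        return st

    stats = {
        "mTC": make_stats(258.0, [0.85, 0.6, 0.3], [4, 5, 6], [0.3, 0.4, 0.3], 2.2),
        "MC": make_stats(500.0, [0.85, 0.6, 0.3], [6, 7, 8], None, 3.2),
    }
    bs_path = out / "branchstats.yaml"
    with open(bs_path, "w") as fh:
        fh.write(
            "# Default synthetic-morphology branch statistics (versioned fixture).\n"
            "# Calibrated so the mTC total-lateral-length distribution peaks near\n"
            "# 8,500 um and the synthetic populations reproduce the full-morphology\n"
            "# input resistances; path_length_dist is the descriptive terminal\n"
            "# path-length distribution implied by the growth rule (regenerated by\n"
            "# brute-force resampling in make_fixtures).\n"
        )
        yaml.safe_dump({k: v.to_dict() for k, v in stats.items()}, fh,
                       default_flow_style=None)
    paths["branchstats"] = bs_path

    swc_path = out / "gc_morphology.swc"
    write_swc(gc_fixture_morphology(50), str(swc_path))
    paths["gc_morphology"] = swc_path

    demo = ExperimentConfig(
        name="cluster_gating",
        seed=1,
        params=dict(CLUSTER_DEFAULTS, population="mTC",
                    configs=["no_columns", "columns", "columns_dsacs"]),
    )
    demo_path = out / "demo_cluster_config.json"
    with open(demo_path, "w") as fh:
        fh.write(demo.to_json() + "\n")
    paths["demo_config"] = demo_path
    return paths
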