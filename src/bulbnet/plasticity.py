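"""Activity-dependent plasticity of reciprocal dendrodendritic synapses.

All weights start at zero.  During learning, simulation windows alternate
with batch weight updates: in each window the local spike count is measured
at every synapse's principal-side dendritic compartment and at its granule
cell, and each component is modified independently --

* excitatory (principal->GC): potentiated when the principal-side local
  rate exceeds theta_LTP (backpropagating somatic action potentials
  potentiate the excitatory synapses along their way), depressed below
  theta_LTD;
* inhibitory (GC->principal): potentiated when the GC fires above
  theta_LTP, depressed below theta_LTD.

Because growing GC inhibition hinders action-potential back-propagation far
from the soma, distal sites lose their local activity and are selectively
depressed, so the potentiated synapses concentrate near strongly active
glomeruli: a granule-cell column.  Column formation is robust to the
specific increments as long as potentiation and depression are driven by
different activity levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glomin import GlomerularDrive
from .netbuild import NetworkError, NetworkModel
from .netsim import NetSim


@dataclass
class PlasticityRule:
    """Batch plasticity parameters (spike counts per window)."""

    window: float = 50.0  # ms
    theta_ltp: float = 1.5  # spikes/window above which a component potentiates
    theta_ltd: float = 1.0  # spikes/window below which it depresses
    delta_up: float = 0.1  # increment, fraction of w_max
    delta_down: float = 0.01
    w_max: float = 1.0

    def __post_init__(self):
        if not self.theta_ltp > self.theta_ltd >= 0:
            raise ValueError("theta_LTP must exceed theta_LTD >= 0")
        if self.window <= 0 or self.w_max <= 0:
            raise ValueError("window and w_max must be positive")


@dataclass
class ColumnMap:
    """Granule cells with potentiated inhibition under one glomerulus."""

    glom_id: int
    member_gc_ids: list[int]
    depth_extent: float  # fraction of GCL depth spanned by members
    lateral_spread: float  # um, max member distance from the unit position
    potentiated_sites: dict[int, list[float]] = field(default_factory=dict)
    # principal cell id -> path distances (um) of potentiated inhibitory sites


def run_learning(
    net: NetworkModel,
    drive: GlomerularDrive,
    rule: PlasticityRule,
    n_sniffs: int = 20,
    seed: int = 0,
    dt: float = 0.05,
    drive_row_of=None,
    n_drive_rows: int | None = None,
    sim: NetSim | None = None,
) -> NetworkModel:
    """Alternate simulation windows and batch weight updates.

    The drive should already be glomerular-layer normalized (weak glomeruli
    suppressed).  Weights are clipped to [0, w_max] after every update and
    written back to ``net.synapses`` (dimensionless, w_max-normalized).
    Deterministic given the network, drive and seed.
    """
    if net.synapses is None:
        raise NetworkError("connect_reciprocal before learning")
    if sim is None:
        sim = NetSim(net, dt=dt, drive_row_of=drive_row_of, n_drive_rows=n_drive_rows)
        sim.sync_weights_from_net()
    tab = net.synapses
    n = len(tab)
    w_exc = tab.w_exc.astype(float).copy()
    w_inh = tab.w_inh.astype(float).copy()
    pcomp = sim.syn_pcomp
    gsoma = sim.syn_gc_soma
    duration = n_sniffs * (1000.0 / drive.sniff_rate)

    def update(s, _w, delta):
        nonlocal w_exc, w_inh
        if n == 0:
            return
        pre = delta[pcomp]
        gcc = delta[gsoma]
        w_exc = np.clip(
            w_exc
            + rule.delta_up * rule.w_max * (pre > rule.theta_ltp)
            - rule.delta_down * rule.w_max * (pre < rule.theta_ltd),
            0.0, rule.w_max,
        )
        # inhibitory potentiation requires a firing GC *and* a locally
        # active dendritic site: inhibition-suppressed (distal or silent)
        # sites lose their inhibitory weight, which is what confines the
        # column beneath active glomeruli
        w_inh = np.clip(
            w_inh
            + rule.delta_up * rule.w_max
            * ((gcc > rule.theta_ltp) & (pre >= rule.theta_ltd))
            - rule.delta_down * rule.w_max
            * ((gcc < rule.theta_ltd) | (pre < rule.theta_ltd)),
            0.0, rule.w_max,
        )
        s.set_weights(w_exc / rule.w_max, w_inh / rule.w_max)

    sim.run(drive, duration, window_ms=rule.window, on_window=update)
    tab.w_exc = w_exc
    tab.w_inh = w_inh
    return net


def extract_column(
    net: NetworkModel,
    glom_id: int,
    membership_threshold: float = 0.5,
    w_max: float = 1.0,
) -> ColumnMap:
    """GCs with any inhibitory weight >= threshold*w_max onto the unit.

    depth_extent is (max - min member soma depth) / GCL depth;
    lateral_spread is the maximal surface distance of a member from the
    glomerulus position.
    """
    unit = net.unit(glom_id)  # raises for unknown glomeruli
    tab = net.synapses
    if tab is None or len(tab) == 0:
        return ColumnMap(glom_id, [], 0.0, 0.0)
    pids = set(unit.principal_ids)
    thr = membership_threshold * w_max
    sel = np.asarray([
        (int(p) in pids) and w >= thr
        for p, w in zip(tab.principal_id, tab.w_inh)
    ])
    members = sorted({int(g) for g in tab.gc_id[sel]}) if sel.any() else []
    if not members:
        return ColumnMap(glom_id, [], 0.0, 0.0)
    depths = np.asarray([net.cells[g].depth for g in members])
    extent = float((depths.max() - depths.min()) / net.geometry.gcl_depth)
    spread = float(max(
        np.linalg.norm(net.cells[g].position - unit.position) for g in members
    ))
    sites: dict[int, list[float]] = {}
    for k in np.flatnonzero(sel):
        sites.setdefault(int(tab.principal_id[k]), []).append(float(tab.path_dist[k]))
    return ColumnMap(glom_id, members, extent, spread, sites)


def uniformize_weights(net: NetworkModel, glom_id: int) -> NetworkModel:
    """Redistribute each component's total weight uniformly over the unit.

    The control for columnar connectivity: the summed potentiated weight on
    the unit's principal cells is conserved but spread evenly over all of
    their GC synapses, removing the spatial structure of the column.
    """
    unit = net.unit(glom_id)
    tab = net.synapses
    if tab is None or len(tab) == 0:
        return net
    pids = set(unit.principal_ids)
    sel = np.asarray([int(p) in pids for p in tab.principal_id])
    nsel = int(sel.sum())
    if nsel == 0:
        return net
    for arr in (tab.w_exc, tab.w_inh):
        total = float(arr[sel].sum())
        arr[sel] = total / nsel
    return net
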