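"""Network construction: glomerular units, reciprocal synapses, dSAC wiring.

Principal cells (MCs and mTCs) are grouped into glomerular units (GUs) at
2-D surface positions; granule-cell somata fill a 3-D granule-cell-layer
(GCL) slab below.  Reciprocal dendrodendritic synapses are placed along
principal-cell lateral dendrites as a Poisson process (default density
0.1 synapses/um) and paired with granule cells whose soma lies within a
reach radius of the site and whose depth stratum matches the principal
type: deep GCs pair with MC dendrites, superficial GCs with mTC dendrites,
and a configurable fraction of GCs is eligible for both strata
(co-connectivity).  Deep short-axon cells are excited by mTC axons and
inhibit exactly those GCs whose synaptic partners span two different
glomerular-unit clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .membrane import Subtype
from .morpho import (
    BranchStats,
    CellType,
    Morphology,
    SectionKind,
    make_reduced_morphology,
    synthesize_morphology,
)


class NetworkError(ValueError):
    pass


@dataclass
class Geometry:
    """Surface extent (um x um) and GCL depth (um)."""

    extent: tuple[float, float] = (600.0, 600.0)
    gcl_depth: float = 400.0


@dataclass
class GlomerularUnit:
    glom_id: int
    position: np.ndarray  # 2-D surface coordinate, um
    mc_ids: list[int] = field(default_factory=list)
    mtc_ids: list[int] = field(default_factory=list)

    @property
    def principal_ids(self) -> list[int]:
        return self.mc_ids + self.mtc_ids


@dataclass
class CellInfo:
    cell_id: int
    subtype: Subtype
    glom_id: int | None
    position: np.ndarray  # 2-D, um
    depth: float = 0.0  # um below the EPL border (GCs)
    morphology: Morphology | None = None
    stem_angle: dict[int, float] = field(default_factory=dict)  # stem sec -> rad


class SynapseTable:
    """Columnar store of reciprocal dendrodendritic synapses.

    Each row pairs a principal-cell lateral-dendrite site (section +
    fraction, path distance from soma, surface position) with one granule
    cell gemmule.  Weights are dimensionless in [0, w_max]; both start at
    zero and are set by learning.
    """

    COLS = (
        "principal_id",
        "section_id",
        "sec_frac",
        "path_dist",
        "x",
        "y",
        "gc_id",
        "gc_slot",
    )

    def __init__(self):
        self._rows: list[tuple] = []
        self._frozen = False

    def append(self, principal_id, section_id, sec_frac, path_dist, x, y, gc_id, gc_slot):
        self._rows.append(
            (principal_id, section_id, sec_frac, path_dist, x, y, gc_id, gc_slot)
        )

    def freeze(self):
        n = len(self._rows)
        arr = np.asarray(self._rows, dtype=float) if n else np.zeros((0, 8))
        self.principal_id = arr[:, 0].astype(np.int64)
        self.section_id = arr[:, 1].astype(np.int64)
        self.sec_frac = arr[:, 2]
        self.path_dist = arr[:, 3]
        self.x = arr[:, 4]
        self.y = arr[:, 5]
        self.gc_id = arr[:, 6].astype(np.int64)
        self.gc_slot = arr[:, 7].astype(np.int64)
        self.w_exc = np.zeros(n)
        self.w_inh = np.zeros(n)
        self._frozen = True
        del self._rows
        return self

    def __len__(self):
        return self.principal_id.shape[0] if self._frozen else len(self._rows)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({c: getattr(self, c) for c in self.COLS})
        df["w_exc"] = self.w_exc
        df["w_inh"] = self.w_inh
        return df


@dataclass
class DSACWiring:
    dsac_id: int
    excitatory_inputs: list[int]  # mTC ids (axonal excitation only)
    inhibitory_targets: list[int]  # bridging GC ids


@dataclass
class NetworkModel:
    units: list[GlomerularUnit]
    cells: dict[int, CellInfo]
    geometry: Geometry
    seed: int
    n_gemmule: int = 12
    synapses: SynapseTable | None = None
    dsacs: list[DSACWiring] = field(default_factory=list)
    clusters: dict[int, int] | None = None  # glom_id -> cluster label

    # -- convenience ---------------------------------------------------------

    def unit(self, glom_id: int) -> GlomerularUnit:
        for u in self.units:
            if u.glom_id == glom_id:
                return u
        raise NetworkError(f"no glomerular unit {glom_id}")

    @property
    def gc_ids(self) -> list[int]:
        return [c.cell_id for c in self.cells.values()
                if c.subtype in (Subtype.SGC, Subtype.DGC)]

    @property
    def principal_ids(self) -> list[int]:
        return [c.cell_id for c in self.cells.values()
                if c.subtype in (Subtype.MC, Subtype.MTC)]

    def cluster_of(self, glom_id: int) -> int:
        if self.clusters is None:
            raise NetworkError("clusters not assigned")
        return self.clusters[glom_id]

    def total_lateral_length(self, cell_id: int) -> float:
        return self.cells[cell_id].morphology.total_length(SectionKind.LATERAL)

    def gc_partner_gloms(self, gc_id: int) -> set[int]:
        syn = self.synapses
        sel = syn.gc_id == gc_id
        return {
            self.cells[p].glom_id for p in np.unique(syn.principal_id[sel])
        }

    def bridging_gcs(self) -> list[int]:
        """GCs whose synaptic partners span two or more clusters."""
        if self.clusters is None:
            raise NetworkError("clusters not assigned")
        out = []
        for g in np.unique(self.synapses.gc_id):
            labels = {self.clusters[gl] for gl in self.gc_partner_gloms(int(g))}
            if len(labels) >= 2:
                out.append(int(g))
        return out


def build_network(
    n_glomeruli: int,
    n_mc_per_glom: int = 1,
    n_mtc_per_glom: int = 2,
    n_gc: int = 100,
    geometry: Geometry | None = None,
    seed: int = 0,
    glom_positions=None,
    aligned_axis: bool = False,
    synthetic_stats: dict[str, BranchStats] | None = None,
    n_gemmule: int = 12,
) -> NetworkModel:
    """Place glomerular units, principal cells, and granule cells.

    The default mTC:MC ratio is 2:1.  GC somata are uniform in the GCL
    slab.  ``aligned_axis`` orients all lateral dendrites along +-x — the
    one-dimensional probe geometry used by the paired-glomerulus
    experiments; otherwise stem directions are drawn uniformly.
    ``synthetic_stats`` maps 'MC'/'mTC' to BranchStats for statistical
    morphologies (reduced morphologies by default).  Deterministic given
    ``seed``.
    """
    if n_glomeruli < 1:
        raise NetworkError("need at least one glomerulus")
    geometry = geometry or Geometry()
    rng = np.random.default_rng(seed)
    if glom_positions is None:
        pos = rng.uniform((0, 0), geometry.extent, size=(n_glomeruli, 2))
    else:
        pos = np.asarray(glom_positions, dtype=float)
        if pos.shape != (n_glomeruli, 2):
            raise NetworkError("glom_positions must be (n_glomeruli, 2)")
    units = []
    cells: dict[int, CellInfo] = {}
    cid = 0
    for g in range(n_glomeruli):
        unit = GlomerularUnit(g, pos[g])
        for subtype, count in ((Subtype.MC, n_mc_per_glom), (Subtype.MTC, n_mtc_per_glom)):
            for _ in range(count):
                if synthetic_stats and subtype.value in synthetic_stats:
                    morph = synthesize_morphology(
                        synthetic_stats[subtype.value],
                        CellType(subtype.value),
                        seed=int(rng.integers(2**31)),
                    )
                else:
                    morph = make_reduced_morphology(CellType(subtype.value))
                stems = [
                    s.id
                    for s in morph.sections
                    if s.kind is SectionKind.LATERAL and s.parent_id == morph.soma.id
                ]
                if aligned_axis:
                    angles = {
                        s: (0.0 if i % 2 == 0 else np.pi) for i, s in enumerate(stems)
                    }
                else:
                    angles = {s: float(rng.uniform(0, 2 * np.pi)) for s in stems}
                info = CellInfo(cid, subtype, g, pos[g].copy(), 0.0, morph, angles)
                cells[cid] = info
                (unit.mc_ids if subtype is Subtype.MC else unit.mtc_ids).append(cid)
                cid += 1
        units.append(unit)
    gc_xy = rng.uniform((0, 0), geometry.extent, size=(n_gc, 2))
    gc_depth = rng.uniform(0, geometry.gcl_depth, size=n_gc)
    half = geometry.gcl_depth / 2.0
    for i in range(n_gc):
        st = Subtype.SGC if gc_depth[i] < half else Subtype.DGC
        cells[cid] = CellInfo(cid, st, None, gc_xy[i], float(gc_depth[i]))
        cid += 1
    return NetworkModel(units, cells, geometry, seed, n_gemmule=n_gemmule)


def _stem_of(morph: Morphology, sid: int) -> int:
    """Root lateral section of the subtree containing section sid."""
    s = morph.section(sid)
    while s.parent_id is not None and morph.section(s.parent_id).kind is SectionKind.LATERAL:
        s = morph.section(s.parent_id)
    return s.id


def connect_reciprocal(
    net: NetworkModel,
    density: float = 0.1,
    co_connectivity: float = 0.0,
    seed: int = 0,
    reach_radius: float = 50.0,
) -> NetworkModel:
    """Place reciprocal synapses along lateral dendrites at Poisson density.

    Sites are drawn per lateral section at ``density`` synapses/um; each
    site's surface position extends from the soma along the stem direction
    by the site's path distance.  Candidate GCs lie within
    ``reach_radius`` of the site and in the matching stratum (deep GCs for
    MC dendrites, superficial GCs for mTC dendrites); a fraction
    ``co_connectivity`` of GCs is eligible for both strata.  Pairing among
    candidates is uniform.  Weights start at zero.
    """
    if density < 0:
        raise NetworkError("density must be >= 0")
    if not 0.0 <= co_connectivity <= 1.0:
        raise NetworkError("co_connectivity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    gcs = [net.cells[i] for i in net.gc_ids]
    half = net.geometry.gcl_depth / 2.0
    bi = rng.uniform(size=len(gcs)) < co_connectivity
    sup_set = [
        (g.cell_id, g.position)
        for k, g in enumerate(gcs)
        if g.depth < half or bi[k]
    ]
    deep_set = [
        (g.cell_id, g.position)
        for k, g in enumerate(gcs)
        if g.depth >= half or bi[k]
    ]
    trees = {}
    for name, subset in (("sup", sup_set), ("deep", deep_set)):
        if subset:
            trees[name] = (
                [i for i, _ in subset],
                cKDTree(np.asarray([p for _, p in subset])),
            )
    table = SynapseTable()
    for pid in sorted(net.principal_ids):
        cell = net.cells[pid]
        stratum = "deep" if cell.subtype is Subtype.MC else "sup"
        if stratum not in trees:
            continue
        ids, tree = trees[stratum]
        for sec in cell.morphology.sections:
            if sec.kind is not SectionKind.LATERAL:
                continue
            n_here = rng.poisson(density * sec.length)
            if n_here == 0:
                continue
            fracs = np.sort(rng.uniform(size=n_here))
            stem = _stem_of(cell.morphology, sec.id)
            angle = cell.stem_angle.get(stem, 0.0)
            u = np.asarray([np.cos(angle), np.sin(angle)])
            start = cell.morphology.path_distance(sec.id) - sec.length
            for f in fracs:
                pdist = start + f * sec.length
                site = cell.position + u * pdist
                cand = tree.query_ball_point(site, reach_radius)
                if not cand:
                    continue
                gc = ids[cand[int(rng.integers(len(cand)))]]
                slot = int(rng.integers(net.n_gemmule))
                table.append(pid, sec.id, f, pdist, site[0], site[1], gc, slot)
    net.synapses = table.freeze()
    return net


def assign_clusters(net: NetworkModel, partition) -> NetworkModel:
    """Label glomeruli with cluster ids; unlabeled ones become singletons.

    ``partition`` is an iterable of disjoint glomerulus-id collections.
    """
    blocks = [list(b) for b in partition]
    seen: set[int] = set()
    labels: dict[int, int] = {}
    valid = {u.glom_id for u in net.units}
    for li, block in enumerate(blocks):
        for g in block:
            if g not in valid:
                raise NetworkError(f"glomerulus {g} not in network")
            if g in seen:
                raise NetworkError(f"glomerulus {g} appears in two blocks")
            seen.add(g)
            labels[g] = li
    nxt = len(blocks)
    for u in net.units:
        if u.glom_id not in labels:
            labels[u.glom_id] = nxt
            nxt += 1
    net.clusters = labels
    return net


def wire_dsacs(net: NetworkModel, n_dsac: int = 1, seed: int = 0) -> NetworkModel:
    """Wire dSACs: mTC axonal excitation in, inhibition of bridging GCs out.

    Every dSAC receives excitation from all mTC axons (which units are
    active is decided by the stimulus at run time) and inhibits exactly the
    GCs whose reciprocal-synapse partners belong to two different clusters.
    """
    if net.clusters is None:
        raise NetworkError("assign_clusters before wiring dSACs")
    if net.synapses is None:
        raise NetworkError("connect_reciprocal before wiring dSACs")
    targets = net.bridging_gcs()
    mtc_ids = sorted(i for u in net.units for i in u.mtc_ids)
    next_id = max(net.cells) + 1
    rng = np.random.default_rng(seed)
    center = np.mean([u.position for u in net.units], axis=0)
    net.dsacs = []
    for k in range(n_dsac):
        did = next_id + k
        net.cells[did] = CellInfo(
            did, Subtype.DSAC, None,
            center + rng.uniform(-20, 20, 2), net.geometry.gcl_depth * 0.25,
        )
        net.dsacs.append(DSACWiring(did, list(mtc_ids), list(targets)))
    return net
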