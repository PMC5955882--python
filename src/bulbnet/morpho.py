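"""Reduced and synthetic morphologies for olfactory-bulb neurons.

A morphology is a tree of cylindrical sections (the soma is a sphere,
represented by an equivalent-area cylinder during discretization).  No 3-D
embedding is kept: the model's geometry is path-based, so all distances are
path distances from the soma.

Cell types
----------
MC    mitral cell: 20 um soma, 4 x 400 um apical ending in four 0.8 x 80 um
      tuft branches, two 3 x 800 um lateral dendrites, axon.
mTC   middle tufted cell: same topology, apical 250 um, laterals 2.5 x 600 um.
GC    granule cell: soma plus an apical shaft carrying gemmule (spine)
      compartments; shipped as a packaged SWC fixture.
dSAC  deep short-axon cell: ball-and-stick with a 1,400 um dendrite
      (doubled when no slice correction is applied, to account for the
      dendritic membrane lost in a slice).

Populations of statistical morphologies are grown from ``BranchStats``:
per-order branching probabilities and branch-length distributions for the
lateral dendrites, with a diameter taper rule.  The default fixture
statistics are chosen so that the total-lateral-dendrite-length
distribution of synthetic mTCs peaks near 8,500 um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Sequence

import numpy as np


class SectionKind(str, Enum):
    SOMA = "soma"
    APICAL = "apical"
    TUFT = "tuft"
    LATERAL = "lateral"
    AXON = "axon"


#: section kinds that count as dendrite for Sholl / branch-order analysis
DENDRITIC_KINDS = (SectionKind.APICAL, SectionKind.TUFT, SectionKind.LATERAL)


class CellType(str, Enum):
    MC = "MC"
    MTC = "mTC"
    GC = "GC"
    DSAC = "dSAC"


class MorphologyError(ValueError):
    """Raised for structurally invalid morphologies or SWC records."""


@dataclass
class Section:
    """One cylindrical section.  Lengths and diameters in micrometers."""

    id: int
    parent_id: int | None
    kind: SectionKind
    length: float
    diameter: float

    def __post_init__(self) -> None:
        self.kind = SectionKind(self.kind)
        if self.length <= 0:
            raise MorphologyError(f"section {self.id}: length must be > 0")
        if self.diameter <= 0:
            raise MorphologyError(f"section {self.id}: diameter must be > 0")


class Morphology:
    """A validated tree of sections with a designated spherical soma root."""

    def __init__(self, sections: Iterable[Section], cell_type: CellType | str):
        self.sections: list[Section] = list(sections)
        self.cell_type = CellType(cell_type)
        self._by_id = {s.id: s for s in self.sections}
        if len(self._by_id) != len(self.sections):
            raise MorphologyError("duplicate section ids")
        roots = [s for s in self.sections if s.parent_id is None]
        if len(roots) != 1 or roots[0].kind is not SectionKind.SOMA:
            raise MorphologyError(
                "exactly one root section of kind 'soma' is required"
            )
        self.soma = roots[0]
        self._children: dict[int, list[int]] = {s.id: [] for s in self.sections}
        for s in self.sections:
            if s.parent_id is None:
                continue
            if s.parent_id not in self._by_id:
                raise MorphologyError(
                    f"section {s.id}: parent {s.parent_id} does not exist"
                )
            self._children[s.parent_id].append(s.id)
        # cycle check + path distances by one sweep from the root
        self._dist_end: dict[int, float] = {self.soma.id: 0.0}
        stack = [self.soma.id]
        seen = 1
        while stack:
            sid = stack.pop()
            for cid in self._children[sid]:
                child = self._by_id[cid]
                self._dist_end[cid] = self._dist_end[sid] + child.length
                stack.append(cid)
                seen += 1
        if seen != len(self.sections):
            raise MorphologyError("section graph is not a tree (cycle or orphan)")

    # -- basic queries ---------------------------------------------------

    def section(self, sid: int) -> Section:
        return self._by_id[sid]

    def children(self, sid: int) -> list[Section]:
        return [self._by_id[c] for c in self._children[sid]]

    def path_distance(self, sid: int) -> float:
        """Path distance from the soma surface to the distal end of `sid`."""
        return self._dist_end[sid]

    def path_interval(self, sid: int) -> tuple[float, float]:
        """(proximal, distal) path-distance interval covered by a section."""
        s = self._by_id[sid]
        end = self._dist_end[sid]
        return end - s.length, end

    def total_length(self, kind: SectionKind | str | None = None) -> float:
        if kind is None:
            return sum(s.length for s in self.sections if s.kind != SectionKind.SOMA)
        kind = SectionKind(kind)
        return sum(s.length for s in self.sections if s.kind == kind)

    def area(self, sid: int) -> float:
        """Membrane area in um^2 (sphere for the soma, open cylinder else)."""
        s = self._by_id[sid]
        if s.kind is SectionKind.SOMA:
            return math.pi * s.diameter**2
        return math.pi * s.diameter * s.length

    def total_area(self) -> float:
        return sum(self.area(s.id) for s in self.sections)

    def dendritic_sections(self) -> list[Section]:
        return [s for s in self.sections if s.kind in DENDRITIC_KINDS]

    def branch_points(self) -> set[int]:
        """Ids of non-soma sections with two or more dendritic children."""
        out = set()
        for s in self.sections:
            if s.kind is SectionKind.SOMA:
                continue
            nd = sum(
                1 for c in self.children(s.id) if c.kind in DENDRITIC_KINDS
            )
            if nd >= 2:
                out.add(s.id)
        return out

    def branch_order(self, sid: int) -> int:
        """Number of branch points on the path from `sid` to the soma."""
        bps = self.branch_points()
        order = 0
        s = self._by_id[sid]
        while s.parent_id is not None:
            s = self._by_id[s.parent_id]
            if s.id in bps:
                order += 1
        return order


# ---------------------------------------------------------------------------
# reduced (canonical) morphologies
# ---------------------------------------------------------------------------

#: reduced-cell geometry in um: (apical L, apical d, lateral L, lateral d)
_REDUCED_PRINCIPAL = {
    CellType.MC: (400.0, 4.0, 800.0, 3.0),
    CellType.MTC: (250.0, 4.0, 600.0, 2.5),
}

SOMA_DIAMETER = 20.0
TUFT_LENGTH, TUFT_DIAMETER, N_TUFT = 80.0, 0.8, 4
# The axon geometry is not constrained by the reduced-cell dimensions; a
# single thin section is used, with its passive load scaled in the membrane
# module so the axon/somatodendrite ratio of passive properties is preserved.
AXON_LENGTH, AXON_DIAMETER = 100.0, 1.5
DSAC_DENDRITE_LENGTH = 1400.0
DSAC_DENDRITE_DIAMETER = 1.2
DSAC_SOMA_DIAMETER = 15.0

# GC fixture geometry (soma + apical shaft bearing gemmule compartments).
GC_SOMA_DIAMETER = 8.0
GC_SHAFT_LENGTH, GC_SHAFT_DIAMETER = 150.0, 1.0
GC_N_GEMMULE = 50
GC_GEMMULE_LENGTH, GC_GEMMULE_DIAMETER = 1.0, 1.0


def gc_fixture_morphology(n_gemmule: int = GC_N_GEMMULE) -> Morphology:
    """The granule-cell morphology encoded in the packaged SWC fixture.

    A soma bearing a single apical shaft subdivided into ``n_gemmule``
    sub-sections, each carrying one gemmule (spine) compartment where
    reciprocal dendrodendritic synapses attach.
    """
    secs = [Section(0, None, SectionKind.SOMA, GC_SOMA_DIAMETER, GC_SOMA_DIAMETER)]
    sub_len = GC_SHAFT_LENGTH / n_gemmule
    sid = 1
    parent = 0
    for i in range(n_gemmule):
        secs.append(Section(sid, parent, SectionKind.APICAL, sub_len, GC_SHAFT_DIAMETER))
        shaft_id = sid
        sid += 1
        secs.append(
            Section(sid, shaft_id, SectionKind.TUFT, GC_GEMMULE_LENGTH, GC_GEMMULE_DIAMETER)
        )
        sid += 1
        parent = shaft_id
    return Morphology(secs, CellType.GC)


def make_reduced_morphology(
    cell_type: CellType | str, slice_corrected: bool = True
) -> Morphology:
    """Build the reduced canonical morphology for a cell type.

    Parameters
    ----------
    cell_type:
        One of MC, mTC, GC, dSAC.
    slice_corrected:
        For dSACs only: when False the dendrite length is doubled (to
        2,800 um) to account for membrane lost in slice preparations.
    """
    try:
        ct = CellType(cell_type)
    except ValueError:
        raise MorphologyError(f"unknown cell type: {cell_type!r}") from None

    if ct in _REDUCED_PRINCIPAL:
        ap_len, ap_d, lat_len, lat_d = _REDUCED_PRINCIPAL[ct]
        secs = [Section(0, None, SectionKind.SOMA, SOMA_DIAMETER, SOMA_DIAMETER)]
        secs.append(Section(1, 0, SectionKind.APICAL, ap_len, ap_d))
        sid = 2
        for _ in range(N_TUFT):
            secs.append(Section(sid, 1, SectionKind.TUFT, TUFT_LENGTH, TUFT_DIAMETER))
            sid += 1
        for _ in range(2):
            secs.append(Section(sid, 0, SectionKind.LATERAL, lat_len, lat_d))
            sid += 1
        secs.append(Section(sid, 0, SectionKind.AXON, AXON_LENGTH, AXON_DIAMETER))
        return Morphology(secs, ct)

    if ct is CellType.DSAC:
        length = DSAC_DENDRITE_LENGTH if slice_corrected else 2 * DSAC_DENDRITE_LENGTH
        secs = [
            Section(0, None, SectionKind.SOMA, DSAC_SOMA_DIAMETER, DSAC_SOMA_DIAMETER),
            Section(1, 0, SectionKind.LATERAL, length, DSAC_DENDRITE_DIAMETER),
        ]
        return Morphology(secs, ct)

    # GC: the prior-work morphology as encoded in the packaged fixture
    return gc_fixture_morphology()


# ---------------------------------------------------------------------------
# distributions and branch statistics
# ---------------------------------------------------------------------------


@dataclass
class Distribution:
    """A small serializable sampling distribution.

    kinds: constant(value) | uniform(low, high) | normal(mean, sd)
    | lognormal(mean, sd of log) | choice(values, probs) | empirical(values)
    """

    kind: str
    params: dict = field(default_factory=dict)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        p = self.params
        if self.kind == "constant":
            v = float(p["value"])
            return v if size is None else np.full(size, v)
        if self.kind == "uniform":
            return rng.uniform(p["low"], p["high"], size)
        if self.kind == "normal":
            return rng.normal(p["mean"], p["sd"], size)
        if self.kind == "lognormal":
            return rng.lognormal(p["mean"], p["sd"], size)
        if self.kind == "choice":
            probs = p.get("probs")
            return rng.choice(np.asarray(p["values"]), size=size, p=probs)
        if self.kind == "empirical":
            return rng.choice(np.asarray(p["values"], dtype=float), size=size)
        raise MorphologyError(f"unknown distribution kind: {self.kind!r}")

    def support_positive(self) -> bool:
        p = self.params
        if self.kind == "constant":
            return p["value"] > 0
        if self.kind == "uniform":
            return p["low"] > 0
        if self.kind == "normal":
            # normals are truncated at resample time; require positive mean
            return p["mean"] > 0
        if self.kind == "lognormal":
            return True
        if self.kind in ("choice", "empirical"):
            return bool(np.all(np.asarray(p["values"], dtype=float) > 0))
        return False

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": _plain(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "Distribution":
        return cls(d["kind"], dict(d["params"]))


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _positive_draw(dist: Distribution, rng: np.random.Generator) -> float:
    for _ in range(100):
        v = float(dist.sample(rng))
        if v > 0:
            return v
    raise MorphologyError("distribution has non-positive support")


@dataclass
class BranchStats:
    """Growth statistics for synthetic lateral dendrites.

    ``branching_prob[k]`` is the probability that a branch of order ``k``
    bifurcates at its distal end (orders beyond the list never branch).
    ``branch_length_dist`` governs every grown segment.
    ``path_length_dist`` is the descriptive distribution of terminal path
    lengths implied by the growth rule; it is used for validation (the
    synthesizer's output is compared against it) and is regenerated by
    brute-force resampling via :meth:`implied_path_lengths`.
    ``diameter_rule`` tapers the stem diameter with branch order.
    """

    branch_length_dist: Distribution
    branching_prob: Sequence[float]
    n_lateral_dendrites_dist: Distribution
    path_length_dist: Distribution | None = None
    stem_diameter: float = 2.5
    taper: float = 0.8
    min_diameter: float = 0.3

    def __post_init__(self) -> None:
        if any(not (0.0 <= p <= 1.0) for p in self.branching_prob):
            raise MorphologyError("branching probabilities must lie in [0, 1]")
        for dist in (self.branch_length_dist, self.n_lateral_dendrites_dist):
            if not dist.support_positive():
                raise MorphologyError(
                    "degenerate distribution with non-positive support"
                )

    def diameter(self, order: int) -> float:
        return max(self.stem_diameter * self.taper**order, self.min_diameter)

    def p_branch(self, order: int) -> float:
        if order < len(self.branching_prob):
            return float(self.branching_prob[order])
        return 0.0

    def implied_path_lengths(self, rng: np.random.Generator, n_trees: int) -> np.ndarray:
        """Brute-force resampling of terminal path lengths from the rule."""
        out: list[float] = []
        for _ in range(n_trees):
            stack = [(0, 0.0)]
            while stack:
                order, path = stack.pop()
                path += _positive_draw(self.branch_length_dist, rng)
                if rng.uniform() < self.p_branch(order):
                    stack.append((order + 1, path))
                    stack.append((order + 1, path))
                else:
                    out.append(path)
        return np.asarray(out)

    def to_dict(self) -> dict:
        return {
            "branch_length_dist": self.branch_length_dist.to_dict(),
            "branching_prob": [float(p) for p in self.branching_prob],
            "n_lateral_dendrites_dist": self.n_lateral_dendrites_dist.to_dict(),
            "path_length_dist": (
                self.path_length_dist.to_dict() if self.path_length_dist else None
            ),
            "stem_diameter": self.stem_diameter,
            "taper": self.taper,
            "min_diameter": self.min_diameter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BranchStats":
        pl = d.get("path_length_dist")
        return cls(
            branch_length_dist=Distribution.from_dict(d["branch_length_dist"]),
            branching_prob=list(d["branching_prob"]),
            n_lateral_dendrites_dist=Distribution.from_dict(
                d["n_lateral_dendrites_dist"]
            ),
            path_length_dist=Distribution.from_dict(pl) if pl else None,
            stem_diameter=float(d.get("stem_diameter", 2.5)),
            taper=float(d.get("taper", 0.8)),
            min_diameter=float(d.get("min_diameter", 0.3)),
        )


def default_branch_stats(cell_type: CellType | str) -> BranchStats:
    """Packaged default BranchStats for synthetic MC/mTC populations."""
    import functools
    from importlib import resources

    import yaml

    @functools.lru_cache(maxsize=1)
    def _load():
        with resources.files("bulbnet.fixtures").joinpath("branchstats.yaml").open() as fh:
            return yaml.safe_load(fh)

    ct = CellType(cell_type)
    data = _load()
    if ct.value not in data:
        raise MorphologyError(f"no default branch statistics for {ct.value}")
    return BranchStats.from_dict(data[ct.value])


def synthesize_morphology(
    stats: BranchStats,
    cell_type: CellType | str,
    seed: int,
) -> Morphology:
    """Grow a synthetic principal-cell morphology from branch statistics.

    The soma, apical dendrite, tuft and axon use the reduced-cell
    dimensions of ``cell_type``; the lateral dendrites are grown from
    ``stats``: the number of stems is drawn from
    ``n_lateral_dendrites_dist``, each branch length from
    ``branch_length_dist``, and each branch of order ``k`` bifurcates with
    probability ``branching_prob[k]``.  Deterministic given ``seed``.
    """
    ct = CellType(cell_type)
    if ct not in _REDUCED_PRINCIPAL:
        raise MorphologyError(
            f"synthetic morphologies are defined for MC/mTC, not {ct.value}"
        )
    rng = np.random.default_rng(seed)
    ap_len, ap_d, _lat_len, _lat_d = _REDUCED_PRINCIPAL[ct]
    secs = [Section(0, None, SectionKind.SOMA, SOMA_DIAMETER, SOMA_DIAMETER)]
    secs.append(Section(1, 0, SectionKind.APICAL, ap_len, ap_d))
    sid = 2
    for _ in range(N_TUFT):
        secs.append(Section(sid, 1, SectionKind.TUFT, TUFT_LENGTH, TUFT_DIAMETER))
        sid += 1

    n_stems = int(round(float(stats.n_lateral_dendrites_dist.sample(rng))))
    if n_stems < 1:
        raise MorphologyError("sampled a non-positive number of lateral dendrites")
    for _ in range(n_stems):
        # grow one dendritic subtree (stack of (parent section id, order))
        stack = [(0, 0)]
        while stack:
            parent, order = stack.pop()
            length = _positive_draw(stats.branch_length_dist, rng)
            secs.append(
                Section(sid, parent, SectionKind.LATERAL, length, stats.diameter(order))
            )
            me = sid
            sid += 1
            if rng.uniform() < stats.p_branch(order):
                stack.append((me, order + 1))
                stack.append((me, order + 1))
    secs.append(Section(sid, 0, SectionKind.AXON, AXON_LENGTH, AXON_DIAMETER))
    return Morphology(secs, ct)


# ---------------------------------------------------------------------------
# morphometric analysis
# ---------------------------------------------------------------------------


def sholl_profile(
    m: Morphology, shell_step: float
) -> list[tuple[float, int]]:
    """Sholl crossings at path-distance shells ``shell_step, 2*shell_step...``

    A dendritic section with path interval (prox, dist] crosses radius r
    when prox < r <= dist.  Radii extend to the maximal dendritic path
    length.  Path distance (not Euclidean) is used throughout: no 3-D
    embedding exists in this model.
    """
    if shell_step <= 0:
        raise ValueError("shell_step must be > 0")
    dend = m.dendritic_sections()
    if not dend:
        return []
    intervals = [m.path_interval(s.id) for s in dend]
    rmax = max(d for _, d in intervals)
    out = []
    r = shell_step
    while r <= rmax + 1e-9:
        count = sum(1 for p, d in intervals if p < r <= d + 1e-9)
        out.append((r, count))
        r += shell_step
    return out


def branch_order_histogram(m: Morphology) -> dict[int, int]:
    """Histogram of dendritic sections per branch order.

    The order of a section is the number of branch points on its path to
    the soma; the histogram totals the number of dendritic sections.
    """
    hist: dict[int, int] = {}
    bps = m.branch_points()
    for s in m.dendritic_sections():
        order = 0
        cur = s
        while cur.parent_id is not None:
            cur = m.section(cur.parent_id)
            if cur.id in bps:
                order += 1
        hist[order] = hist.get(order, 0) + 1
    return hist


# ---------------------------------------------------------------------------
# SWC input / output
# ---------------------------------------------------------------------------

_KIND_TO_SWC = {
    SectionKind.SOMA: 1,
    SectionKind.AXON: 2,
    SectionKind.LATERAL: 3,
    SectionKind.APICAL: 4,
    SectionKind.TUFT: 5,
}
_SWC_TO_KIND = {v: k for k, v in _KIND_TO_SWC.items()}


def write_swc(m: Morphology, path: str) -> None:
    """Write a morphology as a 7-column SWC file.

    The model keeps no 3-D embedding, so sections are laid out along
    synthetic directions chosen per child index; point-to-point distances
    reproduce section lengths exactly, which is all SWC round-tripping
    must preserve here.
    """
    # golden-angle directions in 3-D keep sibling points distinct
    pos: dict[int, np.ndarray] = {m.soma.id: np.zeros(3)}
    order = _topological_order(m)
    lines = []
    idx_of: dict[int, int] = {}
    for i, sid in enumerate(order, start=1):
        s = m.section(sid)
        idx_of[sid] = i
        if s.parent_id is None:
            p = np.zeros(3)
            parent_idx = -1
        else:
            theta = 2.399963229728653 * i
            z = math.cos(0.7 * i)
            r = math.sqrt(max(1.0 - z * z, 1e-12))
            direction = np.array([r * math.cos(theta), r * math.sin(theta), z])
            p = pos[s.parent_id] + direction * s.length
            parent_idx = idx_of[s.parent_id]
        pos[sid] = p
        lines.append(
            f"{i} {_KIND_TO_SWC[s.kind]} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g} "
            f"{s.diameter / 2:.9g} {parent_idx}"
        )
    with open(path, "w") as fh:
        fh.write(f"# SWC export, cell_type={m.cell_type.value}\n")
        fh.write("\n".join(lines) + "\n")


def _topological_order(m: Morphology) -> list[int]:
    order = []
    stack = [m.soma.id]
    while stack:
        sid = stack.pop()
        order.append(sid)
        for c in sorted(m._children[sid], reverse=True):
            stack.append(c)
    return order


def read_swc(path: str, cell_type: CellType | str = CellType.MTC) -> Morphology:
    """Parse a 7-column SWC file into a Morphology.

    Two-pass: records may reference parent ids defined on later lines.
    Raises :class:`MorphologyError` naming the offending line for
    malformed records, orphan parents and cyclic references.
    """
    records: dict[int, tuple[int, int, np.ndarray, float, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise MorphologyError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                idx = int(parts[0])
                swc_type = int(parts[1])
                xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
                radius = float(parts[5])
                parent = int(parts[6])
            except ValueError as exc:
                raise MorphologyError(f"{path}:{lineno}: malformed record ({exc})")
            if idx in records:
                raise MorphologyError(f"{path}:{lineno}: duplicate point id {idx}")
            records[idx] = (swc_type, lineno, xyz, radius, parent)

    somas = [i for i, r in records.items() if r[0] == 1 and r[4] == -1]
    if not somas:
        raise MorphologyError(f"{path}: no soma record")
    if len(somas) > 1:
        raise MorphologyError(f"{path}: multiple root soma records")
    root = somas[0]

    secs = []
    for idx, (swc_type, lineno, xyz, radius, parent) in sorted(records.items()):
        kind = _SWC_TO_KIND.get(swc_type)
        if kind is None:
            raise MorphologyError(
                f"{path}:{lineno}: unknown SWC structure type {swc_type}"
            )
        if idx == root:
            secs.append(Section(idx, None, kind, 2 * radius, 2 * radius))
            continue
        if parent not in records:
            raise MorphologyError(
                f"{path}:{lineno}: parent id {parent} does not exist"
            )
        length = float(np.linalg.norm(xyz - records[parent][2]))
        if length <= 0:
            raise MorphologyError(
                f"{path}:{lineno}: zero-length segment (coincident points)"
            )
        secs.append(Section(idx, parent, kind, length, 2 * radius))
    # cycle detection is delegated to the Morphology constructor, but give
    # a file-level message
    try:
        return Morphology(secs, cell_type)
    except MorphologyError as exc:
        raise MorphologyError(f"{path}: {exc}") from None
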