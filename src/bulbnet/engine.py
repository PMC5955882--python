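"""Compartmental simulation engine.

Backward-Euler integration of the cable equation on trees (Hines-ordered
elimination: one forward/backward sweep per step, unconditionally stable
for the passive subsystem), with Hodgkin-Huxley-style channel gates
advanced by an exponential (Rush-Larsen) integrator.  Gate steady states
and step factors are tabulated on a voltage grid once per (dt), which keeps
the per-step cost linear in compartments with small constants.

Units: mV, ms, uS, nA, nF, um; channel densities are supplied in S/cm^2
and converted to uS per compartment on construction.

The same kernel serves single-cell protocols and full network runs: cells
are flattened into one forest of compartments, synapses are event-triggered
double-exponential conductances, and external event schedules, current
injection, voltage clamp and per-glomerulus drive waveforms are all
per-chunk inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

# gate indices
GATE_M, GATE_H, GATE_N, GATE_A, GATE_B, GATE_S, GATE_U = range(7)
NGATE = 7

E_NA = 50.0
E_K = -90.0

VMIN, VMAX, DV = -120.0, 60.0, 0.5
NV = int(round((VMAX - VMIN) / DV)) + 1


# ---------------------------------------------------------------------------
# gate kinetics (Boltzmann steady states, constant or bell/switch taus)
# ---------------------------------------------------------------------------


def _boltz(v, vhalf, k):
    return 1.0 / (1.0 + np.exp(-(v - vhalf) / k))


def gate_tables(kin: dict, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Tabulate x_inf(V) and exp(-dt/tau(V)) for the seven gates.

    ``kin`` maps gate names (na_m, na_h, kdr_n, ka_a, ka_b, ks_s, ks_u) to
    parameter dicts with keys: vhalf, k, and either tau (constant), a bell
    profile (tau_min, tau_amp, v_peak, width), or a switch profile
    (tau_hyp, tau_dep, v_switch, switch_width); optional 'floor' raises the
    steady-state minimum (used for incomplete inactivation).
    """
    v = np.linspace(VMIN, VMAX, NV)
    inf = np.empty((NGATE, NV))
    ef = np.empty((NGATE, NV))
    names = ["na_m", "na_h", "kdr_n", "ka_a", "ka_b", "ks_s", "ks_u"]
    for gi, name in enumerate(names):
        p = kin[name]
        x = _boltz(v, p["vhalf"], p["k"])
        floor = p.get("floor", 0.0)
        x = floor + (1.0 - floor) * x
        if "tau" in p:
            tau = np.full(NV, p["tau"])
        elif "tau_amp" in p:
            tau = p["tau_min"] + p["tau_amp"] * np.exp(
                -(((v - p["v_peak"]) / p["width"]) ** 2)
            )
        else:
            tau = p["tau_hyp"] + (p["tau_dep"] - p["tau_hyp"]) * _boltz(
                v, p["v_switch"], p["switch_width"]
            )
        inf[gi] = x
        ef[gi] = np.exp(-dt / np.maximum(tau, 1e-3))
    return inf, ef


# ---------------------------------------------------------------------------
# the kernel
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _run_chunk(
    nsteps,
    dt,
    t0,
    parent,
    axial,
    diag0,
    rhs0,
    c_over_dt,
    gbar_na,
    gbar_kdr,
    gbar_ka,
    gbar_ks,
    tab_inf,
    tab_exp,
    gates,
    V,
    drive_idx,
    drive_g,
    wave,
    syn_pre_start,
    syn_pre_list,
    syn_post,
    syn_w,
    syn_e,
    syn_dr,
    syn_dd,
    syn_norm,
    syn_A,
    syn_B,
    ext_step,
    ext_syn,
    thresh,
    refrac,
    last_spike,
    spike_count,
    rec_idx,
    rec_out,
    clamp_idx,
    clamp_g,
    clamp_v,
    clamp_out,
    spk_flag,
    spk_comp,
    spk_time,
):
    ncomp = V.shape[0]
    nsyn = syn_post.shape[0]
    nspk = 0
    ep = 0
    next = 0  # noqa: A001 (numba-local)
    d = np.empty(ncomp)
    r = np.empty(ncomp)
    gs = np.empty(ncomp)
    gse = np.empty(ncomp)
    inv_dv = 1.0 / DV
    for istep in range(nsteps):
        t = t0 + (istep + 1) * dt
        # external synaptic events scheduled for this step
        while ep < ext_step.shape[0] and ext_step[ep] == istep:
            k = ext_syn[ep]
            syn_A[k] += 1.0
            syn_B[k] += 1.0
            ep += 1
        # synaptic conductances
        for i in range(ncomp):
            gs[i] = 0.0
            gse[i] = 0.0
        for k in range(nsyn):
            syn_A[k] *= syn_dr[k]
            syn_B[k] *= syn_dd[k]
            g = syn_w[k] * syn_norm[k] * (syn_B[k] - syn_A[k])
            if g != 0.0:
                p = syn_post[k]
                gs[p] += g
                gse[p] += g * syn_e[k]
        # gates + membrane currents, assemble diagonal and rhs
        for i in range(ncomp):
            vi = V[i]
            x = (vi - VMIN) * inv_dv
            if x < 0.0:
                x = 0.0
            elif x > NV - 1.001:
                x = NV - 1.001
            j = int(x)
            w1 = x - j
            w0 = 1.0 - w1
            gtot = gs[i]
            ge = gse[i]
            gna = gbar_na[i]
            if gna > 0.0:
                m = (
                    tab_exp[0, j] * w0 + tab_exp[0, j + 1] * w1
                ) * (gates[0, i] - (tab_inf[0, j] * w0 + tab_inf[0, j + 1] * w1)) + (
                    tab_inf[0, j] * w0 + tab_inf[0, j + 1] * w1
                )
                h = (
                    tab_exp[1, j] * w0 + tab_exp[1, j + 1] * w1
                ) * (gates[1, i] - (tab_inf[1, j] * w0 + tab_inf[1, j + 1] * w1)) + (
                    tab_inf[1, j] * w0 + tab_inf[1, j + 1] * w1
                )
                gates[0, i] = m
                gates[1, i] = h
                g = gna * m * m * m * h
                gtot += g
                ge += g * E_NA
            gk = gbar_kdr[i]
            if gk > 0.0:
                ninf = tab_inf[2, j] * w0 + tab_inf[2, j + 1] * w1
                nn = (tab_exp[2, j] * w0 + tab_exp[2, j + 1] * w1) * (
                    gates[2, i] - ninf
                ) + ninf
                gates[2, i] = nn
                g = gk * nn * nn
                gtot += g
                ge += g * E_K
            gka = gbar_ka[i]
            if gka > 0.0:
                ainf = tab_inf[3, j] * w0 + tab_inf[3, j + 1] * w1
                aa = (tab_exp[3, j] * w0 + tab_exp[3, j + 1] * w1) * (
                    gates[3, i] - ainf
                ) + ainf
                binf = tab_inf[4, j] * w0 + tab_inf[4, j + 1] * w1
                bb = (tab_exp[4, j] * w0 + tab_exp[4, j + 1] * w1) * (
                    gates[4, i] - binf
                ) + binf
                gates[3, i] = aa
                gates[4, i] = bb
                g = gka * aa * aa * aa * aa * bb
                gtot += g
                ge += g * E_K
            gks = gbar_ks[i]
            if gks > 0.0:
                sinf = tab_inf[5, j] * w0 + tab_inf[5, j + 1] * w1
                ss = (tab_exp[5, j] * w0 + tab_exp[5, j + 1] * w1) * (
                    gates[5, i] - sinf
                ) + sinf
                uinf = tab_inf[6, j] * w0 + tab_inf[6, j + 1] * w1
                uu = (tab_exp[6, j] * w0 + tab_exp[6, j + 1] * w1) * (
                    gates[6, i] - uinf
                ) + uinf
                gates[5, i] = ss
                gates[6, i] = uu
                g = gks * ss * uu
                gtot += g
                ge += g * E_K
            di = drive_idx[i]
            if di >= 0:
                gd = drive_g[i] * wave[di, istep]
                gtot += gd
                # drive reversal is 0 mV: no rhs contribution
            d[i] = diag0[i] + gtot
            r[i] = rhs0[i] + c_over_dt[i] * V[i] + ge
        # Hines elimination (children come after parents)
        for i in range(ncomp - 1, 0, -1):
            p = parent[i]
            if p >= 0:
                f = axial[i] / d[i]
                d[p] -= f * axial[i]
                r[p] += f * r[i]
        for i in range(ncomp):
            p = parent[i]
            if p < 0:
                vnew = r[i] / d[i]
            else:
                vnew = (r[i] + axial[i] * V[p]) / d[i]
            dvdt = (vnew - V[i]) / dt
            V[i] = vnew
            if dvdt >= thresh[i] and (t - last_spike[i]) >= refrac:
                last_spike[i] = t
                spike_count[i] += 1
                if spk_flag[i] and nspk < spk_comp.shape[0]:
                    spk_comp[nspk] = i
                    spk_time[nspk] = t
                    nspk += 1
                # trigger synapses whose presynaptic compartment is i
                for k in range(syn_pre_start[i], syn_pre_start[i + 1]):
                    sk = syn_pre_list[k]
                    syn_A[sk] += 1.0
                    syn_B[sk] += 1.0
        for k in range(rec_idx.shape[0]):
            rec_out[k, istep] = V[rec_idx[k]]
        for k in range(clamp_idx.shape[0]):
            clamp_out[k, istep] = clamp_g[k] * (clamp_v[k] - V[clamp_idx[k]])
    return nspk


# ---------------------------------------------------------------------------
# compartmentalization
# ---------------------------------------------------------------------------


@dataclass
class CompartmentTree:
    """Flattened iso-potential compartments for one morphology."""

    parent: np.ndarray  # local parent index, -1 for the root
    area_cm2: np.ndarray
    axial_uS: np.ndarray  # conductance to parent
    kind: list  # SectionKind per compartment
    section_id: np.ndarray  # originating section id
    sec_frac: np.ndarray  # position (0..1] of compartment center in section
    path_dist: np.ndarray  # um from soma to compartment center

    @property
    def ncomp(self) -> int:
        return self.parent.shape[0]

    def comp_at(self, section_id: int, frac: float) -> int:
        idx = np.where(self.section_id == section_id)[0]
        if idx.size == 0:
            raise KeyError(f"no compartments for section {section_id}")
        return int(idx[np.argmin(np.abs(self.sec_frac[idx] - frac))])


def discretize(morph, max_seg_length: float) -> CompartmentTree:
    """Split each section into ceil(length/max_seg_length) compartments.

    The spherical soma maps to an equivalent-area cylinder (one
    compartment).  Axial conductances follow from Ra and the cylinder
    geometry of each half-compartment (Ra is applied later: the stored
    'axial' here is geometry-only, 1/(sum L/A_cross) in um^-1, scaled by
    1/Ra at assembly time).
    """
    if max_seg_length <= 0:
        raise ValueError("max_seg_length must be > 0")
    from .morpho import SectionKind

    parents: list[int] = []
    areas: list[float] = []
    geom: list[float] = []  # L/(2*Across) of each compartment half, um^-1
    kinds: list = []
    sec_ids: list[int] = []
    fracs: list[float] = []
    pdist: list[float] = []
    last_comp_of_section: dict[int, int] = {}

    order = _dfs_sections(morph)
    for sid in order:
        s = morph.section(sid)
        if s.kind is SectionKind.SOMA:
            parents.append(-1)
            areas.append(math.pi * s.diameter**2 * 1e-8)  # sphere, cm^2
            # equivalent cylinder L=d: half-axial geometry term
            across = math.pi * (s.diameter / 2) ** 2
            geom.append(s.length / 2 / across)
            kinds.append(s.kind)
            sec_ids.append(sid)
            fracs.append(0.5)
            pdist.append(0.0)
            last_comp_of_section[sid] = len(parents) - 1
            continue
        n = max(1, math.ceil(s.length / max_seg_length))
        seg_len = s.length / n
        across = math.pi * (s.diameter / 2) ** 2
        prox = last_comp_of_section[s.parent_id]
        base_dist = morph.path_distance(s.parent_id) if s.parent_id is not None else 0.0
        # parent section's distal end distance
        for i in range(n):
            parents.append(prox)
            areas.append(math.pi * s.diameter * seg_len * 1e-8)
            geom.append(seg_len / 2 / across)
            kinds.append(s.kind)
            sec_ids.append(sid)
            fracs.append((i + 0.5) / n)
            start = morph.path_distance(sid) - s.length
            pdist.append(start + (i + 0.5) * seg_len)
            prox = len(parents) - 1
        last_comp_of_section[sid] = prox

    parent = np.asarray(parents, dtype=np.int64)
    geom_arr = np.asarray(geom)
    axial = np.zeros(len(parents))
    for i in range(1, len(parents)):
        p = parent[i]
        # resistance = Ra * (geom_i + geom_p); conductance in uS with Ra in
        # Ohm*cm: R[Ohm] = Ra * (um^-1) * 1e4  ->  g[uS] = 1e6 / R
        axial[i] = 1.0 / (geom_arr[i] + geom_arr[p])  # um, divide by Ra*1e-2 later
    return CompartmentTree(
        parent=parent,
        area_cm2=np.asarray(areas),
        axial_uS=axial,
        kind=kinds,
        section_id=np.asarray(sec_ids, dtype=np.int64),
        sec_frac=np.asarray(fracs),
        path_dist=np.asarray(pdist),
    )


def _dfs_sections(morph) -> list[int]:
    order = []
    stack = [morph.soma.id]
    while stack:
        sid = stack.pop()
        order.append(sid)
        for c in sorted(morph._children[sid], reverse=True):
            stack.append(c)
    return order


def axial_conductance_uS(geom_axial: np.ndarray, ra_ohm_cm: float) -> np.ndarray:
    """Convert the geometry-only axial term (um) into uS given Ra."""
    out = np.zeros_like(geom_axial)
    nz = geom_axial > 0
    # R[Ohm] = Ra[Ohm cm] / (axial[um]) * 1e4 um/cm  => g[uS] = axial*1e2/Ra
    out[nz] = geom_axial[nz] * 1e2 / ra_ohm_cm
    return out


# ---------------------------------------------------------------------------
# simulation group
# ---------------------------------------------------------------------------


@dataclass
class CellHandle:
    index: int
    offset: int
    ncomp: int
    tree: CompartmentTree
    soma: int  # global soma compartment index


class SimGroup:
    """A set of cells flattened into one solvable forest plus synapses."""

    def __init__(self, kinetics: dict, dt: float = 0.025):
        self.kinetics = kinetics
        self.dt = dt
        self.cells: list[CellHandle] = []
        self._parent: list[np.ndarray] = []
        self._axial: list[np.ndarray] = []
        self._carea: list[np.ndarray] = []
        self._gl: list[np.ndarray] = []
        self._el: list[np.ndarray] = []
        self._gna: list[np.ndarray] = []
        self._gkdr: list[np.ndarray] = []
        self._gka: list[np.ndarray] = []
        self._gks: list[np.ndarray] = []
        self._cm: list[np.ndarray] = []
        self._ncomp = 0
        # synapses
        self.syn_pre: list[int] = []
        self.syn_post: list[int] = []
        self.syn_e: list[float] = []
        self.syn_tr: list[float] = []
        self.syn_td: list[float] = []
        self.syn_w: list[float] = []
        self._final = False
        self.t = 0.0

    # -- construction ------------------------------------------------------

    def add_cell(self, cell, max_seg_length: float = 20.0) -> CellHandle:
        from .morpho import SectionKind

        tree = discretize(cell.morphology, max_seg_length)
        n = tree.ncomp
        off = self._ncomp
        parent = tree.parent.copy()
        parent[parent >= 0] += off
        parent[0] = -1
        pas = cell.passive
        axial = axial_conductance_uS(tree.axial_uS, pas.ra)
        gl = np.full(n, pas.g_l)
        cmv = np.full(n, pas.cm)
        for i, k in enumerate(tree.kind):
            if k is SectionKind.AXON:
                gl[i] *= pas.axon_gl_scale
        gl_uS = gl * tree.area_cm2 * 1e6
        el = np.full(n, pas.e_l)
        gna = np.zeros(n)
        gkdr = np.zeros(n)
        gka = np.zeros(n)
        gks = np.zeros(n)
        target = {"Na": gna, "K_DR": gkdr, "K_A": gka, "K_S": gks}
        for ch in cell.channels:
            arr = target[ch.kind]
            for i, k in enumerate(tree.kind):
                dens = ch.gbar.get(k.value, 0.0)
                arr[i] += dens * tree.area_cm2[i] * 1e6
        h = CellHandle(len(self.cells), off, n, tree, off)
        self.cells.append(h)
        self._parent.append(parent)
        self._axial.append(axial)
        self._carea.append(tree.area_cm2)
        self._gl.append(gl_uS)
        self._el.append(el)
        self._gna.append(gna)
        self._gkdr.append(gkdr)
        self._gka.append(gka)
        self._gks.append(gks)
        self._cm.append(cmv * tree.area_cm2 * 1e3)  # nF
        self._ncomp += n
        return h

    def add_synapse(
        self,
        pre_comp: int,
        post_comp: int,
        e_rev: float,
        tau_rise: float,
        tau_decay: float,
        weight_uS: float,
    ) -> int:
        """Register a double-exponential synapse; pre_comp -1 => external."""
        self.syn_pre.append(pre_comp)
        self.syn_post.append(post_comp)
        self.syn_e.append(e_rev)
        self.syn_tr.append(tau_rise)
        self.syn_td.append(tau_decay)
        self.syn_w.append(weight_uS)
        return len(self.syn_w) - 1

    def finalize(self, v_init: float = -65.0):
        n = self._ncomp
        self.parent = np.concatenate(self._parent) if self._parent else np.zeros(0, np.int64)
        self.axial = np.concatenate(self._axial)
        self.c_nF = np.concatenate(self._cm)
        self.gl_uS = np.concatenate(self._gl)
        self.el = np.concatenate(self._el)
        self.gna = np.concatenate(self._gna)
        self.gkdr = np.concatenate(self._gkdr)
        self.gka = np.concatenate(self._gka)
        self.gks = np.concatenate(self._gks)
        self.V = np.full(n, v_init)
        # gate states at steady state for v_init
        inf, _ = gate_tables(self.kinetics, 1.0)
        j = int(round((v_init - VMIN) / DV))
        self.gates = np.empty((NGATE, n))
        for gi in range(NGATE):
            self.gates[gi, :] = inf[gi, j]
        self.last_spike = np.full(n, -1e9)
        self.spike_count = np.zeros(n, dtype=np.int64)
        self.thresh = np.full(n, 20.0)
        self.i_inj = np.zeros(n)
        self.g_tonic = np.zeros(n)
        self.e_tonic = -75.0
        self.drive_idx = np.full(n, -1, dtype=np.int64)
        self.drive_g = np.zeros(n)
        self.spk_flag = np.zeros(n, dtype=np.bool_)
        self.clamp_idx = np.zeros(0, dtype=np.int64)
        self.clamp_g = np.zeros(0)
        self.clamp_v = np.zeros(0)
        # synapse arrays
        self.syn_post_a = np.asarray(self.syn_post, dtype=np.int64)
        self.syn_pre_a = np.asarray(self.syn_pre, dtype=np.int64)
        self.syn_e_a = np.asarray(self.syn_e)
        tr = np.asarray(self.syn_tr)
        td = np.asarray(self.syn_td)
        self.syn_tr_a = tr
        self.syn_td_a = td
        self.syn_w_a = np.asarray(self.syn_w)
        nsyn = self.syn_w_a.shape[0]
        self.syn_A = np.zeros(nsyn)
        self.syn_B = np.zeros(nsyn)
        # peak normalization of B-A
        self.syn_norm = np.ones(nsyn)
        valid = nsyn > 0
        if valid:
            with np.errstate(divide="ignore", invalid="ignore"):
                tp = tr * td / (td - tr) * np.log(td / tr)
                peak = np.exp(-tp / td) - np.exp(-tp / tr)
            self.syn_norm = np.where(peak > 0, 1.0 / peak, 1.0)
        # presynaptic CSR map
        counts = np.zeros(n + 1, dtype=np.int64)
        for p in self.syn_pre_a:
            if p >= 0:
                counts[p + 1] += 1
        self.syn_pre_start = np.cumsum(counts)
        fill = self.syn_pre_start[:-1].copy()
        self.syn_pre_list = np.zeros(nsyn, dtype=np.int64)
        for k, p in enumerate(self.syn_pre_a):
            if p >= 0:
                self.syn_pre_list[fill[p]] = k
                fill[p] += 1
        self._tab_dt = None
        self._final = True

    # -- per-chunk controls --------------------------------------------------

    def set_clamp(self, comps, holdings, g_clamp: float = 500.0):
        comps = np.atleast_1d(np.asarray(comps, dtype=np.int64))
        self.clamp_idx = comps
        self.clamp_g = np.full(comps.shape[0], g_clamp)
        self.clamp_v = np.atleast_1d(np.asarray(holdings, dtype=float))

    def _tables(self, dt):
        if self._tab_dt != dt:
            self._tab_inf, self._tab_exp = gate_tables(self.kinetics, dt)
            self._tab_dt = dt
        return self._tab_inf, self._tab_exp

    def run(
        self,
        nsteps: int,
        dt: float | None = None,
        wave: np.ndarray | None = None,
        record: np.ndarray | None = None,
        ext_events: tuple[np.ndarray, np.ndarray] | None = None,
        spike_buffer: int = 200_000,
    ):
        """Advance the group by ``nsteps`` of ``dt`` ms.

        Returns (rec_out, clamp_out, spikes) where spikes is an array of
        (compartment, time) for compartments flagged in ``spk_flag``.
        """
        if not self._final:
            raise RuntimeError("finalize() before running")
        dt = self.dt if dt is None else dt
        tab_inf, tab_exp = self._tables(dt)
        if wave is None:
            wave = np.zeros((1, nsteps))
        rec_idx = (
            np.asarray(record, dtype=np.int64)
            if record is not None
            else np.zeros(0, dtype=np.int64)
        )
        rec_out = np.empty((rec_idx.shape[0], nsteps))
        clamp_out = np.empty((self.clamp_idx.shape[0], nsteps))
        if ext_events is None:
            ext_step = np.zeros(0, dtype=np.int64)
            ext_syn = np.zeros(0, dtype=np.int64)
        else:
            ext_step, ext_syn = ext_events
        spk_comp = np.empty(spike_buffer, dtype=np.int64)
        spk_time = np.empty(spike_buffer)
        c_over_dt = self.c_nF / dt
        diag0 = c_over_dt + self.gl_uS + self.g_tonic
        rhs0 = self.gl_uS * self.el + self.g_tonic * self.e_tonic + self.i_inj
        # static axial sums
        for i in range(self.parent.shape[0]):
            p = self.parent[i]
            if p >= 0:
                diag0[i] += self.axial[i]
                diag0[p] += self.axial[i]
        for k in range(self.clamp_idx.shape[0]):
            ci = self.clamp_idx[k]
            diag0[ci] += self.clamp_g[k]
            rhs0[ci] += self.clamp_g[k] * self.clamp_v[k]
        nspk = _run_chunk(
            nsteps,
            dt,
            self.t,
            self.parent,
            self.axial,
            diag0,
            rhs0,
            c_over_dt,
            self.gna,
            self.gkdr,
            self.gka,
            self.gks,
            tab_inf,
            tab_exp,
            self.gates,
            self.V,
            self.drive_idx,
            self.drive_g,
            wave,
            self.syn_pre_start,
            self.syn_pre_list,
            self.syn_post_a,
            self.syn_w_a,
            self.syn_e_a,
            np.exp(-dt / self.syn_tr_a) if self.syn_w_a.size else np.zeros(0),
            np.exp(-dt / self.syn_td_a) if self.syn_w_a.size else np.zeros(0),
            self.syn_norm,
            self.syn_A,
            self.syn_B,
            ext_step,
            ext_syn,
            self.thresh,
            2.0,
            self.last_spike,
            self.spike_count,
            rec_idx,
            rec_out,
            self.clamp_idx,
            self.clamp_g,
            self.clamp_v,
            clamp_out,
            self.spk_flag,
            spk_comp,
            spk_time,
        )
        self.t += nsteps * dt
        if not np.all(np.isfinite(self.V)):
            bad = int(np.argmax(~np.isfinite(self.V)))
            raise FloatingPointError(
                f"voltage diverged (compartment {bad}, t <= {self.t:.3f} ms)"
            )
        return rec_out, clamp_out, (spk_comp[:nspk].copy(), spk_time[:nspk].copy())


def passive_linear_system(cell, max_seg_length: float = 20.0):
    """Conductance matrix (uS) and capacitance vector (nF) of a cell.

    Used for steady-state input resistance and for dense matrix-exponential
    cross-checks of the time stepping on small trees.
    """
    from .morpho import SectionKind

    tree = discretize(cell.morphology, max_seg_length)
    n = tree.ncomp
    pas = cell.passive
    axial = axial_conductance_uS(tree.axial_uS, pas.ra)
    gl = np.full(n, pas.g_l)
    for i, k in enumerate(tree.kind):
        if k is SectionKind.AXON:
            gl[i] *= pas.axon_gl_scale
    gl_uS = gl * tree.area_cm2 * 1e6
    G = np.diag(gl_uS)
    for i in range(1, n):
        p = tree.parent[i]
        G[i, i] += axial[i]
        G[p, p] += axial[i]
        G[i, p] -= axial[i]
        G[p, i] -= axial[i]
    C = np.full(n, pas.cm) * tree.area_cm2 * 1e3
    return G, C, tree
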