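"""Cable solver oracles, input resistances and firing phenotypes."""

import numpy as np
import pytest
from scipy.linalg import expm

from bulbnet.engine import SimGroup, discretize, passive_linear_system
from bulbnet.membrane import (
    CellModel,
    PassiveProps,
    Protocol,
    SpikeTrain,
    VoltageTrace,
    classify_firing,
    detect_spikes,
    input_resistance,
    make_cell,
    rebound_response,
    simulate,
    swap_channel,
)
from bulbnet.morpho import CellType, Morphology, Section, SectionKind


def single_sphere(g_l=1e-4, cm=1.0, d=20.0):
    m = Morphology([Section(0, None, SectionKind.SOMA, d, d)], CellType.MC)
    return CellModel(m, PassiveProps(ra=100.0, cm=cm, g_l=g_l, e_l=-65.0), [], "MC")


class TestDiscretization:
    def test_segment_count(self):
        m = Morphology(
            [Section(0, None, SectionKind.SOMA, 20, 20),
             Section(1, 0, SectionKind.APICAL, 400, 4)],
            CellType.MC,
        )
        tree = discretize(m, 50.0)
        apical = [i for i, k in enumerate(tree.kind) if k is SectionKind.APICAL]
        assert len(apical) == 8

    def test_halving_max_length_doubles_compartments(self, reduced_mc):
        n1 = discretize(reduced_mc, 40.0).ncomp
        n2 = discretize(reduced_mc, 20.0).ncomp
        assert abs(n2 - 2 * n1) <= len(reduced_mc.sections)

    def test_membrane_area_conserved(self, reduced_mc):
        target = reduced_mc.total_area() * 1e-8  # um^2 -> cm^2
        for seg in (5.0, 20.0, 80.0):
            tree = discretize(reduced_mc, seg)
            assert tree.area_cm2.sum() == pytest.approx(target, abs=1e-9)


class TestPassiveOracles:
    def test_rc_step_response(self):
        """Single compartment: V - V_rest = I R (1 - exp(-t/tau))."""
        cell = single_sphere()
        res = simulate(cell, Protocol([(5.0, 0.0), (120.0, -20.0)]), dt=0.01)
        v, t = res.trace.values, res.trace.times
        area = np.pi * (20e-4) ** 2
        R = 1 / (1e-4 * area)          # Ohm
        tau = 10.0                      # ms: Cm/gL = 1 uF/cm2 / 1e-4 S/cm2
        dv_inf = -20e-12 * R * 1e3      # mV
        for mult in (1.0, 2.0, 5.0):
            idx = np.argmin(np.abs(t - (5.0 + mult * tau)))
            analytic = -65.0 + dv_inf * (1 - np.exp(-mult))
            assert abs(v[idx] - analytic) / abs(dv_inf) < 0.01

    def test_sealed_end_cable_input_resistance(self):
        """Soma + uniform cylinder: G_in = G_soma + G_inf tanh(L/lambda)."""
        d_um, L_um = 2.0, 500.0
        m = Morphology(
            [Section(0, None, SectionKind.SOMA, 2, 2),
             Section(1, 0, SectionKind.LATERAL, L_um, d_um)],
            CellType.MC,
        )
        cell = CellModel(m, PassiveProps(ra=150.0, cm=1.0, g_l=5e-5, e_l=-65.0), [], "MC")
        rin = input_resistance(cell, max_seg_length=1.0)
        Rm, Ra = 1 / 5e-5, 150.0
        d, L = d_um * 1e-4, L_um * 1e-4
        lam = np.sqrt(Rm * d / (4 * Ra))
        Ginf = (np.pi * d**1.5) / 2 * np.sqrt(1 / (Rm * Ra))
        Gsoma = 5e-5 * np.pi * (2e-4) ** 2
        closed = 1 / (Gsoma + Ginf * np.tanh(L / lam)) / 1e6
        assert rin == pytest.approx(closed, rel=0.01)

    def test_matrix_exponential_oracle_small_tree(self):
        """Backward Euler matches a dense matrix-exponential solution to 0.5%."""
        secs = [Section(0, None, SectionKind.SOMA, 10, 10),
                Section(1, 0, SectionKind.LATERAL, 60, 2),
                Section(2, 1, SectionKind.LATERAL, 40, 1.5),
                Section(3, 1, SectionKind.LATERAL, 50, 1.0)]
        cell = CellModel(Morphology(secs, CellType.MC),
                         PassiveProps(ra=120.0, cm=0.9, g_l=8e-5, e_l=-65.0), [], "MC")
        G, C, _tree = passive_linear_system(cell, max_seg_length=25.0)
        assert G.shape[0] <= 10
        A = -(G / C[:, None])
        I = np.zeros(G.shape[0])
        I[0] = -0.02
        b = I / C
        res = simulate(cell, Protocol([(100.0, -20.0)]), dt=0.0125, max_seg_length=25.0)
        v, t = res.trace.values, res.trace.times
        for T in (5.0, 20.0, 60.0):
            dv = np.linalg.solve(A, (expm(A * T) - np.eye(G.shape[0])) @ b)
            idx = np.argmin(np.abs(t - T))
            assert abs(v[idx] - (-65.0 + dv[0])) / abs(dv[0]) < 0.005


class TestInputResistance:
    def test_isopotential_sphere_analytic(self):
        cell = single_sphere(g_l=1e-4)
        area = np.pi * (20e-4) ** 2
        assert input_resistance(cell) == pytest.approx(1 / (1e-4 * area) / 1e6, rel=1e-6)

    @pytest.mark.parametrize("subtype, target, tol", [
        ("MC", 91.5, 0.02),
        ("mTC", 125.3, 0.02),
        ("dSAC", 278.3, 0.02),
        ("sGC", 603.2, 0.05),
        ("dGC", 603.2, 0.05),
    ])
    def test_calibrated_cells(self, subtype, target, tol):
        assert abs(input_resistance(make_cell(subtype)) / target - 1) < tol

    def test_mtc_exceeds_mc(self):
        assert input_resistance(make_cell("mTC")) > input_resistance(make_cell("MC"))


class TestSpikeDetection:
    def test_flat_trace_empty(self):
        tr = VoltageTrace(0.1, 0, np.full(1000, -65.0))
        assert len(detect_spikes(tr)) == 0

    def test_sawtooth_known_slope(self):
        # five 20-ms ramps rising at 25 mV/ms for 2 ms then resetting
        dt = 0.025
        t = np.arange(0, 100, dt)
        v = np.full(t.shape, -65.0)
        starts = np.arange(5.0, 100.0, 20.0)
        for s in starts:
            ramp = (t >= s) & (t < s + 2.0)
            v[ramp] = -65.0 + 25.0 * (t[ramp] - s)
        spikes = detect_spikes(VoltageTrace(dt, 0, v), dvdt_threshold=20.0)
        assert len(spikes) == 5
        assert np.allclose(spikes.times, starts + dt, atol=2 * dt)

    def test_lowering_threshold_monotone(self):
        rng = np.random.default_rng(0)
        v = -65 + np.cumsum(rng.normal(0, 0.4, 4000))
        tr = VoltageTrace(0.05, 0, v)
        counts = [len(detect_spikes(tr, th)) for th in (30.0, 20.0, 10.0, 5.0)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            detect_spikes(VoltageTrace(0.1, 0, np.zeros(10)), 0.0)


class TestClassification:
    def test_empty_is_silent(self):
        assert classify_firing(SpikeTrain(np.zeros(0))) == "silent"

    def test_regular_20hz_is_tonic(self):
        assert classify_firing(SpikeTrain(np.arange(0.0, 1000.0, 50.0))) == "tonic"

    def test_clusters_with_gaps_are_bursting(self):
        t = np.concatenate([np.array([0, 5, 10]), 200 + np.array([0, 5, 10]),
                            400 + np.array([0, 5, 10])])
        assert classify_firing(SpikeTrain(t)) == "bursting"


class TestFiringPhenotypes:
    """Channel-complement phenotypes (each check runs in well under a minute)."""

    def test_mc_tonic_at_all_suprathreshold_steps(self):
        mc = make_cell("MC")
        for amp in (300.0, 500.0, 800.0):
            res = simulate(mc, Protocol.step(amp, onset=200, length=1200), dt=0.025)
            t = res.spikes.times[res.spikes.times > 205]
            assert len(t) > 5
            assert classify_firing(SpikeTrain(t)) == "tonic"

    def test_mtc_bursts_low_tonic_high(self):
        mtc = make_cell("mTC")
        low = simulate(mtc, Protocol.step(300.0, onset=200, length=1500), dt=0.025)
        t = low.spikes.times[low.spikes.times > 205]
        assert classify_firing(SpikeTrain(t)) == "bursting"
        high = simulate(mtc, Protocol.step(1200.0, onset=200, length=1500), dt=0.025)
        t = high.spikes.times[high.spikes.times > 600]  # past the adaptation transient
        assert classify_firing(SpikeTrain(t)) == "tonic"
        assert len(t) / 1.1 > 30  # high-frequency tonic

    def test_rebound_clusters_mtc_not_mc(self):
        assert rebound_response(make_cell("mTC"), 300.0, duration_ms=1500)[0]
        assert not rebound_response(make_cell("MC"), 400.0, duration_ms=1500)[0]

    def test_ks_to_kdr_swap_abolishes_bursting(self):
        swapped = swap_channel(make_cell("mTC"), "K_S", "K_DR")
        for amp in (300.0, 500.0):
            res = simulate(swapped, Protocol.step(amp, onset=200, length=1500), dt=0.025)
            t = res.spikes.times[res.spikes.times > 205]
            assert classify_firing(SpikeTrain(t)) == "tonic"

    def test_dt_refinement_stability(self):
        """Halving dt changes the soma trajectory by < 0.5 mV on the
        two-cell pulse protocol's drive regime (subthreshold segment)."""
        mtc = make_cell("mTC")
        proto = Protocol([(150.0, 0.0), (100.0, 150.0), (150.0, 0.0)])
        a = simulate(mtc, proto, dt=0.025).trace.values
        b = simulate(mtc, proto, dt=0.0125).trace.values[::2]
        assert np.max(np.abs(a - b[: a.shape[0]])) < 0.5


class TestSyntheticPopulationResistances:
    def test_full_trees_lower_than_reduced(self):
        from bulbnet.morpho import default_branch_stats, synthesize_morphology

        stats = default_branch_stats(CellType.MTC)
        m = synthesize_morphology(stats, CellType.MTC, seed=0)
        assert input_resistance(make_cell("mTC", morphology=m)) < input_resistance(
            make_cell("mTC")
        )

    @pytest.mark.parametrize("subtype, target", [("MC", 27.4), ("mTC", 65.2)])
    def test_population_means(self, subtype, target):
        from bulbnet.morpho import default_branch_stats, synthesize_morphology

        stats = default_branch_stats(subtype)
        rins = np.array([
            input_resistance(make_cell(subtype, morphology=synthesize_morphology(
                stats, subtype, seed=i)))
            for i in range(20)
        ])
        assert abs(rins.mean() - target) < 2 * rins.std()
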