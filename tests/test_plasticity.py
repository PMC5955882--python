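"""Column formation: learning rule, extraction, uniformization."""

import numpy as np
import pytest

from bulbnet.glomin import GlomerularDrive, glomerular_inhibition
from bulbnet.membrane import Subtype
from bulbnet.netbuild import Geometry, NetworkError, build_network, connect_reciprocal
from bulbnet.plasticity import (
    PlasticityRule,
    extract_column,
    run_learning,
    uniformize_weights,
)


def make_pair_net(seed=1, n_gc=240):
    net = build_network(2, 1, 2, n_gc=n_gc, geometry=Geometry((800, 600), 400),
                        seed=seed, glom_positions=[(150, 300), (500, 300)],
                        aligned_axis=True)
    return connect_reciprocal(net, density=0.1, co_connectivity=0.0, seed=seed + 1)


def strong_weak_drive(seed=3, weak=0.35):
    amps = glomerular_inhibition(np.array([1.0, weak]))
    return GlomerularDrive(amps, sniff_rate=3.0, modulation_depth=0.3,
                           amp_jitter=0.05, phase_jitter_ms=10, seed=seed)


@pytest.fixture(scope="module")
def learned_net():
    """One strong + one suppressed unit after learning (shared fixture)."""
    net = make_pair_net(seed=1)
    return run_learning(net, strong_weak_drive(), PlasticityRule(), n_sniffs=10)


class TestRule:
    def test_theta_ordering_enforced(self):
        with pytest.raises(ValueError):
            PlasticityRule(theta_ltp=1.0, theta_ltd=1.0)
        with pytest.raises(ValueError):
            PlasticityRule(theta_ltp=0.5, theta_ltd=1.0)

    def test_requires_connectivity(self):
        net = build_network(1, 1, 1, n_gc=5, seed=0)
        with pytest.raises(NetworkError):
            run_learning(net, strong_weak_drive(), PlasticityRule(), n_sniffs=1)


class TestLearning:
    def test_no_drive_leaves_weights_at_zero(self):
        net = make_pair_net(seed=4, n_gc=60)
        drive = GlomerularDrive(np.zeros(2))
        net = run_learning(net, drive, PlasticityRule(), n_sniffs=2)
        assert np.all(net.synapses.w_exc == 0)
        assert np.all(net.synapses.w_inh == 0)

    def test_weight_bounds_maintained(self, learned_net):
        rule = PlasticityRule()
        tab = learned_net.synapses
        assert np.all(tab.w_exc >= 0) and np.all(tab.w_exc <= rule.w_max)
        assert np.all(tab.w_inh >= 0) and np.all(tab.w_inh <= rule.w_max)

    def test_strong_unit_gets_full_depth_column(self, learned_net):
        col = extract_column(learned_net, 0)
        assert len(col.member_gc_ids) > 0
        assert col.depth_extent >= 0.9

    def test_suppressed_unit_gets_no_column(self, learned_net):
        col = extract_column(learned_net, 1)
        assert col.member_gc_ids == []
        assert col.depth_extent == 0.0

    def test_inhibitory_weight_nonincreasing_with_distance(self, learned_net):
        """Beyond the column core, potentiated inhibition falls off with
        path distance from the soma (selective distal depression)."""
        tab = learned_net.synapses
        mc = learned_net.unit(0).mc_ids[0]
        sel = tab.principal_id == mc
        d, w = tab.path_dist[sel], tab.w_inh[sel]
        edges = np.arange(0.0, 801.0, 160.0)
        means = [w[(d >= a) & (d < b)].mean() for a, b in zip(edges, edges[1:])
                 if ((d >= a) & (d < b)).any()]
        core = means[0]
        assert core > 0.5
        beyond = np.asarray(means[1:])
        assert np.all(np.diff(beyond) <= 1e-9 + 0.05)
        assert beyond[-1] < 0.5 * core


class TestColumnExtraction:
    def test_unknown_glomerulus_rejected(self, learned_net):
        with pytest.raises(NetworkError):
            extract_column(learned_net, 99)

    def test_before_learning_empty(self):
        net = make_pair_net(seed=6, n_gc=60)
        col = extract_column(net, 0)
        assert col.member_gc_ids == [] and col.depth_extent == 0.0

    def test_members_span_both_strata(self, learned_net):
        col = extract_column(learned_net, 0)
        depths = [learned_net.cells[m].depth for m in col.member_gc_ids]
        half = learned_net.geometry.gcl_depth / 2
        assert any(x < half for x in depths) and any(x >= half for x in depths)


class TestUniformize:
    def test_totals_conserved_and_variance_zero(self, learned_net):
        import copy

        net = copy.deepcopy(learned_net)
        tab = net.synapses
        pids = set(net.unit(0).principal_ids)
        sel = np.asarray([int(p) in pids for p in tab.principal_id])
        before = (tab.w_exc[sel].sum(), tab.w_inh[sel].sum())
        uniformize_weights(net, 0)
        after = (tab.w_exc[sel].sum(), tab.w_inh[sel].sum())
        assert after[0] == pytest.approx(before[0], abs=1e-9)
        assert after[1] == pytest.approx(before[1], abs=1e-9)
        assert tab.w_inh[sel].var() == pytest.approx(0.0, abs=1e-18)

    def test_other_unit_untouched(self, learned_net):
        import copy

        net = copy.deepcopy(learned_net)
        tab = net.synapses
        pids1 = set(net.unit(1).principal_ids)
        sel1 = np.asarray([int(p) in pids1 for p in tab.principal_id])
        before = tab.w_inh[sel1].copy()
        uniformize_weights(net, 0)
        assert np.array_equal(tab.w_inh[sel1], before)


class TestRuleRobustness:
    @pytest.mark.parametrize("scale", [0.5, 2.0])
    def test_column_forms_for_halved_and_doubled_increments(self, scale):
        """Column formation survives halving/doubling the weight increments
        (it depends on potentiation and depression having different
        activity thresholds, not on the specific learning rule)."""
        net = make_pair_net(seed=2)
        rule = PlasticityRule(delta_up=0.1 * scale, delta_down=0.01 * scale)
        net = run_learning(net, strong_weak_drive(seed=5), rule, n_sniffs=10)
        col = extract_column(net, 0)
        assert col.depth_extent >= 0.9
        assert extract_column(net, 1).member_gc_ids == []
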