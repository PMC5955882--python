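"""Network construction: placement, reciprocal connectivity, clusters, dSACs."""

import numpy as np
import pytest
from scipy.stats import chisquare, poisson

from bulbnet.membrane import Subtype
from bulbnet.netbuild import (
    Geometry,
    NetworkError,
    assign_clusters,
    build_network,
    connect_reciprocal,
    wire_dsacs,
)


def small_net(seed=0, n_gc=150, co=0.0, **kw):
    net = build_network(4, 1, 2, n_gc=n_gc, geometry=Geometry((600, 600), 400),
                        seed=seed, **kw)
    return connect_reciprocal(net, density=0.1, co_connectivity=co, seed=seed + 1)


class TestBuild:
    def test_counts(self):
        net = build_network(4, 1, 2, n_gc=10, seed=0)
        mcs = [c for c in net.cells.values() if c.subtype is Subtype.MC]
        mtcs = [c for c in net.cells.values() if c.subtype is Subtype.MTC]
        assert len(mcs) == 4 and len(mtcs) == 8
        for u in net.units:
            assert len(u.mc_ids) == 1 and len(u.mtc_ids) == 2

    def test_zero_glomeruli_rejected(self):
        with pytest.raises(NetworkError):
            build_network(0, 1, 2, n_gc=10)

    def test_gc_somata_fill_the_slab(self):
        net = build_network(2, 1, 2, n_gc=400, geometry=Geometry((500, 500), 300), seed=1)
        depths = np.array([net.cells[g].depth for g in net.gc_ids])
        assert depths.min() >= 0 and depths.max() <= 300
        # roughly uniform: both halves populated
        assert 100 < (depths < 150).sum() < 300

    def test_determinism(self):
        a = small_net(seed=5)
        b = small_net(seed=5)
        assert np.array_equal(a.synapses.principal_id, b.synapses.principal_id)
        assert np.array_equal(a.synapses.gc_id, b.synapses.gc_id)
        assert np.allclose(a.synapses.path_dist, b.synapses.path_dist)

    def test_full_scale_instantiation_counts(self):
        """Full-system cell counts instantiate (placement only)."""
        net = build_network(635, 1, 2, n_gc=191_485,
                            geometry=Geometry((3000, 3000), 400), seed=0)
        assert len(net.principal_ids) == 635 * 3
        assert len(net.gc_ids) == 191_485
        assert sum(len(u.mtc_ids) for u in net.units) == 1270


class TestReciprocalConnectivity:
    def test_expected_density(self):
        # one MC: 1,600 um of lateral dendrite at 0.1 syn/um -> ~160 sites
        net = build_network(1, 1, 0, n_gc=4000, geometry=Geometry((2000, 2000), 400),
                            seed=3, glom_positions=[(1000, 1000)])
        net = connect_reciprocal(net, density=0.1, seed=4)
        n = len(net.synapses)
        assert abs(n - 160) <= 3 * np.sqrt(160)

    def test_poisson_counts_across_seeds(self):
        """Synapse counts over seeds follow Poisson(0.1 L) (chi-square, 5%)."""
        counts = []
        for seed in range(100):
            # GC field dense enough that every site finds a partner
            net = build_network(1, 1, 0, n_gc=5000,
                                geometry=Geometry((2000, 2000), 400), seed=seed,
                                glom_positions=[(1000, 1000)])
            net = connect_reciprocal(net, density=0.02, seed=seed + 1000)
            counts.append(len(net.synapses))
        counts = np.asarray(counts)
        lam = 0.02 * 1600.0
        edges = [0, 24, 28, 31, 34, 37, 41, 1000]
        obs = np.histogram(counts, edges)[0]
        cdf = poisson.cdf(np.asarray(edges[1:]) - 1, lam)
        probs = np.diff(np.concatenate([[0.0], cdf]))
        probs[-1] = 1 - cdf[-2]
        stat, p = chisquare(obs, probs * 100)
        assert p > 0.05

    def test_zero_density_no_synapses(self):
        net = build_network(2, 1, 2, n_gc=50, seed=0)
        net = connect_reciprocal(net, density=0.0, seed=1)
        assert len(net.synapses) == 0

    def test_zero_coconnectivity_separates_populations(self):
        net = small_net(seed=7, co=0.0)
        for g in np.unique(net.synapses.gc_id):
            partners = {
                net.cells[int(p)].subtype
                for p in net.synapses.principal_id[net.synapses.gc_id == g]
            }
            assert partners in ({Subtype.MC}, {Subtype.MTC})

    def test_full_coconnectivity_mixes_populations(self):
        net = small_net(seed=7, co=1.0, n_gc=300)
        mixed = 0
        for g in np.unique(net.synapses.gc_id):
            partners = {
                net.cells[int(p)].subtype
                for p in net.synapses.principal_id[net.synapses.gc_id == g]
            }
            mixed += len(partners) == 2
        assert mixed > 0

    def test_weights_start_at_zero(self):
        net = small_net(seed=2)
        assert np.all(net.synapses.w_exc == 0) and np.all(net.synapses.w_inh == 0)

    def test_sites_on_lateral_dendrites(self):
        from bulbnet.morpho import SectionKind

        net = small_net(seed=2)
        tab = net.synapses
        for k in range(len(tab)):
            morph = net.cells[int(tab.principal_id[k])].morphology
            assert morph.section(int(tab.section_id[k])).kind is SectionKind.LATERAL

    def test_stratum_pairing(self):
        net = small_net(seed=9, n_gc=400)
        half = net.geometry.gcl_depth / 2
        tab = net.synapses
        for k in range(len(tab)):
            st = net.cells[int(tab.principal_id[k])].subtype
            depth = net.cells[int(tab.gc_id[k])].depth
            if st is Subtype.MC:
                assert depth >= half
            else:
                assert depth < half


class TestClusters:
    def test_assignment_and_singletons(self):
        net = small_net(seed=1)
        net = assign_clusters(net, [[0, 1]])
        assert net.cluster_of(0) == net.cluster_of(1)
        assert net.cluster_of(2) != net.cluster_of(3)

    def test_empty_partition_all_singletons(self):
        net = small_net(seed=1)
        net = assign_clusters(net, [])
        labels = {net.cluster_of(u.glom_id) for u in net.units}
        assert len(labels) == len(net.units)

    def test_overlapping_blocks_rejected(self):
        net = small_net(seed=1)
        with pytest.raises(NetworkError):
            assign_clusters(net, [[0, 1], [1, 2]])

    def test_unknown_glomerulus_rejected(self):
        net = small_net(seed=1)
        with pytest.raises(NetworkError):
            assign_clusters(net, [[0, 99]])


class TestDSACs:
    def test_requires_clusters(self):
        net = small_net(seed=1)
        with pytest.raises(NetworkError):
            wire_dsacs(net)

    def test_targets_equal_bruteforce_cross_cluster_scan(self):
        for seed in range(4):
            net = small_net(seed=seed, n_gc=250)
            net = assign_clusters(net, [[0, 1], [2, 3]])
            net = wire_dsacs(net, n_dsac=1, seed=seed)
            tab = net.synapses
            brute = set()
            for g in np.unique(tab.gc_id):
                gloms = {net.cells[int(p)].glom_id
                         for p in tab.principal_id[tab.gc_id == g]}
                labels = {net.clusters[gl] for gl in gloms}
                if len(labels) >= 2:
                    brute.add(int(g))
            assert set(net.dsacs[0].inhibitory_targets) == brute

    def test_single_cluster_empty_target_set(self):
        net = small_net(seed=3)
        net = assign_clusters(net, [[0, 1, 2, 3]])
        net = wire_dsacs(net, seed=3)
        assert net.dsacs[0].inhibitory_targets == []

    def test_excitation_only_from_mtcs(self):
        net = small_net(seed=3)
        net = assign_clusters(net, [[0, 1], [2, 3]])
        net = wire_dsacs(net, seed=3)
        for w in net.dsacs:
            assert all(net.cells[i].subtype is Subtype.MTC for i in w.excitatory_inputs)


class TestReciprocity:
    def test_every_site_has_both_components(self):
        """Each synapse row carries paired excitatory and inhibitory weights
        at the same site (checked through the simulation mapping)."""
        from bulbnet.netsim import NetSim

        net = small_net(seed=4, n_gc=200)
        sim = NetSim(net)
        n = len(net.synapses)
        assert sim.exc_idx.shape == (n,) and sim.inh_idx.shape == (n,)
        # exc pre-compartment equals inh post-compartment (same principal site)
        assert np.array_equal(
            sim.grp.syn_pre_a[sim.exc_idx], sim.grp.syn_post_a[sim.inh_idx]
        )
        # and the GC side matches likewise
        assert np.array_equal(
            sim.grp.syn_post_a[sim.exc_idx], sim.grp.syn_pre_a[sim.inh_idx]
        )
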