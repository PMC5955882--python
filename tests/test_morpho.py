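"""Morphology construction, synthesis, morphometrics and SWC round-trips."""

import math

import numpy as np
import pytest
from scipy.stats import ks_2samp

from bulbnet.morpho import (
    BranchStats,
    CellType,
    Distribution,
    Morphology,
    MorphologyError,
    Section,
    SectionKind,
    branch_order_histogram,
    default_branch_stats,
    make_reduced_morphology,
    read_swc,
    sholl_profile,
    synthesize_morphology,
    write_swc,
)


class TestReducedMorphologies:
    def test_mc_dimensions(self, reduced_mc):
        apicals = [s for s in reduced_mc.sections if s.kind is SectionKind.APICAL]
        laterals = [s for s in reduced_mc.sections if s.kind is SectionKind.LATERAL]
        tufts = [s for s in reduced_mc.sections if s.kind is SectionKind.TUFT]
        assert [s.length for s in apicals] == [400.0]
        assert sorted(s.length for s in laterals) == [800.0, 800.0]
        assert all(s.diameter == 3.0 for s in laterals)
        assert len(tufts) == 4
        assert all(s.length == 80.0 and s.diameter == 0.8 for s in tufts)

    def test_mtc_dimensions(self, reduced_mtc):
        apicals = [s for s in reduced_mtc.sections if s.kind is SectionKind.APICAL]
        laterals = [s for s in reduced_mtc.sections if s.kind is SectionKind.LATERAL]
        assert apicals[0].length == 250.0
        assert all(s.length == 600.0 and s.diameter == 2.5 for s in laterals)

    def test_soma_sphere_area(self, reduced_mc):
        # sphere surface, pi * d^2 for a 20 um soma
        assert reduced_mc.area(reduced_mc.soma.id) == pytest.approx(
            math.pi * 20.0**2
        )
        assert reduced_mc.area(reduced_mc.soma.id) == pytest.approx(1256.64, abs=0.01)

    def test_dsac_ball_and_stick(self):
        m = make_reduced_morphology(CellType.DSAC)
        dend = [s for s in m.sections if s.kind is not SectionKind.SOMA]
        assert len(dend) == 1 and dend[0].length == 1400.0
        m2 = make_reduced_morphology(CellType.DSAC, slice_corrected=False)
        assert m2.total_length() == 2800.0

    def test_gc_fixture_has_gemmules(self):
        m = make_reduced_morphology(CellType.GC)
        gem = [s for s in m.sections if s.kind is SectionKind.TUFT]
        assert len(gem) == 50

    def test_unknown_type_rejected(self):
        with pytest.raises(MorphologyError):
            make_reduced_morphology("PGC")


class TestMorphologyInvariants:
    def test_single_soma_required(self):
        with pytest.raises(MorphologyError):
            Morphology([Section(0, None, SectionKind.LATERAL, 10, 1)], CellType.MC)

    def test_orphan_parent_rejected(self):
        with pytest.raises(MorphologyError):
            Morphology(
                [Section(0, None, SectionKind.SOMA, 10, 10),
                 Section(1, 99, SectionKind.LATERAL, 10, 1)],
                CellType.MC,
            )

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(MorphologyError):
            Section(0, None, SectionKind.SOMA, 0.0, 10)


class TestSynthesis:
    def test_zero_branching_gives_unbranched_dendrites(self):
        stats = BranchStats(
            Distribution("constant", {"value": 100.0}),
            [0.0],
            Distribution("constant", {"value": 3}),
        )
        m = synthesize_morphology(stats, CellType.MTC, seed=0)
        laterals = [s for s in m.sections if s.kind is SectionKind.LATERAL]
        assert len(laterals) == 3
        assert all(s.length == 100.0 for s in laterals)

    def test_deterministic_given_seed(self):
        stats = default_branch_stats(CellType.MTC)
        a = synthesize_morphology(stats, CellType.MTC, seed=7)
        b = synthesize_morphology(stats, CellType.MTC, seed=7)
        assert [(s.id, s.parent_id, s.length, s.diameter) for s in a.sections] == [
            (s.id, s.parent_id, s.length, s.diameter) for s in b.sections
        ]

    def test_total_lateral_length_mode_near_8500(self):
        """Synthetic mTC total-lateral-length distribution peaks near 8,500 um."""
        from scipy.stats import gaussian_kde

        stats = default_branch_stats(CellType.MTC)
        totals = np.array([
            synthesize_morphology(stats, CellType.MTC, seed=i).total_length(
                SectionKind.LATERAL
            )
            for i in range(200)
        ])
        kde = gaussian_kde(totals)
        grid = np.linspace(totals.min(), totals.max(), 500)
        mode = grid[np.argmax(kde(grid))]
        assert abs(mode - 8500.0) / 8500.0 < 0.15

    def test_terminal_path_lengths_match_descriptive_distribution(self):
        """Sampled terminal path lengths agree with the stored distribution
        (two-sample KS below the 5 percent critical value)."""
        stats = default_branch_stats(CellType.MTC)
        rng = np.random.default_rng(99)
        n_trees, n_ref_trees = 500, 800
        sampled = []
        for i in range(n_trees):
            m = synthesize_morphology(stats, CellType.MTC, seed=10_000 + i)
            sampled += [
                m.path_distance(s.id)
                for s in m.sections
                if s.kind is SectionKind.LATERAL and not any(
                    c.kind is SectionKind.LATERAL for c in m.children(s.id)
                )
            ]
        reference = stats.implied_path_lengths(rng, n_ref_trees)
        stat, _p = ks_2samp(np.asarray(sampled), reference)
        # terminals within a tree share parent segments, so the effective
        # sample size is the number of trees, not the number of terminals
        critical = 1.358 * np.sqrt((n_trees + n_ref_trees) / (n_trees * n_ref_trees))
        assert stat < critical

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(MorphologyError):
            BranchStats(
                Distribution("constant", {"value": -5.0}),
                [0.5],
                Distribution("constant", {"value": 2}),
            )


class TestSholl:
    def test_single_dendrite(self):
        m = Morphology(
            [Section(0, None, SectionKind.SOMA, 10, 10),
             Section(1, 0, SectionKind.LATERAL, 100, 2)],
            CellType.MC,
        )
        profile = dict(sholl_profile(m, 25.0))
        assert profile == {25.0: 1, 50.0: 1, 75.0: 1, 100.0: 1}

    def test_bifurcation_counts(self, simple_bifurcation):
        profile = dict(sholl_profile(simple_bifurcation, 25.0))
        assert profile[25.0] == 1
        assert profile[75.0] == 2
        assert profile[50.0] == 1
        assert profile[100.0] == 2

    def test_matches_bruteforce_on_random_trees(self, rng):
        stats = default_branch_stats(CellType.MTC)
        for seed in range(3):
            m = synthesize_morphology(stats, CellType.MTC, seed=seed)
            step = 50.0
            prof = sholl_profile(m, step)
            dend = m.dendritic_sections()
            for r, count in prof:
                brute = sum(
                    1
                    for s in dend
                    if m.path_interval(s.id)[0] < r <= m.path_interval(s.id)[1] + 1e-9
                )
                assert brute == count

    def test_invalid_step_rejected(self, reduced_mc):
        with pytest.raises(ValueError):
            sholl_profile(reduced_mc, 0.0)


class TestBranchOrder:
    def test_unbranched(self):
        m = Morphology(
            [Section(0, None, SectionKind.SOMA, 10, 10),
             Section(1, 0, SectionKind.LATERAL, 100, 2)],
            CellType.MC,
        )
        assert branch_order_histogram(m) == {0: 1}

    def test_one_bifurcation(self, simple_bifurcation):
        assert branch_order_histogram(simple_bifurcation) == {0: 1, 1: 2}

    def test_total_equals_dendritic_section_count(self):
        stats = default_branch_stats(CellType.MC)
        m = synthesize_morphology(stats, CellType.MC, seed=3)
        hist = branch_order_histogram(m)
        assert sum(hist.values()) == len(m.dendritic_sections())


class TestSWC:
    def test_roundtrip_preserves_topology_and_lengths(self, reduced_mc, tmp_path):
        path = tmp_path / "mc.swc"
        write_swc(reduced_mc, str(path))
        back = read_swc(str(path), CellType.MC)
        assert back.total_length() == pytest.approx(reduced_mc.total_length(), abs=1e-6)
        orig = sorted((s.kind.value, round(s.length, 6), s.diameter)
                      for s in reduced_mc.sections)
        rt = sorted((s.kind.value, round(s.length, 6), s.diameter)
                    for s in back.sections)
        assert orig == rt

    def test_roundtrip_synthetic(self, tmp_path):
        stats = default_branch_stats(CellType.MTC)
        m = synthesize_morphology(stats, CellType.MTC, seed=5)
        path = tmp_path / "mtc.swc"
        write_swc(m, str(path))
        back = read_swc(str(path))
        assert back.total_length() == pytest.approx(m.total_length(), abs=1e-6)

    def test_forward_reference_accepted(self, tmp_path):
        # a child record may appear before its parent (two-pass parse)
        path = tmp_path / "fwd.swc"
        path.write_text(
            "2 3 10 0 0 1 1\n"
            "1 1 0 0 0 5 -1\n"
            "3 3 30 0 0 0.8 2\n"
        )
        m = read_swc(str(path))
        assert len(m.sections) == 3
        assert m.path_distance(3) == pytest.approx(30.0)

    def test_empty_file_reports_no_soma(self, tmp_path):
        path = tmp_path / "empty.swc"
        path.write_text("")
        with pytest.raises(MorphologyError, match="no soma"):
            read_swc(str(path))

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 1 0 0 0 5 -1\nnot a record at all\n")
        with pytest.raises(MorphologyError, match=":2"):
            read_swc(str(path))
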