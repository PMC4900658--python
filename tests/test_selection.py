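"""Panel construction: filtering, grouping, allocation, spread, evaluation,
resampling optimization, and trait association."""

import itertools

import numpy as np
import pytest

from panelqc.marker_stats import MarkerStatsRecord, compute_marker_stats
from panelqc.matrix import HET, MISSING, MarkerRecord, subset
from panelqc.selection import (
    FilterThresholds,
    MarkerGroupAssignment,
    PanelSpec,
    STRINGENT_QC,
    allocate_by_strategy,
    evaluate_panel,
    filter_markers,
    group_markers,
    optimize_panel,
    select_rapid_panel,
    select_uniform_genomic,
    trait_marker_scan,
)

from conftest import build_matrix, oracle_pair_mismatches, random_matrix


def _stats(mid, missing, maf, het, cov):
    return MarkerStatsRecord(mid, maf, het, missing, 0.3, cov, "AG_TC")


class TestFilterMarkers:
    def test_stringent_rules_on_toy_fixture(self):
        """Hand-applying the stringent rules leaves exactly 3 survivors."""
        stats = [
            _stats("m1", 0.5, 0.02, 0.02, 1.0),   # fails missing + maf? no maf rule; + coverage
            _stats("m2", 0.1, 0.30, 0.15, 5.0),   # fails het
            _stats("m3", 0.1, 0.30, 0.02, 5.0),
            _stats("m4", 0.1, 0.30, 0.02, 5.0),
            _stats("m5", 0.1, 0.30, 0.02, 20.0),  # fails coverage
            _stats("m6", 0.1, 0.30, 0.02, 5.0),
        ]
        placed = {s.marker_id: True for s in stats}
        survivors, removed = filter_markers(stats, STRINGENT_QC, placed=placed)
        assert survivors == ["m3", "m4", "m6"]
        assert set(removed["m1"]) == {"missing_rate", "coverage"}
        assert removed["m2"] == ["het_rate"]
        assert removed["m5"] == ["coverage"]

    def test_loosest_thresholds_keep_everything(self):
        stats = [_stats(f"m{i}", 0.9, 0.0, 0.9, None) for i in range(4)]
        survivors, _ = filter_markers(stats, FilterThresholds())
        assert len(survivors) == 4

    def test_impossible_maf_bound_empties_panel(self):
        stats = [_stats(f"m{i}", 0.1, 0.5, 0.0, None) for i in range(4)]
        survivors, removed = filter_markers(
            stats, FilterThresholds(min_maf=0.6)
        )
        assert survivors == [] and len(removed) == 4

    def test_initial_screen_boundaries(self):
        """The first-pass screen removes strictly-exceeding markers only."""
        from panelqc.selection import INITIAL_SCREEN

        stats = [
            _stats("at_bound", 0.40, 0.05, 0.10, None),
            _stats("over", 0.41, 0.05, 0.10, None),
        ]
        survivors, _ = filter_markers(stats, INITIAL_SCREEN)
        assert survivors == ["at_bound"]


class TestGroupMarkers:
    def test_separated_blocks_recovered(self):
        """Two marker blocks with opposite profiles split cleanly at k=2."""
        block1 = np.tile([0, 0, 0, 2, 2, 2], (10, 1))
        block2 = np.tile([2, 2, 2, 0, 0, 0], (10, 1))
        gm = build_matrix(np.vstack([block1, block2]))
        ga = group_markers(gm, None, k=2, n_components=2, seed=1)
        g_first = {ga.assignment[f"m{i + 1}"] for i in range(10)}
        g_second = {ga.assignment[f"m{i + 11}"] for i in range(10)}
        assert len(g_first) == 1 and len(g_second) == 1 and g_first != g_second

    def test_k_equals_markers_gives_singletons(self):
        codes = np.array([[0, 2, 0], [2, 0, 0], [0, 0, 2], [2, 2, 2]])
        gm = build_matrix(codes)
        ga = group_markers(gm, None, k=4, n_components=3, seed=0)
        assert sorted(
            [len(ga.members(g)) for g in range(1, 5)]
        ) == [1, 1, 1, 1]

    def test_deterministic_under_seed(self, structured_panel):
        gm, _ = structured_panel
        ids = gm.marker_ids[:100]
        a = group_markers(gm, ids, 5, 3, seed=3).assignment
        b = group_markers(gm, ids, 5, 3, seed=3).assignment
        assert a == b

    def test_too_few_distinct_profiles_error(self):
        gm = build_matrix(np.zeros((5, 4), dtype=int))
        with pytest.raises(ValueError, match="distinct marker profiles"):
            group_markers(gm, None, k=3, n_components=2, seed=0)


def _fake_groups(sizes, scores):
    assignment = {}
    mid = 0
    for g, n in enumerate(sizes, start=1):
        for _ in range(n):
            assignment[f"m{mid}"] = g
            mid += 1
    k = len(sizes)
    return MarkerGroupAssignment(
        assignment=assignment,
        centroids=np.zeros((k, 2)),
        distance_scores=np.asarray(scores, dtype=float),
    )


class TestAllocation:
    def test_pgd_proportional_to_distance_scores(self):
        groups = _fake_groups([10, 10, 10], [1.0, 2.0, 3.0])
        counts, picked = allocate_by_strategy(groups, 12, "PGD", seed=0)
        assert counts == {1: 2, 2: 4, 3: 6}
        assert len(picked) == 12 and len(set(picked)) == 12

    def test_ng_equal_split(self):
        groups = _fake_groups([5, 5, 5, 5], [1, 1, 1, 1])
        counts, _ = allocate_by_strategy(groups, 8, "NG", seed=0)
        assert counts == {1: 2, 2: 2, 3: 2, 4: 2}

    def test_pg_proportional_to_sizes(self):
        groups = _fake_groups([50, 50], [9.0, 1.0])
        counts, _ = allocate_by_strategy(groups, 10, "PG", seed=0)
        assert counts == {1: 5, 2: 5}

    def test_pgd_with_equal_scores_matches_ng(self):
        groups = _fake_groups([7, 7, 7], [2.0, 2.0, 2.0])
        c1, _ = allocate_by_strategy(groups, 9, "PGD", seed=1)
        c2, _ = allocate_by_strategy(groups, 9, "NG", seed=1)
        assert c1 == c2

    def test_counts_always_sum_to_total(self):
        groups = _fake_groups([3, 9, 5, 2], [0.5, 1.5, 2.5, 3.5])
        for strat in ("RANDOM", "PG", "NG", "PGD"):
            for total in (4, 7, 13):
                counts, picked = allocate_by_strategy(groups, total, strat, seed=5)
                assert sum(counts.values()) == total == len(picked)

    def test_small_group_deficit_reallocated(self):
        groups = _fake_groups([2, 20], [10.0, 1.0])
        counts, _ = allocate_by_strategy(groups, 10, "PGD", seed=0)
        assert counts[1] == 2 and counts[2] == 8

    def test_every_group_represented_when_budget_allows(self):
        groups = _fake_groups([10, 10, 10], [100.0, 1.0, 1.0])
        counts, _ = allocate_by_strategy(groups, 6, "PGD", seed=0)
        assert all(c >= 1 for c in counts.values())


class TestUniformGenomic:
    def _markers(self, positions, chrom="1"):
        return [
            MarkerRecord(f"u{i}", chrom, p, "A", "G")
            for i, p in enumerate(positions)
        ]

    def test_bin_midpoint_picks(self):
        """Chromosome of 100 bp, markers at 10/50/90, two bins -> 10 and 90."""
        sel = select_uniform_genomic(
            self._markers([10, 50, 90]), 2, chrom_lengths={"1": 100}
        )
        positions = sorted(int(s[1:]) for s in sel)
        assert [10, 90] == sorted(
            [10, 50, 90][i] for i in positions
        )

    def test_total_equals_all(self):
        mk = self._markers([5, 15, 25])
        assert sorted(select_uniform_genomic(mk, 3)) == [m.marker_id for m in mk]

    def test_two_equal_chromosomes_split_evenly(self):
        mk = self._markers([10, 30, 60, 90], "1") + [
            MarkerRecord(f"v{i}", "2", p, "C", "T")
            for i, p in enumerate([10, 30, 60, 90])
        ]
        sel = select_uniform_genomic(mk, 4, chrom_lengths={"1": 100, "2": 100})
        assert sum(s.startswith("u") for s in sel) == 2
        assert sum(s.startswith("v") for s in sel) == 2

    def test_unplaced_markers_rejected(self):
        mk = [MarkerRecord("w0", "0", 5, "A", "G")]
        with pytest.raises(ValueError, match="unplaced"):
            select_uniform_genomic(mk, 1)

    def test_empty_bin_forfeits_to_neighbor(self):
        # all markers in the first half; second bin forfeits
        sel = select_uniform_genomic(
            self._markers([10, 20, 30]), 2, chrom_lengths={"1": 100}
        )
        assert len(sel) == 2


class TestEvaluatePanel:
    def test_one_of_three_pairs_undistinguished(self):
        gm = build_matrix([[0, 0, 2], [2, 2, 0]], entries=["L1", "L2", "L3"])
        ev = evaluate_panel(gm, PanelSpec(markers=["m1", "m2"]))
        assert ev.undistinguished_pair_proportion == pytest.approx(1 / 3)
        assert ev.undistinguished_pairs == [("L1", "L2")]

    def test_fully_discriminating_panel(self):
        gm = build_matrix([[0, 2, 1], [0, 0, 2]])
        ev = evaluate_panel(gm, PanelSpec(markers=["m1", "m2"]))
        assert ev.undistinguished_pair_proportion == 0.0

    def test_empty_panel_distinguishes_nothing(self):
        gm = build_matrix([[0, 2]])
        ev = evaluate_panel(gm, PanelSpec(markers=[]))
        assert ev.undistinguished_pair_proportion == 1.0

    def test_zero_overlap_pair_counts_as_undistinguished(self):
        gm = build_matrix([[0, MISSING], [MISSING, 2]])
        ev = evaluate_panel(gm, PanelSpec(markers=["m1", "m2"]))
        assert ev.undistinguished_pair_proportion == 1.0

    def test_matches_bruteforce_oracle(self):
        """Matrix-algebra mismatch counts equal pairwise enumeration."""
        rng = np.random.default_rng(12)
        for _ in range(10):
            gm = random_matrix(rng, 30, 12)
            panel_ids = list(
                rng.choice(gm.marker_ids, size=rng.integers(1, 30), replace=False)
            )
            ev = evaluate_panel(gm, PanelSpec(markers=panel_ids))
            assert ev.pair_mismatch_counts == oracle_pair_mismatches(gm, panel_ids)

    def test_monotone_under_panel_growth(self):
        rng = np.random.default_rng(21)
        gm = random_matrix(rng, 40, 10)
        ids = gm.marker_ids
        prev = 1.1
        for size in (5, 10, 20, 40):
            ev = evaluate_panel(gm, PanelSpec(markers=ids[:size]))
            assert ev.undistinguished_pair_proportion <= prev
            prev = ev.undistinguished_pair_proportion


class TestOptimizePanel:
    def test_unique_separator_always_included(self):
        """When only marker M splits a twin pair, every top panel has M."""
        rng = np.random.default_rng(3)
        codes = rng.choice([0, 2], size=(10, 6))
        codes[:, 1] = codes[:, 0]  # E1, E2 twins everywhere...
        codes[4, 1] = 2 - codes[4, 0]  # ...except marker m5
        gm = build_matrix(codes)
        panels, evals = optimize_panel(
            gm, gm.marker_ids, size=5, reps=100, seed=8
        )
        for spec, ev in zip(panels, evals):
            if ev.undistinguished_pair_proportion == 0.0:
                assert "m5" in spec.markers

    def test_deterministic_under_seed(self, structured_panel):
        gm, _ = structured_panel
        ids = gm.marker_ids[:60]
        p1, _ = optimize_panel(gm, ids, size=12, reps=20, seed=42)
        p2, _ = optimize_panel(gm, ids, size=12, reps=20, seed=42)
        assert [p.markers for p in p1] == [p.markers for p in p2]

    def test_matches_exhaustive_enumeration(self):
        """Random search saturating C(8,4) finds the enumeration optimum."""
        rng = np.random.default_rng(5)
        gm = random_matrix(rng, 8, 7, missing_rate=0.1)
        ids = gm.marker_ids

        def key(panel_ids):
            ev = evaluate_panel(gm, PanelSpec(markers=list(panel_ids)))
            return (ev.undistinguished_pair_proportion, -ev.min_mismatch,
                    -ev.mean_mismatch)

        best_exhaustive = min(key(c) for c in itertools.combinations(ids, 4))
        panels, evals = optimize_panel(gm, ids, size=4, reps=2000, seed=1)
        got = (evals[0].undistinguished_pair_proportion,
               -evals[0].min_mismatch, -evals[0].mean_mismatch)
        assert got == pytest.approx(best_exhaustive)

    def test_mandatory_markers_forced_in(self, structured_panel):
        gm, _ = structured_panel
        ids = gm.marker_ids[:40]
        panels, _ = optimize_panel(
            gm, ids, size=8, reps=10, mandatory=ids[:2], seed=0
        )
        for p in panels:
            assert set(ids[:2]) <= set(p.markers)

    def test_size_below_mandatory_errors(self, structured_panel):
        gm, _ = structured_panel
        ids = gm.marker_ids[:10]
        with pytest.raises(ValueError, match="mandatory"):
            optimize_panel(gm, ids, size=2, reps=5, mandatory=ids[:3], seed=0)


class TestRapidPanel:
    def test_nested_in_broad_by_construction(self, structured_panel):
        gm, _ = structured_panel
        broad = PanelSpec(markers=gm.marker_ids[:30], name="broad")
        panels, _ = select_rapid_panel(gm, broad, size=10, reps=30, seed=2)
        for p in panels:
            assert set(p.markers) <= set(broad.markers)

    def test_full_size_returns_broad_itself(self, structured_panel):
        gm, _ = structured_panel
        broad = PanelSpec(markers=gm.marker_ids[:12], name="broad")
        panels, _ = select_rapid_panel(gm, broad, size=12, reps=20, seed=2)
        assert len(panels) == 1
        assert set(panels[0].markers) == set(broad.markers)

    def test_planted_unique_subset_ranks_first(self):
        """A 5-marker subset that uniquely separates all lines wins."""
        rng = np.random.default_rng(9)
        n_lines = 12
        # 5 planted markers: binary encoding + parity makes all lines distinct
        planted = np.array(
            [[(i >> b) & 1 for i in range(n_lines)] for b in range(4)]
            + [[bin(i).count("1") % 2 for i in range(n_lines)]]
        ) * 2
        # 5 fillers: constant -> useless for discrimination
        fillers = np.zeros((5, n_lines), dtype=int)
        gm = build_matrix(np.vstack([planted, fillers]))
        broad = PanelSpec(markers=gm.marker_ids)
        panels, evals = select_rapid_panel(gm, broad, size=5, reps=3000, seed=4)
        assert evals[0].undistinguished_pair_proportion == 0.0
        assert sorted(panels[0].markers) == ["m1", "m2", "m3", "m4", "m5"]


class TestTraitScan:
    def test_fixture_chi_square_value(self):
        """Cases 18A/2B vs controls 5A/15B give chi-square 17.29."""
        # 10 case entries: 8 AA + 2 AB -> A=18, B=2
        # 10 control entries: 5 BB + 5 AB -> wait: need A=5, B=15
        case = [0] * 8 + [1] * 2
        ctrl = [1] * 5 + [2] * 5
        gm = build_matrix([case + ctrl])
        traits = {f"E{j + 1}": (1 if j < 10 else 0) for j in range(20)}
        results, best = trait_marker_scan(gm, traits)
        assert results[0].statistic == pytest.approx(17.29, abs=0.005)
        assert best.marker_id == "m1"

    def test_equal_frequencies_score_zero(self):
        gm = build_matrix([[0, 2, 0, 2]])
        traits = {"E1": 1, "E2": 1, "E3": 0, "E4": 0}
        results, _ = trait_marker_scan(gm, traits)
        assert results[0].statistic == 0.0 and results[0].p_value == 1.0

    def test_monomorphic_marker_null(self):
        gm = build_matrix([[0, 0, 0, 0]])
        traits = {"E1": 1, "E2": 1, "E3": 0, "E4": 0}
        results, _ = trait_marker_scan(gm, traits)
        assert results[0].statistic == 0.0 and results[0].p_value == 1.0

    def test_planted_concordant_marker_is_best(self, structured_panel):
        from panelqc.simulate import simulate_trait_introgression

        gm, _ = structured_panel
        carriers = gm.entries[:6]
        gm2, table, truth = simulate_trait_introgression(
            gm, ["M00010"], carriers, "qpm"
        )
        values = {e: table.values[e]["qpm"] for e in gm2.entries}
        _, best = trait_marker_scan(gm2, values, "qpm")
        assert best.marker_id == "M00010"

    def test_empty_class_rejected(self):
        gm = build_matrix([[0, 2]])
        with pytest.raises(ValueError, match="non-empty"):
            trait_marker_scan(gm, {"E1": 1, "E2": 1})
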