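import numpy as np
import pytest

from concordex.rrho import (
    QUADRANTS,
    RankedList,
    RRHOMap,
    hypergeom_overlap_p,
    intersect_peak_sets,
    quadrant_peaks,
    rrho_map,
)

from .conftest import hypergeom_tail_exact


def make_list(n, n_pos, rng):
    """Ranked list over genes G0..G{n-1} with a random order and n_pos ups."""
    genes = [f"G{i}" for i in rng.permutation(n)]
    scores = np.concatenate(
        [np.sort(rng.uniform(0.1, 5, n_pos))[::-1], -np.sort(rng.uniform(0.1, 5, n - n_pos))]
    )
    return RankedList(genes=genes, scores=scores)


class TestHypergeomOverlap:
    def test_exact_value(self):
        # P(X >= 3) for 5-and-5 from 20: 1126/15504
        assert hypergeom_overlap_p(3, 5, 5, 20) == pytest.approx(
            1126 / 15504, abs=1e-12
        )
        assert hypergeom_overlap_p(3, 5, 5, 20) == pytest.approx(
            hypergeom_tail_exact(3, 5, 5, 20), abs=1e-12
        )

    def test_certain_events(self):
        assert hypergeom_overlap_p(0, 5, 7, 20) == 1.0
        assert hypergeom_overlap_p(9, 9, 9, 9) == 1.0

    @pytest.mark.parametrize("k,i,j,N", [(6, 5, 5, 20), (1, 5, 25, 20), (-1, 5, 5, 20)])
    def test_bound_violations(self, k, i, j, N):
        with pytest.raises(ValueError):
            hypergeom_overlap_p(k, i, j, N)


class TestRrhoMap:
    def test_cells_match_brute_force_sets(self):
        """Every grid cell equals the hypergeometric tail of the explicitly
        materialized top/bottom slice intersection (N = 30, step = 1)."""
        rng = np.random.default_rng(5)
        l1 = make_list(30, 13, rng)
        l2 = make_list(30, 17, rng)
        rmap = rrho_map(l1, l2, step=1)
        strata1 = {"U": l1.up_genes(), "D": l1.down_genes()}
        strata2 = {"U": l2.up_genes(), "D": l2.down_genes()}
        for q in QUADRANTS:
            s1, s2 = strata1[q[0]], strata2[q[1]]
            for a, i in enumerate(rmap.i_thresholds[q]):
                for b, j in enumerate(rmap.j_thresholds[q]):
                    k = len(set(s1[:i]) & set(s2[:j]))
                    expected = hypergeom_tail_exact(k, i, j, 30)
                    assert 10 ** (-rmap.grids[q][a, b]) == pytest.approx(
                        expected, abs=1e-12
                    )

    def test_self_overlap_beats_permutations(self):
        rng = np.random.default_rng(6)
        l1 = make_list(60, 30, rng)
        self_peak = quadrant_peaks(rrho_map(l1, l1, step=1))["UU"].neglog_p
        for _ in range(20):
            perm = list(rng.permutation(l1.genes))
            l2 = RankedList(genes=perm, scores=l1.scores.copy())
            perm_peak = quadrant_peaks(rrho_map(l1, l2, step=1))["UU"].neglog_p
            assert self_peak >= perm_peak

    def test_empty_up_stratum(self):
        rng = np.random.default_rng(7)
        l1 = make_list(20, 0, rng)
        l2 = make_list(20, 10, rng)
        rmap = rrho_map(l1, l2, step=1)
        assert rmap.grids["UU"].size == 0
        assert rmap.grids["UD"].size == 0
        assert rmap.grids["DD"].size > 0
        peaks = quadrant_peaks(rmap)
        assert not peaks["UU"].present
        assert peaks["DD"].present

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(8)
        l1 = make_list(40, 22, rng)
        l2 = make_list(40, 15, rng)
        m12 = rrho_map(l1, l2, step=1)
        m21 = rrho_map(l2, l1, step=1)
        swap = {"UU": "UU", "DD": "DD", "UD": "DU", "DU": "UD"}
        for q in QUADRANTS:
            np.testing.assert_allclose(m12.grids[q], m21.grids[swap[q]].T)

    def test_background_mismatch_reports_difference(self):
        l1 = RankedList(genes=["a", "b"], scores=np.array([1.0, -1.0]))
        l2 = RankedList(genes=["a", "c"], scores=np.array([1.0, -1.0]))
        with pytest.raises(ValueError, match="[bc]"):
            rrho_map(l1, l2)

    def test_default_step_scales_with_background(self):
        rng = np.random.default_rng(9)
        l1 = make_list(100, 50, rng)
        rmap = rrho_map(l1, l1)
        assert rmap.step == 10

    def test_corrected_map_not_below_raw_significance(self):
        rng = np.random.default_rng(10)
        l1 = make_list(30, 15, rng)
        rmap = rrho_map(l1, l1, step=1, correction="by")
        for q in QUADRANTS:
            assert np.all(rmap.corrected_grids[q] <= rmap.grids[q] + 1e-12)


class TestQuadrantPeaks:
    def _map_with_grid(self, grid):
        n = 10
        genes = [f"G{i}" for i in range(n)]
        half = genes[:5]
        return RRHOMap(
            background=genes,
            step=1,
            n1_pos=5,
            n2_pos=5,
            strata1={"up": half, "down": genes[5:][::-1]},
            strata2={"up": half, "down": genes[5:][::-1]},
            i_thresholds={q: np.arange(1, grid.shape[0] + 1) for q in QUADRANTS},
            j_thresholds={q: np.arange(1, grid.shape[1] + 1) for q in QUADRANTS},
            grids={q: grid.copy() for q in QUADRANTS},
        )

    def test_unique_maximum(self):
        grid = np.zeros((4, 4))
        grid[2, 3] = 5.0
        peak = quadrant_peaks(self._map_with_grid(grid))["UU"]
        assert (peak.i, peak.j, peak.neglog_p) == (3, 4, 5.0)

    def test_tie_prefers_smallest_thresholds(self):
        grid = np.zeros((4, 4))
        grid[3, 1] = grid[1, 2] = grid[1, 3] = 7.0
        peak = quadrant_peaks(self._map_with_grid(grid))["UU"]
        assert (peak.i, peak.j) == (2, 3)

    def test_peak_genes_respect_direction_strata(self):
        rng = np.random.default_rng(11)
        l1 = make_list(40, 20, rng)
        l2 = make_list(40, 18, rng)
        peaks = quadrant_peaks(rrho_map(l1, l2, step=1))
        up1, up2 = set(l1.up_genes()), set(l2.up_genes())
        dn1, dn2 = set(l1.down_genes()), set(l2.down_genes())
        assert peaks["UU"].genes <= up1 & up2
        assert peaks["DD"].genes <= dn1 & dn2
        assert peaks["UD"].genes <= up1 & dn2
        assert peaks["DU"].genes <= dn1 & up2


class TestIntersectPeakSets:
    def test_pairwise(self):
        regions = intersect_peak_sets({"x": {"A", "B", "C"}, "y": {"B", "C", "D"}})
        assert regions[frozenset({"x", "y"})] == {"B", "C"}
        assert regions[frozenset({"x"})] == {"A"}
        assert regions[frozenset({"y"})] == {"D"}

    def test_identical_sets_single_region(self):
        s = {"a", "b", "c"}
        regions = intersect_peak_sets({k: s for k in "wxyz"})
        assert regions == {frozenset("wxyz"): s}

    def test_three_sets_hand_enumeration(self):
        a = set(range(10))
        b = set(range(5, 15))
        c = set(range(8, 18))
        regions = intersect_peak_sets({"a": a, "b": b, "c": c})
        assert len(regions[frozenset("ab")]) == 3  # 5,6,7
        assert len(regions[frozenset("abc")]) == 2  # 8,9
        assert len(regions[frozenset("bc")]) == 5  # 10..14
        assert len(regions[frozenset("a")]) == 5  # 0..4
        assert len(regions[frozenset("c")]) == 3  # 15..17
        total = sum(len(v) for v in regions.values())
        assert total == len(a | b | c)


class TestPeakRecoveryOnSimulatedData:
    def test_uu_peak_enriched_for_planted_concordant_genes(self, pipeline_run):
        """The concordant-up peak of the WT-vs-SH comparison recovers the
        planted shared susceptibility genes far beyond chance."""
        import json

        from .conftest import hypergeom_tail_exact

        _, report, out = pipeline_run
        peaks = json.loads((out / "rrho_WT_vs_SH_peaks.json").read_text())
        truth = json.loads((out / "ground_truth.json").read_text())
        de = truth["de_genes_per_contrast"]
        planted_cc_up = {g for g, s in de["WT"].items() if s > 0} & {
            g for g, s in de["SH"].items() if s > 0
        }
        uu = set(peaks["UU"]["genes"])
        assert peaks["UU"]["present"]
        k = len(uu & planted_cc_up)
        n_genes = len(truth["module_of_gene"])
        assert k >= 2
        p = hypergeom_tail_exact(k, len(planted_cc_up), len(uu), n_genes)
        assert p < 1e-6
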