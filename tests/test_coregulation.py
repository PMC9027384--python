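"""Level grouping, direction-aware tests and the decisive rule."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

import regclust as rc
from regclust.coregulation import _direction_deg_sets
from regclust.regnet import ACTIVATION, REPRESSION, Combo


def pooled_t_oracle(x, y):
    """Textbook pooled-variance two-sample t statistic."""
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    sx2 = sum((v - mx) ** 2 for v in x) / (nx - 1)
    sy2 = sum((v - my) ** 2 for v in y) / (ny - 1)
    sp2 = ((nx - 1) * sx2 + (ny - 1) * sy2) / (nx + ny - 2)
    return (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny)), nx + ny - 2


def _toy_matrix(values, times=(1.0, 2.0)):
    genes = [f"g{i}" for i in range(len(values))]
    return rc.TimeCourseMatrix(genes, times, values)


CA = Combo("A", "RpoD", ACTIVATION)
CB = Combo("B", "RpoD", REPRESSION)
CC = Combo("C", "RpoS", ACTIVATION)


@pytest.fixture(scope="module")
def toy():
    # 6 genes, 3 important combos, one decoy combo that must be ignored
    decoy = Combo("D", "RpoD", ACTIVATION)
    sig = {
        "g0": frozenset([CA]),
        "g1": frozenset([CA, decoy]),
        "g2": frozenset([CA, CB]),
        "g3": frozenset([CB, CC]),
        "g4": frozenset([decoy]),
        "g5": frozenset(),
    }
    m = _toy_matrix([[-2, -2], [-2, -1], [1, 2], [2, 2], [0, 1], [0, 0]])
    return sig, m


class TestAssignLevels:

    def test_matches_powerset_bucketing(self, toy):
        sig, m = toy
        important = [CA, CB, CC]
        groups = rc.assign_levels(sig.keys(), important, sig, m)
        got = {g.combos: set(g.genes) for g in groups}
        # brute-force bucketing over the powerset of important combos
        expected = {}
        for subset_size in range(1, 4):
            for subset in itertools.combinations(important, subset_size):
                key = frozenset(subset)
                members = {g for g, s in sig.items() if s & frozenset(important) == key}
                if members:
                    expected[key] = members
        assert got == expected

    def test_uncontrolled_genes_excluded(self, toy):
        sig, m = toy
        groups = rc.assign_levels(sig.keys(), [CA, CB, CC], sig, m)
        grouped = {g for grp in groups for g in grp.genes}
        assert "g4" not in grouped and "g5" not in grouped

    def test_levels_equal_subset_cardinality_and_partition(self, toy):
        sig, m = toy
        groups = rc.assign_levels(sig.keys(), [CA, CB, CC], sig, m)
        for g in groups:
            assert g.level == len(g.combos)
        controlled = [g for g, s in sig.items()
                      if s & frozenset([CA, CB, CC])]
        assert sum(len(g.genes) for g in groups) == len(controlled)

    def test_direction_from_mean_sign(self, toy):
        sig, m = toy
        groups = rc.assign_levels(sig.keys(), [CA, CB, CC], sig, m)
        by_key = {g.combos: g for g in groups}
        assert by_key[frozenset([CA])].direction == "down"
        assert by_key[frozenset([CB, CC])].direction == "up"

    def test_small_groups_marked_untestable(self, toy):
        sig, m = toy
        groups = rc.assign_levels(sig.keys(), [CA, CB, CC], sig, m)
        for g in groups:
            assert g.testable == (len(g.genes) >= 2)


class TestGroupFisher:
    def test_concentrated_direction_small_p(self):
        # group of 5, all down-DEGs; only 1 other down-DEG among 45 others
        group = rc.LevelGroup(frozenset([CA]), 1,
                              tuple(f"g{i}" for i in range(5)), "down")
        universe = [f"g{i}" for i in range(50)]
        dirs = {"down": frozenset(universe[:5] + ["g40"]), "up": frozenset()}
        p = rc.group_fisher(group, dirs, universe)
        assert p == pytest.approx(
            rc.fisher_right_tail(5, 5, 6, 50), rel=1e-12
        )
        assert p < 1e-5

    def test_background_like_composition_p_near_one(self):
        group = rc.LevelGroup(frozenset([CA]), 1, ("g0", "g1"), "down")
        universe = [f"g{i}" for i in range(10)]
        dirs = {"down": frozenset(universe), "up": frozenset()}
        assert rc.group_fisher(group, dirs, universe) == 1.0

    def test_degenerate_margins_warn_p_one(self):
        group = rc.LevelGroup(frozenset([CA]), 1, ("g0",), "up")
        with pytest.warns(UserWarning, match="degenerate"):
            p = rc.group_fisher(group, {"up": frozenset(), "down": frozenset()},
                                ["g0", "g1"])
        assert p == 1.0


class TestTimepointTtests:
    def test_identical_samples_give_p_half(self):
        vals = [[1.0, 0.0], [1.0, 0.0], [1.0 + 1e-9, 0.0], [1.0 - 1e-9, 0.0]]
        m = _toy_matrix(vals)
        g = rc.LevelGroup(frozenset([CA]), 1, ("g0", "g1"), "up")
        tests = rc.timepoint_ttests([g], m, rc.Config())
        t0 = [t for t in tests if t.time == 1.0][0]
        assert t0.t_stat == pytest.approx(0.0, abs=1e-4)
        assert t0.p_one_sided == pytest.approx(0.5, abs=1e-4)

    def test_pinned_pooled_t_value(self):
        # group (1.0, 1.2, 0.8) vs complement (0.0, 0.1, -0.1, 0.0)
        x, y = [1.0, 1.2, 0.8], [0.0, 0.1, -0.1, 0.0]
        m = _toy_matrix([[v, v] for v in x + y])
        g = rc.LevelGroup(frozenset([CA]), 1, ("g0", "g1", "g2"), "up")
        tests = rc.timepoint_ttests([g], m, rc.Config())
        t_oracle, df = pooled_t_oracle(x, y)
        assert t_oracle == pytest.approx(9.258200997, rel=1e-9)  # frozen oracle
        t0 = tests[0]
        assert t0.t_stat == pytest.approx(t_oracle, rel=1e-12)
        assert t0.p_one_sided == pytest.approx(
            float(stats.t.sf(t_oracle, df)), rel=1e-12
        )

    def test_one_sided_is_half_two_sided_in_direction(self):
        rng = np.random.default_rng(4)
        vals = np.column_stack([rng.normal(size=9), rng.normal(size=9)])
        vals[:3] += 1.0  # group shifted up
        m = _toy_matrix(vals)
        g = rc.LevelGroup(frozenset([CA]), 1, ("g0", "g1", "g2"), "up")
        tests = rc.timepoint_ttests([g], m, rc.Config())
        for t in tests:
            x = vals[:3, int(t.time) - 1]
            y = vals[3:, int(t.time) - 1]
            p_two = stats.ttest_ind(x, y, equal_var=True).pvalue
            if t.t_stat > 0:
                assert t.p_one_sided == pytest.approx(p_two / 2, rel=1e-10)

    def test_zero_variance_flagged_not_corrected(self):
        m = _toy_matrix([[1.0, 2.0], [1.0, 2.5], [0.0, 1.0], [0.0, 0.5]])
        g = rc.LevelGroup(frozenset([CA]), 1, ("g0", "g1"), "up")
        with pytest.warns(UserWarning, match="zero pooled variance"):
            tests = rc.timepoint_ttests([g], m, rc.Config())
        flagged = [t for t in tests if t.time == 1.0][0]
        assert math.isnan(flagged.p_one_sided) and math.isnan(flagged.p_adj)
        valid = [t for t in tests if t.time == 2.0][0]
        assert math.isfinite(valid.p_adj)

    def test_holm_family_is_per_level(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(12, 2))
        m = _toy_matrix(vals)
        g1 = rc.LevelGroup(frozenset([CA]), 1, ("g0", "g1"), "up")
        g2 = rc.LevelGroup(frozenset([CA, CB]), 2, ("g2", "g3"), "up")
        tests = rc.timepoint_ttests([g1, g2], m, rc.Config())
        for level in (1, 2):
            fam = [t for t in tests if t.level == level]
            raw = [t.p_one_sided for t in fam]
            assert [t.p_adj for t in fam] == pytest.approx(
                list(rc.holm_bonferroni(raw)), abs=1e-12
            )


class TestDecisiveFlags:
    def _group(self):
        return rc.LevelGroup(frozenset([CA]), 1, ("g0", "g1"), "down")

    @pytest.mark.parametrize("pf,pt,expected", [
        (0.04, 0.2, False),   # t-test fails
        (0.2, 0.01, False),   # fisher fails
        (0.01, 0.01, True),   # both pass
    ])
    def test_and_rule(self, pf, pt, expected):
        g = self._group()
        tt = rc.TimepointTest(g.label(), 1, 1.0, 2.0, pt / 2, pt, "less")
        out = rc.decisive_flags([g], {g.label(): pf}, [tt], alpha_level=0.05)
        assert out[0].decisive is expected

    def test_untestable_never_decisive(self):
        g = rc.LevelGroup(frozenset([CA]), 1, ("g0",), "down", testable=False)
        out = rc.decisive_flags([g], {g.label(): 1e-9}, [], 0.05)
        assert not out[0].decisive


class TestLevelStageOnSyntheticTruth:
    def test_planted_level1_groups_decisive(self, truth, degs, signatures, matrix):
        important = [p.combo for p in truth.planted_combos]
        groups, tests = rc.run_level_analysis(
            degs.gene_ids, important, signatures, matrix, rc.Config()
        )
        level1 = {next(iter(g.combos)): g for g in groups if g.level == 1}
        crp = level1[Combo("CRP-cAMP", "RpoD", ACTIVATION)]
        assert crp.direction == "down" and crp.decisive

    def test_groups_partition_controlled_degs(self, truth, degs, signatures, matrix):
        important = frozenset(p.combo for p in truth.planted_combos)
        groups, _ = rc.run_level_analysis(
            degs.gene_ids, important, signatures, matrix, rc.Config()
        )
        controlled = [g for g in degs.gene_ids
                      if signatures.get(g, frozenset()) & important]
        assert sum(len(g.genes) for g in groups) == len(controlled)


class TestExportHeatmap:
    def test_empty_tests_header_only(self, tmp_path):
        p = tmp_path / "hm.tsv"
        rc.export_heatmap([], p)
        assert p.read_text() == "group\tlevel\t\n"

    def test_round_trip_and_signs(self, truth, degs, signatures, matrix, tmp_path):
        important = [p.combo for p in truth.planted_combos]
        groups, tests = rc.run_level_analysis(
            degs.gene_ids, important, signatures, matrix, rc.Config()
        )
        p = tmp_path / "hm.tsv"
        rc.export_heatmap(tests, p)
        lines = p.read_text().strip().split("\n")
        times = [float(v) for v in lines[0].split("\t")[2:]]
        by_group = {}
        for line in lines[1:]:
            parts = line.split("\t")
            by_group[parts[0]] = [float(v) for v in parts[2:]]
        directions = {g.label(): g.direction for g in groups}
        for t in tests:
            if not math.isfinite(t.p_adj) or t.p_adj <= 0:
                continue
            j = times.index(t.time)
            cell = by_group[t.group_label][j]
            expected = -math.log10(t.p_adj)
            if directions[t.group_label] == "down":
                expected = -expected
            assert cell == pytest.approx(expected, abs=1e-9)
            if directions[t.group_label] == "down":
                assert cell <= 0
            else:
                assert cell >= 0
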