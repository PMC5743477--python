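import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from localadapt._studentized_range import sr_sf
from localadapt.design_and_io import DesignError, TransplantDataset
from localadapt.local_foreign import (
    CellFit,
    PairwiseComparison,
    PairwiseComparisonTable,
    Verdict,
    classify_cell,
    fit_cell,
    run_local_foreign,
    tukey_pairwise,
    verdicts_frame,
)
from localadapt.synthetic_data import generate_dataset, study_design_config


def _cell_dataset(groups: dict[str, list[float]], species="s", garden="G") -> TransplantDataset:
    rows = []
    for e, vals in groups.items():
        for r, v in enumerate(vals, start=1):
            rows.append(
                {"species": species, "garden": garden, "ecotype": e, "replicate": r, "biomass": v}
            )
    return TransplantDataset(pd.DataFrame(rows))


class TestFitCell:
    def test_hand_computed_anova(self):
        """Two groups {2,4} and {6,8}: means 3/7, pooled var 2, R^2 = 0.8."""
        ds = _cell_dataset({"A": [2, 4], "B": [6, 8]})
        fit = fit_cell(ds, "s", "G")
        assert fit.ecotype_means == pytest.approx({"A": 3.0, "B": 7.0})
        assert fit.residual_variance == pytest.approx(2.0, abs=1e-10)
        assert fit.residual_df == 2
        assert fit.r_squared == pytest.approx(0.8, abs=1e-10)

    def test_constant_data_degenerate(self):
        ds = _cell_dataset({"A": [5, 5], "B": [5, 5]})
        fit = fit_cell(ds, "s", "G")
        assert fit.residual_variance == 0.0
        assert fit.r_squared == 0.0

    def test_label_invariance(self):
        g = {"A": [2.0, 4.0, 3.0], "B": [6.0, 8.0, 7.0], "C": [1.0, 2.0, 1.5]}
        fit1 = fit_cell(_cell_dataset(g), "s", "G")
        relabel = {"A": "C", "B": "A", "C": "B"}
        fit2 = fit_cell(_cell_dataset({relabel[k]: v for k, v in g.items()}), "s", "G")
        assert fit1.r_squared == pytest.approx(fit2.r_squared, abs=1e-12)
        assert fit1.residual_variance == pytest.approx(fit2.residual_variance, abs=1e-12)
        for e, m in fit1.ecotype_means.items():
            assert fit2.ecotype_means[relabel[e]] == pytest.approx(m)

    def test_preconditions(self):
        with pytest.raises(DesignError, match="ecotype"):
            fit_cell(_cell_dataset({"A": [1, 2]}), "s", "G")
        with pytest.raises(DesignError, match="'B'"):
            fit_cell(_cell_dataset({"A": [1, 2], "B": [3]}), "s", "G")

    def test_missing_excluded(self):
        ds = _cell_dataset({"A": [2, 4], "B": [6, 8]})
        df = ds.df
        extra = pd.DataFrame(
            [{"species": "s", "garden": "G", "ecotype": "A", "replicate": 9, "biomass": np.nan}]
        )
        ds2 = TransplantDataset(pd.concat([df, extra], ignore_index=True))
        assert fit_cell(ds2, "s", "G") == fit_cell(ds, "s", "G")


class TestStudentizedRange:
    def test_matches_scipy(self):
        """Quadrature evaluation vs scipy's implementation, k >= 3."""
        q = np.linspace(0.05, 9.0, 30)
        for k in (3, 4, 5, 8):
            for df in (2, 5, 44, 300):
                ref = stats.studentized_range.sf(q, k, df)
                assert np.max(np.abs(sr_sf(q, k, df) - ref)) < 1e-6

    def test_two_groups_equals_pooled_t(self):
        """k = 2 identity: p = two-sided t on q / sqrt(2), to 1e-10."""
        for df in (1, 3, 10, 50):
            q = np.linspace(0.1, 7, 20)
            expected = 2 * stats.t.sf(q / np.sqrt(2), df)
            assert np.max(np.abs(sr_sf(q, 2, df) - expected)) < 1e-10

    def test_monte_carlo_tail(self, rng):
        """Simulation oracle for the q distribution, 1e6 draws, k = 3."""
        k, df, n = 3, 12, 1_000_000
        z = rng.standard_normal((n, k))
        s = np.sqrt(rng.chisquare(df, n) / df)
        qs = (z.max(axis=1) - z.min(axis=1)) / s
        for q0 in (2.0, 3.0, 3.77):
            mc = (qs >= q0).mean()
            assert sr_sf(q0, k, df) == pytest.approx(mc, abs=0.005)

    def test_edge_cases(self):
        assert sr_sf(0.0, 4, 10) == 1.0
        assert sr_sf(-1.0, 4, 10) == 1.0
        assert sr_sf(50.0, 4, 10) < 1e-6
        with pytest.raises(ValueError):
            sr_sf(1.0, 1, 10)


class TestTukey:
    def test_equal_means_all_p_one(self):
        ds = _cell_dataset({"A": [1.0, 2.0], "B": [1.0, 2.0], "C": [2.0, 1.0]})
        table = tukey_pairwise(fit_cell(ds, "s", "G"))
        assert all(c.p_adjusted == 1.0 for c in table.comparisons)

    def test_two_group_p_equals_t_test(self):
        ds = _cell_dataset({"A": [2.1, 4.0, 3.3], "B": [6.2, 8.5, 7.0]})
        table = tukey_pairwise(fit_cell(ds, "s", "G"))
        a = [2.1, 4.0, 3.3]
        b = [6.2, 8.5, 7.0]
        t_p = stats.ttest_ind(a, b).pvalue
        assert table.comparisons[0].p_adjusted == pytest.approx(t_p, abs=1e-10)

    def test_covers_all_pairs_once(self):
        ds = _cell_dataset({e: [1.0 + i, 2.0 + i] for i, e in enumerate("ABCD")})
        table = tukey_pairwise(fit_cell(ds, "s", "G"))
        assert len(table.comparisons) == 6
        pairs = {frozenset((c.ecotype_a, c.ecotype_b)) for c in table.comparisons}
        assert len(pairs) == 6
        assert all(0.0 <= c.p_adjusted <= 1.0 for c in table.comparisons)

    def test_zero_variance_unequal_means(self):
        ds = _cell_dataset({"A": [1.0, 1.0], "B": [2.0, 2.0], "C": [1.0, 1.0]})
        table = tukey_pairwise(fit_cell(ds, "s", "G"))
        assert table.lookup("A", "B").p_adjusted == 0.0
        assert table.lookup("A", "C").p_adjusted == 1.0

    def test_unbalanced_kramer_matches_statsmodels(self):
        """Tukey-Kramer with unequal n against statsmodels' implementation."""
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(7)
        vals = {"A": list(rng.normal(5, 1, 8)), "B": list(rng.normal(6, 1, 5)), "C": list(rng.normal(5.5, 1, 11))}
        table = tukey_pairwise(fit_cell(_cell_dataset(vals), "s", "G"))
        data = np.concatenate([vals[k] for k in "ABC"])
        labels = np.repeat(list("ABC"), [8, 5, 11])
        res = sm.pairwise_tukeyhsd(data, labels)
        for (a, b), p_ref in zip(
            itertools.combinations("ABC", 2), res.pvalues
        ):
            assert table.lookup(a, b).p_adjusted == pytest.approx(float(p_ref), abs=1e-4)


def _table(mean_diffs, pvals, alpha=0.05):
    """Build a table for local ecotype 'L' vs nonlocals N1..Nk plus filler pairs."""
    comps = []
    names = [f"N{i}" for i in range(1, len(mean_diffs) + 1)]
    for name, d, p in zip(names, mean_diffs, pvals):
        comps.append(PairwiseComparison("L", name, d, p))
    for a, b in itertools.combinations(names, 2):
        comps.append(PairwiseComparison(a, b, 0.0, 1.0))
    return PairwiseComparisonTable("s", "G", tuple(comps), alpha)


class TestClassify:
    def test_local_beats_all(self):
        t = _table([1.0, 2.0, 0.5], [0.01, 0.001, 0.04])
        assert classify_cell(t, "L").verdict is Verdict.LOCAL_IS_BEST

    def test_one_nonlocal_beats_local(self):
        t = _table([-1.0, 0.2, 0.1], [0.02, 0.9, 0.9])
        assert classify_cell(t, "L").verdict is Verdict.NONLOCAL_IS_BEST

    def test_no_significant_pairs(self):
        t = _table([1.0, -0.5, 0.2], [0.5, 0.3, 0.9])
        assert classify_cell(t, "L").verdict is Verdict.NO_DIFFERENCE

    def test_partial_wins_are_not_enough(self):
        t = _table([1.0, 2.0, 0.5], [0.01, 0.001, 0.2])
        assert classify_cell(t, "L").verdict is Verdict.NO_DIFFERENCE

    def test_missing_local_raises(self):
        t = _table([1.0], [0.01])
        with pytest.raises(KeyError):
            classify_cell(t, "X")

    def test_rule_table_enumeration(self):
        """Exhaustive oracle over all sign x significance patterns (3 nonlocals)."""
        for signs in itertools.product([-1.0, 1.0], repeat=3):
            for sigs in itertools.product([0.01, 0.5], repeat=3):
                t = _table(list(signs), list(sigs))
                got = classify_cell(t, "L").verdict
                loses = any(s < 0 and p < 0.05 for s, p in zip(signs, sigs))
                wins_all = all(s > 0 and p < 0.05 for s, p in zip(signs, sigs))
                if loses:
                    expected = Verdict.NONLOCAL_IS_BEST
                elif wins_all:
                    expected = Verdict.LOCAL_IS_BEST
                else:
                    expected = Verdict.NO_DIFFERENCE
                assert got is expected

    def test_nonlocal_relabel_invariance(self):
        t1 = _table([1.0, -2.0, 0.5], [0.01, 0.001, 0.2])
        # permute the nonlocal labels
        perm = {"N1": "N2", "N2": "N3", "N3": "N1", "L": "L"}
        comps = tuple(
            PairwiseComparison(perm[c.ecotype_a], perm[c.ecotype_b], c.mean_difference, c.p_adjusted)
            for c in t1.comparisons
        )
        t2 = PairwiseComparisonTable("s", "G", comps, t1.alpha)
        assert classify_cell(t1, "L").verdict is classify_cell(t2, "L").verdict


class TestRunLocalForeign:
    def test_benchmark_design_yields_22_verdicts(self, null_dataset):
        out = run_local_foreign(null_dataset)
        assert len(out) == 22
        assert all(oc.verdict is not None for oc in out.values())
        frame = verdicts_frame(out)
        assert len(frame) == 22
        assert set(frame["verdict"]) <= {v.value for v in Verdict}

    def test_saturated_effect_all_local_is_best(self):
        cfg = study_design_config(
            3.0, seed=2, species_sd_log=0.05, garden_effect_sd=0.0, ecotype_quality_sd=0.0
        )
        out = run_local_foreign(generate_dataset(cfg))
        assert all(oc.verdict is Verdict.LOCAL_IS_BEST for oc in out.values())

    def test_skipped_cells_reported(self):
        rows = [
            {"species": "s", "garden": "A", "ecotype": e, "replicate": r, "biomass": 1.0 + r}
            for e in ("A", "B")
            for r in (1, 2)
        ]
        # garden B cell has a single ecotype -> skip with reason
        rows += [
            {"species": "s", "garden": "B", "ecotype": "B", "replicate": r, "biomass": 1.0}
            for r in (1, 2)
        ]
        out = run_local_foreign(TransplantDataset(pd.DataFrame(rows)))
        assert out[("s", "A")].verdict is not None
        assert out[("s", "B")].verdict is None
        assert "ecotype" in out[("s", "B")].skipped_reason
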