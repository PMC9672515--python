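"""Normalization and differential-expression calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernapipe.expression import (
    DEThresholds,
    ExpressionMatrix,
    call_de,
    compute_srpbm,
    filter_highly_expressed,
    log2_fold_change,
    normalize_cpm,
    overlap_de,
    welch_t_test,
)


def _matrix(values, layer="mRNA", units="raw", samples=None, features=None):
    arr = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(arr, index=features, columns=samples), units=units, layer=layer
    )


def _design(stages=("6M", "18M"), reps=3):
    rows = [
        {"sample_id": f"{st}_r{r}", "stage": st, "replicate": r}
        for st in stages
        for r in range(1, reps + 1)
    ]
    return pd.DataFrame(rows)


class TestNormalization:
    def test_cpm_columns_sum_to_one_million(self, rng):
        m = _matrix(rng.integers(0, 1000, size=(50, 6)))
        cpm = normalize_cpm(m)
        assert np.allclose(cpm.data.sum(axis=0), 1e6, rtol=1e-9)
        assert cpm.units == "CPM"

    def test_cpm_scale_invariance(self, rng):
        vals = rng.integers(1, 500, size=(20, 3)).astype(float)
        doubled = vals.copy()
        doubled[:, 0] *= 2
        a = normalize_cpm(_matrix(vals)).data
        b = normalize_cpm(_matrix(doubled)).data
        assert np.allclose(a.iloc[:, 0], b.iloc[:, 0])

    def test_cpm_zero_total_sample_rejected(self):
        with pytest.raises(ValueError, match="s1"):
            normalize_cpm(_matrix([[1, 0], [2, 0]]))

    @pytest.mark.parametrize(
        "reads,total,expected", [(10, 2e9, 5.0), (0, 5e8, 0.0), (7, 7e7, 100.0)]
    )
    def test_srpbm_closed_form(self, reads, total, expected):
        m = _matrix([[reads]], layer="circRNA")
        totals = pd.Series([total], index=["s0"])
        assert compute_srpbm(m, totals).data.iloc[0, 0] == pytest.approx(expected)

    def test_srpbm_missing_total_rejected(self):
        m = _matrix([[1, 2]], layer="circRNA")
        with pytest.raises(ValueError, match="s1"):
            compute_srpbm(m, pd.Series([1e9], index=["s0"]))

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            _matrix([[1, -3]])


class TestLog2FoldChange:
    def test_small_pseudocount_limit(self):
        assert log2_fold_change(8, 2, 1e-9) == pytest.approx(2.0, abs=1e-6)

    def test_equal_means_give_zero(self):
        assert log2_fold_change(7.3, 7.3, 0.5) == 0.0

    def test_hand_evaluated_closed_form(self):
        assert log2_fold_change(8, 0, 0.5) == pytest.approx(np.log2(17.0))

    def test_antisymmetric(self, rng):
        for _ in range(50):
            a, b = rng.uniform(0, 100, 2)
            assert log2_fold_change(a, b) == pytest.approx(-log2_fold_change(b, a))


class TestWelch:
    def test_identical_groups_p_one(self):
        assert welch_t_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_against_t_distribution_oracle(self):
        # independent evaluation of the Welch statistic and t CDF
        b, a = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        vb, va = b.var(ddof=1) / 3, a.var(ddof=1) / 3
        t = (b.mean() - a.mean()) / np.sqrt(vb + va)
        df = (vb + va) ** 2 / (vb**2 / 2 + va**2 / 2)
        expected = 2 * stats.t.sf(abs(t), df)
        assert t == pytest.approx(-3.6742346, abs=1e-6)
        assert df == pytest.approx(4.0)
        assert expected == pytest.approx(0.0213, abs=2e-4)
        assert welch_t_test(b, a) == pytest.approx(expected, rel=1e-10)

    def test_label_exchange_symmetry(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=4)
        assert welch_t_test(a, b) == pytest.approx(welch_t_test(b, a))

    def test_zero_variance_conventions(self):
        assert welch_t_test([2, 2, 2], [2, 2, 2]) == 1.0
        assert welch_t_test([2, 2, 2], [3, 3, 3]) == 0.0

    def test_minimum_group_size(self):
        with pytest.raises(ValueError, match="at least 2"):
            welch_t_test([1.0], [1, 2, 3])


class TestCallDE:
    def _run(self, layer, thresholds=None, seed=5, n=60):
        rng = np.random.default_rng(seed)
        design = _design()
        vals = rng.lognormal(5, 1, size=(n, 6))
        m = _matrix(vals, layer=layer, units="CPM", samples=design["sample_id"].tolist())
        return m, design, call_de(m, design, ("18M", "6M"), thresholds)

    def test_mirna_rule_has_no_fold_change_gate(self):
        m, design, de = self._run("miRNA")
        expected = de["p_value"] < 0.05
        assert (de["significant"] == expected).all()

    def test_mrna_rule_requires_both_gates(self):
        m, design, de = self._run("mRNA")
        expected = (de["p_value"] < 0.05) & (de["log2fc"].abs() > 1)
        assert (de["significant"] == expected).all()

    def test_direction_follows_fold_change_sign(self):
        _m, _d, de = self._run("circRNA")
        up = de["log2fc"] > 0
        assert (de.loc[up, "direction"] == "up").all()
        assert (de.loc[~up & (de["log2fc"] < 0), "direction"] == "down").all()

    def test_reversing_comparison_flips_signs_not_pvalues(self):
        rng = np.random.default_rng(11)
        design = _design()
        m = _matrix(
            rng.lognormal(4, 1, size=(30, 6)), units="CPM",
            samples=design["sample_id"].tolist(),
        )
        fwd = call_de(m, design, ("18M", "6M"))
        rev = call_de(m, design, ("6M", "18M"))
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["p_value"], rev["p_value"])
        flipped = fwd["direction"].map({"up": "down", "down": "up", "none": "none"})
        assert (flipped == rev["direction"]).all()

    def test_raw_matrix_rejected(self):
        design = _design()
        m = _matrix(np.ones((3, 6)), samples=design["sample_id"].tolist())
        with pytest.raises(ValueError, match="normalized"):
            call_de(m, design, ("18M", "6M"))

    def test_too_few_replicates_rejected(self):
        design = _design(reps=1)
        m = _matrix(np.ones((3, 2)), units="CPM", samples=design["sample_id"].tolist())
        with pytest.raises(ValueError, match="replicates"):
            call_de(m, design, ("18M", "6M"))


class TestOverlap:
    def test_triple_intersection(self):
        regions = overlap_de({"A": {"a", "b", "c"}, "B": {"b", "c"}, "C": {"c"}})
        assert regions[("A", "B", "C")] == 1
        assert regions[("A",)] == 1
        assert regions[("A", "B")] == 1

    def test_disjoint_sets(self):
        regions = overlap_de({"A": {"a"}, "B": {"b"}})
        assert regions[("A", "B")] == 0

    def test_regions_sum_to_union_on_random_triples(self, rng):
        for _ in range(100):
            sets = {
                name: set(rng.integers(0, 30, size=rng.integers(0, 20)).tolist())
                for name in "ABC"
            }
            regions = overlap_de(sets)
            assert sum(regions.values()) == len(set().union(*sets.values()))


class TestHighExpressionFilter:
    def test_strictly_greater_than_threshold(self):
        m = _matrix([[1000, 1000], [1000.5, 1000.5], [0, 0]], units="CPM")
        assert filter_highly_expressed(m, 1000) == ["f1"]

    def test_raising_threshold_never_grows_set(self, rng):
        m = _matrix(rng.uniform(0, 3000, size=(50, 4)), units="CPM")
        prev = set(filter_highly_expressed(m, 100))
        for thr in (500, 1000, 2000):
            cur = set(filter_highly_expressed(m, thr))
            assert cur <= prev
            prev = cur
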