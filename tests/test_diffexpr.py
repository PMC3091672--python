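import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from supersage.diffexpr import (
    ROLES,
    classify_tags,
    concordance_correlation,
    fold_change,
    g_test,
    gene_level_expression,
    standard_designs,
    z_test,
)
from supersage.matrix import TagCountMatrix

counts_st = st.integers(min_value=0, max_value=500)


def _matrix(rows: dict[str, list[int]], base_rows: int = 0, rng=None) -> TagCountMatrix:
    """Matrix with the given tag rows plus filler rows to give realistic totals."""
    data = {t.ljust(22, "A"): c for t, c in rows.items()}
    rng = rng or np.random.default_rng(0)
    for k in range(base_rows):
        data[f"FILL{k:05d}".ljust(22, "C")] = list(rng.integers(1, 20, len(ROLES)))
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(ROLES))
    return TagCountMatrix(df)


class TestZTest:
    def test_equal_proportions_give_zero(self):
        r = z_test(5, 100, 5, 100)
        assert r.z == 0.0 and r.p == 1.0

    def test_double_zero_degenerate_rule(self):
        r = z_test(0, 100, 0, 100)
        assert r.z == 0.0 and r.p == 1.0

    def test_hand_evaluated_formula(self):
        # closed-form evaluation at SAGE library scale
        c1, n1, c2, n2 = 5, 65378, 50, 87388
        p0 = (c1 + c2) / (n1 + n2)
        import math
        from scipy.stats import norm
        z_exp = (c1 / n1 - c2 / n2) / math.sqrt(p0 * (1 - p0) * (1 / n1 + 1 / n2))
        r = z_test(c1, n1, c2, n2)
        assert r.z == pytest.approx(z_exp, rel=1e-12)
        assert r.p == pytest.approx(2 * norm.sf(abs(z_exp)), rel=1e-12)

    @settings(deadline=None)
    @given(c1=counts_st, c2=counts_st)
    def test_antisymmetry(self, c1, c2):
        a = z_test(c1, 60000, c2, 80000)
        b = z_test(c2, 80000, c1, 60000)
        assert a.z == pytest.approx(-b.z, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            z_test(0, 0, 1, 10)


class TestGTest:
    def test_null_table_not_significant(self):
        d = standard_designs()["G-Test1"]
        r = g_test({"C2h": 10, "C12h": 10, "LowCa2h": 10, "LowCa12h": 10},
                   dict.fromkeys(ROLES, 70000), d)
        assert r.G_total == pytest.approx(0.0, abs=1e-9)
        assert not r.pass_all_rules and not r.pass_intrinsic

    def test_between_group_signal_with_homogeneous_groups(self):
        d = standard_designs()["G-Test1"]
        r = g_test({"C2h": 10, "C12h": 10, "LowCa2h": 100, "LowCa12h": 100},
                   dict.fromkeys(ROLES, 70000), d)
        assert r.pass_all_rules
        assert r.G_pooled > 100
        assert r.G_heterogeneity == pytest.approx(0.0, abs=1e-9)

    def test_heterogeneous_groups_fail_homogeneity(self):
        d = standard_designs()["G-Test1"]
        r = g_test({"C2h": 5, "C12h": 200, "LowCa2h": 210, "LowCa12h": 2},
                   dict.fromkeys(ROLES, 70000), d)
        assert r.fail_homogeneity and not r.pass_all_rules

    def test_additivity_identity_random_tables(self, rng):
        d = standard_designs()["G-Test1"]
        totals = dict.fromkeys(ROLES, 50000)
        for _ in range(200):
            counts = dict(zip(ROLES, rng.integers(0, 300, len(ROLES))))
            r = g_test(counts, totals, d)
            assert r.G_total == pytest.approx(r.G_pooled + r.G_heterogeneity, abs=1e-9)
            assert r.G_total >= -1e-12 and r.G_heterogeneity >= -1e-12
            assert r.df_total == r.df_pooled + r.df_heterogeneity

    def test_missing_library_errors(self):
        d = standard_designs()["G-Test1"]
        with pytest.raises(KeyError):
            g_test({"C2h": 1}, {"C2h": 100}, d)


class TestFoldChange:
    @pytest.mark.parametrize(
        "control,treatment,fold,direction",
        [
            (0, 38, 110, "up"),
            (21, 0, 61, "down"),
            (3, 144, 48, "up"),
            (5, 5, 1, "up"),
            (1, 113, 113, "up"),
        ],
    )
    def test_reference_pairs(self, control, treatment, fold, direction):
        r = fold_change(control, treatment)
        assert r.fold == fold and r.direction == direction

    @settings(deadline=None, max_examples=300)
    @given(c=counts_st, t=counts_st)
    def test_against_independent_oracle(self, c, t):
        # independently coded rule: substitute, ratio of max to min, round half up
        import math
        a = c or 0.345
        b = t or 0.345
        expected = math.floor(max(a, b) / min(a, b) + 0.5)
        assert fold_change(c, t).fold == expected

    @settings(deadline=None)
    @given(c=counts_st, t=counts_st)
    def test_fold_at_least_one_and_direction(self, c, t):
        r = fold_change(c, t)
        assert r.fold >= 1
        assert (r.direction == "up") == (r.R >= 1)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            fold_change(-1, 3)


class TestClassifyTags:
    def test_flat_tag_gets_no_class(self):
        m = _matrix({"FLATTAG": [12, 12, 12, 12, 12]}, base_rows=300)
        rec = next(r for r in classify_tags(m) if r.tag.startswith("FLATTAG"))
        assert rec.de_class == set() and not rec.retained

    def test_single_library_singleton_not_retained(self):
        m = _matrix({"SINGLETON": [0, 1, 0, 0, 0]}, base_rows=300)
        rec = next(r for r in classify_tags(m) if r.tag.startswith("SINGLETON"))
        assert not rec.retained

    def test_lowca_global_effect_is_class1(self):
        # strong LowCa effect at both time points, HighCa untouched
        m = _matrix({"UPTAG": [5, 80, 5, 5, 80]}, base_rows=400)
        rec = next(r for r in classify_tags(m) if r.tag.startswith("UPTAG"))
        assert 1 in rec.de_class and rec.retained

    def test_highca_only_effect_is_class3_not_class1(self):
        m = _matrix({"HITAG": [8, 8, 8, 90, 8]}, base_rows=400)
        rec = next(r for r in classify_tags(m) if r.tag.startswith("HITAG"))
        assert 3 in rec.de_class
        assert 1 not in rec.de_class

    def test_column_order_invariance_given_role_map(self):
        rng = np.random.default_rng(5)
        m = _matrix({"UPTAG": [5, 80, 5, 5, 80]}, base_rows=200, rng=rng)
        shuffled = TagCountMatrix(m.counts[list(reversed(ROLES))])
        a = {r.tag: (sorted(r.de_class), r.retained) for r in classify_tags(m)}
        role_map = {r: r for r in ROLES}
        b = {r.tag: (sorted(r.de_class), r.retained) for r in classify_tags(shuffled, role_map)}
        assert a == b

    def test_missing_role_errors(self):
        df = pd.DataFrame({"A": [1]}, index=["T" * 22])
        with pytest.raises(KeyError):
            classify_tags(TagCountMatrix(df))


class TestGeneLevel:
    def test_sums_tags_of_same_gene(self):
        m = _matrix({"TAGA": [3, 0, 0, 0, 0], "TAGB": [4, 1, 0, 0, 0]})
        mapping = {t: "g1" for t in m.tags}
        out = gene_level_expression(m, mapping)
        assert out.loc["g1", "C2h"] == 7

    def test_unannotated_tags_skipped(self):
        m = _matrix({"TAGA": [3, 0, 0, 0, 0]})
        out = gene_level_expression(m, {})
        assert out.empty


class TestConcordance:
    def test_perfect_and_anticorrelation(self):
        x = [0.5, 1.0, 2.0, 3.0]
        r, _ = concordance_correlation(x, x)
        assert r == pytest.approx(1.0)
        r, _ = concordance_correlation(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_independent_noise_usually_insignificant(self, rng):
        x = rng.normal(size=16)
        y = rng.normal(size=16)
        r, p = concordance_correlation(x, y)
        assert abs(r) < 0.9

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            concordance_correlation([1, 1, 1], [1, 2, 3])
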