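import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lincforge.stats import anova_lsd, rel_expression, star_label, two_group_t
from oracles import pooled_t_p


def test_star_label_boundaries_strict():
    assert star_label(0.2) == "ns"
    assert star_label(0.05) == "ns"
    assert star_label(0.049999) == "*"
    assert star_label(0.01) == "*"
    assert star_label(0.009999) == "**"
    assert star_label(0.001) == "**"
    assert star_label(0.0005) == "***"
    assert star_label(0.0001) == "***"
    assert star_label(0.00009) == "****"
    assert star_label(0.0) == "****"
    assert star_label(1.0) == "ns"
    with pytest.raises(ValueError):
        star_label(1.5)


def test_rel_expression_dct_closed_form():
    out = rel_expression([("s1", 24.0, 20.0)], method="dct")
    assert out[0].rel_expression == pytest.approx(2.0 ** -4)
    zero = rel_expression([("s1", 20.0, 20.0)], method="dct")
    assert zero[0].rel_expression == 1.0


def test_rel_expression_ddct_calibrator_exactly_one():
    recs = [("cal", 22.0, 20.0), ("trt", 25.0, 20.5)]
    out = rel_expression(recs, method="ddct", calibrator="cal")
    by = {q.sample: q for q in out}
    assert by["cal"].rel_expression == 1.0
    assert by["trt"].rel_expression == pytest.approx(2.0 ** -(4.5 - 2.0))


def test_rel_expression_ddct_missing_calibrator_raises():
    with pytest.raises(ValueError):
        rel_expression([("s1", 24.0, 20.0)], method="ddct", calibrator="nope")
    with pytest.raises(ValueError):
        rel_expression([("s1", 24.0, 20.0)], method="bad")


def test_rel_expression_shift_invariance():
    a = rel_expression([("s1", 24.0, 20.0)], method="dct")[0].rel_expression
    b = rel_expression([("s1", 27.5, 23.5)], method="dct")[0].rel_expression
    assert a == pytest.approx(b)


def test_two_group_t_matches_textbook_oracle():
    x, y = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
    res = two_group_t(x, y)
    t_oracle, p_oracle = pooled_t_p(x, y)
    assert res.statistic == pytest.approx(t_oracle, abs=1e-12)
    assert res.p_value == pytest.approx(p_oracle, abs=1e-8)


def test_two_group_t_identical_groups():
    res = two_group_t([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
    assert (res.statistic, res.p_value, res.star) == (0.0, 1.0, "ns")


def test_two_group_t_translation_invariance():
    rng = np.random.default_rng(1)
    x, y = rng.normal(0, 1, 5), rng.normal(1, 1, 6)
    a = two_group_t(x, y)
    b = two_group_t(x + 7.0, y + 7.0)
    assert a.statistic == pytest.approx(b.statistic, abs=1e-10)


def test_two_group_t_welch_differs_under_unequal_variance():
    x = [1.0, 1.1, 0.9, 1.05, 0.95]
    y = [2.0, 6.0, -1.0, 4.5, 0.2]
    assert two_group_t(x, y).p_value != pytest.approx(
        two_group_t(x, y, welch=True).p_value, abs=1e-6
    )


def test_two_group_t_small_n_raises():
    with pytest.raises(ValueError):
        two_group_t([1.0], [1.0, 2.0])


def test_anova_lsd_two_groups_equals_pooled_t():
    rng = np.random.default_rng(2)
    for _ in range(10):
        x = list(rng.normal(10, 2, 4))
        y = list(rng.normal(12, 2, 5))
        res = anova_lsd({"a": x, "b": y}, protected=False)
        t_res = two_group_t(x, y)
        assert res.pairwise_lsd[("a", "b")] == pytest.approx(t_res.p_value, abs=1e-10)


def test_anova_lsd_three_group_f_matches_hand_computation():
    groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [6.0, 7.0, 8.0]}
    res = anova_lsd(groups)
    grand = np.mean([1, 2, 3, 2, 3, 4, 6, 7, 8])
    ssb = 3 * ((2 - grand) ** 2 + (3 - grand) ** 2 + (7 - grand) ** 2)
    ssw = 6.0  # each group contributes (1-0)^2+(0)^2+(1)^2 = 2
    f_hand = (ssb / 2) / (ssw / 6)
    assert res.statistic == pytest.approx(f_hand, abs=1e-12)
    assert res.p_value < 0.05
    # protected LSD ran; 'c' separated from 'a' and 'b'
    assert res.letters["c"] != res.letters["a"]
    assert res.letters["a"] == res.letters["b"]


def test_anova_lsd_identical_groups():
    res = anova_lsd({"a": [2.0, 2.0], "b": [2.0, 2.0], "c": [2.0, 2.0]})
    assert (res.statistic, res.p_value) == (0.0, 1.0)
    assert len(set(res.letters.values())) == 1


def test_anova_lsd_protected_skips_pairwise_when_omnibus_ns():
    rng = np.random.default_rng(3)
    groups = {g: list(rng.normal(5, 1, 4)) for g in "abc"}
    res = anova_lsd(groups, alpha=1e-9, protected=True)
    assert res.pairwise_lsd == {}


def test_anova_lsd_small_group_raises():
    with pytest.raises(ValueError):
        anova_lsd({"a": [1.0], "b": [1.0, 2.0]})


@given(st.floats(min_value=-50, max_value=50, allow_nan=False))
def test_anova_f_translation_invariant(shift):
    groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 9.0], "c": [2.0, 2.5, 3.5]}
    base = anova_lsd(groups).statistic
    shifted = anova_lsd({g: [v + shift for v in vs] for g, vs in groups.items()}).statistic
    assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)
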