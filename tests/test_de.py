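import numpy as np
import pandas as pd
import pytest

from lincforge.de import (
    ExpressionMatrix,
    call_de,
    counts_to_fpkm,
    de_results_frame,
    size_factors,
    summarize_del,
    timepoint_overlaps,
)


def _matrix(values, groups):
    cols = list(values.columns)
    design = pd.DataFrame({"group": groups}, index=cols)
    return ExpressionMatrix(values=values, design=design, kind="counts")


def test_expression_matrix_rejects_negative_and_fractional_counts():
    design = pd.DataFrame({"g": ["a"]}, index=["s1"])
    with pytest.raises(ValueError):
        ExpressionMatrix(pd.DataFrame({"s1": [-1]}, index=["f1"]), design)
    with pytest.raises(ValueError):
        ExpressionMatrix(pd.DataFrame({"s1": [1.5]}, index=["f1"]), design)


def test_counts_to_fpkm_closed_form():
    values = pd.DataFrame({"s1": [100, 50]}, index=["f1", "f2"])
    design = pd.DataFrame({"g": ["a"]}, index=["s1"])
    m = ExpressionMatrix(values, design, feature_lengths=pd.Series({"f1": 1000, "f2": 500}))
    fpkm = counts_to_fpkm(m, library_sizes=pd.Series({"s1": 1_000_000}))
    # FPKM = count * 1e9 / (length * library)
    assert fpkm.values.loc["f1", "s1"] == pytest.approx(100 * 1e9 / (1000 * 1e6))
    assert fpkm.values.loc["f2", "s1"] == pytest.approx(50 * 1e9 / (500 * 1e6))
    assert fpkm.kind == "fpkm"


def test_counts_to_fpkm_prefers_stored_library_sizes():
    values = pd.DataFrame({"s1": [10]}, index=["f1"])
    design = pd.DataFrame({"g": ["a"]}, index=["s1"])
    m = ExpressionMatrix(
        values, design,
        feature_lengths=pd.Series({"f1": 100}),
        library_sizes=pd.Series({"s1": 2e7}),
    )
    fpkm = counts_to_fpkm(m)
    assert fpkm.values.loc["f1", "s1"] == pytest.approx(10 * 1e9 / (100 * 2e7))


def test_counts_to_fpkm_missing_length_raises():
    values = pd.DataFrame({"s1": [10]}, index=["f1"])
    design = pd.DataFrame({"g": ["a"]}, index=["s1"])
    with pytest.raises(ValueError):
        counts_to_fpkm(ExpressionMatrix(values, design))


def test_size_factors_recover_scaled_libraries():
    rng = np.random.default_rng(0)
    base = rng.lognormal(5, 1, 300)
    values = pd.DataFrame(
        {
            "s1": np.round(base),
            "s2": np.round(2 * base),
            "s3": np.round(0.5 * base),
        },
        index=[f"f{i}" for i in range(300)],
    )
    sf = size_factors(values)
    ratios = sf / sf.iloc[0]
    assert ratios["s2"] == pytest.approx(2.0, rel=0.02)
    assert ratios["s3"] == pytest.approx(0.5, rel=0.02)


def test_call_de_recovers_planted_direction_and_magnitude():
    rng = np.random.default_rng(5)
    n = 400
    base = rng.lognormal(np.log(200), 0.3, n)
    up = np.zeros(n, dtype=bool)
    up[:40] = True
    mu_t = np.where(up, base * 8, base)
    counts = {}
    for i in range(3):
        counts[f"t{i}"] = rng.poisson(mu_t)
        counts[f"c{i}"] = rng.poisson(base)
    values = pd.DataFrame(counts, index=[f"f{i:03d}" for i in range(n)])
    m = _matrix(values, ["t", "c", "t", "c", "t", "c"])
    res = call_de(m, ["t0", "t1", "t2"], ["c0", "c1", "c2"])
    sig_up = {r.feature_id for r in res if r.significant and r.direction == "up"}
    assert sig_up == {f"f{i:03d}" for i in range(40)}
    mean_lfc = np.mean([r.log2_fold_change for r in res[:40]])
    assert mean_lfc == pytest.approx(3.0, abs=0.35)


def test_call_de_requires_counts_and_replicates():
    values = pd.DataFrame({"t0": [1], "c0": [1]}, index=["f1"])
    m = _matrix(values, ["t", "c"])
    with pytest.raises(ValueError):
        call_de(m, ["t0"], ["c0"])
    m.kind = "fpkm"
    with pytest.raises(ValueError):
        call_de(m, ["t0", "c0"], ["t0", "c0"])


def test_call_de_all_zero_feature_is_null():
    values = pd.DataFrame(
        {"t0": [0, 5], "t1": [0, 6], "c0": [0, 5], "c1": [0, 4]}, index=["zero", "flat"]
    )
    m = _matrix(values, ["t", "t", "c", "c"])
    res = {r.feature_id: r for r in call_de(m, ["t0", "t1"], ["c0", "c1"])}
    assert res["zero"].p_value == 1.0
    assert res["zero"].log2_fold_change == 0.0
    assert not res["zero"].significant


def test_call_de_fdr_is_no_less_conservative():
    m = _matrix(
        pd.DataFrame(
            np.random.default_rng(3).poisson(50, size=(200, 6)),
            index=[f"f{i}" for i in range(200)],
            columns=["t0", "t1", "t2", "c0", "c1", "c2"],
        ),
        ["t"] * 3 + ["c"] * 3,
    )
    raw = call_de(m, ["t0", "t1", "t2"], ["c0", "c1", "c2"], fdr=False)
    adj = call_de(m, ["t0", "t1", "t2"], ["c0", "c1", "c2"], fdr=True)
    for r, a in zip(raw, adj):
        assert a.p_value >= r.p_value - 1e-12


def test_de_results_frame_sorted_and_complete():
    values = pd.DataFrame(
        {"t0": [5, 9], "t1": [6, 8], "c0": [5, 9], "c1": [6, 9]}, index=["b", "a"]
    )
    m = _matrix(values, ["t", "t", "c", "c"])
    df = de_results_frame(call_de(m, ["t0", "t1"], ["c0", "c1"]))
    assert df.feature_id.tolist() == ["a", "b"]
    assert {"log2_fold_change", "p_value", "significant", "direction"} <= set(df.columns)


def test_summarize_del_ratios():
    from lincforge.de import DEResult

    mk = lambda fid, sig, lfc: DEResult(fid, "c", 1.0, lfc, 0.1, 0.01, sig, "up")
    df = summarize_del(
        {"lncRNA": [mk("l1", True, 2.5), mk("l2", False, 0.1)], "mRNA": [mk("m1", True, -3.0)]},
        {"lncRNA": 10, "mRNA": 20},
    )
    row = df.set_index("feature_class")
    assert row.loc["lncRNA", "ratio"] == pytest.approx(0.1)
    assert row.loc["mRNA", "n_down"] == 1


def test_timepoint_overlaps_counts():
    df = timepoint_overlaps({"a": {"x", "y"}, "b": {"y", "z"}, "c": set()})
    pair = df.set_index(["contrast_a", "contrast_b"])
    assert pair.loc[("a", "b"), "n_overlap"] == 1
    assert pair.loc[("a", "c"), "n_overlap"] == 0
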