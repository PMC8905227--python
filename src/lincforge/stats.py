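"""Small-sample phenotype/expression statistics: qRT-PCR relative
expression (2^-ΔCt and 2^-ΔΔCt), Student's t, one-way ANOVA with Fisher's
LSD pairwise comparisons, and significance-star labelling.
"""
from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .models import GroupComparison, QpcrRecord


def star_label(p: float) -> str:
    """Significance stars; strict inequalities, p >= 0.05 is 'ns'."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def rel_expression(
    records: list[tuple[str, float, float]],
    method: str = "dct",
    calibrator: str | None = None,
) -> list[QpcrRecord]:
    """Relative expression from Ct values.

    ``dct``: 2^(−ΔCt) with ΔCt = target − reference.
    ``ddct``: 2^(−(ΔCt − ΔCt_calibrator)); the calibrator sample is exactly 1.
    """
    if method not in ("dct", "ddct"):
        raise ValueError("method must be 'dct' or 'ddct'")
    out = [QpcrRecord(sample=s, target_ct=t, reference_ct=r, method=method) for s, t, r in records]
    if method == "dct":
        for q in out:
            q.rel_expression = 2.0 ** (-q.delta_ct)
        return out
    cal = [q for q in out if q.sample == calibrator]
    if calibrator is None or not cal:
        raise ValueError("ddct mode requires a calibrator present in the records")
    cal_dct = cal[0].delta_ct
    for q in out:
        q.rel_expression = 2.0 ** (-(q.delta_ct - cal_dct))
    return out


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    nx, ny = len(x), len(y)
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0, df  # degenerate: no variance, no difference
        return math.inf, 0.0, df
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p), df


def two_group_t(x, y, welch: bool = False) -> GroupComparison:
    """Two-sided two-sample t test (pooled Student by default)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if welch:
        res = sps.ttest_ind(x, y, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        if math.isnan(t):
            t, p = 0.0, 1.0
    else:
        t, p, _ = _pooled_t(x, y)
    return GroupComparison(
        group_labels=["x", "y"],
        means=[float(x.mean()), float(y.mean())],
        sds=[float(x.std(ddof=1)), float(y.std(ddof=1))],
        ns=[len(x), len(y)],
        statistic=t,
        p_value=p,
        test="t",
        star=star_label(p),
    )


def _letters(groups: list[str], means: dict[str, float], distinct: set[tuple[str, str]]) -> dict:
    """Compact letter display: groups not significantly different share a letter."""
    order = sorted(groups, key=lambda g: (-means[g], g))
    letter_sets: list[set[str]] = []
    for g in order:
        placed = False
        for s in letter_sets:
            if all((min(g, h), max(g, h)) not in distinct for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in groups}
    for i, s in enumerate(letter_sets):
        for g in s:
            out[g] += alphabet[i]
    return {g: "".join(sorted(v)) for g, v in out.items()}


def anova_lsd(
    groups: dict[str, list[float]], alpha: float = 0.05, protected: bool = True
) -> GroupComparison:
    """One-way ANOVA with Fisher's LSD pairwise comparisons.

    LSD pairwise t uses the pooled MSE and residual df:
    t_ij = (m_i − m_j) / sqrt(MSE · (1/n_i + 1/n_j)).  When ``protected``
    (default), pairwise tests run only if the omnibus p < alpha.  With two
    groups the LSD p equals the pooled two-sample t-test p.
    """
    labels = sorted(groups)
    arrays = {g: np.asarray(groups[g], dtype=float) for g in labels}
    for g, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {g} has n < 2")
    N = sum(len(a) for a in arrays.values())
    k = len(labels)
    grand = np.concatenate(list(arrays.values())).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b, df_w = k - 1, N - k
    if ss_within == 0 and ss_between == 0:
        f, p = 0.0, 1.0
        mse = 0.0
    elif ss_within == 0:
        f, p, mse = math.inf, 0.0, 0.0
    else:
        mse = ss_within / df_w
        f = (ss_between / df_b) / mse
        p = float(sps.f.sf(f, df_b, df_w))
    means = {g: float(a.mean()) for g, a in arrays.items()}
    pairwise: dict[tuple[str, str], float] = {}
    if (not protected) or p < alpha:
        for g, h in combinations(labels, 2):
            a, b = arrays[g], arrays[h]
            if mse == 0:
                pp = 1.0 if a.mean() == b.mean() else 0.0
            else:
                t = (a.mean() - b.mean()) / math.sqrt(mse * (1 / len(a) + 1 / len(b)))
                pp = 2.0 * float(sps.t.sf(abs(t), df_w))
            pairwise[(g, h)] = pp
    distinct = {pair for pair, pp in pairwise.items() if pp < alpha}
    return GroupComparison(
        group_labels=labels,
        means=[means[g] for g in labels],
        sds=[float(arrays[g].std(ddof=1)) for g in labels],
        ns=[len(arrays[g]) for g in labels],
        statistic=float(f),
        p_value=float(p),
        test="anova",
        star=star_label(min(max(p, 0.0), 1.0)),
        pairwise_lsd=pairwise,
        letters=_letters(labels, means, distinct),
    )
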