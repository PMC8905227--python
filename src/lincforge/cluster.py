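"""Expression-profile clustering and term-enrichment machinery.

Profiles are z-scored per feature and clustered with k-means (k = 10 by
default, mirroring the time-course analysis this package reproduces).
Enrichment is a one-sided Fisher exact test (hypergeometric upper tail) per
term with Benjamini–Hochberg FDR.  lncRNA function is transferred by
guilt-by-association: a lncRNA inherits the significant terms of the
cluster it shares with protein-coding genes, always labelled "associated".

Three significance presets mirror the thresholds used downstream:
``cluster`` (P < 0.01 on profile clusters), ``network`` (P < 0.05) and
``ko`` (FDR < 1e-4 for knock-out-line enrichment).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

PRESETS = {
    "cluster": {"alpha": 0.01, "use_fdr": False},
    "network": {"alpha": 0.05, "use_fdr": False},
    "ko": {"alpha": 1e-4, "use_fdr": True},
}


def zscore_rows(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-score; constant rows are excluded with a notice."""
    sd = expr.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"excluded {int(constant.sum())} constant rows from clustering")
    kept = expr.loc[~constant]
    return kept.sub(kept.mean(axis=1), axis=0).div(sd[~constant], axis=0)


def kmeans_profiles(
    expr: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> tuple[pd.Series, float]:
    """K-means (k-means++ init, best of n_init restarts) on z-scored rows.

    Returns (assignments as a Series of 1-based cluster labels, inertia).
    """
    z = zscore_rows(expr)
    if k > len(z):
        raise ValueError(f"k={k} exceeds number of clusterable features ({len(z)})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, max_iter=max_iter, random_state=seed)
    labels = km.fit_predict(z.to_numpy())
    return pd.Series(labels + 1, index=z.index, name="cluster"), float(km.inertia_)


def fisher_enrichment(
    feature_set: set[str],
    universe: set[str],
    annotation: pd.DataFrame,
    alpha: float = 0.05,
    min_term_size: int = 2,
    use_fdr: bool = False,
    preset: str | None = None,
) -> pd.DataFrame:
    """One-sided (enrichment) Fisher exact test per term.

    ``annotation`` is a flat two-column table (feature_id, term).  The 2×2
    table per term is (a = in-set annotated, b = in-set not, c = out-set
    annotated, d = out-set not); p = P(X >= a) with X hypergeometric.
    """
    if preset is not None:
        cfg = PRESETS[preset]
        alpha, use_fdr = cfg["alpha"], cfg["use_fdr"]
    if not universe:
        raise ValueError("empty universe")
    if not feature_set <= universe:
        raise ValueError("feature_set must be a subset of the universe")
    ann = annotation[annotation.iloc[:, 0].isin(universe)]
    by_term = ann.groupby(ann.columns[1])[ann.columns[0]].apply(set)
    N, n = len(universe), len(feature_set)
    rows = []
    for term, members in sorted(by_term.items()):
        K = len(members)
        if K < min_term_size:
            continue
        a = len(feature_set & members)
        b = n - a
        c = K - a
        d = N - n - c
        p = float(stats.hypergeom.sf(a - 1, N, K, n))
        odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
        rows.append(
            {"term": term, "a": a, "b": b, "c": c, "d": d, "odds_ratio": odds, "p_value": min(p, 1.0)}
        )
    res = pd.DataFrame(rows, columns=["term", "a", "b", "c", "d", "odds_ratio", "p_value"])
    if len(res):
        res["fdr"] = multipletests(res.p_value.to_numpy(), method="fdr_bh")[1]
        res["significant"] = (res.fdr if use_fdr else res.p_value) < alpha
    else:
        res["fdr"] = []
        res["significant"] = []
    return res.sort_values(["p_value", "term"]).reset_index(drop=True)


def cluster_enrichments(
    clusters: pd.Series,
    annotation: pd.DataFrame,
    universe: set[str] | None = None,
    preset: str = "cluster",
    min_term_size: int = 2,
) -> dict[int, pd.DataFrame]:
    """Per-cluster enrichment over the clustered universe (default)."""
    universe = universe or set(clusters.index)
    out = {}
    for c in sorted(clusters.unique()):
        members = set(clusters.index[clusters == c]) & universe
        out[int(c)] = fisher_enrichment(
            members, universe, annotation, preset=preset, min_term_size=min_term_size
        )
    return out


def transfer_function(
    lnc_ids: set[str],
    clusters: pd.Series,
    enrichments: dict[int, pd.DataFrame],
) -> pd.DataFrame:
    """Guilt-by-association: lncRNAs inherit their cluster's significant terms.

    The evidence label is always "associated" — co-clustering suggests, never
    demonstrates, function.
    """
    rows = []
    for lnc in sorted(lnc_ids & set(clusters.index)):
        c = int(clusters[lnc])
        enr = enrichments.get(c)
        if enr is None or enr.empty:
            continue
        for _, r in enr[enr.significant].iterrows():
            rows.append(
                {
                    "lncrna_id": lnc,
                    "cluster": c,
                    "term": r.term,
                    "term_p_value": r.p_value,
                    "term_fdr": r.fdr,
                    "evidence": "associated",
                }
            )
    return pd.DataFrame(
        rows, columns=["lncrna_id", "cluster", "term", "term_p_value", "term_fdr", "evidence"]
    )
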