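"""Transcript classification against a reference annotation and the
candidate-lncRNA filter cascade.

Class codes follow the cuffcompare vocabulary restricted to what the
analysis needs: ``u`` (intergenic — no exonic overlap with any reference
gene span), ``i`` (entirely within an intron), ``x`` (exonic overlap with a
reference exon on the opposite strand) and ``overlapping_other`` for any
same- or unknown-strand exonic overlap, which disqualifies a transcript from
lncRNA candidacy.

The cascade then keeps a transcript iff, in order: its class code is
allowed; spliced length >= 200 nt; FPKM > 0.5 in at least one sample;
distance to the nearest annotated gene span > 500 bp; and (optionally) at
least one exon has EST/long-read support.  The first failed rule is recorded
per rejected transcript.
"""
from __future__ import annotations

import pandas as pd
from scipy import stats

from .de import ExpressionMatrix
from .models import ClassCodeAssignment, FilterParams, GeneModel, TranscriptModel

CASCADE_ORDER = ("code", "length", "fpkm", "distance", "est")


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap between closest interval ends; 0 when overlapping or touching."""
    if _overlap(a, b):
        return 0
    return max(a[0] - b[1], b[0] - a[1], 0)


def _introns(gene: GeneModel) -> list[tuple[int, int]]:
    return [
        (e1, s2) for (_, e1), (s2, _) in zip(gene.exons, gene.exons[1:]) if s2 > e1
    ]


def assign_class_codes(
    assembled: list[TranscriptModel], reference: list[GeneModel]
) -> tuple[list[ClassCodeAssignment], list[str]]:
    """Assign one class code per transcript; returns (assignments, errors).

    Transcripts on chromosomes absent from the reference are reported in the
    error list and excluded from the assignments (processing continues).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in reference:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: (g.start, g.id))

    assignments, errors = [], []
    for t in assembled:
        genes = by_chrom.get(t.chromosome)
        if genes is None:
            errors.append(f"{t.id}: unknown chromosome {t.chromosome}")
            continue
        span = (t.start, t.end)
        # nearest gene by span gap; ties broken by lowest gene id
        nearest_gene, nearest_dist = None, None
        for g in genes:
            d = _gap(span, (g.start, g.end))
            if nearest_dist is None or d < nearest_dist or (
                d == nearest_dist and g.id < nearest_gene
            ):
                nearest_gene, nearest_dist = g.id, d
        overlapping = [g for g in genes if _overlap(span, (g.start, g.end))]
        span_hit = [
            g for g in overlapping if any(_overlap(te, (g.start, g.end)) for te in t.exons)
        ]
        if not span_hit:
            code = "u"
        else:
            exon_hits = [
                g
                for g in span_hit
                if any(_overlap(te, ge) for te in t.exons for ge in g.exons)
            ]
            if exon_hits:
                opposite = all(
                    t.strand in "+-" and g.strand in "+-" and t.strand != g.strand
                    for g in exon_hits
                )
                code = "x" if opposite else "overlapping_other"
            else:
                intronic = any(
                    any(
                        all(i[0] <= te[0] and te[1] <= i[1] for te in t.exons)
                        for i in _introns(g)
                    )
                    for g in span_hit
                )
                code = "i" if intronic else "overlapping_other"
        assignments.append(
            ClassCodeAssignment(
                transcript_id=t.id,
                class_code=code,
                nearest_gene_id=nearest_gene,
                distance_to_nearest_gene=nearest_dist if nearest_dist is not None else -1,
            )
        )
    return assignments, errors


def filter_candidates(
    assigned: list[ClassCodeAssignment],
    transcripts: list[TranscriptModel],
    expression: ExpressionMatrix,
    params: FilterParams,
    est_support: dict[str, list[tuple[int, int]]] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Run the cascade; returns (survivor ids, rejection ledger).

    The ledger has one row per rejected transcript with the FIRST failed rule
    in cascade order (code -> length -> fpkm -> distance -> est).
    """
    if expression.kind != "fpkm":
        raise ValueError("filter expects FPKM expression")
    tmap = {t.id: t for t in transcripts}
    survivors, rejected = [], []
    for a in assigned:
        t = tmap[a.transcript_id]
        if a.transcript_id not in expression.values.index:
            raise KeyError(f"no expression row for transcript {a.transcript_id}")
        rule = None
        if a.class_code not in params.allowed_codes:
            rule = "code"
        elif t.spliced_length < params.min_length:
            rule = "length"
        elif not (expression.values.loc[a.transcript_id].max() > params.min_fpkm):
            rule = "fpkm"
        elif a.distance_to_nearest_gene <= params.min_gene_distance:
            rule = "distance"
        elif params.require_est_support:
            ivs = (est_support or {}).get(t.chromosome, [])
            if not any(_overlap(te, iv) for te in t.exons for iv in ivs):
                rule = "est"
        if rule is None:
            survivors.append(a.transcript_id)
        else:
            rejected.append({"transcript_id": a.transcript_id, "rule_failed": rule})
    ledger = pd.DataFrame(rejected, columns=["transcript_id", "rule_failed"]).sort_values(
        "transcript_id"
    ).reset_index(drop=True)
    return sorted(survivors), ledger


def gc_content(sequence: str) -> float:
    seq = sequence.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def feature_summary(
    transcripts: list[TranscriptModel], expression: ExpressionMatrix, kind: str
) -> pd.DataFrame:
    """Per-transcript GC, length, exon count, median FPKM and subgenome."""
    rows = []
    for t in transcripts:
        med = (
            float(expression.values.loc[t.id].median())
            if t.id in expression.values.index
            else float("nan")
        )
        rows.append(
            {
                "transcript_id": t.id,
                "kind": kind,
                "gc_content": gc_content(t.sequence),
                "length": t.spliced_length,
                "exon_count": t.exon_count,
                "median_fpkm": med,
                "subgenome": t.subgenome,
            }
        )
    return pd.DataFrame(rows)


def _wilcoxon_row(feature: str, comparison: str, x, y) -> dict:
    if len(x) < 2 or len(y) < 2:
        return {
            "feature": feature,
            "comparison": comparison,
            "median_a": float(pd.Series(x).median()) if len(x) else float("nan"),
            "median_b": float(pd.Series(y).median()) if len(y) else float("nan"),
            "p_value": float("nan"),
            "note": "skipped: group too small",
        }
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return {
        "feature": feature,
        "comparison": comparison,
        "median_a": float(pd.Series(x).median()),
        "median_b": float(pd.Series(y).median()),
        "p_value": float(res.pvalue),
        "note": "",
    }


def summarize_features(
    candidates: list[TranscriptModel],
    mrnas: list[TranscriptModel],
    expression: ExpressionMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature tables plus Wilcoxon rank-sum comparisons.

    Compares GC, length, exon count and median FPKM between lncRNA
    candidates and mRNAs, and GC between At and Dt candidates.
    """
    lnc = feature_summary(candidates, expression, "lncRNA")
    mrna = feature_summary(mrnas, expression, "mRNA")
    summary = pd.concat([lnc, mrna], ignore_index=True)
    comps = []
    for feat in ("gc_content", "length", "exon_count", "median_fpkm"):
        comps.append(
            _wilcoxon_row(
                feat, "lncRNA_vs_mRNA", lnc[feat].dropna().to_numpy(), mrna[feat].dropna().to_numpy()
            )
        )
    at = lnc.loc[lnc.subgenome == "At", "gc_content"].dropna().to_numpy()
    dt = lnc.loc[lnc.subgenome == "Dt", "gc_content"].dropna().to_numpy()
    comps.append(_wilcoxon_row("gc_content", "At_vs_Dt_lncRNA", at, dt))
    return summary, pd.DataFrame(comps)
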