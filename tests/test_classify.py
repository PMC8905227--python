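import pandas as pd
import pytest

from lincforge.classify import (
    CASCADE_ORDER,
    assign_class_codes,
    filter_candidates,
    gc_content,
    summarize_features,
)
from lincforge.de import ExpressionMatrix, counts_to_fpkm
from lincforge.models import FilterParams, GeneModel, TranscriptModel


def _gene(gid, chrom, exons, strand="+"):
    return GeneModel(id=gid, chromosome=chrom, strand=strand, exons=exons)


def _tx(tid, chrom, exons, strand="+", seq=""):
    return TranscriptModel(id=tid, chromosome=chrom, strand=strand, exons=exons, sequence=seq)


REF = [
    _gene("g1", "A01", [(1000, 1400), (2000, 2400)]),
    _gene("g2", "A01", [(8000, 8500)]),
]


def test_class_code_u_when_no_span_overlap():
    asg, errs = assign_class_codes([_tx("t1", "A01", [(4000, 4300)])], REF)
    assert not errs
    assert asg[0].class_code == "u"
    assert asg[0].nearest_gene_id == "g1"
    assert asg[0].distance_to_nearest_gene == 4000 - 2400


def test_class_code_i_contained_in_intron():
    asg, _ = assign_class_codes([_tx("t1", "A01", [(1500, 1900)])], REF)
    assert asg[0].class_code == "i"
    assert asg[0].distance_to_nearest_gene == 0


def test_class_code_x_requires_opposite_strand_exon_overlap():
    same, _ = assign_class_codes([_tx("t1", "A01", [(1200, 1500)], strand="+")], REF)
    anti, _ = assign_class_codes([_tx("t2", "A01", [(1200, 1500)], strand="-")], REF)
    assert same[0].class_code == "overlapping_other"
    assert anti[0].class_code == "x"


def test_span_overlap_without_exon_or_intron_containment_is_overlapping_other():
    # straddles the intron boundary but touches no reference exon
    asg, _ = assign_class_codes([_tx("t1", "A01", [(1450, 1480), (2500, 2600)])], REF)
    assert asg[0].class_code == "overlapping_other"


def test_unknown_chromosome_collects_error_and_continues():
    asg, errs = assign_class_codes(
        [_tx("bad", "Z99", [(0, 100)]), _tx("ok", "A01", [(4000, 4200)])], REF
    )
    assert len(errs) == 1 and "Z99" in errs[0]
    assert [a.transcript_id for a in asg] == ["ok"]


def test_nearest_gene_tie_breaks_to_lowest_id():
    ref = [_gene("gb", "A01", [(0, 100)]), _gene("ga", "A01", [(400, 500)])]
    asg, _ = assign_class_codes([_tx("t1", "A01", [(200, 300)])], ref)
    assert asg[0].distance_to_nearest_gene == 100
    assert asg[0].nearest_gene_id == "ga"


def _fpkm_for(tids, value=10.0):
    values = pd.DataFrame({"s1": [value] * len(tids), "s2": [value] * len(tids)}, index=tids)
    design = pd.DataFrame({"genotype": ["HR", "HR"]}, index=["s1", "s2"])
    return ExpressionMatrix(values=values, design=design, kind="fpkm")


def test_filter_first_failed_rule_in_cascade_order():
    # fails length AND distance; ledger must report length (earlier in cascade)
    t = _tx("t1", "A01", [(2500, 2650)])
    asg, _ = assign_class_codes([t], REF)
    surv, ledger = filter_candidates(asg, [t], _fpkm_for(["t1"]), FilterParams())
    assert surv == []
    assert ledger.rule_failed.tolist() == ["length"]
    assert list(CASCADE_ORDER) == ["code", "length", "fpkm", "distance", "est"]


def test_filter_fpkm_rule_is_strict_and_uses_max_sample():
    t = _tx("t1", "A01", [(4000, 4300)])
    asg, _ = assign_class_codes([t], REF)
    at_threshold = _fpkm_for(["t1"], value=0.5)
    _, ledger = filter_candidates(asg, [t], at_threshold, FilterParams())
    assert ledger.rule_failed.tolist() == ["fpkm"]  # 0.5 is NOT > 0.5
    one_high = _fpkm_for(["t1"], value=0.5)
    one_high.values.loc["t1", "s2"] = 0.6
    surv, _ = filter_candidates(asg, [t], one_high, FilterParams())
    assert surv == ["t1"]


def test_filter_distance_rule_boundary():
    # exactly 500 bp away fails (> 500 required); 501 passes
    t_at = _tx("t1", "A01", [(2900, 3200)])
    t_past = _tx("t2", "A01", [(2901, 3201)])
    asg, _ = assign_class_codes([t_at, t_past], REF)
    surv, ledger = filter_candidates(
        asg, [t_at, t_past], _fpkm_for(["t1", "t2"]), FilterParams()
    )
    assert surv == ["t2"]
    assert ledger.rule_failed.tolist() == ["distance"]


def test_filter_est_rule_requires_exon_overlap():
    t = _tx("t1", "A01", [(4000, 4300)])
    asg, _ = assign_class_codes([t], REF)
    params = FilterParams(require_est_support=True)
    surv, ledger = filter_candidates(
        asg, [t], _fpkm_for(["t1"]), params, est_support={"A01": [(5000, 5100)]}
    )
    assert ledger.rule_failed.tolist() == ["est"]
    surv, _ = filter_candidates(
        asg, [t], _fpkm_for(["t1"]), params, est_support={"A01": [(4290, 4310)]}
    )
    assert surv == ["t1"]


def test_filter_relaxing_a_threshold_is_monotone():
    t = _tx("t1", "A01", [(2901, 3151)])  # length 250, distance 501
    asg, _ = assign_class_codes([t], REF)
    expr = _fpkm_for(["t1"], value=1.0)
    strict, _ = filter_candidates(asg, [t], expr, FilterParams(min_length=300))
    relaxed, _ = filter_candidates(asg, [t], expr, FilterParams(min_length=200))
    assert set(strict) <= set(relaxed)


def test_filter_missing_expression_row_raises():
    t = _tx("t1", "A01", [(4000, 4300)])
    asg, _ = assign_class_codes([t], REF)
    with pytest.raises(KeyError):
        filter_candidates(asg, [t], _fpkm_for(["other"]), FilterParams())


def test_gc_content_ignores_n():
    assert gc_content("GGCC") == 1.0
    assert gc_content("ATGCN") == pytest.approx(0.5)


def test_summarize_features_reports_wilcoxon_rows(genome, counts):
    from lincforge.de import counts_to_fpkm

    fpkm = counts_to_fpkm(counts)
    lnc = [t for t in genome.assembled if not t.id.endswith(".t1")][:20]
    mrna = [t for t in genome.assembled if t.id.endswith(".t1")][:20]
    summary, comps = summarize_features(lnc, mrna, fpkm)
    assert set(summary.kind) == {"lncRNA", "mRNA"}
    assert set(comps.comparison) == {"lncRNA_vs_mRNA", "At_vs_Dt_lncRNA"}
    assert ((comps.p_value.dropna() >= 0) & (comps.p_value.dropna() <= 1)).all()
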