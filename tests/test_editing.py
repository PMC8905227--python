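import numpy as np
import pytest

from lincforge.editing import (
    EDITED_OUTCOMES,
    calls_frame,
    classify_read,
    detect_dropout,
    locate_guide,
    summarize_editing,
)
from lincforge.models import EditCall
from lincforge.synthetic import generate_amplicons, make_amplicon


def _amplicon():
    return make_amplicon(seed=21)


def test_locate_guide_plus_strand_cut_three_bp_from_pam():
    ref, guide = _amplicon()
    site = locate_guide(ref, guide)
    assert site.strand == "+"
    assert ref[site.pam_start + 1 : site.pam_start + 3] == "GG"
    assert site.cut_pos == site.pam_start - 3


def test_locate_guide_minus_strand():
    from Bio.Seq import Seq

    ref, guide = _amplicon()
    rc_ref = str(Seq(ref).reverse_complement())
    site = locate_guide(rc_ref, guide)
    assert site.strand == "-"
    # cut position mirrors the plus-strand cut through the reverse complement
    plus = locate_guide(ref, guide)
    assert site.cut_pos == len(ref) - plus.cut_pos


def test_locate_guide_rejects_bad_guides_and_multisite():
    ref, guide = _amplicon()
    with pytest.raises(ValueError):
        locate_guide(ref, "ACGT")
    with pytest.raises(ValueError, match="0 site"):
        locate_guide("A" * 100, guide)
    with pytest.raises(ValueError, match="2 site"):
        double = ref + ref
        locate_guide(double, guide)


def test_classify_read_planted_outcomes_exact():
    ref, guide = _amplicon()
    site = locate_guide(ref, guide)
    cut = site.cut_pos
    wt = ref
    deletion = ref[: cut - 2] + ref[cut + 3 :]  # 5 bp deletion over the cut
    insertion = ref[:cut] + "ACGTA" + ref[cut:]
    sub = list(ref)
    sub[cut - 1] = {"A": "C", "C": "G", "G": "T", "T": "A"}[sub[cut - 1]]
    sub[cut] = {"A": "C", "C": "G", "G": "T", "T": "A"}[sub[cut]]
    substitution = "".join(sub)
    assert classify_read(wt, ref, site).outcome == "WT"
    d = classify_read(deletion, ref, site)
    assert (d.outcome, d.length) == ("deletion", 5)
    i = classify_read(insertion, ref, site)
    assert (i.outcome, i.length) == ("insertion", 5)
    s = classify_read(substitution, ref, site)
    assert (s.outcome, s.length) == ("substitution", 2)


def test_classify_read_single_sub_below_min_count_is_wt():
    ref, guide = _amplicon()
    site = locate_guide(ref, guide)
    one = list(ref)
    one[site.cut_pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[one[site.cut_pos]]
    assert classify_read("".join(one), ref, site, min_sub_count=2).outcome == "WT"
    assert classify_read("".join(one), ref, site, min_sub_count=1).outcome == "substitution"


def test_classify_read_events_outside_window_are_wt():
    ref, guide = _amplicon()
    site = locate_guide(ref, guide)
    far = 20 if site.cut_pos > 40 else len(ref) - 30
    distal = ref[: far - 2] + ref[far + 3 :]
    call = classify_read(distal, ref, site, window_bp=10)
    assert call.outcome == "WT"


def test_classify_read_garbage_is_unaligned():
    ref, guide = _amplicon()
    site = locate_guide(ref, guide)
    rng = np.random.default_rng(0)
    garbage = "".join(np.array(list("ACGT"))[rng.integers(0, 4, len(ref))])
    assert classify_read(garbage, ref, site).outcome == "unaligned"


def test_generate_amplicons_exact_mix_and_recovery():
    ref, guide = _amplicon()
    site = locate_guide(ref, guide)
    mix = [("WT", 0, 0.5), ("deletion", 7, 0.2), ("insertion", 2, 0.2), ("substitution", 3, 0.1)]
    reads, truth = generate_amplicons(ref, guide, mix, n_reads=100, seed=5)
    assert len(reads) == 100
    assert truth.true_outcome.value_counts().to_dict() == {
        "WT": 50, "deletion": 20, "insertion": 20, "substitution": 10
    }
    calls = {rid: classify_read(seq, ref, site) for rid, seq in reads}
    for _, row in truth.iterrows():
        assert calls[row.read_id].outcome == row.true_outcome


def test_summarize_editing_efficiency_formula():
    calls = (
        [EditCall(f"w{i}", "WT") for i in range(6)]
        + [EditCall(f"d{i}", "deletion", length=4) for i in range(3)]
        + [EditCall("u0", "unaligned")]
    )
    s = summarize_editing(calls, min_reads=5)
    assert s["n_aligned"] == 9 and s["n_unaligned"] == 1
    assert s["efficiency_pct"] == pytest.approx(100 * 3 / 9)
    assert s["deletion_length_hist"] == {4: 3}
    assert not s["low_coverage"]
    assert set(EDITED_OUTCOMES) == {"deletion", "insertion", "substitution", "mixed"}


def test_summarize_editing_low_coverage_flag_and_empty_error():
    s = summarize_editing([EditCall("a", "WT")], min_reads=50)
    assert s["low_coverage"]
    with pytest.raises(ValueError):
        summarize_editing([EditCall("a", "unaligned")])


def test_calls_frame_one_based_positions():
    ref, guide = _amplicon()
    site = locate_guide(ref, guide)
    deletion = ref[: site.cut_pos - 2] + ref[site.cut_pos + 3 :]
    df = calls_frame([classify_read(deletion, ref, site, read_id="r1")])
    assert df.iloc[0].read_id == "r1"
    assert df.iloc[0].outcome == "deletion"


def test_detect_dropout_spanning_deletion():
    ref, guide = _amplicon()
    site = locate_guide(ref, guide)
    other = site.__class__(site.guide_seq, site.pam, "+", site.pam_start + 40, site.cut_pos + 40)
    spanning = ref[: site.cut_pos - 5] + ref[other.cut_pos + 5 :]
    assert detect_dropout(spanning, ref, site, other)
    assert not detect_dropout(ref, ref, site, other)
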