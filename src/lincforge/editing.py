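"""On-target CRISPR editing-outcome analysis on amplicon reads.

The SpCas9 cut site is the blunt cut 3 bp 5' of the NGG PAM (between guide
bases 17 and 18).  Reads are aligned to the amplicon reference globally with
free end gaps (match 2, mismatch −2, gap of length k costs 6 + (k−1)·1) and
classified by the events falling inside a window around the predicted cut:
WT, deletion, insertion, substitution (>= min_sub_count mismatches, no gap),
mixed (gap plus qualifying substitutions, or several gap runs), or unaligned.
Reported positions in tables are 1-based for human reading; internal
coordinates stay 0-based.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .models import EditCall, GuideSite


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def locate_guide(amplicon_ref: str, guide_seq: str) -> GuideSite:
    """Locate the unique guide+NGG protospacer on either strand.

    Zero or multiple sites raise, listing the positions found.
    """
    guide = guide_seq.upper()
    ref = amplicon_ref.upper()
    if len(guide) != 20 or set(guide) - set("ACGT"):
        raise ValueError("guide must be 20 nt over ACGT")
    sites = []
    # plus strand: guide then NGG
    for i in range(len(ref) - 22):
        if ref[i : i + 20] == guide and ref[i + 21 : i + 23] == "GG":
            pam_start = i + 20
            sites.append(GuideSite(guide, ref[pam_start : pam_start + 3], "+", pam_start, pam_start - 3))
    # minus strand: forward sequence reads CCN + revcomp(guide)
    rc = _revcomp(guide)
    for p in range(len(ref) - 22):
        if ref[p : p + 2] == "CC" and ref[p + 3 : p + 23] == rc:
            # PAM occupies forward p..p+3; cut 3 nt into the protospacer
            sites.append(GuideSite(guide, _revcomp(ref[p : p + 3]), "-", p, p + 6))
    if len(sites) != 1:
        positions = [s.pam_start for s in sites]
        raise ValueError(
            f"guide must match exactly once; found {len(sites)} site(s) at PAM positions {positions}"
        )
    return sites[0]


def make_read_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -6.0
    aligner.extend_gap_score = -1.0
    # free end gaps on both sequences (partial reads / long deletions)
    aligner.open_left_insertion_score = 0.0
    aligner.extend_left_insertion_score = 0.0
    aligner.open_right_insertion_score = 0.0
    aligner.extend_right_insertion_score = 0.0
    aligner.open_left_deletion_score = 0.0
    aligner.extend_left_deletion_score = 0.0
    aligner.open_right_deletion_score = 0.0
    aligner.extend_right_deletion_score = 0.0
    return aligner


@dataclass
class _Event:
    kind: str  # "del" / "ins" / "sub"
    ref_start: int  # target coordinate (for ins: position the insert precedes)
    length: int


def _alignment_events(aln, ref: str, read: str) -> list[_Event]:
    tblocks, qblocks = aln.aligned
    events: list[_Event] = []
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        for k in range(te - ts):
            if ref[ts + k] != read[qs + k]:
                events.append(_Event("sub", ts + k, 1))
    for i in range(len(tblocks) - 1):
        t_gap = tblocks[i + 1][0] - tblocks[i][1]
        q_gap = qblocks[i + 1][0] - qblocks[i][1]
        if t_gap > 0:
            events.append(_Event("del", tblocks[i][1], t_gap))
        if q_gap > 0:
            events.append(_Event("ins", tblocks[i + 1][0], q_gap))
    return events


def _in_window(ev: _Event, lo: int, hi: int) -> bool:
    if ev.kind == "del":
        return ev.ref_start < hi and ev.ref_start + ev.length > lo
    return lo <= ev.ref_start < hi


def classify_read(
    read: str,
    amplicon_ref: str,
    site: GuideSite,
    window_bp: int = 10,
    min_sub_count: int = 2,
    min_score_frac: float = 0.5,
    read_id: str = "",
) -> EditCall:
    """Classify one read against the predicted cut site."""
    ref, rd = amplicon_ref.upper(), read.upper()
    aligner = make_read_aligner()
    aln = aligner.align(ref, rd)[0]
    if aln.score < min_score_frac * 2.0 * min(len(ref), len(rd)):
        return EditCall(read_id=read_id, outcome="unaligned")
    events = _alignment_events(aln, ref, rd)
    lo, hi = site.cut_pos - window_bp, site.cut_pos + window_bp
    gaps = [e for e in events if e.kind in ("del", "ins") and _in_window(e, lo, hi)]
    subs = [e for e in events if e.kind == "sub" and _in_window(e, lo, hi)]
    n_subs = len(subs)
    if not gaps and n_subs < min_sub_count:
        return EditCall(read_id=read_id, outcome="WT", allele_string=rd)
    if len(gaps) == 1 and n_subs < min_sub_count:
        g = gaps[0]
        return EditCall(
            read_id=read_id,
            outcome="deletion" if g.kind == "del" else "insertion",
            length=g.length,
            offset_from_cut=g.ref_start - site.cut_pos,
            allele_string=rd,
        )
    if not gaps:
        return EditCall(
            read_id=read_id,
            outcome="substitution",
            length=n_subs,
            offset_from_cut=min((s.ref_start - site.cut_pos for s in subs), key=abs),
            allele_string=rd,
        )
    return EditCall(
        read_id=read_id,
        outcome="mixed",
        length=max(g.length for g in gaps),
        offset_from_cut=gaps[0].ref_start - site.cut_pos,
        allele_string=rd,
    )


def detect_dropout(
    read: str,
    amplicon_ref: str,
    site_a: GuideSite,
    site_b: GuideSite,
    window_bp: int = 10,
) -> bool:
    """True when a single deletion run spans both paired-guide windows."""
    aligner = make_read_aligner()
    aln = aligner.align(amplicon_ref.upper(), read.upper())[0]
    events = _alignment_events(aln, amplicon_ref.upper(), read.upper())
    for e in events:
        if e.kind == "del":
            a = _in_window(e, site_a.cut_pos - window_bp, site_a.cut_pos + window_bp)
            b = _in_window(e, site_b.cut_pos - window_bp, site_b.cut_pos + window_bp)
            if a and b:
                return True
    return False


EDITED_OUTCOMES = ("deletion", "insertion", "substitution", "mixed")


def summarize_editing(calls: list[EditCall], min_reads: int = 50) -> dict:
    """Per-sample editing summary.

    Efficiency (%) = 100 · edited / aligned reads; unaligned reads are
    excluded from the denominator and counted separately.
    """
    aligned = [c for c in calls if c.outcome != "unaligned"]
    if not aligned:
        raise ValueError("zero aligned reads")
    edited = [c for c in aligned if c.outcome in EDITED_OUTCOMES]
    dels = [c.length for c in aligned if c.outcome == "deletion"]
    hist: dict[int, int] = {}
    for length in dels:
        hist[int(length)] = hist.get(int(length), 0) + 1
    type_counts = {t: sum(c.outcome == t for c in aligned) for t in ("WT",) + EDITED_OUTCOMES}
    return {
        "n_reads": len(calls),
        "n_aligned": len(aligned),
        "n_unaligned": len(calls) - len(aligned),
        "n_edited": len(edited),
        "efficiency_pct": 100.0 * len(edited) / len(aligned),
        "type_counts": type_counts,
        "deletion_length_hist": dict(sorted(hist.items())),
        "low_coverage": len(aligned) < min_reads,
    }


def calls_frame(calls: list[EditCall]) -> pd.DataFrame:
    """Per-read call table; positions reported 1-based."""
    return pd.DataFrame(
        {
            "read_id": [c.read_id for c in calls],
            "outcome": [c.outcome for c in calls],
            "length": [c.length for c in calls],
            "offset_from_cut": [c.offset_from_cut for c in calls],
        }
    ).sort_values("read_id").reset_index(drop=True)
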