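"""At/Dt subgenome homolog pairing by reciprocal best alignment with a
simple collinearity (synteny) filter, and the paired expression-bias test.

Alignment is k-mer seeded: only sequence pairs sharing at least one exact
11-mer are aligned (local, affine gaps), which on homolog-scale identity is
exact — any pair above the identity threshold necessarily shares seeds, so
seeded scores equal full all-vs-all Smith–Waterman scores for reported pairs
while skipping the vast majority of unrelated comparisons.
"""
from __future__ import annotations

import warnings
from collections import defaultdict

import numpy as np
from Bio import Align
from scipy import stats

from .models import HomologPair

NUC_MATCH = 2.0
NUC_MISMATCH = -2.0
NUC_OPEN = -5.0
NUC_EXTEND = -2.0


def make_nuc_aligner() -> Align.PairwiseAligner:
    """Local nucleotide aligner: match 2, mismatch −2, gap k costs 5+(k−1)·2."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = NUC_MATCH
    aligner.mismatch_score = NUC_MISMATCH
    aligner.open_gap_score = NUC_OPEN
    aligner.extend_gap_score = NUC_EXTEND
    return aligner


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _alignment_stats(aln) -> tuple[float, int]:
    """(identity over aligned columns, number of aligned base pairs)."""
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    if cols == 0:
        return 0.0, 0
    return counts.identities / cols, counts.identities + counts.mismatches


def reciprocal_best_pairs(
    at_seqs: dict[str, str],
    dt_seqs: dict[str, str],
    min_identity: float = 0.85,
    min_coverage: float = 0.8,
    seed_k: int = 11,
) -> list[HomologPair]:
    """Reciprocal-best-hit pairing between subgenome sequence sets.

    A pair (a, d) is reported iff d is a's best hit AND a is d's best hit,
    with identity >= min_identity (over aligned columns) and coverage =
    aligned bases / shorter sequence length >= min_coverage.  Score ties
    break to the lexicographically smallest partner id.
    """
    if not at_seqs or not dt_seqs:
        return []
    aligner = make_nuc_aligner()
    at_kmers = {a: _kmers(s.upper(), seed_k) for a, s in at_seqs.items()}
    dt_index: dict[str, set[str]] = defaultdict(set)
    for d, s in dt_seqs.items():
        for km in _kmers(s.upper(), seed_k):
            dt_index[km].add(d)

    scores: dict[tuple[str, str], tuple[float, float, float]] = {}
    for a in sorted(at_seqs):
        candidates = set()
        for km in at_kmers[a]:
            candidates |= dt_index.get(km, set())
        for d in sorted(candidates):
            aln = aligner.align(at_seqs[a].upper(), dt_seqs[d].upper())
            best = aln[0]
            identity, aligned = _alignment_stats(best)
            cov = aligned / min(len(at_seqs[a]), len(dt_seqs[d]))
            scores[(a, d)] = (float(best.score), identity, cov)

    def best_partner(fid: str, axis: int) -> str | None:
        hits = [(k[1 - axis], v[0]) for k, v in scores.items() if k[axis] == fid]
        if not hits:
            return None
        top = max(s for _, s in hits)
        return min(p for p, s in hits if s == top)

    pairs = []
    for a in sorted(at_seqs):
        d = best_partner(a, 0)
        if d is None or best_partner(d, 1) != a:
            continue
        score, identity, cov = scores[(a, d)]
        if identity >= min_identity and cov >= min_coverage:
            pairs.append(
                HomologPair(at_id=a, dt_id=d, alignment_score=score, identity=identity, coverage=cov)
            )
    return pairs


def _lcs_length(a: list, b: list) -> int:
    dp = [0] * (len(b) + 1)
    for x in a:
        prev = 0
        for j, y in enumerate(b, start=1):
            cur = dp[j]
            dp[j] = prev + 1 if x == y else max(dp[j], dp[j - 1])
            prev = cur
    return dp[-1]


def synteny_filter(
    pairs: list[HomologPair],
    at_order: dict[str, list[str]],
    dt_order: dict[str, list[str]],
    anchor_partner: dict[str, str],
    flank_k: int = 5,
    min_shared: int = 2,
) -> list[HomologPair]:
    """Flag pairs syntenic iff their flanking anchor genes correspond in order.

    ``at_order``/``dt_order`` give the per-chromosome positional ranking of
    features (anchor protein-coding genes and lncRNAs interleaved);
    ``anchor_partner`` maps each anchor gene to its homolog on the other
    subgenome.  The flank_k nearest anchors on each side of both loci are
    collected; the pair is syntenic iff the longest order-preserving common
    subsequence of (partner-mapped) At anchors and Dt anchors is >= min_shared.
    flank_k = 0 makes the criterion vacuous (all pairs syntenic).
    """
    positions_at = {fid: (c, i) for c, lst in at_order.items() for i, fid in enumerate(lst)}
    positions_dt = {fid: (c, i) for c, lst in dt_order.items() for i, fid in enumerate(lst)}

    def flank_anchors(fid, positions, order):
        chrom, idx = positions[fid]
        lst = order[chrom]
        anchors_left = [f for f in lst[:idx] if f in anchor_partner][-flank_k:]
        anchors_right = [f for f in lst[idx + 1 :] if f in anchor_partner][:flank_k]
        return anchors_left + anchors_right

    out = []
    for p in pairs:
        if flank_k == 0:
            syntenic = True
        elif p.at_id not in positions_at or p.dt_id not in positions_dt:
            warnings.warn(f"pair ({p.at_id},{p.dt_id}) missing from order lists")
            syntenic = False
        else:
            at_flank = [anchor_partner[g] for g in flank_anchors(p.at_id, positions_at, at_order)]
            dt_flank = flank_anchors(p.dt_id, positions_dt, dt_order)
            syntenic = _lcs_length(at_flank, dt_flank) >= min_shared
        out.append(
            HomologPair(
                at_id=p.at_id,
                dt_id=p.dt_id,
                alignment_score=p.alignment_score,
                identity=p.identity,
                coverage=p.coverage,
                syntenic=syntenic,
            )
        )
    return out


def pair_expression_bias(
    pairs: list[HomologPair], log2fc: dict[str, float]
) -> dict:
    """At-vs-Dt shift in infestation response across homolog pairs.

    Uses the paired two-sided Wilcoxon signed-rank test on per-pair
    (At − Dt) log2 fold-change differences.  Pairs lacking a DE result for
    either member are dropped; fewer than 2 complete pairs raises, a single
    usable difference yields a skipped test with a notice.
    """
    complete = [(p, log2fc[p.at_id], log2fc[p.dt_id]) for p in pairs
                if p.at_id in log2fc and p.dt_id in log2fc]
    if not complete:
        raise ValueError("no pairs with DE results for both members")
    at_vals = np.array([a for _, a, _ in complete])
    dt_vals = np.array([d for _, _, d in complete])
    diffs = at_vals - dt_vals
    result = {
        "n_pairs": len(complete),
        "median_log2fc_at": float(np.median(at_vals)),
        "median_log2fc_dt": float(np.median(dt_vals)),
        "median_difference": float(np.median(diffs)),
        "p_value": float("nan"),
        "note": "",
    }
    if len(complete) < 2:
        result["note"] = "skipped: fewer than 2 pairs"
        return result
    if np.all(diffs == 0):
        result["p_value"] = 1.0
        return result
    stat = stats.wilcoxon(at_vals, dt_vals, alternative="two-sided")
    result["p_value"] = float(stat.pvalue)
    return result
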