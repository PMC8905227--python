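"""Independent reference implementations used only by the test suite.

Each oracle is written from the mathematical definition with primitives
different from the library under test (math.comb tail sums, exhaustive
enumeration, hand-rolled dynamic programming), so agreement is evidence
rather than tautology.
"""
from __future__ import annotations

import math
from itertools import product

STOPS = {"TAA", "TAG", "TGA"}
CODON_TABLE = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate(product(_BASES, _BASES, _BASES)):
    CODON_TABLE[_a + _b + _c] = _AA[_i]


def translate(seq: str) -> str:
    return "".join(CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3))


def brute_force_orfs(sequence: str, min_peptide_aa: int = 20) -> set[tuple[int, int, int]]:
    """All forward-frame ATG->stop ORFs as (frame, start, end) triples.

    An ORF is an ATG codon followed, in frame, by codons none of which is a
    stop or contains N, terminated by the first in-frame stop codon (N-free).
    Per (frame, stop position) only the earliest qualifying ATG is kept.
    Exhaustive over every (ATG, stop) candidate rather than a single scan.
    """
    seq = sequence.upper()
    out: dict[tuple[int, int], int] = {}  # (frame, end) -> min start
    for f in range(3):
        codons = [(pos, seq[pos : pos + 3]) for pos in range(f, len(seq) - 2, 3)]
        for ai, (apos, acod) in enumerate(codons):
            if acod != "ATG":
                continue
            for bi in range(ai, len(codons)):
                bpos, bcod = codons[bi]
                if "N" in bcod:
                    break  # no valid ORF can run through an N codon
                if bcod in STOPS:
                    end = bpos + 3
                    if (end - 3 - apos) // 3 >= min_peptide_aa:
                        key = (f, end)
                        if key not in out or apos < out[key]:
                            out[key] = apos
                    break
    return {(f, s, e) for (f, e), s in out.items()}


def hypergeom_upper_tail(a: int, N: int, K: int, n: int) -> float:
    """P(X >= a) for X ~ Hypergeom(N, K, n), via math.comb term sums."""
    denom = math.comb(N, n)
    total = 0
    for k in range(a, min(K, n) + 1):
        if n - k > N - K:
            continue
        total += math.comb(K, k) * math.comb(N - K, n - k)
    return total / denom


def wilcoxon_exact_two_sided(x, y) -> float:
    """Exact signed-rank two-sided p by full sign-flip enumeration.

    Zero differences are dropped (wilcox zero policy); requires untied
    absolute differences, n <= 16 after zero removal.
    """
    d = [xi - yi for xi, yi in zip(x, y) if xi != yi]
    n = len(d)
    if n == 0:
        raise ValueError("all differences zero")
    mags = sorted(abs(v) for v in d)
    if len(set(mags)) != n:
        raise ValueError("tied magnitudes not supported by this oracle")
    rank = {m: i + 1 for i, m in enumerate(mags)}
    ranks = [rank[abs(v)] for v in d]
    w_obs = sum(r for r, v in zip(ranks, d) if v > 0)
    le = ge = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        le += w <= w_obs
        ge += w >= w_obs
    total = 2**n
    return min(1.0, 2.0 * min(le / total, ge / total))


def pooled_t_p(x, y) -> tuple[float, float]:
    """Classic pooled two-sample t and two-sided p from the textbook formula.

    The p-value uses a numerically integrated t density (Simpson) rather
    than scipy, so it is an independent route.
    """
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    ssx = sum((v - mx) ** 2 for v in x)
    ssy = sum((v - my) ** 2 for v in y)
    df = nx + ny - 2
    sp2 = (ssx + ssy) / df
    t = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return t, 2.0 * t_sf(abs(t), df)


def t_sf(t: float, df: int) -> float:
    """Upper tail of Student's t by adaptive Simpson on the density."""
    if t < 0:
        return 1.0 - t_sf(-t, df)
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def dens(u: float) -> float:
        return c * (1 + u * u / df) ** (-(df + 1) / 2)

    # integrate density from t to a far cutoff with fine Simpson steps
    hi = max(t + 60.0, 120.0)
    n = 200_000
    h = (hi - t) / n
    s = dens(t) + dens(hi)
    for i in range(1, n):
        s += dens(t + i * h) * (4 if i % 2 else 2)
    # beyond hi the density is ~ c * (u^2/df)^(-(df+1)/2); add that analytic tail
    tail = c * df ** ((df + 1) / 2) * hi ** (-df) / df
    return s * h / 3.0 + tail


NUC_MATCH, NUC_MISMATCH, NUC_OPEN, NUC_EXTEND = 2.0, -2.0, 5.0, 2.0


def gotoh_local_score(a: str, b: str) -> float:
    """Smith-Waterman with affine gaps: gap of length k costs open+(k-1)*ext.

    Plain O(nm) dynamic programming over three states; returns the best
    local score.
    """
    n, m = len(a), len(b)
    NEG = -1e18
    best = 0.0
    H_prev = [0.0] * (m + 1)
    E_prev = [NEG] * (m + 1)  # gap in a (consuming b)
    for i in range(1, n + 1):
        H_cur = [0.0] * (m + 1)
        E_cur = [NEG] * (m + 1)
        F = NEG  # gap in b (consuming a), row-local
        ai = a[i - 1]
        for j in range(1, m + 1):
            E_cur[j] = max(H_prev[j] - NUC_OPEN, E_prev[j] - NUC_EXTEND)
            F = max(H_cur[j - 1] - NUC_OPEN, F - NUC_EXTEND)
            sub = NUC_MATCH if ai == b[j - 1] else NUC_MISMATCH
            h = max(0.0, H_prev[j - 1] + sub, E_cur[j], F)
            H_cur[j] = h
            if h > best:
                best = h
        H_prev, E_prev = H_cur, E_cur
    return best


def gotoh_local_stats(a: str, b: str) -> tuple[float, float, float]:
    """(score, identity over aligned columns, aligned-bases / shorter length).

    Full traceback variant of gotoh_local_score, used only for the handful
    of reported pairs.
    """
    n, m = len(a), len(b)
    NEG = -1e18
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - NUC_OPEN, E[i][j - 1] - NUC_EXTEND)
            F[i][j] = max(H[i - 1][j] - NUC_OPEN, F[i - 1][j] - NUC_EXTEND)
            sub = NUC_MATCH if a[i - 1] == b[j - 1] else NUC_MISMATCH
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    # traceback from (bi, bj) in state H until score 0
    i, j, state = bi, bj, "H"
    ident = mism = gaps = 0
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0.0:
                break
            sub = NUC_MATCH if a[i - 1] == b[j - 1] else NUC_MISMATCH
            if H[i][j] == H[i - 1][j - 1] + sub:
                ident += a[i - 1] == b[j - 1]
                mism += a[i - 1] != b[j - 1]
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            gaps += 1
            if E[i][j] == H[i][j - 1] - NUC_OPEN:
                state = "H"
            j -= 1
        else:
            gaps += 1
            if F[i][j] == H[i - 1][j] - NUC_OPEN:
                state = "H"
            i -= 1
    cols = ident + mism + gaps
    identity = ident / cols if cols else 0.0
    coverage = (ident + mism) / min(n, m)
    return best, identity, coverage
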