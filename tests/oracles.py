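"""Independent brute-force oracles used to check the package's fast paths.

Everything here is written from first principles (rational arithmetic,
full enumeration, double loops) and deliberately shares no code with
the implementation under test.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def hypergeom_pmf_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """P[X = k] for X ~ Hypergeometric(N, K, n), exact rational."""
    if k < 0 or k > K or n - k < 0 or n - k > N - K:
        return Fraction(0)
    return Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))


def hypergeom_tail_exact(k: int, n: int, K: int, N: int) -> Fraction:
    """P[X >= k] by direct summation, exact rational."""
    return sum(
        (hypergeom_pmf_exact(j, N, K, n) for j in range(k, min(n, K) + 1)),
        Fraction(0),
    )


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by enumerating all tables with the same margins.

    Minimum-likelihood rule: sum the probabilities of every table whose
    probability is <= that of the observed table.
    """
    r1 = a + b
    c1 = a + c
    N = a + b + c + d
    if N == 0:
        return Fraction(1)
    p_obs = hypergeom_pmf_exact(a, N, c1, r1)
    total = Fraction(0)
    for a2 in range(max(0, r1 + c1 - N), min(r1, c1) + 1):
        p = hypergeom_pmf_exact(a2, N, c1, r1)
        if p <= p_obs:
            total += p
    return min(total, Fraction(1))


def mwu_u_statistic(x, y) -> float:
    """U for sample x: #(x_i > y_j) + half-ties, by double loop."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mwu_two_sided_exact(x, y) -> Fraction:
    """Two-sided exact Mann-Whitney p by full enumeration (tie-free only).

    Enumerates every assignment of the pooled values to the two
    samples; p doubles the smaller tail P[U <= min(u, nm - u)], capped
    at 1 (the null distribution is symmetric, so this equals the
    two-tail sum).
    """
    nx, ny = len(x), len(y)
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == nx + ny, "oracle requires tie-free data"
    u_obs = mwu_u_statistic(x, y)
    u_small = min(u_obs, nx * ny - u_obs)
    count = 0
    total = 0
    for x_idx in itertools.combinations(range(nx + ny), nx):
        xs = [pooled[i] for i in x_idx]
        ys = [pooled[i] for i in range(nx + ny) if i not in x_idx]
        total += 1
        if mwu_u_statistic(xs, ys) <= u_small + 1e-9:
            count += 1
    return min(Fraction(2 * count, total), Fraction(1))


def mhg_score_prefix_scan(labels) -> tuple[Fraction, int]:
    """mHG score by exhaustive prefix scan with exact tails."""
    N = len(labels)
    B = sum(labels)
    best = Fraction(1)
    best_rank = 0
    b = 0
    for n in range(1, N):
        b += labels[n - 1]
        tail = hypergeom_tail_exact(b, n, B, N)
        if tail < best:
            best = tail
            best_rank = n
    return best, best_rank


def mhg_pvalue_enumeration(score: float, N: int, B: int) -> Fraction:
    """P[mHG <= score] by enumerating every label arrangement."""
    hits = 0
    total = 0
    for ones in itertools.combinations(range(N), B):
        labels = [1 if i in ones else 0 for i in range(N)]
        s, _ = mhg_score_prefix_scan(labels)
        total += 1
        if float(s) <= score * (1 + 1e-12):
            hits += 1
    return Fraction(hits, total)


def classify_brute_force(genes, peaks_by, condition_a, condition_b,
                         upstream, downstream):
    """Double-loop reference transition classification.

    Returns {gene_id: (state_a, state_b, group)} using plain string
    states, computed without any of the package's classification code
    beyond the promoter-window coordinate convention.
    """
    out = {}
    for gene in genes:
        tss = gene.body.start if gene.body.strand == "+" else gene.body.end - 1
        if gene.body.strand == "+":
            w_start, w_end = tss - upstream, tss + downstream
        else:
            w_start, w_end = tss - downstream + 1, tss + upstream + 1
        w_start = max(w_start, 0)
        states = {}
        for cond in (condition_a, condition_b):
            present = {}
            for mark in ("H3K4me3", "H3K27me3"):
                hit = False
                for peak in peaks_by[(mark, cond)]:
                    iv = peak.interval
                    if (
                        iv.chrom == gene.body.chrom
                        and iv.start < w_end
                        and w_start < iv.end
                    ):
                        hit = True
                        break
                present[mark] = hit
            if present["H3K4me3"] and present["H3K27me3"]:
                states[cond] = "BIVALENT"
            elif present["H3K4me3"]:
                states[cond] = "K4_ONLY"
            elif present["H3K27me3"]:
                states[cond] = "K27_ONLY"
            else:
                states[cond] = "UNMARKED"
        sa, sb = states[condition_a], states[condition_b]
        if sb != "BIVALENT":
            group = "NONE"
        else:
            group = {
                "K4_ONLY": "I",
                "K27_ONLY": "II",
                "UNMARKED": "III",
                "BIVALENT": "IV",
            }[sa]
        out[gene.gene_id] = (sa, sb, group)
    return out
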