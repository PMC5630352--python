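"""Term enrichment: hypergeometric (two-list) and minimum-hypergeometric.

Two modes mirror the two common usages of threshold-free GO tools:

* ``two_list`` - a fixed target set against a background universe;
  per-term p is the hypergeometric upper tail of the overlap.
* ``ranked_mHG`` - a ranked gene list; per-term score is the minimum
  hypergeometric tail over all prefixes of the ranking, with an exact
  p-value from the standard lattice-path dynamic programme.

Term annotations are user-supplied GMT files; no ontology database is
bundled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

from bivtrans.signature_overlap import GeneSet


@dataclass(frozen=True)
class TermAnnotation:
    term_id: str
    term_name: str
    members: frozenset[str]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    overlap_count: int
    expected_count: float
    enrichment: float
    p_value: float
    p_bonferroni: float
    mode: str
    threshold_rank: int | None = None


def read_gmt(path: str | Path) -> list[TermAnnotation]:
    """Read a GMT file (term_id <tab> description <tab> members...)."""
    terms = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"line {lineno}: GMT requires term_id, description and >= 1 member"
                )
            terms.append(
                TermAnnotation(fields[0], fields[1], frozenset(fields[2:]))
            )
    return terms


def write_gmt(terms: Iterable[TermAnnotation], path: str | Path) -> None:
    with open(path, "w") as handle:
        for t in terms:
            members = "\t".join(sorted(t.members))
            handle.write(f"{t.term_id}\t{t.term_name}\t{members}\n")


def hypergeometric_tail(k: int, n: int, K: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n).

    ``k`` successes observed drawing ``n`` from a universe of ``N``
    containing ``K`` successes. Computed via the survival function in
    log space for stability.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError(
            f"invalid hypergeometric bounds: k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def mhg_statistic(labels: Sequence[int]) -> tuple[float, int]:
    """Minimum hypergeometric score of a ranked binary label vector.

    Returns ``(score, threshold_rank)`` where the score is the minimum
    over prefixes n in [1, N-1] of the hypergeometric tail of the
    prefix overlap, and the threshold rank is the smallest minimizing
    prefix length. An all-zero (or length-1) vector scores 1.0 at rank 0.
    """
    N = len(labels)
    B = sum(labels)
    if N < 1:
        raise ValueError("labels must be non-empty")
    best = 1.0
    best_rank = 0
    b = 0
    for n in range(1, N):
        b += labels[n - 1]
        tail = hypergeometric_tail(b, n, B, N)
        # strict improvement up to float noise, so exact ties keep the
        # smallest minimizing rank
        if tail < best * (1.0 - 1e-9):
            best = tail
            best_rank = n
    return best, best_rank


def mhg_exact_pvalue(score: float, N: int, B: int) -> float:
    """Exact P[mHG <= score] under uniform permutation of labels.

    Lattice-path dynamic programme over (prefix length n, prefix ones
    b): paths entering a cell whose hypergeometric tail is <= score are
    removed; the surviving path count over C(N, B) gives the retention
    probability.
    """
    if not (0.0 < score <= 1.0):
        raise ValueError("score must be in (0, 1]")
    if not (0 <= B <= N):
        raise ValueError("require 0 <= B <= N")
    if score >= 1.0:
        return 1.0
    # rejection region over interior prefixes, matching mhg_statistic
    eps = 1e-12
    reject = [
        [
            n >= 1
            and n <= N - 1
            and b <= min(n, B)
            and hypergeometric_tail(b, n, B, N) <= score * (1 + eps)
            for b in range(B + 1)
        ]
        for n in range(N + 1)
    ]
    # integer path counts: w[b] = number of prefixes of length n with b
    # ones that never entered the rejection region
    w = [0] * (B + 1)
    w[0] = 1
    for n in range(1, N + 1):
        new = [0] * (B + 1)
        for b in range(min(n, B) + 1):
            if reject[n][b]:
                continue
            stay = w[b] if b <= B else 0
            step = w[b - 1] if b >= 1 else 0
            new[b] = stay + step
        w = new
    surviving = w[B]
    total = math.comb(N, B)
    return 1.0 - surviving / total


def enrich_terms(
    target: GeneSet,
    universe: GeneSet,
    terms: Sequence[TermAnnotation],
    mode: str = "two_list",
    ranking: Sequence[str] | None = None,
) -> list[EnrichmentResult]:
    """Rank terms by enrichment p-value for a target gene set.

    In ``two_list`` mode the target is tested against the universe via
    the hypergeometric tail. In ``ranked_mHG`` mode a full ranking of
    the universe must be supplied; per-term labels are term membership
    down the ranking. Only terms with >= 1 overlap (with the target, or
    the universe in ranked mode) are reported, sorted ascending by p;
    Bonferroni-adjusted p values are included (raw p primary).
    """
    if not target.members:
        raise ValueError("empty target set")
    if not target.members <= universe.members:
        raise ValueError("target must be a subset of the universe")
    N = len(universe.members)
    n = len(target.members)
    results: list[EnrichmentResult] = []
    if mode == "two_list":
        for term in terms:
            members = term.members & universe.members
            K = len(members)
            k = len(term.members & target.members)
            if k == 0:
                continue
            p = hypergeometric_tail(k, n, K, N)
            expected = n * K / N
            results.append(
                EnrichmentResult(
                    term.term_id,
                    term.term_name,
                    k,
                    expected,
                    (k / n) / (K / N),
                    p,
                    min(1.0, p * max(len(terms), 1)),
                    mode,
                )
            )
    elif mode == "ranked_mHG":
        if ranking is None:
            raise ValueError("ranked_mHG mode requires a ranking of the universe")
        if set(ranking) != universe.members:
            raise ValueError("ranking must contain exactly the universe genes")
        for term in terms:
            members = term.members & universe.members
            K = len(members)
            if K == 0:
                continue
            labels = [1 if g in members else 0 for g in ranking]
            score, rank = mhg_statistic(labels)
            p = mhg_exact_pvalue(score, N, K)
            k = sum(labels[:rank])
            n_eff = max(rank, 1)
            expected = n_eff * K / N
            results.append(
                EnrichmentResult(
                    term.term_id,
                    term.term_name,
                    k,
                    expected,
                    (k / n_eff) / (K / N) if K else 0.0,
                    p,
                    min(1.0, p * max(len(terms), 1)),
                    mode,
                    threshold_rank=rank,
                )
            )
    else:
        raise ValueError(f"unknown enrichment mode {mode!r}")
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def write_enrichment_tsv(
    results: Iterable[EnrichmentResult], path: str | Path
) -> None:
    with open(path, "w") as handle:
        handle.write(
            "term_id\tterm_name\toverlap\texpected\tenrichment\t"
            "p_value\tp_bonferroni\tmode\tthreshold_rank\n"
        )
        for r in results:
            rank = "" if r.threshold_rank is None else str(r.threshold_rank)
            handle.write(
                f"{r.term_id}\t{r.term_name}\t{r.overlap_count}\t"
                f"{r.expected_count:.4g}\t{r.enrichment:.4g}\t"
                f"{r.p_value:.6g}\t{r.p_bonferroni:.6g}\t{r.mode}\t{rank}\n"
            )
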