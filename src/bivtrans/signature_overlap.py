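"""Gene-set overlap statistics: Fisher's exact test and odds ratios.

Association between each transition group and a reference gene
signature is quantified on a 2x2 contingency table over a stated gene
universe. Two-sided Fisher p-values follow the minimum-likelihood rule;
zero-cell odds ratios use the Haldane-Anscombe correction (add 0.5 to
every cell) rather than reporting infinity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from scipy import stats

from bivtrans.state_classifier import TransitionGroup, TransitionTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        return cls(name, frozenset(genes))

    def __len__(self) -> int:
        return len(self.members)


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-gene-per-line text file into a GeneSet."""
    genes = []
    with open(path) as handle:
        for line in handle:
            token = line.strip()
            if token and not token.startswith("#"):
                genes.append(token)
    return GeneSet.from_iterable(name or Path(path).stem, genes)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d): in both / group only / reference only / neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class OverlapResult:
    group: str
    table: ContingencyTable2x2
    odds_ratio: float
    corrected: bool
    p_value: float
    empty: bool = False


def build_contingency(
    group_set: GeneSet, reference_set: GeneSet, universe: GeneSet
) -> ContingencyTable2x2:
    """2x2 overlap table of group vs reference within a universe.

    Reference members outside the universe are dropped (count logged);
    the group must be a subset of the universe.
    """
    if not universe.members:
        raise ValueError("empty universe")
    stray = group_set.members - universe.members
    if stray:
        raise ValueError(
            f"group set contains {len(stray)} genes outside the universe"
        )
    ref = reference_set.members & universe.members
    dropped = len(reference_set.members) - len(ref)
    if dropped:
        logger.info(
            "dropped %d reference genes outside the universe (%s)",
            dropped,
            reference_set.name,
        )
    group = group_set.members
    a = len(group & ref)
    b = len(group - ref)
    c = len(ref - group)
    d = len(universe.members) - a - b - c
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact_p(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (minimum-likelihood rule).

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed
    table. Degenerate margins give p = 1.
    """
    _, p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return min(float(p), 1.0)


def odds_ratio(table: ContingencyTable2x2) -> tuple[float, bool]:
    """(a*d)/(b*c); Haldane-Anscombe corrected when any cell is zero.

    Returns (odds ratio, corrected flag).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c), True
    return (a * d) / (b * c), False


def overlap_all_groups(
    transition_table: TransitionTable,
    reference_set: GeneSet,
    universe: GeneSet | None = None,
) -> list[OverlapResult]:
    """Overlap of each transition group (I-IV) with a reference signature.

    The universe defaults to all genes scored in the transition
    analysis. Empty groups yield a flagged degenerate result rather
    than being dropped.
    """
    if universe is None:
        universe = GeneSet.from_iterable(
            "scored_genes", (r.gene_id for r in transition_table.records)
        )
    results = []
    for group in (
        TransitionGroup.I,
        TransitionGroup.II,
        TransitionGroup.III,
        TransitionGroup.IV,
    ):
        members = transition_table.genes_in_group(group) & universe.members
        group_set = GeneSet.from_iterable(f"group_{group.value}", members)
        table = build_contingency(group_set, reference_set, universe)
        if not members:
            results.append(
                OverlapResult(group.value, table, float("nan"), False, 1.0, empty=True)
            )
            continue
        orat, corrected = odds_ratio(table)
        results.append(
            OverlapResult(group.value, table, orat, corrected, fisher_exact_p(table))
        )
    return results


def write_overlap_tsv(results: Iterable[OverlapResult], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("group\ta\tb\tc\td\todds_ratio\tcorrected\tp_value\n")
        for r in results:
            t = r.table
            handle.write(
                f"{r.group}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t"
                f"{r.odds_ratio:.6g}\t{int(r.corrected)}\t{r.p_value:.6g}\n"
            )
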