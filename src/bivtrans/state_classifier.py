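"""Promoter chromatin-state calls and transition-group classification.

A promoter is scored for presence of each histone mark (binary, >= 1 bp
peak overlap) in two conditions. Genes bivalent in condition B are
partitioned into four transition groups by their condition-A state:

* Group I   - K4-only in A, bivalent in B (gained the repressive mark)
* Group II  - K27-only in A, bivalent in B (gained the activating mark)
* Group III - unmarked in A, bivalent in B (acquired both marks)
* Group IV  - bivalent in A with no change
"""

from __future__ import annotations

import enum
import json
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from bivtrans.annotation_io import (
    MARK_K4,
    MARK_K27,
    GeneAnnotation,
    GenomicInterval,
    Peak,
    promoter_window,
)


class ChromatinState(str, enum.Enum):
    K4_ONLY = "K4_ONLY"
    K27_ONLY = "K27_ONLY"
    BIVALENT = "BIVALENT"
    UNMARKED = "UNMARKED"


class TransitionGroup(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    NONE = "NONE"


@dataclass(frozen=True)
class TransitionRecord:
    gene_id: str
    state_a: ChromatinState
    state_b: ChromatinState
    group: TransitionGroup


@dataclass
class TransitionTable:
    """Per-gene transition records plus summary counts.

    Invariant (asserted on construction): group counts over I-IV sum to
    the number of genes bivalent in condition B.
    """

    records: list[TransitionRecord]
    condition_a: str = "A"
    condition_b: str = "B"
    counts: dict[TransitionGroup, int] = field(init=False)
    n_bivalent_a: int = field(init=False)
    n_bivalent_b: int = field(init=False)

    def __post_init__(self) -> None:
        seen = Counter(r.gene_id for r in self.records)
        dups = [g for g, c in seen.items() if c > 1]
        if dups:
            raise ValueError(f"duplicate gene_ids in transition table: {dups[:5]}")
        counts = Counter(r.group for r in self.records)
        self.counts = {g: counts.get(g, 0) for g in TransitionGroup}
        self.n_bivalent_a = sum(
            1 for r in self.records if r.state_a is ChromatinState.BIVALENT
        )
        self.n_bivalent_b = sum(
            1 for r in self.records if r.state_b is ChromatinState.BIVALENT
        )
        grouped = sum(
            self.counts[g]
            for g in (
                TransitionGroup.I,
                TransitionGroup.II,
                TransitionGroup.III,
                TransitionGroup.IV,
            )
        )
        assert grouped == self.n_bivalent_b, (
            f"partition violated: {grouped} grouped vs {self.n_bivalent_b} bivalent"
        )

    def genes_in_group(self, group: TransitionGroup) -> set[str]:
        return {r.gene_id for r in self.records if r.group is group}

    def group_shares(self) -> dict[str, float]:
        """Share of each group among genes bivalent in condition B."""
        if self.n_bivalent_b == 0:
            return {g.value: 0.0 for g in TransitionGroup if g is not TransitionGroup.NONE}
        return {
            g.value: self.counts[g] / self.n_bivalent_b
            for g in (
                TransitionGroup.I,
                TransitionGroup.II,
                TransitionGroup.III,
                TransitionGroup.IV,
            )
        }

    def to_tsv(self, path: str | Path) -> None:
        rows = sorted(self.records, key=lambda r: r.gene_id)
        with open(path, "w") as handle:
            handle.write("gene_id\tstate_a\tstate_b\tgroup\n")
            for r in rows:
                handle.write(
                    f"{r.gene_id}\t{r.state_a.value}\t{r.state_b.value}\t{r.group.value}\n"
                )

    def summary(self) -> dict:
        out: dict = {
            "n_genes": len(self.records),
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "n_bivalent_a": self.n_bivalent_a,
            "n_bivalent_b": self.n_bivalent_b,
            "group_counts": {g.value: self.counts[g] for g in TransitionGroup},
            "group_shares": self.group_shares(),
            "unit": "genes",
        }
        if self.n_bivalent_a > 0:
            out["bivalency_fold_change"] = bivalency_fold_change(self)
        else:
            out["bivalency_fold_change"] = None
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(self.summary(), handle, indent=2, sort_keys=True)
            handle.write("\n")


def call_mark_presence(
    promoter: GenomicInterval, peaks: Sequence[Peak]
) -> bool:
    """True iff any peak overlaps the promoter by >= 1 bp.

    All peaks must carry the same mark and condition labels.
    """
    marks = {p.mark for p in peaks}
    conditions = {p.condition for p in peaks}
    if len(marks) > 1 or len(conditions) > 1:
        raise ValueError(
            f"mixed peak labels: marks={sorted(marks)}, conditions={sorted(conditions)}"
        )
    return any(p.interval.overlaps(promoter) for p in peaks)


class PeakIndex:
    """Per-chromosome sorted-interval index for overlap queries."""

    def __init__(self, peaks: Iterable[Peak]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for p in peaks:
            by_chrom.setdefault(p.interval.chrom, []).append(
                (p.interval.start, p.interval.end)
            )
        self._starts: dict[str, list[int]] = {}
        self._max_end: dict[str, list[int]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts = [s for s, _ in ivs]
            max_end: list[int] = []
            running = 0
            for _, e in ivs:
                running = max(running, e)
                max_end.append(running)
            self._starts[chrom] = starts
            self._max_end[chrom] = max_end

    def overlaps(self, query: GenomicInterval) -> bool:
        starts = self._starts.get(query.chrom)
        if starts is None:
            return False
        max_end = self._max_end[query.chrom]
        # candidates start before query.end; any of them reaching past
        # query.start overlaps
        hi = bisect_right(starts, query.end - 1)
        return hi > 0 and max_end[hi - 1] > query.start


def classify_state(k4_present: bool, k27_present: bool) -> ChromatinState:
    """Map binary mark presence to a chromatin state."""
    if k4_present and k27_present:
        return ChromatinState.BIVALENT
    if k4_present:
        return ChromatinState.K4_ONLY
    if k27_present:
        return ChromatinState.K27_ONLY
    return ChromatinState.UNMARKED


def assign_transition_group(
    state_a: ChromatinState, state_b: ChromatinState
) -> TransitionGroup:
    """Transition group from the (condition A, condition B) state pair.

    Genes not bivalent in condition B get NONE.
    """
    if state_b is not ChromatinState.BIVALENT:
        return TransitionGroup.NONE
    return {
        ChromatinState.K4_ONLY: TransitionGroup.I,
        ChromatinState.K27_ONLY: TransitionGroup.II,
        ChromatinState.UNMARKED: TransitionGroup.III,
        ChromatinState.BIVALENT: TransitionGroup.IV,
    }[state_a]


def classify_transitions(
    genes: Sequence[GeneAnnotation],
    peaks_by_mark_and_condition: Mapping[tuple[str, str], Sequence[Peak]],
    condition_a: str,
    condition_b: str,
    upstream: int = 2000,
    downstream: int = 2000,
) -> TransitionTable:
    """Classify every gene's chromatin-state transition between conditions.

    Parameters
    ----------
    peaks_by_mark_and_condition
        Mapping keyed by (mark, condition) for both marks in both
        conditions; all four collections are required (they may be
        empty lists, but not absent).
    """
    if not genes:
        raise ValueError("empty gene list")
    required = [
        (mark, cond)
        for cond in (condition_a, condition_b)
        for mark in (MARK_K4, MARK_K27)
    ]
    missing = [key for key in required if key not in peaks_by_mark_and_condition]
    if missing:
        raise ValueError(f"missing peak collections for: {missing}")

    indexes = {
        key: PeakIndex(peaks_by_mark_and_condition[key]) for key in required
    }
    records = []
    for gene in genes:
        window = promoter_window(gene, upstream, downstream)
        state_a = classify_state(
            indexes[(MARK_K4, condition_a)].overlaps(window),
            indexes[(MARK_K27, condition_a)].overlaps(window),
        )
        state_b = classify_state(
            indexes[(MARK_K4, condition_b)].overlaps(window),
            indexes[(MARK_K27, condition_b)].overlaps(window),
        )
        records.append(
            TransitionRecord(
                gene.gene_id, state_a, state_b, assign_transition_group(state_a, state_b)
            )
        )
    records.sort(key=lambda r: r.gene_id)
    return TransitionTable(records, condition_a=condition_a, condition_b=condition_b)


def bivalency_fold_change(table: TransitionTable) -> float:
    """Ratio of bivalent gene counts, condition B over condition A."""
    if table.n_bivalent_a == 0:
        raise ValueError(
            "fold change undefined: no bivalent genes in condition "
            f"{table.condition_a!r}"
        )
    return table.n_bivalent_b / table.n_bivalent_a
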