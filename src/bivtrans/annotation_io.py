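"""Genomic annotation and peak I/O.

All coordinates are handled internally as 0-based half-open intervals
(the native BED convention); GTF records (1-based closed) are converted
on read. Promoter windows are derived strand-aware from the TSS.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

MARK_K4 = "H3K4me3"
MARK_K27 = "H3K27me3"
VALID_MARKS = frozenset({MARK_K4, MARK_K27})


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed; names the offending line."""


class AnnotationError(ValueError):
    """Raised for malformed or incomplete gene annotation records."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval.

    ``start`` is inclusive, ``end`` exclusive; ``strand`` is one of
    ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with a canonical TSS.

    Invariant: ``tss == body.start`` on the + strand and
    ``tss == body.end - 1`` on the - strand.
    """

    gene_id: str
    symbol: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id}: strand required to define the TSS"
            )

    @property
    def tss(self) -> int:
        if self.body.strand == "+":
            return self.body.start
        return self.body.end - 1


@dataclass(frozen=True)
class Peak:
    """A mark-labeled peak interval from one condition."""

    interval: GenomicInterval
    mark: str
    condition: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.mark not in VALID_MARKS:
            raise ValueError(
                f"mark must be one of {sorted(VALID_MARKS)}, got {self.mark!r}"
            )


def _parse_bed_line(line: str, lineno: int) -> tuple[GenomicInterval, float | None]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise BedParseError(
            f"line {lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
        )
    chrom = fields[0]
    try:
        start = int(fields[1])
        end = int(fields[2])
    except ValueError as exc:
        raise BedParseError(
            f"line {lineno}: non-integer coordinate in {fields[1]!r}/{fields[2]!r}"
        ) from exc
    if end <= start or start < 0:
        raise BedParseError(
            f"line {lineno}: invalid interval [{start}, {end})"
        )
    strand = "."
    if len(fields) >= 6 and fields[5] in ("+", "-"):
        strand = fields[5]
    score: float | None = None
    if len(fields) >= 5 and fields[4] not in (".", ""):
        try:
            score = float(fields[4])
        except ValueError:
            score = None
    return GenomicInterval(chrom, start, end, strand), score


def read_bed(path: str | Path, mark: str, condition: str) -> list[Peak]:
    """Read a 3-6 column BED file into mark/condition-labeled peaks.

    Input ordering is preserved. Comment (``#``), ``track`` and
    ``browser`` lines and blank lines are skipped.

    Raises
    ------
    BedParseError
        On malformed coordinates, naming the line number.
    """
    peaks: list[Peak] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if (
                not stripped
                or stripped.startswith("#")
                or stripped.startswith("track")
                or stripped.startswith("browser")
            ):
                continue
            interval, score = _parse_bed_line(line, lineno)
            peaks.append(Peak(interval, mark=mark, condition=condition, score=score))
    return peaks


def write_bed(intervals: Iterable[GenomicInterval | Peak], path: str | Path) -> None:
    """Write intervals (or peaks) as 3-column BED."""
    with open(path, "w") as handle:
        for item in intervals:
            iv = item.interval if isinstance(item, Peak) else item
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(attr_field))


def read_gene_annotation(
    path: str | Path,
    format: str = "GTF",
    normalize_chrom: str | None = None,
) -> list[GeneAnnotation]:
    """Read gene annotations from GTF or 6-column BED.

    GTF coordinates (1-based closed) are converted to 0-based half-open.
    One record is kept per ``gene_id``: the first occurrence wins and
    duplicates are logged. GTF ``gene`` features are preferred; if the
    file has none, the first feature line per gene_id is used.

    Parameters
    ----------
    format : {"GTF", "BED"}
    normalize_chrom : {None, "strip", "add"}
        Optionally strip or add a "chr" prefix on chromosome names.
    """
    fmt = format.upper()
    if fmt == "GTF":
        genes = _read_gtf(path)
    elif fmt == "BED":
        genes = _read_bed_genes(path)
    else:
        raise ValueError(f"unsupported annotation format {format!r}")
    if normalize_chrom:
        genes = [_normalize_gene_chrom(g, normalize_chrom) for g in genes]
    return genes


def _normalize_chrom_name(chrom: str, mode: str) -> str:
    if mode == "strip":
        return chrom[3:] if chrom.startswith("chr") else chrom
    if mode == "add":
        return chrom if chrom.startswith("chr") else "chr" + chrom
    raise ValueError(f"unknown chromosome normalization mode {mode!r}")


def _normalize_gene_chrom(gene: GeneAnnotation, mode: str) -> GeneAnnotation:
    body = gene.body
    return GeneAnnotation(
        gene.gene_id,
        gene.symbol,
        GenomicInterval(
            _normalize_chrom_name(body.chrom, mode), body.start, body.end, body.strand
        ),
    )


def _read_gtf(path: str | Path) -> list[GeneAnnotation]:
    by_id: dict[str, GeneAnnotation] = {}
    n_dup = 0
    gene_feature_seen = False
    for lineno, line in enumerate(open(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise AnnotationError(
                f"line {lineno}: GTF requires 9 tab-separated fields"
            )
        chrom, _, feature, start1, end1, _, strand, _, attrs = fields[:9]
        if gene_feature_seen and feature != "gene":
            continue
        attributes = _parse_gtf_attributes(attrs)
        gene_id = attributes.get("gene_id")
        if not gene_id:
            raise AnnotationError(f"line {lineno}: missing gene_id attribute")
        if strand not in ("+", "-"):
            raise AnnotationError(
                f"line {lineno}: gene {gene_id} lacks a strand; TSS undefined"
            )
        if feature == "gene" and not gene_feature_seen:
            # restart keeping only explicit gene features
            gene_feature_seen = True
            by_id.clear()
            n_dup = 0
        symbol = attributes.get("gene_name", gene_id)
        body = GenomicInterval(chrom, int(start1) - 1, int(end1), strand)
        if gene_id in by_id:
            n_dup += 1
            continue
        by_id[gene_id] = GeneAnnotation(gene_id, symbol, body)
    if n_dup:
        logger.warning("collapsed %d duplicate gene_id records (first wins)", n_dup)
    return list(by_id.values())


def _read_bed_genes(path: str | Path) -> list[GeneAnnotation]:
    by_id: dict[str, GeneAnnotation] = {}
    n_dup = 0
    for lineno, line in enumerate(open(path), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 6:
            raise AnnotationError(
                f"line {lineno}: gene BED requires 6 columns (name and strand)"
            )
        chrom, start, end, name, _, strand = fields[:6]
        if strand not in ("+", "-"):
            raise AnnotationError(
                f"line {lineno}: gene {name} lacks a strand; TSS undefined"
            )
        if name in by_id:
            n_dup += 1
            continue
        by_id[name] = GeneAnnotation(
            name, name, GenomicInterval(chrom, int(start), int(end), strand)
        )
    if n_dup:
        logger.warning("collapsed %d duplicate gene records (first wins)", n_dup)
    return list(by_id.values())


def promoter_window(
    gene: GeneAnnotation, upstream: int = 2000, downstream: int = 2000
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS.

    + strand: ``[tss - upstream, tss + downstream)``;
    - strand: ``[tss - downstream + 1, tss + upstream + 1)``.
    The start is clamped at 0.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    if upstream + downstream == 0:
        raise ValueError("window must have positive total extent")
    tss = gene.tss
    if gene.body.strand == "+":
        start, end = tss - upstream, tss + downstream
    else:
        start, end = tss - downstream + 1, tss + upstream + 1
    return GenomicInterval(
        gene.body.chrom, max(start, 0), end, gene.body.strand
    )


def promoter_windows(
    genes: Sequence[GeneAnnotation], upstream: int = 2000, downstream: int = 2000
) -> dict[str, GenomicInterval]:
    """Promoter windows for a gene collection, keyed by gene_id."""
    return {g.gene_id: promoter_window(g, upstream, downstream) for g in genes}
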