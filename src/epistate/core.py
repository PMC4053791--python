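"""Shared genomic data model.

Coordinates are 0-based half-open everywhere.  BED input is consumed
natively; refFlat transcription coordinates (0-based start, exclusive end)
map onto the same convention without arithmetic.  All window geometry is
strand-aware: a window stated in transcription-relative offsets
``[a, b)`` around the TSS maps to genomic ``[tss+a, tss+b)`` on the plus
strand and to the mirrored ``[tss-b, tss-a)`` on the minus strand, so that
base at transcription offset ``d`` on the minus strand sits at genomic
position ``tss - 1 - d``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("epistate")

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is '+', '-' or '.' (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def tx_window(tss: int, strand: str, rel_start: int, rel_end: int) -> tuple[int, int]:
    """Genomic ``(start, end)`` of transcription-relative window ``[rel_start, rel_end)``.

    On the minus strand the window mirrors about the TSS: offsets
    ``[a, b)`` become genomic ``[tss - b, tss - a)``.
    """
    if rel_end <= rel_start:
        raise ValueError("window must be nonempty")
    if strand == "-":
        return tss - rel_end, tss - rel_start
    return tss + rel_start, tss + rel_end


@dataclass(frozen=True)
class AnalysisParameters:
    """Registry of every analysis threshold, with the study defaults.

    promoter_halfwidth
        Methylation promoter window is ``[TSS-1000, TSS+1000)``.
    mark_window
        Histone-mark promoter window, asymmetric ``(-1000, +500)`` around
        the TSS; deliberately distinct from the methylation window.
    min_coverage
        Minimum DREAM tag coverage per sample (100).
    unmethylated_max / promoter_gain_min
        A promoter is "completely unmethylated" at <= 1%; a gain call
        requires the comparison to exceed 2%.
    global_unmethylated_max / global_methylated_min / global_delta
        Site-level categories: unmethylated <= 10%, methylated >= 70%,
        hyper/hypomethylation require a 20-point shift.
    high_fc / sphere_fc
        Expression fold-change thresholds: 9-fold for "highly altered",
        4-fold for monolayer-vs-sphere comparisons.
    smoothing_neighbors
        TSS meta-profiles average 25-50 neighbor points; default 35.
    pmd_genome_fraction
        Fraction of the genome inside partially methylated domains (~0.40).
    """

    promoter_halfwidth: int = 1000
    mark_window: tuple[int, int] = (-1000, 500)
    min_coverage: int = 100
    unmethylated_max: float = 0.01
    promoter_gain_min: float = 0.02
    global_methylated_min: float = 0.70
    global_unmethylated_max: float = 0.10
    global_delta: float = 0.20
    high_fc: float = 9.0
    sphere_fc: float = 4.0
    smoothing_neighbors: int = 35
    pmd_genome_fraction: float = 0.40

    def __post_init__(self) -> None:
        for name in (
            "unmethylated_max",
            "promoter_gain_min",
            "global_methylated_min",
            "global_unmethylated_max",
            "global_delta",
            "pmd_genome_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.promoter_halfwidth <= 0:
            raise ValueError("promoter_halfwidth must be positive")
        if self.mark_window[1] <= self.mark_window[0]:
            raise ValueError("mark_window must be nonempty")
        if self.high_fc <= 1 or self.sphere_fc <= 1:
            raise ValueError("fold-change thresholds must exceed 1")
        if not 1 <= self.smoothing_neighbors:
            raise ValueError("smoothing_neighbors must be >= 1")


DEFAULT_PARAMS = AnalysisParameters()


@dataclass(frozen=True)
class GeneModel:
    """One transcript with strand-aware promoter / body / mark windows.

    ``start``/``end`` are the genomic transcription span; the TSS is
    ``start`` on the plus strand and ``end`` on the minus strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be '+' or '-', got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if self.start < 0:
            raise ValueError(f"{self.gene_id}: negative start")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def promoter_window(self, halfwidth: int = 1000) -> GenomicInterval:
        s, e = tx_window(self.tss, self.strand, -halfwidth, halfwidth)
        return GenomicInterval(self.chrom, max(s, 0), e, self.strand)

    def body_window(self, offset: int = 1000) -> GenomicInterval | None:
        """Gene body: ``[TSS+offset, TES)`` in transcription orientation.

        Empty (``None``) when the transcript is no longer than ``offset``.
        """
        if self.length <= offset:
            return None
        s, e = tx_window(self.tss, self.strand, offset, self.length)
        return GenomicInterval(self.chrom, max(s, 0), e, self.strand)

    def mark_window_interval(
        self, window: tuple[int, int] = (-1000, 500)
    ) -> GenomicInterval:
        s, e = tx_window(self.tss, self.strand, window[0], window[1])
        return GenomicInterval(self.chrom, max(s, 0), e, self.strand)

    @property
    def promoter(self) -> GenomicInterval:
        return self.promoter_window(DEFAULT_PARAMS.promoter_halfwidth)

    @property
    def body(self) -> GenomicInterval | None:
        return self.body_window(DEFAULT_PARAMS.promoter_halfwidth)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge intervals into disjoint sorted form (union, per chromosome)."""
    by_chrom: dict[str, IntervalTree] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        tree = by_chrom[chrom]
        tree.merge_overlaps()
        for iv in sorted(tree):
            merged.append(GenomicInterval(chrom, iv.begin, iv.end))
    return merged


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total merged (disjoint-union) length in bases."""
    return sum(iv.length for iv in merge_intervals(intervals))


class AnnotationSet:
    """Named set of genomic intervals (PMD, CGI, REPEAT, LAD, ...).

    Intervals are merged to disjoint sorted form on construction, so
    membership queries are deterministic and merge() is idempotent.
    Optional per-interval ``classes`` (e.g. repeat families SINE/LINE/
    satellite) survive via :meth:`by_class`, which splits the raw
    intervals before merging.
    """

    def __init__(
        self,
        name: str,
        intervals: Iterable[GenomicInterval],
        classes: Sequence[str] | None = None,
    ) -> None:
        self.name = name
        self._raw = list(intervals)
        self._classes = list(classes) if classes is not None else None
        if self._classes is not None and len(self._classes) != len(self._raw):
            raise ValueError("classes must align with intervals")
        self.intervals = merge_intervals(self._raw)
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for iv in self.intervals:
            self._index.setdefault(iv.chrom, ([], []))  # type: ignore[arg-type]
        starts: dict[str, list[int]] = {}
        ends: dict[str, list[int]] = {}
        for iv in self.intervals:
            starts.setdefault(iv.chrom, []).append(iv.start)
            ends.setdefault(iv.chrom, []).append(iv.end)
        self._index = {
            c: (np.asarray(starts[c]), np.asarray(ends[c])) for c in starts
        }
        self._warned_chroms: set[str] = set()

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None,
                 use_name_column_as_class: bool = False) -> "AnnotationSet":
        intervals, names = read_bed(path, with_names=True)
        return cls(
            name or Path(path).stem.upper(),
            intervals,
            classes=names if use_name_column_as_class else None,
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def merge(self) -> "AnnotationSet":
        """Idempotent: returns an equivalent disjoint set."""
        return AnnotationSet(self.name, self.intervals)

    def by_class(self) -> dict[str, "AnnotationSet"]:
        if self._classes is None:
            return {self.name: self}
        out: dict[str, list[GenomicInterval]] = {}
        for iv, cls_ in zip(self._raw, self._classes):
            out.setdefault(cls_, []).append(iv)
        return {c: AnnotationSet(c, ivs) for c, ivs in out.items()}

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Any >= 1 bp overlap between ``[start, end)`` and the set."""
        idx = self._index.get(chrom)
        if idx is None:
            if chrom not in self._warned_chroms:
                logger.info("chromosome %r absent from annotation %r", chrom, self.name)
                self._warned_chroms.add(chrom)
            return False
        starts, ends = idx
        i = int(np.searchsorted(starts, end, side="left")) - 1
        return i >= 0 and ends[i] > start

    def membership(
        self, chroms: Sequence[str] | np.ndarray, starts: np.ndarray,
        ends: np.ndarray | None = None,
    ) -> np.ndarray:
        """Vectorized overlap test for many queries (points when ends is None)."""
        starts = np.asarray(starts)
        ends = starts + 1 if ends is None else np.asarray(ends)
        chroms = np.asarray(chroms)
        out = np.zeros(len(starts), dtype=bool)
        for chrom in np.unique(chroms):
            mask = chroms == chrom
            idx = self._index.get(str(chrom))
            if idx is None:
                if str(chrom) not in self._warned_chroms:
                    logger.info(
                        "chromosome %r absent from annotation %r", chrom, self.name
                    )
                    self._warned_chroms.add(str(chrom))
                continue
            a_starts, a_ends = idx
            i = np.searchsorted(a_starts, ends[mask], side="left") - 1
            ok = i >= 0
            hit = np.zeros(mask.sum(), dtype=bool)
            hit[ok] = a_ends[i[ok]] > starts[mask][ok]
            out[mask] = hit
        return out


def assign_membership(query, annotation: AnnotationSet) -> bool:
    """True iff the query overlaps the annotation by >= 1 bp.

    Gene models are evaluated on their promoter interval (a gene sits in a
    PMD iff its promoter does).
    """
    if isinstance(query, GeneModel):
        query = query.promoter
    return annotation.overlaps(query.chrom, query.start, query.end)


# ---------------------------------------------------------------------------
# File formats


def read_bed(
    path: str | Path, with_names: bool = False
) -> list[GenomicInterval] | tuple[list[GenomicInterval], list[str]]:
    """Read BED3/BED6 into intervals (0-based half-open, as in the file)."""
    intervals: list[GenomicInterval] = []
    names: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            names.append(fields[3] if len(fields) >= 4 else "")
    if with_names:
        return intervals, names
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                fields += [names[i], "0", iv.strand]
            elif iv.strand != ".":
                fields += [".", "0", iv.strand]
            fh.write("\t".join(fields) + "\n")


def read_gene_models(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Read transcript models from refFlat or BED12.

    refFlat columns: geneName, name, chrom, strand, txStart, txEnd, ...
    (txStart 0-based, txEnd exclusive — already half-open).  BED12 is
    native half-open.  Format is auto-detected from the column layout
    unless ``fmt`` ('refflat' or 'bed12') is given.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fmt or _sniff_gene_format(fields, path, lineno)
            try:
                if kind == "refflat":
                    gene_id, chrom, strand = fields[1], fields[2], fields[3]
                    start, end = int(fields[4]), int(fields[5])
                else:
                    chrom, gene_id, strand = fields[0], fields[3], fields[5]
                    start, end = int(fields[1]), int(fields[2])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed {kind} record") from exc
            if end < start:
                raise ParseError(f"{path}:{lineno}: end < start")
            try:
                genes.append(GeneModel(gene_id, chrom, start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _sniff_gene_format(fields: Sequence[str], path, lineno: int) -> str:
    def is_int(x: str) -> bool:
        try:
            int(x)
            return True
        except ValueError:
            return False

    if len(fields) >= 11 and is_int(fields[4]) and is_int(fields[5]) and fields[3] in ("+", "-"):
        return "refflat"
    if len(fields) >= 12 and is_int(fields[1]) and is_int(fields[2]):
        return "bed12"
    raise ParseError(f"{path}:{lineno}: cannot determine gene-model format")


def collapse_transcripts(genes: Sequence[GeneModel]) -> dict[str, list[GeneModel]]:
    """Group transcripts by gene_id (callers decide the collapse rule:
    'any transcript qualifies' for marks, highest-expression transcript for
    fold changes)."""
    out: dict[str, list[GeneModel]] = {}
    for g in genes:
        out.setdefault(g.gene_id, []).append(g)
    return out
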