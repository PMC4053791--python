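"""Promoter chromatin states from H3K4me3/H3K27me3 peak sets.

A gene is "marked" by a modification when any peak overlaps its
promoter-mark window ``[TSS-1000, TSS+500)`` (transcription orientation)
by at least one base.  Per condition each gene is in one of four states:
K4 (H3K4me3 only), K27 (H3K27me3 only), BIVALENT (both) or NONE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AnalysisParameters,
    DEFAULT_PARAMS,
    GeneModel,
    GenomicInterval,
    merge_intervals,
    read_bed,
)

logger = logging.getLogger("epistate")

K4 = "K4"
K27 = "K27"
BIVALENT = "BIVALENT"
NONE = "NONE"
STATES = (K4, K27, BIVALENT, NONE)


@dataclass
class PeakSet:
    """Peak intervals for one histone mark in one condition.

    Scores are optional and ignored for marking (presence/absence only).
    """

    mark: str
    condition: str
    intervals: list[GenomicInterval]
    scores: list[float] | None = None

    @classmethod
    def from_bed(cls, path: str | Path, mark: str, condition: str) -> "PeakSet":
        intervals = read_bed(path)
        return cls(mark, condition, intervals)

    def merged(self) -> list[GenomicInterval]:
        return merge_intervals(self.intervals)


def assign_promoter_marks(
    genes: Sequence[GeneModel],
    peaks: PeakSet,
    params: AnalysisParameters = DEFAULT_PARAMS,
) -> pd.Series:
    """Boolean per gene: any peak overlaps the strand-aware mark window."""
    merged = peaks.merged()
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for iv in merged:
        starts.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[arg-type]
        ends.setdefault(iv.chrom, []).append(iv.end)  # type: ignore[arg-type]
    index = {c: (np.asarray(starts[c]), np.asarray(ends[c])) for c in starts}
    out = {}
    for gene in genes:
        win = gene.mark_window_interval(params.mark_window)
        idx = index.get(gene.chrom)
        if idx is None:
            out[gene.gene_id] = False
            continue
        a_starts, a_ends = idx
        i = int(np.searchsorted(a_starts, win.end, side="left")) - 1
        out[gene.gene_id] = bool(i >= 0 and a_ends[i] > win.start)
    return pd.Series(out, dtype=bool)


def classify_states(k4: pd.Series, k27: pd.Series) -> tuple[pd.DataFrame, int]:
    """Four-way promoter state per gene from the two mark indicators.

    Genes present in only one of the two tables are excluded; their count
    is returned alongside the table.
    """
    shared = k4.index.intersection(k27.index)
    n_excluded = (len(k4) - len(shared)) + (len(k27) - len(shared))
    k4s = k4.loc[shared].astype(bool)
    k27s = k27.loc[shared].astype(bool)
    state = pd.Series(NONE, index=shared, dtype=object)
    state[k4s & k27s] = BIVALENT
    state[k4s & ~k27s] = K4
    state[~k4s & k27s] = K27
    return pd.DataFrame({"k4": k4s, "k27": k27s, "state": state}), int(n_excluded)


@dataclass
class SwitchMatrix:
    """4x4 cross-tabulation of promoter states between two conditions.

    Rows are the state in condition A, columns the state in condition B;
    the grand total equals the number of genes evaluated in both.
    """

    matrix: pd.DataFrame
    gene_lists: dict[tuple[str, str], list] = field(repr=False, default_factory=dict)
    condition_a: str = "A"
    condition_b: str = "B"

    @property
    def total(self) -> int:
        return int(self.matrix.to_numpy().sum())

    def genes(self, state_a: str, state_b: str) -> list:
        return self.gene_lists.get((state_a, state_b), [])

    def lost_mark(self, mark: str) -> list:
        """Genes carrying ``mark`` (alone or bivalently) in A but not in B."""
        has = _states_with(mark)
        out: list = []
        for a in has:
            for b in set(STATES) - set(has):
                out.extend(self.genes(a, b))
        return out

    def gained_mark(self, mark: str) -> list:
        has = _states_with(mark)
        out: list = []
        for a in set(STATES) - set(has):
            for b in has:
                out.extend(self.genes(a, b))
        return out

    def k4_k27_switchers(self, strict: bool = False) -> list:
        """Genes switching between the two marks.

        Default (loose): exclusively one mark in A, carrying the other
        (exclusively or bivalently) in B.  ``strict=True`` restricts to
        exclusive-to-exclusive transitions.
        """
        targets_from_k4 = [K27] if strict else [K27, BIVALENT]
        targets_from_k27 = [K4] if strict else [K4, BIVALENT]
        out: list = []
        for b in targets_from_k4:
            out.extend(self.genes(K4, b))
        for b in targets_from_k27:
            out.extend(self.genes(K27, b))
        return out

    def newly_bivalent(self) -> dict[str, list]:
        """Genes bivalent in B but not A, keyed by their prior state."""
        return {a: self.genes(a, BIVALENT) for a in (K4, K27, NONE)}


def _states_with(mark: str) -> tuple[str, str]:
    if mark in ("H3K4me3", K4):
        return (K4, BIVALENT)
    if mark in ("H3K27me3", K27):
        return (K27, BIVALENT)
    raise ValueError(f"unknown mark {mark!r}")


def switch_matrix(
    states_a: pd.Series | pd.DataFrame,
    states_b: pd.Series | pd.DataFrame,
    condition_a: str = "A",
    condition_b: str = "B",
) -> SwitchMatrix:
    """Count every A-state -> B-state transition over the shared universe."""
    sa = states_a["state"] if isinstance(states_a, pd.DataFrame) else states_a
    sb = states_b["state"] if isinstance(states_b, pd.DataFrame) else states_b
    shared = sa.index.intersection(sb.index)
    sa, sb = sa.loc[shared], sb.loc[shared]
    matrix = (
        pd.crosstab(sa, sb)
        .reindex(index=STATES, columns=STATES, fill_value=0)
        .rename_axis(index=condition_a, columns=condition_b)
    )
    gene_lists: dict[tuple[str, str], list] = {}
    frame = pd.DataFrame({"a": sa, "b": sb})
    for (a, b), grp in frame.groupby(["a", "b"], observed=True):
        gene_lists[(a, b)] = list(grp.index)
    return SwitchMatrix(matrix, gene_lists, condition_a, condition_b)


@dataclass(frozen=True)
class Footprint:
    """Merged genomic span of a peak set."""

    bases: int

    @property
    def megabases(self) -> float:
        return self.bases / 1e6


def mark_footprint(peaks: PeakSet) -> Footprint:
    """Total length of the disjoint union of the peak intervals."""
    return Footprint(sum(iv.length for iv in peaks.merged()))


def bivalency_summary(
    states_by_condition: Mapping[str, pd.DataFrame],
    reference: str | None = None,
) -> pd.DataFrame:
    """Bivalency statistics per condition, with fold ratios vs a reference.

    Per condition: number of bivalent genes, number of H3K27me3-marked
    genes (exclusively or bivalently), and the bivalent fraction among
    them.  ``fold_vs_reference`` is the ratio of bivalent counts against
    the reference condition (default: the first); NaN-flagged when the
    reference has zero bivalent genes.
    """
    conditions = list(states_by_condition)
    if reference is None:
        reference = conditions[0]
    ref_bivalent = int(
        (states_by_condition[reference]["state"] == BIVALENT).sum()
    )
    if ref_bivalent == 0:
        logger.warning(
            "reference condition %r has zero bivalent genes; ratios undefined",
            reference,
        )
    rows = []
    for cond in conditions:
        table = states_by_condition[cond]
        n_biv = int((table["state"] == BIVALENT).sum())
        n_k27 = int(table["k27"].sum())
        rows.append(
            {
                "condition": cond,
                "n_bivalent": n_biv,
                "n_k27_marked": n_k27,
                "bivalent_fraction_of_k27": n_biv / n_k27 if n_k27 else np.nan,
                "fold_vs_reference": n_biv / ref_bivalent if ref_bivalent else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("condition")
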