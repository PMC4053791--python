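"""Expression normalization and fold-change analysis.

Tag counts per gene are compared between samples after mode normalization:
assuming most genes do not change expression, the histogram of per-gene
log2 count ratios should peak at "no change", so the scale factor is
chosen to move that modal bin to log-ratio zero.  This is deliberately
more conservative than total-count scaling when transcriptome size itself
shifts between conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chromatin import SwitchMatrix
from .core import AnalysisParameters, DEFAULT_PARAMS

logger = logging.getLogger("epistate")

HIGH_UP = "HIGH_UP"
HIGH_DOWN = "HIGH_DOWN"
MODERATE = "MODERATE"
UNCHANGED = "UNCHANGED"
CATEGORIES = (HIGH_UP, HIGH_DOWN, MODERATE, UNCHANGED)


@dataclass(frozen=True)
class NormalizationResult:
    """Outcome of mode normalization of sample B against sample A.

    ``factor`` multiplies sample B's counts so the modal log2 ratio moves
    to zero.  ``total_count_factor`` is the classical library-size factor
    (sum A / sum B); their relative difference is a diagnostic the study
    design expects to stay small when the transcriptome is stable.
    """

    factor: float
    mode_log2: float
    total_count_factor: float
    relative_difference: float
    n_genes: int
    multimodal: bool = False


def mode_normalize(
    counts_a: pd.Series,
    counts_b: pd.Series,
    min_count: int = 20,
    bin_width: float = 0.1,
    log2_range: float = 8.0,
) -> NormalizationResult:
    """Scale factor for B vs A from the mode of the log2-ratio histogram.

    Genes with at least ``min_count`` raw tags in both samples enter the
    histogram.  Bins are centered on integer multiples of ``bin_width``
    (so a pure global c-fold scaling, whose ratios all equal log2 c, lands
    in the bin centered nearest log2 c and the factor errs by at most half
    a bin).  Ties between maximal bins break toward the bin center nearest
    zero, preferring the positive side.  A warning flag is set when a
    second bin comes within 5% of the maximum.
    """
    a, b = counts_a.align(counts_b, join="inner")
    ok = (a >= min_count) & (b >= min_count)
    n = int(ok.sum())
    if n < 50:
        raise ValueError(
            f"only {n} genes pass min_count={min_count} in both samples (need >= 50)"
        )
    ratios = np.log2(b[ok].to_numpy(dtype=float) / a[ok].to_numpy(dtype=float))
    n_half = int(np.ceil(log2_range / bin_width))
    edges = (np.arange(-n_half, n_half + 1) + 0.5) * bin_width
    centers = (edges[:-1] + edges[1:]) / 2.0
    clipped = np.clip(ratios, edges[0] + 1e-12, edges[-1] - 1e-12)
    hist, _ = np.histogram(clipped, bins=edges)
    top = hist.max()
    candidates = np.flatnonzero(hist == top)
    # tie-break: nearest zero, then positive side
    order = sorted(
        candidates, key=lambda i: (round(abs(centers[i]), 9), centers[i] < 0)
    )
    mode_center = float(centers[order[0]])
    second = int(np.sort(hist)[-2]) if len(hist) > 1 else 0
    multimodal = len(candidates) > 1 or second >= 0.95 * top
    if multimodal:
        logger.warning(
            "mode_normalize: secondary histogram peak within 5%% of the maximum"
        )
    factor = float(2.0 ** (-mode_center))
    total_factor = float(a[ok].sum() / b[ok].sum())
    rel_diff = abs(factor - total_factor) / total_factor
    return NormalizationResult(
        factor=factor,
        mode_log2=mode_center,
        total_count_factor=total_factor,
        relative_difference=rel_diff,
        n_genes=n,
        multimodal=multimodal,
    )


def normalize_matrix(
    counts: pd.DataFrame, reference: str, min_count: int = 20,
    bin_width: float = 0.1,
) -> tuple[pd.DataFrame, dict[str, NormalizationResult]]:
    """Mode-normalize every sample of a counts matrix against a reference."""
    normed = counts.astype(float).copy()
    results: dict[str, NormalizationResult] = {}
    for sample in counts.columns:
        if sample == reference:
            continue
        res = mode_normalize(
            counts[reference], counts[sample], min_count=min_count,
            bin_width=bin_width,
        )
        normed[sample] = counts[sample] * res.factor
        results[sample] = res
    return normed, results


def fold_changes(
    normalized: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    pseudocount: float = 1.0,
    high_fc: float = DEFAULT_PARAMS.high_fc,
    moderate_fc: float = 2.0,
) -> pd.DataFrame:
    """log2 fold change (B vs A) and change category per gene.

    A pseudocount is added to both normalized values before the ratio.
    Categories partition the universe: HIGH_UP/HIGH_DOWN at >= ``high_fc``
    fold, MODERATE at >= ``moderate_fc`` fold, UNCHANGED below that.
    """
    a = normalized[sample_a].to_numpy(dtype=float) + pseudocount
    b = normalized[sample_b].to_numpy(dtype=float) + pseudocount
    log2_fc = np.log2(b / a)
    high = np.log2(high_fc)
    moderate = np.log2(moderate_fc)
    category = np.where(
        log2_fc >= high,
        HIGH_UP,
        np.where(
            log2_fc <= -high,
            HIGH_DOWN,
            np.where(np.abs(log2_fc) >= moderate, MODERATE, UNCHANGED),
        ),
    )
    return pd.DataFrame(
        {"log2_fc": log2_fc, "category": category}, index=normalized.index
    )


@dataclass(frozen=True)
class AssociationResult:
    """Coupling between chromatin-state switches and expression change."""

    per_transition: pd.DataFrame
    contingency: pd.DataFrame
    odds_ratio: float
    fisher_p: float
    high_switch_fraction: float
    other_switch_fraction: float


def switch_expression_association(
    fc: pd.DataFrame,
    switches: SwitchMatrix,
    strict: bool = False,
) -> AssociationResult:
    """Summarize expression change per state transition and test whether
    K4<->K27 switching is enriched among highly altered genes.

    ``per_transition`` holds n, median and quantiles of log2 fold change
    for every populated transition class (empty classes omitted).  The
    2x2 table crosses highly-altered (HIGH_UP/HIGH_DOWN) against
    K4<->K27 switching; the odds ratio and Fisher p quantify enrichment.
    """
    rows = []
    for a in ("K4", "K27", "BIVALENT", "NONE"):
        for b in ("K4", "K27", "BIVALENT", "NONE"):
            ids = [g for g in switches.genes(a, b) if g in fc.index]
            if not ids:
                continue
            vals = fc.loc[ids, "log2_fc"].to_numpy(dtype=float)
            rows.append(
                {
                    "from": a,
                    "to": b,
                    "n": len(vals),
                    "median_log2_fc": float(np.median(vals)),
                    "q10": float(np.quantile(vals, 0.10)),
                    "q25": float(np.quantile(vals, 0.25)),
                    "q75": float(np.quantile(vals, 0.75)),
                    "q90": float(np.quantile(vals, 0.90)),
                }
            )
    per_transition = pd.DataFrame(
        rows, columns=["from", "to", "n", "median_log2_fc", "q10", "q25", "q75", "q90"]
    )
    switchers = set(switches.k4_k27_switchers(strict=strict))
    matrix_genes = {g for lst in switches.gene_lists.values() for g in lst}
    universe = [g for g in fc.index if g in matrix_genes]
    is_high = fc.loc[universe, "category"].isin([HIGH_UP, HIGH_DOWN]).to_numpy()
    is_switch = np.array([g in switchers for g in universe])
    table = pd.DataFrame(
        [
            [int((is_high & is_switch).sum()), int((is_high & ~is_switch).sum())],
            [int((~is_high & is_switch).sum()), int((~is_high & ~is_switch).sum())],
        ],
        index=["high", "not_high"],
        columns=["switch", "no_switch"],
    )
    odds, p = stats.fisher_exact(table.to_numpy())
    n_high = table.loc["high"].sum()
    n_other = table.loc["not_high"].sum()
    return AssociationResult(
        per_transition=per_transition,
        contingency=table,
        odds_ratio=float(odds),
        fisher_p=float(p),
        high_switch_fraction=float(table.loc["high", "switch"] / n_high)
        if n_high
        else np.nan,
        other_switch_fraction=float(table.loc["not_high", "switch"] / n_other)
        if n_other
        else np.nan,
    )


@dataclass(frozen=True)
class CorrelationResult:
    spearman_r: float
    p_value: float
    n: int
    group_summary: pd.DataFrame


def methylation_expression_correlation(
    promoter_methylation: pd.Series,
    expression: pd.Series,
    pmd_membership: pd.Series | None = None,
    unmethylated_max: float = DEFAULT_PARAMS.unmethylated_max,
) -> CorrelationResult:
    """Spearman correlation of promoter methylation with expression,
    plus grouped expression summaries by methylation band (<= 1% vs > 1%)
    optionally crossed with PMD membership."""
    m, e = promoter_methylation.align(expression, join="inner")
    defined = m.notna() & e.notna()
    m, e = m[defined], e[defined]
    if len(m) < 10:
        raise ValueError(f"only {len(m)} shared genes (need >= 10)")
    r, p = stats.spearmanr(m.to_numpy(), e.to_numpy())
    band = np.where(m <= unmethylated_max, "unmethylated", "methylated")
    frame = pd.DataFrame({"band": band, "expression": e})
    group_cols = ["band"]
    if pmd_membership is not None:
        frame["pmd"] = pmd_membership.reindex(m.index).fillna(False).astype(bool)
        group_cols.append("pmd")
    summary = (
        frame.groupby(group_cols, observed=True)["expression"]
        .agg(n="size", mean="mean", median="median")
        .reset_index()
    )
    return CorrelationResult(float(r), float(p), len(m), summary)
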