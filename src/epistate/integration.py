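"""Cross-layer analyses around transcription start sites.

TSS meta-profiles collect a per-position signal (DREAM methylation
fractions, H3K27me3 peak occupancy, ...) at signed strand-aware distances
to the TSSs of a gene subset, then average k neighbor points along the
distance axis.  The neighbor average uses circular (wrap-around) windows
over the ordered distance bins: every bin then contributes equally to the
smoothed track, which therefore conserves the global mean exactly; the
wrapped bins at the two extreme distances mix far-upstream with
far-downstream background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chromatin import PeakSet
from .core import AnnotationSet, GeneModel, merge_intervals

logger = logging.getLogger("epistate")


@dataclass
class MetaProfile:
    """Signal vs distance-to-TSS, raw and neighbor-smoothed.

    ``table`` columns: ``distance`` (bp, negative = upstream in
    transcription orientation), ``raw`` (mean of the contributing
    observations at that distance bin), ``smoothed`` and ``n``.
    """

    table: pd.DataFrame
    smoothing_neighbors: int
    n_genes: int

    @property
    def distances(self) -> np.ndarray:
        return self.table["distance"].to_numpy()

    @property
    def raw(self) -> np.ndarray:
        return self.table["raw"].to_numpy()

    @property
    def smoothed(self) -> np.ndarray:
        return self.table["smoothed"].to_numpy()


def circular_moving_average(values: np.ndarray, k: int) -> np.ndarray:
    """Uniform moving average of ``k`` neighbor points with wrap-around.

    The window is centered and has odd effective size ``2*(k//2) + 1``.
    Being a circulant doubly-stochastic operator it conserves the mean of
    ``values`` exactly (up to float rounding).
    """
    values = np.asarray(values, dtype=float)
    m = len(values)
    if m == 0:
        return values.copy()
    # cap the window so it never exceeds the track length
    half = min(max(k, 1) // 2, (m - 1) // 2)
    if half == 0:
        return values.copy()
    padded = np.concatenate([values[-half:], values, values[:half]])
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    return np.convolve(padded, kernel, mode="valid")


def signed_tss_distances(
    genes: Sequence[GeneModel],
    chroms: np.ndarray,
    positions: np.ndarray,
    values: np.ndarray,
    max_distance: int,
) -> tuple[np.ndarray, np.ndarray]:
    """All (distance, value) pairs of observations near any gene's TSS.

    The distance of genomic position p to a TSS at t is ``p - t`` on the
    plus strand and ``t - 1 - p`` on the minus strand (so offset 0 is the
    first transcribed base on either strand).
    """
    order_by_chrom: dict[str, np.ndarray] = {}
    pos_by_chrom: dict[str, np.ndarray] = {}
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        idx = np.flatnonzero(mask)
        srt = np.argsort(positions[mask], kind="stable")
        order_by_chrom[str(chrom)] = idx[srt]
        pos_by_chrom[str(chrom)] = positions[mask][srt]
    dist_out: list[np.ndarray] = []
    val_out: list[np.ndarray] = []
    for gene in genes:
        pos = pos_by_chrom.get(gene.chrom)
        if pos is None:
            continue
        t = gene.tss
        lo = int(np.searchsorted(pos, t - max_distance, side="left"))
        hi = int(np.searchsorted(pos, t + max_distance, side="right"))
        if hi <= lo:
            continue
        sel = order_by_chrom[gene.chrom][lo:hi]
        p = positions[sel]
        d = p - t if gene.strand == "+" else t - 1 - p
        keep = (d >= -max_distance) & (d < max_distance)
        dist_out.append(d[keep])
        val_out.append(values[sel][keep])
    if not dist_out:
        return np.array([], dtype=int), np.array([], dtype=float)
    return np.concatenate(dist_out), np.concatenate(val_out)


def tss_metaprofile(
    observations: pd.DataFrame,
    genes: Sequence[GeneModel],
    smoothing_neighbors: int = 35,
    max_distance: int = 10_000,
    anchor: str = "sites",
    bin_width: int = 50,
) -> MetaProfile:
    """Meta-profile of a per-position signal around the TSSs of ``genes``.

    ``observations`` has columns ``chrom, pos, value``.  With
    ``anchor='sites'`` (default) the profile bins are the observed
    distances themselves; ``anchor='bins'`` aggregates on a uniform
    distance grid of ``bin_width`` bp.  Each bin's raw value is the mean
    of its contributing observations; the smoothed track is the circular
    ``smoothing_neighbors``-point moving average over the ordered bins.
    """
    if len(genes) == 0:
        raise ValueError("empty gene subset")
    if not 1 <= smoothing_neighbors:
        raise ValueError("smoothing_neighbors must be >= 1")
    d, v = signed_tss_distances(
        list(genes),
        observations["chrom"].to_numpy(),
        observations["pos"].to_numpy(),
        observations["value"].to_numpy(dtype=float),
        max_distance,
    )
    if len(d) == 0:
        raise ValueError("no observations within max_distance of any TSS")
    if anchor == "bins":
        d = (np.floor_divide(d, bin_width) * bin_width) + bin_width // 2
    elif anchor != "sites":
        raise ValueError("anchor must be 'sites' or 'bins'")
    frame = pd.DataFrame({"distance": d, "value": v})
    grouped = (
        frame.groupby("distance")["value"].agg(raw="mean", n="size").reset_index()
    )
    grouped = grouped.sort_values("distance").reset_index(drop=True)
    grouped["smoothed"] = circular_moving_average(
        grouped["raw"].to_numpy(), smoothing_neighbors
    )
    return MetaProfile(
        grouped[["distance", "raw", "smoothed", "n"]],
        smoothing_neighbors,
        len(genes),
    )


def k27_intensity_track(
    peaks: PeakSet,
    chroms: np.ndarray | Sequence[str],
    positions: np.ndarray,
    score_weighted: bool = False,
) -> np.ndarray:
    """Per-position peak intensity.

    Default: binary occupancy (1 inside any peak, 0 outside).  The
    score-weighted variant returns the maximal peak score covering the
    position (0 outside).
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    out = np.zeros(len(positions), dtype=float)
    if not score_weighted:
        ann = AnnotationSet(peaks.mark, peaks.intervals)
        return ann.membership(chroms, positions).astype(float)
    if peaks.scores is None:
        raise ValueError("peak set carries no scores")
    for iv, score in zip(peaks.intervals, peaks.scores):
        mask = (chroms == iv.chrom) & (positions >= iv.start) & (positions < iv.end)
        out[mask] = np.maximum(out[mask], score)
    return out


@dataclass
class CouplingResult:
    """Methylation-gain vs H3K27me3-gain coupling around TSSs."""

    profiles: dict[str, MetaProfile]
    contrast: pd.DataFrame
    statistic: float
    p_value: float
    n_gain: int
    n_control: int
    n_permutations: int


def _gene_window_occupancy(
    genes: Sequence[GeneModel],
    site_positions: pd.DataFrame,
    occupancy: np.ndarray,
    window: int,
) -> pd.Series:
    """Mean occupancy over each gene's CpG sites within +-window of its TSS."""
    chroms = site_positions["chrom"].to_numpy()
    pos = site_positions["pos"].to_numpy()
    out = {}
    for gene in genes:
        mask = (
            (chroms == gene.chrom)
            & (pos >= gene.tss - window)
            & (pos < gene.tss + window)
        )
        if mask.any():
            out[gene.gene_id] = float(occupancy[mask].mean())
    return pd.Series(out, dtype=float)


def methylation_gain_k27_coupling(
    gain_genes: Sequence[GeneModel],
    control_genes: Sequence[GeneModel],
    sites: pd.DataFrame,
    peaks_baseline: PeakSet,
    peaks_comparison: PeakSet,
    window: int = 1000,
    smoothing_neighbors: int = 35,
    max_distance: int = 10_000,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> CouplingResult:
    """Test whether promoters gaining methylation also gain H3K27me3.

    ``gain_genes`` are promoters called GAIN (unmethylated baseline,
    > 2% after), ``control_genes`` a matched NONE set.  For each gene the
    contrast is the change (comparison - baseline) in mean K27 occupancy
    over its CpG sites within ``+-window`` of the TSS; the statistic is
    mean contrast of GAIN genes minus mean contrast of controls, with a
    seeded gene-label permutation p-value (one-sided, add-one corrected).
    Meta-profiles of occupancy per condition are emitted alongside.
    """
    if len(gain_genes) < 5:
        logger.warning(
            "only %d methylation-gain genes; coupling profile still emitted",
            len(gain_genes),
        )
    rng = rng if rng is not None else np.random.default_rng()
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    occ_base = k27_intensity_track(peaks_baseline, chroms, pos)
    occ_comp = k27_intensity_track(peaks_comparison, chroms, pos)

    profiles: dict[str, MetaProfile] = {}
    for label, genes, occ in (
        ("gain_baseline", gain_genes, occ_base),
        ("gain_comparison", gain_genes, occ_comp),
        ("control_baseline", control_genes, occ_base),
        ("control_comparison", control_genes, occ_comp),
    ):
        try:
            profiles[label] = tss_metaprofile(
                pd.DataFrame({"chrom": chroms, "pos": pos, "value": occ}),
                genes,
                smoothing_neighbors=smoothing_neighbors,
                max_distance=max_distance,
            )
        except ValueError:
            logger.warning("no observations for %s profile", label)

    site_pos = sites[["chrom", "pos"]]
    base_gain = _gene_window_occupancy(gain_genes, site_pos, occ_base, window)
    comp_gain = _gene_window_occupancy(gain_genes, site_pos, occ_comp, window)
    base_ctrl = _gene_window_occupancy(control_genes, site_pos, occ_base, window)
    comp_ctrl = _gene_window_occupancy(control_genes, site_pos, occ_comp, window)
    contrast_gain = (comp_gain - base_gain).dropna()
    contrast_ctrl = (comp_ctrl - base_ctrl).dropna()
    pooled = np.concatenate([contrast_gain.to_numpy(), contrast_ctrl.to_numpy()])
    n_gain = len(contrast_gain)
    statistic = float(contrast_gain.mean() - contrast_ctrl.mean())
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        t = perm[:n_gain].mean() - perm[n_gain:].mean()
        if t >= statistic:
            hits += 1
    p_value = (hits + 1) / (n_permutations + 1)

    contrast = pd.DataFrame(
        {
            "group": ["gain"] * n_gain + ["control"] * len(contrast_ctrl),
            "gene_id": list(contrast_gain.index) + list(contrast_ctrl.index),
            "delta_occupancy": pooled,
        }
    )
    return CouplingResult(
        profiles=profiles,
        contrast=contrast,
        statistic=statistic,
        p_value=float(p_value),
        n_gain=n_gain,
        n_control=len(contrast_ctrl),
        n_permutations=n_permutations,
    )


def pmd_stratified_k27(
    peaks_by_condition: Mapping[str, PeakSet],
    genes: Sequence[GeneModel],
    pmd: AnnotationSet,
    smoothing_neighbors: int = 35,
    max_distance: int = 10_000,
    grid_step: int = 50,
) -> dict[tuple[str, str], MetaProfile | None]:
    """K27 occupancy meta-profiles for PMD vs non-PMD genes per condition.

    Occupancy is evaluated on a uniform ``grid_step`` grid around every
    TSS.  Returns ``{(group, condition): MetaProfile}`` with group in
    {'inside_pmd', 'outside_pmd'}; the inside entry is None when no gene's
    promoter falls in a PMD (e.g. an empty PMD track).
    """
    promoters = [g.promoter for g in genes]
    member = pmd.membership(
        np.asarray([p.chrom for p in promoters]),
        np.asarray([p.start for p in promoters]),
        np.asarray([p.end for p in promoters]),
    )
    inside = [g for g, hit in zip(genes, member) if hit]
    outside = [g for g, hit in zip(genes, member) if not hit]
    out: dict[tuple[str, str], MetaProfile | None] = {}
    for cond, peaks in peaks_by_condition.items():
        for group, subset in (("inside_pmd", inside), ("outside_pmd", outside)):
            if not subset:
                out[(group, cond)] = None
                continue
            obs = _grid_occupancy(subset, peaks, max_distance, grid_step)
            out[(group, cond)] = tss_metaprofile(
                obs,
                subset,
                smoothing_neighbors=smoothing_neighbors,
                max_distance=max_distance,
                anchor="bins",
                bin_width=grid_step,
            )
    return out


def _grid_occupancy(
    genes: Sequence[GeneModel], peaks: PeakSet, max_distance: int, step: int
) -> pd.DataFrame:
    chroms: list[str] = []
    positions: list[int] = []
    for gene in genes:
        grid = np.arange(
            max(gene.tss - max_distance, 0), gene.tss + max_distance, step
        )
        chroms.extend([gene.chrom] * len(grid))
        positions.extend(grid.tolist())
    chrom_arr = np.asarray(chroms)
    pos_arr = np.asarray(positions)
    occ = k27_intensity_track(peaks, chrom_arr, pos_arr)
    return pd.DataFrame({"chrom": chrom_arr, "pos": pos_arr, "value": occ})


@dataclass(frozen=True)
class K27CorrelationResult:
    spearman_r: float
    p_value: float
    n: int
    low_range_r: float
    low_range_p: float
    n_low: int
    degenerate: bool = False


def methylation_k27_correlation(
    promoter_methylation: pd.Series,
    k27_marked: pd.Series,
    low_methylation_cap: float = 0.2,
) -> K27CorrelationResult:
    """Spearman correlation of promoter methylation with K27 presence.

    Also reported restricted to the low-methylation range (<= cap), where
    the coupling of interest lives.  Degenerate (constant) inputs yield a
    flagged NaN result instead of an error.
    """
    m, k = promoter_methylation.align(k27_marked, join="inner")
    defined = m.notna() & k.notna()
    m, k = m[defined], k[defined].astype(float)
    if len(m) == 0 or m.nunique() <= 1 or k.nunique() <= 1:
        logger.warning("degenerate input to methylation_k27_correlation")
        return K27CorrelationResult(
            np.nan, np.nan, len(m), np.nan, np.nan, 0, degenerate=True
        )
    r, p = stats.spearmanr(m.to_numpy(), k.to_numpy())
    low = m <= low_methylation_cap
    if low.sum() >= 10 and m[low].nunique() > 1 and k[low].nunique() > 1:
        r_low, p_low = stats.spearmanr(m[low].to_numpy(), k[low].to_numpy())
    else:
        r_low, p_low = np.nan, np.nan
    return K27CorrelationResult(
        float(r), float(p), int(len(m)), float(r_low), float(p_low), int(low.sum())
    )
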