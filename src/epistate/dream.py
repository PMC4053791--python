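"""DREAM methylation quantification and differential calls.

DREAM (digital restriction enzyme analysis of methylation) digests genomic
DNA sequentially with the isoschizomers SmaI and XmaI at CCCGGG sites.
SmaI is blocked by CpG methylation and cuts blunt (CCC^GGG), so reads from
unmethylated alleles begin with ``GGG``.  XmaI cuts regardless of
methylation and leaves a 5' overhang (C^CCGGG); after end fill-in, reads
from methylated alleles begin with ``CCGGG``.  Counting the two signatures
per restriction site yields a per-site methylation fraction.

Site tables are pandas DataFrames with columns ``chrom``, ``pos`` (the
coordinate of the site's internal CpG; both fragment ends of one site are
pooled) and, per sample ``s``, ``meth_<s>`` and ``unmeth_<s>`` integer tag
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AnalysisParameters, AnnotationSet, DEFAULT_PARAMS, GeneModel

logger = logging.getLogger("epistate")

METHYLATED = "METHYLATED"
UNMETHYLATED = "UNMETHYLATED"
UNCLASSIFIED = "UNCLASSIFIED"

#: 5' read prefix left by fill-in of the XmaI overhang (methylated allele).
XMAI_SIGNATURE = "CCGGG"
#: 5' read prefix left by the blunt SmaI cut (unmethylated allele).
SMAI_SIGNATURE = "GGG"

_VALID_BASES = frozenset("ACGTN")

GAIN = "GAIN"
LOSS = "LOSS"
NONE = "NONE"


def classify_read_signature(read_prefix: str) -> str:
    """Classify a read by its 5' enzyme signature.

    Returns METHYLATED for the filled-in XmaI prefix (``CCGGG...``),
    UNMETHYLATED for the blunt SmaI prefix (``GGG...``), UNCLASSIFIED
    otherwise (including prefixes containing N, which never match).
    """
    prefix = read_prefix.upper()
    if not _VALID_BASES.issuperset(prefix):
        bad = sorted(set(prefix) - _VALID_BASES)
        raise ValueError(f"non-ACGTN characters in read prefix: {bad}")
    if prefix.startswith(XMAI_SIGNATURE):
        return METHYLATED
    if prefix.startswith(SMAI_SIGNATURE):
        return UNMETHYLATED
    return UNCLASSIFIED


def classify_fastq(path: str | Path, sample: str) -> pd.DataFrame:
    """Classify every read of a DREAM FASTQ file.

    Read ids must encode the mapped restriction-site locus as
    ``chrom:pos`` (optionally followed by further ``:``-separated
    fields), as emitted by the simulator or by an upstream mapping
    export; alignment itself is out of scope here.  Returns a DataFrame
    with columns ``chrom, pos, sample, status``.
    """
    chroms: list[str] = []
    positions: list[int] = []
    statuses: list[str] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()  # '+'
            fh.readline()  # qualities
            if not header.startswith("@"):
                raise ValueError(f"{path}: malformed FASTQ record {header!r}")
            name = header[1:].split()[0]
            chrom, pos = name.split(":")[:2]
            chroms.append(chrom)
            positions.append(int(pos))
            statuses.append(classify_read_signature(seq[:5]) if len(seq) >= 5
                            else UNCLASSIFIED)
    return pd.DataFrame(
        {"chrom": chroms, "pos": positions, "sample": sample, "status": statuses}
    )


def tally_sites(
    tags: pd.DataFrame, catalog: pd.DataFrame | Iterable[tuple[str, int]]
) -> tuple[pd.DataFrame, int]:
    """Aggregate classified tags into a per-site count table.

    ``tags`` has columns ``chrom, pos, sample, status``; ``catalog`` lists
    the known CCCGGG sites as (chrom, pos of internal CpG) — a DataFrame
    with ``chrom``/``pos`` columns or an iterable of pairs.  UNCLASSIFIED
    tags are ignored; classified tags at uncatalogued positions are
    excluded from the table and returned as a count.
    """
    if isinstance(catalog, pd.DataFrame):
        known = set(zip(catalog["chrom"], catalog["pos"]))
    else:
        known = set(catalog)
    usable = tags[tags["status"].isin([METHYLATED, UNMETHYLATED])].copy()
    in_catalog = [
        (c, p) in known for c, p in zip(usable["chrom"], usable["pos"])
    ]
    in_catalog = np.asarray(in_catalog, dtype=bool)
    n_uncatalogued = int((~in_catalog).sum())
    if n_uncatalogued:
        logger.info("%d classified tags at uncatalogued positions", n_uncatalogued)
    usable = usable[in_catalog]
    pivot = (
        usable.assign(kind=usable["status"].map(
            {METHYLATED: "meth", UNMETHYLATED: "unmeth"}))
        .pivot_table(index=["chrom", "pos"], columns=["kind", "sample"],
                     aggfunc="size", fill_value=0)
    )
    pivot.columns = [f"{kind}_{sample}" for kind, sample in pivot.columns]
    sites = pivot.reset_index()
    # ensure both count columns exist for every sample
    for sample in sorted(usable["sample"].unique()):
        for kind in ("meth", "unmeth"):
            col = f"{kind}_{sample}"
            if col not in sites.columns:
                sites[col] = 0
    return sites.sort_values(["chrom", "pos"]).reset_index(drop=True), n_uncatalogued


def samples_of(sites: pd.DataFrame) -> list[str]:
    """Sample names present in a site table (from its meth_/unmeth_ columns)."""
    return sorted(
        {c[len("meth_"):] for c in sites.columns if c.startswith("meth_")}
    )


def coverage(sites: pd.DataFrame, sample: str) -> pd.Series:
    return sites[f"meth_{sample}"] + sites[f"unmeth_{sample}"]


def methylation(sites: pd.DataFrame, sample: str) -> pd.Series:
    """Per-site methylation fraction; NaN where coverage is zero."""
    cov = coverage(sites, sample)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = sites[f"meth_{sample}"] / cov.replace(0, np.nan)
    return frac


@dataclass(frozen=True)
class CoverageFilterResult:
    sites: pd.DataFrame
    n_retained: int
    n_dropped: int


def filter_by_coverage(
    sites: pd.DataFrame,
    min_coverage: int = DEFAULT_PARAMS.min_coverage,
    samples: Sequence[str] | None = None,
) -> CoverageFilterResult:
    """Retain sites with coverage >= min_coverage in *every* listed sample.

    The boundary is inclusive (coverage exactly 100 passes the default).
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    samples = list(samples) if samples is not None else samples_of(sites)
    keep = np.ones(len(sites), dtype=bool)
    for s in samples:
        keep &= (coverage(sites, s) >= min_coverage).to_numpy()
    out = sites[keep].reset_index(drop=True)
    return CoverageFilterResult(out, int(keep.sum()), int((~keep).sum()))


def aggregate_region_methylation(
    sites: pd.DataFrame,
    genes: Sequence[GeneModel],
    region: str = "promoter",
    samples: Sequence[str] | None = None,
    params: AnalysisParameters = DEFAULT_PARAMS,
    weighted: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Average per-site methylation over promoter or gene-body windows.

    Promoter = ``[TSS-1000, TSS+1000)``; body = ``[TSS+1000, TES)`` in
    transcription orientation.  The default is the unweighted mean of the
    per-site fractions ("averaged the methylation level of all CpG
    sites"); ``weighted=True`` gives the coverage-weighted alternative.
    Genes with zero qualifying sites are omitted; their count is the
    second return value.
    """
    if region not in ("promoter", "body"):
        raise ValueError("region must be 'promoter' or 'body'")
    samples = list(samples) if samples is not None else samples_of(sites)

    by_chrom: dict[str, pd.DataFrame] = {
        str(c): g.sort_values("pos").reset_index(drop=True)
        for c, g in sites.groupby("chrom")
    }
    rows: list[dict] = []
    n_omitted = 0
    for gene in genes:
        window = (
            gene.promoter_window(params.promoter_halfwidth)
            if region == "promoter"
            else gene.body_window(params.promoter_halfwidth)
        )
        if window is None:
            n_omitted += 1
            continue
        chrom_sites = by_chrom.get(gene.chrom)
        if chrom_sites is None:
            n_omitted += 1
            continue
        pos = chrom_sites["pos"].to_numpy()
        lo = int(np.searchsorted(pos, window.start, side="left"))
        hi = int(np.searchsorted(pos, window.end, side="left"))
        if hi <= lo:
            n_omitted += 1
            continue
        block = chrom_sites.iloc[lo:hi]
        row = {"gene_id": gene.gene_id, "region": region, "n_sites": hi - lo}
        for s in samples:
            meth = block[f"meth_{s}"].to_numpy(dtype=float)
            unmeth = block[f"unmeth_{s}"].to_numpy(dtype=float)
            cov = meth + unmeth
            ok = cov > 0
            if not ok.any():
                row[s] = np.nan
            elif weighted:
                row[s] = float(meth[ok].sum() / cov[ok].sum())
            else:
                row[s] = float(np.mean(meth[ok] / cov[ok]))
        rows.append(row)
    table = pd.DataFrame(
        rows, columns=["gene_id", "region", "n_sites", *samples]
    )
    return table, n_omitted


def call_promoter_change(
    baseline: pd.Series,
    comparison: pd.Series,
    params: AnalysisParameters = DEFAULT_PARAMS,
) -> pd.Series:
    """Promoter-scope methylation calls on shared units.

    GAIN: completely unmethylated at baseline (<= 1%) and > 2% in the
    comparison.  LOSS: methylated at baseline (> 1%) and completely
    unmethylated (<= 1%) in the comparison.  Units with an undefined value
    in either sample are skipped (logged).
    """
    b, c = baseline.align(comparison, join="inner")
    defined = b.notna() & c.notna()
    n_skipped = int((~defined).sum())
    if n_skipped:
        logger.info("call_promoter_change: %d units skipped (undefined)", n_skipped)
    b, c = b[defined], c[defined]
    out = pd.Series(NONE, index=b.index, dtype=object)
    out[(b <= params.unmethylated_max) & (c > params.promoter_gain_min)] = GAIN
    out[(b > params.unmethylated_max) & (c <= params.unmethylated_max)] = LOSS
    return out


def call_global_change(
    baseline: pd.Series,
    comparison: pd.Series,
    params: AnalysisParameters = DEFAULT_PARAMS,
) -> pd.Series:
    """Site-scope calls for the heavily methylated bulk of the genome.

    GAIN (hypermethylation): baseline <= 10% and a gain of >= 20 points.
    LOSS (hypomethylation): baseline >= 70% and a loss of >= 20 points.
    """
    b, c = baseline.align(comparison, join="inner")
    defined = b.notna() & c.notna()
    n_skipped = int((~defined).sum())
    if n_skipped:
        logger.info("call_global_change: %d units skipped (undefined)", n_skipped)
    b, c = b[defined], c[defined]
    out = pd.Series(NONE, index=b.index, dtype=object)
    eps = 1e-12  # guard the >= delta comparison against float subtraction error
    out[(b <= params.global_unmethylated_max)
        & (c - b >= params.global_delta - eps)] = GAIN
    out[(b >= params.global_methylated_min)
        & (b - c >= params.global_delta - eps)] = LOSS
    return out


@dataclass(frozen=True)
class FdrEstimate:
    """FDR of a call rule measured on a null pair of equivalent samples."""

    fdr: float
    n_called: int
    n_eligible: int


def estimate_call_fdr(
    baseline: pd.Series,
    comparison: pd.Series,
    rule: str = "promoter_gain",
    params: AnalysisParameters = DEFAULT_PARAMS,
) -> FdrEstimate:
    """Estimate the FDR of a differential call on a null sample pair.

    The two samples are expected to be biologically equivalent (e.g. the
    same cells under two culture conditions whose methylomes are nearly
    identical); every call made between them is counted as false.  The
    eligible universe matches the rule's baseline eligibility band:
    promoter_gain -> units <= 1% at baseline; global_gain -> sites <= 10%;
    global_loss -> sites >= 70%.
    """
    b, c = baseline.align(comparison, join="inner")
    defined = b.notna() & c.notna()
    b, c = b[defined], c[defined]
    if rule == "promoter_gain":
        eligible = b <= params.unmethylated_max
        calls = call_promoter_change(b, c, params) == GAIN
    elif rule == "global_gain":
        eligible = b <= params.global_unmethylated_max
        calls = call_global_change(b, c, params) == GAIN
    elif rule == "global_loss":
        eligible = b >= params.global_methylated_min
        calls = call_global_change(b, c, params) == LOSS
    else:
        raise ValueError(f"unknown rule {rule!r}")
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        raise ValueError("empty eligible universe for FDR estimation")
    n_called = int((calls & eligible).sum())
    return FdrEstimate(n_called / n_eligible, n_called, n_eligible)


def stratify_methylation(
    sites: pd.DataFrame,
    annotations: Mapping[str, AnnotationSet],
    samples: Sequence[str] | None = None,
    crossings: Sequence[tuple[str, str | None]] | None = None,
) -> pd.DataFrame:
    """Mean per-site methylation by annotation-class combination.

    ``crossings`` lists (first, second) annotation-name pairs; the second
    may be None for a single-track stratification.  Default: PMD crossed
    with every other loaded annotation.  Empty classes are reported with
    ``n_sites = 0`` and NaN means.
    """
    samples = list(samples) if samples is not None else samples_of(sites)
    if crossings is None:
        others = [n for n in annotations if n != "PMD"]
        crossings = [("PMD", o) for o in others] or [("PMD", None)]
    member: dict[str, np.ndarray] = {}
    for name, ann in annotations.items():
        member[name] = ann.membership(
            sites["chrom"].to_numpy(), sites["pos"].to_numpy()
        )
    rows = []
    for first, second in crossings:
        flags_first = member[first]
        combos = (
            [(True, True), (True, False), (False, True), (False, False)]
            if second is not None
            else [(True, None), (False, None)]
        )
        for in_first, in_second in combos:
            mask = flags_first == in_first
            if second is not None:
                mask = mask & (member[second] == in_second)
            row = {
                "first": first,
                "second": second if second is not None else "",
                "in_first": in_first,
                "in_second": in_second if in_second is not None else "",
                "n_sites": int(mask.sum()),
            }
            for s in samples:
                frac = methylation(sites, s).to_numpy()
                vals = frac[mask]
                vals = vals[~np.isnan(vals)]
                row[s] = float(np.mean(vals)) if len(vals) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
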