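"""Synthetic genomes with known epigenetic ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: ~40% of the genome inside partially methylated domains (PMDs),
CpG-island promoters near zero methylation, gene bodies more methylated
outside PMDs (~40%) than inside (~20%), intergenic background heavily
methylated, binomially sampled DREAM tags at configurable coverage,
two-condition peak sets drawn from a planted state-transition matrix, and
negative-binomial expression counts whose fold changes are coupled to
K4<->K27 switches (default: 32-fold repression for K4->K27, 5-fold
induction for K27->K4).  Every quantity the analysis estimates is emitted
as machine-readable truth, and regeneration under the same seed is
byte-identical.

Gene placement reserves a margin around every transcript large enough
that one gene's peaks can never reach a neighbor's promoter windows, so
discrete recovery (states, switch matrix) is exact in noiseless mode.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chromatin import BIVALENT, K4, K27, NONE, PeakSet, STATES
from .core import AnnotationSet, GeneModel, GenomicInterval, write_bed
from .dream import SMAI_SIGNATURE, XMAI_SIGNATURE

logger = logging.getLogger("epistate")

GAIN = "GAIN"

#: Geometry guaranteeing promoter-window isolation between neighbors:
#: the broad K27 peak extends at most 1,500 bp past the TSS and the mark
#: window 1,000 bp past the transcript span, so a 1,300 bp margin on each
#: side of every gene keeps peak and window sets of adjacent genes disjoint.
_GENE_MARGIN = 1300
_GENE_LEN_RANGE = (1400, 2200)


@dataclass
class SimulationConfig:
    """All tunable study conditions; defaults mirror the analyzed system."""

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 2000
    pmd_fraction: float = 0.40
    pmd_block: int = 100_000
    cgi_promoter_fraction: float = 0.90
    repeat_fraction: float = 0.15
    lad_fraction: float = 0.30
    lad_block: int = 200_000
    sites_per_promoter: tuple[int, int] = (4, 8)
    sites_per_body: tuple[int, int] = (2, 5)
    intergenic_sites_per_gene: int = 5
    conditions: tuple[str, str] = ("epithelial", "mesenchymal")
    # methylome
    n_promoter_gain_genes: int = 90
    promoter_gain_delta: float = 0.05
    global_loss_fraction: float = 0.186
    global_loss_delta: float = 0.25
    # DREAM sampling
    coverage: int = 200
    poisson_coverage: bool = True
    # chromatin states
    state_fractions: Mapping[str, float] = field(
        default_factory=lambda: {K4: 0.55, K27: 0.22, BIVALENT: 0.03, NONE: 0.20}
    )
    transition_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            K4: {K4: 0.90, K27: 0.015, BIVALENT: 0.035, NONE: 0.05},
            K27: {K4: 0.06, K27: 0.45, BIVALENT: 0.09, NONE: 0.40},
            BIVALENT: {K4: 0.25, K27: 0.20, BIVALENT: 0.50, NONE: 0.05},
            NONE: {K4: 0.35, K27: 0.05, BIVALENT: 0.05, NONE: 0.55},
        }
    )
    peak_noise_sd: float = 0.0
    # expression
    expression_mean_log: float = math.log(300.0)
    expression_sigma_log: float = 1.0
    nb_dispersion: float = 0.1
    library_factor: float = 1.0
    fold_k4_to_k27: float = 1.0 / 32.0
    fold_k27_to_k4: float = 5.0
    #: exponent k in the (1 - m)^k repression of expected expression by
    #: promoter methylation m (monotone; 0 disables the coupling)
    methylation_repression_exponent: float = 3.0

    def validate(self) -> None:
        if not 0.0 <= self.pmd_fraction <= 1.0:
            raise ValueError("pmd_fraction must lie in [0, 1]")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        total = sum(self.state_fractions.get(s, 0.0) for s in STATES)
        if total > 1.0 + 1e-9:
            raise ValueError("state fractions must sum to <= 1")
        for a, row in self.transition_probs.items():
            s = sum(row.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"transition probabilities from {a} sum to {s}")


@dataclass
class SyntheticDataset:
    """A generated dataset plus its full ground truth."""

    config: SimulationConfig
    seed: int
    genes: list[GeneModel]
    annotations: dict[str, AnnotationSet]
    site_truth: pd.DataFrame  # chrom,pos,site_class,gene_id,in_pmd,in_cgi,p_<cond>
    gene_truth: pd.DataFrame  # gene_id,state_<cond>,promoter_call,fold_change
    dream_counts: pd.DataFrame  # chrom,pos,meth_<cond>,unmeth_<cond>
    peaks: dict[tuple[str, str], PeakSet]  # (mark, condition) -> PeakSet
    expression: pd.DataFrame  # gene_id x condition raw counts
    pmd_fraction_realized: float
    true_scale_factor: float  # factor mode_normalize should recover for B


def generate_genome(
    n_chroms: int,
    chrom_length: int,
    n_genes: int,
    pmd_fraction: float,
    rng: np.random.Generator,
    config: SimulationConfig | None = None,
) -> tuple[list[GeneModel], dict[str, AnnotationSet], pd.DataFrame, float]:
    """Gene models, annotation tracks and the CpG-site catalog.

    Genes are packed into equal slots per chromosome with isolation
    margins; PMDs/LADs are random disjoint block sets realizing the
    requested genome fraction (within one block of rounding); CpG islands
    cover most promoters.  Returns (genes, annotations, sites, realized
    PMD fraction); ``sites`` has columns chrom, pos, site_class
    (promoter/body/intergenic), gene_id, in_pmd, in_cgi (point membership)
    and cgi_promoter (gene-level CGI status).
    """
    cfg = config or SimulationConfig()
    per_chrom = _split_counts(n_genes, n_chroms)
    genes: list[GeneModel] = []
    gene_no = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        n = per_chrom[ci]
        if n == 0:
            continue
        slot = chrom_length // n
        lo, hi = _GENE_LEN_RANGE
        if slot < hi + 2 * _GENE_MARGIN:
            raise ValueError(
                f"infeasible packing: {n} genes of <= {hi} bp with "
                f"{_GENE_MARGIN} bp margins need slots > {hi + 2 * _GENE_MARGIN} bp, "
                f"got {slot}"
            )
        for si in range(n):
            length = int(rng.integers(lo, hi + 1))
            offset = int(rng.integers(_GENE_MARGIN, slot - _GENE_MARGIN - length + 1))
            start = si * slot + offset
            strand = "+" if rng.random() < 0.5 else "-"
            gene_no += 1
            genes.append(
                GeneModel(f"gene{gene_no:05d}", chrom, start, start + length, strand)
            )

    chrom_names = [f"chr{ci + 1}" for ci in range(n_chroms)]
    pmd_ivs = _block_track(chrom_names, chrom_length, pmd_fraction, cfg.pmd_block, rng)
    lad_ivs = _block_track(chrom_names, chrom_length, cfg.lad_fraction, cfg.lad_block, rng)
    genome_len = n_chroms * chrom_length
    pmd = AnnotationSet("PMD", pmd_ivs)
    realized = pmd.total_length / genome_len

    cgi_ivs: list[GenomicInterval] = []
    cgi_gene_ids: set[str] = set()
    for gene in genes:
        if rng.random() < cfg.cgi_promoter_fraction:
            cgi_ivs.append(
                GenomicInterval(gene.chrom, max(gene.tss - 500, 0), gene.tss + 500)
            )
            cgi_gene_ids.add(gene.gene_id)

    n_repeats = int(cfg.repeat_fraction * genome_len / 300)
    rep_chroms = rng.integers(0, n_chroms, size=n_repeats)
    rep_lens = rng.integers(150, 451, size=n_repeats)
    rep_starts = rng.integers(0, chrom_length - 500, size=n_repeats)
    rep_classes = rng.choice(["SINE", "LINE", "satellite"], size=n_repeats)
    repeat_ivs = [
        GenomicInterval(chrom_names[c], int(s), int(s + l))
        for c, s, l in zip(rep_chroms, rep_starts, rep_lens)
    ]

    annotations = {
        "PMD": pmd,
        "CGI": AnnotationSet("CGI", cgi_ivs),
        "REPEAT": AnnotationSet("REPEAT", repeat_ivs, classes=list(rep_classes)),
        "LAD": AnnotationSet("LAD", lad_ivs),
    }

    sites = _site_catalog(genes, cgi_gene_ids, chrom_names, chrom_length, cfg, rng)
    sites["in_pmd"] = annotations["PMD"].membership(
        sites["chrom"].to_numpy(), sites["pos"].to_numpy()
    )
    sites["in_cgi"] = annotations["CGI"].membership(
        sites["chrom"].to_numpy(), sites["pos"].to_numpy()
    )
    return genes, annotations, sites, realized


def _split_counts(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


def _block_track(
    chrom_names: Sequence[str],
    chrom_length: int,
    fraction: float,
    block: int,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    if fraction <= 0:
        return []
    out: list[GenomicInterval] = []
    for chrom in chrom_names:
        n_blocks = chrom_length // block
        n_pick = int(round(fraction * n_blocks))
        picked = rng.choice(n_blocks, size=n_pick, replace=False)
        for b in sorted(int(x) for x in picked):
            out.append(GenomicInterval(chrom, b * block, (b + 1) * block))
    return out


def _site_catalog(
    genes: Sequence[GeneModel],
    cgi_gene_ids: set[str],
    chrom_names: Sequence[str],
    chrom_length: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows: list[tuple[str, int, str, str]] = []
    for gene in genes:
        prom = gene.promoter
        n_p = int(rng.integers(cfg.sites_per_promoter[0], cfg.sites_per_promoter[1] + 1))
        for p in sorted(rng.choice(prom.length, size=n_p, replace=False)):
            rows.append((gene.chrom, prom.start + int(p), "promoter", gene.gene_id))
        body = gene.body
        if body is not None:
            n_b = int(rng.integers(cfg.sites_per_body[0], cfg.sites_per_body[1] + 1))
            for p in sorted(rng.choice(body.length, size=n_b, replace=False)):
                rows.append((gene.chrom, body.start + int(p), "body", gene.gene_id))
    # intergenic background, rejected near any transcript
    gene_neighborhoods = AnnotationSet(
        "genes",
        [
            GenomicInterval(g.chrom, max(g.start - 1500, 0), g.end + 1500)
            for g in genes
        ],
    )
    n_inter = cfg.intergenic_sites_per_gene * len(genes)
    ic = rng.integers(0, len(chrom_names), size=2 * n_inter)
    ip = rng.integers(0, chrom_length, size=2 * n_inter)
    chroms = np.asarray([chrom_names[i] for i in ic])
    near_gene = gene_neighborhoods.membership(chroms, ip)
    kept = np.flatnonzero(~near_gene)[:n_inter]
    for i in kept:
        rows.append((str(chroms[i]), int(ip[i]), "intergenic", ""))
    frame = pd.DataFrame(rows, columns=["chrom", "pos", "site_class", "gene_id"])
    frame = frame.drop_duplicates(["chrom", "pos"]).sort_values(["chrom", "pos"])
    # gene-level CGI status: a CGI promoter is unmethylated across its full span
    frame["cgi_promoter"] = frame["gene_id"].isin(cgi_gene_ids)
    return frame.reset_index(drop=True)


def simulate_methylome(
    genes: Sequence[GeneModel],
    sites: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series]:
    """True per-site methylation per condition, with planted effects.

    Baseline: CGI promoters uniform in [0, 0.9%]; non-CGI promoters
    intermediate; gene bodies Beta-distributed around 20% (PMD) / 40%
    (non-PMD); intergenic background around 70% (PMD) / 85% (non-PMD).
    The comparison condition adds ``promoter_gain_delta`` to the promoter
    sites of ``n_promoter_gain_genes`` CGI genes and subtracts
    ``global_loss_delta`` from a ``global_loss_fraction`` of the
    baseline-methylated (>= 70%) sites, drawn inside PMDs first.
    Returns the augmented site table (columns ``p_<condition>``) and the
    per-gene planted promoter call (GAIN / NONE).
    """
    cond_a, cond_b = config.conditions
    n = len(sites)
    site_class = sites["site_class"].to_numpy()
    in_pmd = sites["in_pmd"].to_numpy()
    cgi_gene = sites["cgi_promoter"].to_numpy()
    gene_ids = sites["gene_id"].to_numpy()

    p = np.empty(n, dtype=float)
    is_prom = site_class == "promoter"
    prom_cgi = is_prom & cgi_gene
    prom_noncgi = is_prom & ~cgi_gene
    p[prom_cgi] = rng.uniform(0.0, 0.009, size=prom_cgi.sum())
    p[prom_noncgi] = rng.uniform(0.05, 0.60, size=prom_noncgi.sum())
    is_body = site_class == "body"
    p[is_body & in_pmd] = rng.beta(10, 40, size=(is_body & in_pmd).sum())
    p[is_body & ~in_pmd] = rng.beta(20, 30, size=(is_body & ~in_pmd).sum())
    is_inter = site_class == "intergenic"
    p[is_inter & in_pmd] = rng.beta(14, 6, size=(is_inter & in_pmd).sum())
    p[is_inter & ~in_pmd] = rng.beta(34, 6, size=(is_inter & ~in_pmd).sum())

    p_b = p.copy()

    # planted promoter gains on CGI genes (completely unmethylated baseline)
    cgi_genes = sorted(set(gene_ids[prom_cgi]))
    n_gain = min(config.n_promoter_gain_genes, len(cgi_genes))
    gain_genes = (
        set(rng.choice(cgi_genes, size=n_gain, replace=False)) if n_gain else set()
    )
    gain_sites = is_prom & np.isin(gene_ids, sorted(gain_genes))
    p_b[gain_sites] = p_b[gain_sites] + config.promoter_gain_delta

    # planted global hypomethylation, preferentially inside PMDs
    eligible = np.flatnonzero(p >= 0.70)
    n_loss = int(round(config.global_loss_fraction * len(eligible)))
    if n_loss:
        pmd_first = eligible[in_pmd[eligible]]
        others = eligible[~in_pmd[eligible]]
        if len(pmd_first) >= n_loss:
            chosen = rng.choice(pmd_first, size=n_loss, replace=False)
        else:
            extra = rng.choice(others, size=n_loss - len(pmd_first), replace=False)
            chosen = np.concatenate([pmd_first, extra])
        p_b[chosen] = p_b[chosen] - config.global_loss_delta

    clipped = (p_b < 0) | (p_b > 1)
    if clipped.any():
        logger.warning("%d planted effects clipped into [0, 1]", int(clipped.sum()))
        p_b = np.clip(p_b, 0.0, 1.0)

    out = sites.copy()
    out[f"p_{cond_a}"] = p
    out[f"p_{cond_b}"] = p_b
    promoter_call = pd.Series(
        {
            g: (GAIN if g in gain_genes else "NONE")
            for g in sorted({gid for gid in gene_ids if gid})
        },
        dtype=object,
    )
    return out, promoter_call


def simulate_dream_tags(
    site_truth: pd.DataFrame,
    conditions: Sequence[str],
    coverage: int,
    rng: np.random.Generator,
    poisson_coverage: bool = True,
) -> pd.DataFrame:
    """Binomially sampled methylated/unmethylated tag counts per site.

    Coverage is Poisson around the target (or fixed), methylated tags are
    Binomial(coverage, true p).
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    out = site_truth[["chrom", "pos"]].copy()
    n = len(out)
    for cond in conditions:
        p = site_truth[f"p_{cond}"].to_numpy()
        cov = (
            rng.poisson(coverage, size=n)
            if poisson_coverage
            else np.full(n, coverage, dtype=int)
        )
        meth = rng.binomial(cov, p)
        out[f"meth_{cond}"] = meth
        out[f"unmeth_{cond}"] = cov - meth
    return out


def write_dream_fastq(
    site_truth: pd.DataFrame,
    condition: str,
    path: str | Path,
    coverage: int,
    rng: np.random.Generator,
    read_length: int = 36,
) -> None:
    """Emit DREAM reads with correct 5' enzyme signatures as FASTQ.

    Read ids encode the site locus as ``chrom:pos:serial`` so the tally
    step can proceed without alignment.
    """
    bases = np.array(list("ACGT"))
    with open(path, "w") as fh:
        for _, row in site_truth.iterrows():
            cov = int(rng.poisson(coverage))
            meth = int(rng.binomial(cov, row[f"p_{condition}"]))
            for i in range(cov):
                sig = XMAI_SIGNATURE if i < meth else SMAI_SIGNATURE
                tail = "".join(
                    rng.choice(bases, size=read_length - len(sig))
                )
                fh.write(
                    f"@{row['chrom']}:{row['pos']}:{i}\n{sig}{tail}\n+\n"
                    f"{'I' * read_length}\n"
                )


def simulate_peaks_and_expression(
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator,
    promoter_methylation: pd.Series | None = None,
) -> tuple[dict[tuple[str, str], PeakSet], pd.DataFrame, pd.DataFrame]:
    """Planted promoter states, matching peak BED sets, and NB counts.

    Condition-A states are drawn from ``state_fractions``; condition-B
    states follow ``transition_probs``.  Each marked gene receives a peak
    fully covering its mark window (K27 peaks broader than K4, as peak
    callers produce); optional Gaussian jitter (``peak_noise_sd``) shifts
    peak edges.  Expression counts are negative-binomial with per-gene
    log-normal means; K4->K27 switchers are repressed and K27->K4
    switchers induced by the configured folds, and the second condition's
    means carry the planted library-size multiplier.  When a per-gene
    promoter methylation series is supplied, expected expression is
    repressed monotonically by ``(1 - m)^k`` (the methylation-silencing
    coupling the integrative analyses look for).
    Returns (peaks, gene_truth, counts).
    """
    config.validate()
    cond_a, cond_b = config.conditions
    fractions = np.array([config.state_fractions.get(s, 0.0) for s in STATES])
    leftover = 1.0 - fractions.sum()
    if leftover > 1e-9:  # remainder goes to NONE
        fractions[STATES.index(NONE)] += leftover
    states_a = rng.choice(STATES, size=len(genes), p=fractions / fractions.sum())
    states_b = np.empty(len(genes), dtype=object)
    for i, a in enumerate(states_a):
        row = config.transition_probs[a]
        probs = np.array([row.get(s, 0.0) for s in STATES])
        states_b[i] = rng.choice(STATES, p=probs / probs.sum())

    peaks: dict[tuple[str, str], PeakSet] = {}
    for cond, states in ((cond_a, states_a), (cond_b, states_b)):
        k4_ivs: list[GenomicInterval] = []
        k27_ivs: list[GenomicInterval] = []
        for gene, state in zip(genes, states):
            win = gene.mark_window_interval()
            if state in (K4, BIVALENT):
                k4_ivs.append(_jitter(win, 100, config.peak_noise_sd, rng))
            if state in (K27, BIVALENT):
                k27_ivs.append(_jitter(win, 500, config.peak_noise_sd, rng))
        peaks[("H3K4me3", cond)] = PeakSet("H3K4me3", cond, k4_ivs)
        peaks[("H3K27me3", cond)] = PeakSet("H3K27me3", cond, k27_ivs)

    mu = rng.lognormal(config.expression_mean_log, config.expression_sigma_log,
                       size=len(genes))
    if promoter_methylation is not None and config.methylation_repression_exponent > 0:
        m = (
            promoter_methylation.reindex([g.gene_id for g in genes])
            .fillna(0.0)
            .to_numpy()
        )
        mu = mu * (1.0 - np.clip(m, 0.0, 1.0)) ** config.methylation_repression_exponent
    fold = np.ones(len(genes))
    fold[(states_a == K4) & (states_b == K27)] = config.fold_k4_to_k27
    fold[(states_a == K27) & (states_b == K4)] = config.fold_k27_to_k4
    mu_b = mu * fold * config.library_factor
    counts = pd.DataFrame(
        {
            cond_a: _nb_counts(mu, config.nb_dispersion, rng),
            cond_b: _nb_counts(mu_b, config.nb_dispersion, rng),
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )
    gene_truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            f"state_{cond_a}": states_a,
            f"state_{cond_b}": states_b,
            "true_fold_change": fold,
            "true_mean_a": mu,
        }
    ).set_index("gene_id")
    return peaks, gene_truth, counts


def _jitter(
    win: GenomicInterval, pad: int, sd: float, rng: np.random.Generator
) -> GenomicInterval:
    start, end = win.start - pad, win.end + pad
    if sd > 0:
        shift = int(round(rng.normal(0.0, sd)))
        start, end = start + shift, end + shift
    return GenomicInterval(win.chrom, max(start, 0), end)


def _nb_counts(
    mu: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_all(
    config: SimulationConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> SyntheticDataset:
    """Run every generator stage under one seed; optionally write files.

    Independent child generators are spawned deterministically per stage,
    so regenerating with the same seed and config is byte-identical.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    ss = np.random.SeedSequence(seed)
    rng_genome, rng_meth, rng_tags, rng_peaks = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    genes, annotations, sites, realized = generate_genome(
        cfg.n_chroms, cfg.chrom_length, cfg.n_genes, cfg.pmd_fraction,
        rng_genome, cfg,
    )
    site_truth, promoter_call = simulate_methylome(genes, sites, cfg, rng_meth)
    dream_counts = simulate_dream_tags(
        site_truth, cfg.conditions, cfg.coverage, rng_tags, cfg.poisson_coverage
    )
    prom_sites = site_truth[site_truth["site_class"] == "promoter"]
    promoter_meth = prom_sites.groupby("gene_id")[f"p_{cfg.conditions[0]}"].mean()
    peaks, gene_truth, counts = simulate_peaks_and_expression(
        genes, cfg, rng_peaks, promoter_methylation=promoter_meth
    )
    gene_truth = gene_truth.join(promoter_call.rename("promoter_call"))

    dataset = SyntheticDataset(
        config=cfg,
        seed=seed,
        genes=genes,
        annotations=annotations,
        site_truth=site_truth,
        gene_truth=gene_truth,
        dream_counts=dream_counts,
        peaks=peaks,
        expression=counts,
        pmd_fraction_realized=realized,
        true_scale_factor=1.0 / cfg.library_factor,
    )
    if outdir is not None:
        _write_dataset(dataset, Path(outdir))
    return dataset


def _write_dataset(ds: SyntheticDataset, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _write_refflat(ds.genes, outdir / "genes.refflat")
    for name, ann in ds.annotations.items():
        write_bed(ann.intervals, outdir / f"{name.lower()}.bed")
    write_bed(
        [GenomicInterval(c, p, p + 1) for c, p in
         zip(ds.site_truth["chrom"], ds.site_truth["pos"])],
        outdir / "sites.bed",
    )
    for (mark, cond), ps in ds.peaks.items():
        write_bed(ps.intervals, outdir / f"peaks_{mark}_{cond}.bed")
    ds.dream_counts.to_csv(outdir / "dream_counts.tsv", sep="\t", index=False)
    ds.expression.to_csv(outdir / "counts.tsv", sep="\t")
    ds.site_truth.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    ds.gene_truth.to_csv(outdir / "truth_genes.tsv", sep="\t")
    summary = {
        "seed": ds.seed,
        "pmd_fraction_realized": ds.pmd_fraction_realized,
        "true_scale_factor": ds.true_scale_factor,
        "conditions": list(ds.config.conditions),
        "n_genes": len(ds.genes),
        "n_sites": int(len(ds.site_truth)),
        "config": _jsonable(asdict(ds.config)),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_refflat(genes: Sequence[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.gene_id,
                        g.chrom,
                        g.strand,
                        str(g.start),
                        str(g.end),
                        str(g.start),
                        str(g.end),
                        "1",
                        f"{g.start},",
                        f"{g.end},",
                    ]
                )
                + "\n"
            )
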