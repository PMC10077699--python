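"""Synthetic MeRIP-seq / RNA-seq data with planted ground truth.

Emulates the design of a two-group m6A-seq study of porcine
*longissimus dorsi* muscle: two phenotype-extreme groups of ~10 animals,
paired IP and input libraries, negative-binomial counts, m6A peaks
enriched in IP over input with group-differential effects concentrated
near stop codons, RRACH motifs planted at methylation sites,
block-correlated expression modules and sample traits (IMF %, m6A/A
ratio) tied with opposite signs to one module's latent factor.

Every generator is deterministic under a fixed seed, and the returned
:class:`SyntheticTruth` manifest is sufficient to score peak recovery,
differential-methylation recovery, differential-expression recovery,
module recovery and hub-gene recovery downstream.

The negative-binomial is parameterized by mean ``mu`` and dispersion
``d`` with variance ``mu + mu^2 * d``; ``d = 0`` is treated as the
Poisson limit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from meripkit.intervals import GenomicInterval, PeakPanel, merge_intervals, write_bed

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "PlantedPeak",
    "TranscriptomeSim",
    "MeripSim",
    "ExpressionSim",
    "SyntheticDataset",
    "ConfigurationError",
    "simulate_transcriptome",
    "simulate_merip_counts",
    "simulate_expression",
    "simulate_dataset",
]

RRACH_CHOICES = [
    r1 + r2 + "AC" + h for r1 in "AG" for r2 in "AG" for h in "ACT"
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated study design at desk scale: two groups
    of 10 samples, ~30% of genes methylated, 20% of methylated peaks
    group-differential at |log2FC| = 2, IMF trait correlated +0.62 with
    the adipogenic module's factor and the m6A/A trait correlated with
    the opposite sign (-0.51).
    """

    n_genes: int = 1000
    n_samples_per_group: int = 10
    n_modules: int = 4
    module_size: int = 50
    frac_methylated_genes: float = 0.3
    frac_differential_peaks: float = 0.2
    dm_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    mean_library_size: int = 1_000_000
    trait_module_corr: float = 0.62
    trait2_module_corr: float = -0.51
    seed: int = 0
    # transcript geometry
    peak_width: int = 100
    stop_codon_bias: float = 0.8
    stop_codon_window: int = 50
    # MeRIP model
    baseline_log2_enrichment: float = 2.0
    false_positive_peak_rate: float = 0.10
    peak_boundary_jitter: int = 10
    # expression model
    frac_de_genes: float = 0.10
    de_log2fc: float = 2.0
    module_signal_scale: float = 1.0
    expr_noise_sd: float = 0.3
    group_factor_shift: float = 0.8

    def validate(self) -> None:
        for name in ("n_genes", "n_samples_per_group", "n_modules", "module_size",
                     "mean_library_size", "peak_width"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("frac_methylated_genes", "frac_differential_peaks",
                     "stop_codon_bias", "false_positive_peak_rate", "frac_de_genes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        for name in ("trait_module_corr", "trait2_module_corr"):
            if abs(getattr(self, name)) >= 1.0:
                raise ConfigurationError(f"|{name}| must be < 1")
        if self.module_size * self.n_modules > self.n_genes:
            raise ConfigurationError(
                f"module_size * n_modules = {self.module_size * self.n_modules} "
                f"exceeds n_genes = {self.n_genes}"
            )


@dataclass
class PlantedPeak:
    """Ground-truth m6A site: genomic + transcript coordinates and effects."""

    gene: str
    chrom: str
    start: int  # genomic, 0-based half-open
    end: int
    tx_start: int  # transcript coordinates of the same window
    tx_end: int
    region: str  # 5UTR / CDS / 3UTR at the peak midpoint
    baseline_log2_enrichment: float
    group_effect: float  # planted High-vs-Low log2 effect on IP enrichment

    @property
    def is_differential(self) -> bool:
        return self.group_effect != 0.0


@dataclass
class SyntheticTruth:
    """Planted ground truth shared by all generators."""

    genes: list[str]
    transcript_lengths: dict[str, int]
    region_lengths: dict[str, tuple[int, int, int]]  # gene -> (5'UTR, CDS, 3'UTR)
    strands: dict[str, str]
    gene_spans: dict[str, tuple[str, int, int]]  # gene -> (chrom, start, end)
    planted_peaks: list[PlantedPeak] = field(default_factory=list)
    module_assignment: dict[str, int] = field(default_factory=dict)  # 0 = background
    loadings: dict[str, float] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> true log2FC
    trait_module: int = 1
    trait_corrs: tuple[float, float] = (0.62, -0.51)

    def dm_peak_ids(self, panel: PeakPanel, min_reciprocal: float = 0.5) -> dict[str, float]:
        """Map panel peak ids to planted group effects (differential only).

        A panel peak is matched to a planted differential site when they
        overlap; the planted effect is carried over.
        """
        out: dict[str, float] = {}
        planted = [p for p in self.planted_peaks if p.is_differential]
        for pid, peak in zip(panel.ids, panel.peaks):
            for p in planted:
                if peak.chrom == p.chrom and peak.start < p.end and p.start < peak.end:
                    out[pid] = p.group_effect
                    break
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": self.genes,
            "transcript_lengths": self.transcript_lengths,
            "region_lengths": {g: list(v) for g, v in self.region_lengths.items()},
            "strands": self.strands,
            "gene_spans": {g: list(v) for g, v in self.gene_spans.items()},
            "planted_peaks": [dataclasses.asdict(p) for p in self.planted_peaks],
            "module_assignment": self.module_assignment,
            "loadings": self.loadings,
            "de_genes": self.de_genes,
            "trait_module": self.trait_module,
            "trait_corrs": list(self.trait_corrs),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class TranscriptomeSim:
    """Transcript models plus mRNA-sense sequences."""

    models: pd.DataFrame  # gene, transcript, chrom, strand, start, end, cds_start, cds_end
    sequences: dict[str, str]  # transcript id -> mRNA-sense sequence
    truth: SyntheticTruth

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for tid, seq in self.sequences.items():
                fh.write(f">{tid}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    def write_gtf(self, path: str | Path) -> None:
        """Write transcript models as GTF (1-based closed coordinates)."""
        with open(path, "w") as fh:
            for row in self.models.itertuples():
                attrs = f'gene_id "{row.gene}"; transcript_id "{row.transcript}";'
                for feat, s, e in (
                    ("exon", row.start, row.end),
                    ("CDS", row.cds_start, row.cds_end),
                ):
                    fh.write(
                        f"{row.chrom}\tsim\t{feat}\t{s + 1}\t{e}\t.\t{row.strand}\t.\t{attrs}\n"
                    )


def _tx_to_genomic(tx_pos: int, gene_start: int, gene_end: int, strand: str) -> int:
    """Map a transcript coordinate to genomic for a single-exon model."""
    if strand == "-":
        return gene_end - tx_pos
    return gene_start + tx_pos


def simulate_transcriptome(config: SimConfig) -> TranscriptomeSim:
    """Build single-exon transcript models, sequences and planted m6A sites.

    Each gene carries one transcript with 5'UTR / CDS / 3'UTR segments.
    A fraction ``frac_methylated_genes`` of genes receives one planted
    m6A site whose transcript position is drawn from a mixture: with
    probability ``stop_codon_bias`` within ``stop_codon_window`` nt of
    the stop codon, otherwise uniform along the transcript. An RRACH
    pentamer is written into the sequence at each site's midpoint.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_genes
    genes = [f"gene_{i + 1:05d}" for i in range(n)]

    len5 = rng.integers(80, 301, size=n)
    lencds = 3 * rng.integers(100, 501, size=n)
    len3 = rng.integers(150, 801, size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    # lay genes along 18 autosomes with inter-gene gaps
    n_chroms = 18
    chrom_of = np.array([f"chr{(i % n_chroms) + 1}" for i in range(n)])
    gene_start = np.zeros(n, dtype=int)
    cursor: dict[str, int] = {}
    total_len = len5 + lencds + len3
    for i in range(n):
        c = chrom_of[i]
        pos = cursor.get(c, 1000)
        gene_start[i] = pos
        cursor[c] = pos + int(total_len[i]) + int(rng.integers(500, 2000))

    methylated = rng.random(n) < config.frac_methylated_genes
    dm_flags = rng.random(n) < config.frac_differential_peaks

    bases = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    rows = []
    truth = SyntheticTruth(
        genes=genes,
        transcript_lengths={},
        region_lengths={},
        strands={},
        gene_spans={},
        trait_corrs=(config.trait_module_corr, config.trait2_module_corr),
    )
    half = config.peak_width // 2
    for i, g in enumerate(genes):
        L5, Lc, L3 = int(len5[i]), int(lencds[i]), int(len3[i])
        L = L5 + Lc + L3
        strand = str(strands[i])
        gstart = int(gene_start[i])
        gend = gstart + L
        seq = rng.choice(bases, size=L)
        # mRNA-sense sequence: 5'UTR | CDS | 3'UTR
        tid = f"tx_{g.split('_')[1]}"
        rows.append(
            {
                "gene": g,
                "transcript": tid,
                "chrom": str(chrom_of[i]),
                "strand": strand,
                "start": gstart,
                "end": gend,
                "cds_start": gstart + (L3 if strand == "-" else L5),
                "cds_end": gend - (L5 if strand == "-" else L3),
            }
        )
        truth.transcript_lengths[tid] = L
        truth.region_lengths[g] = (L5, Lc, L3)
        truth.strands[g] = strand
        truth.gene_spans[g] = (str(chrom_of[i]), gstart, gend)

        if methylated[i]:
            stop_pos = L5 + Lc  # transcript coordinate just past the stop codon
            if rng.random() < config.stop_codon_bias:
                mid = int(np.clip(
                    round(stop_pos + rng.normal(0, config.stop_codon_window / 2)),
                    half, L - half - 5,
                ))
            else:
                mid = int(rng.integers(half, L - half - 4))
            pent = RRACH_CHOICES[rng.integers(len(RRACH_CHOICES))]
            seq[mid:mid + 5] = list(pent)
            tx_s, tx_e = max(0, mid - half), min(L, mid + half)
            if mid < L5:
                region = "5UTR"
            elif mid < L5 + Lc:
                region = "CDS"
            else:
                region = "3UTR"
            if strand == "-":
                g_s = _tx_to_genomic(tx_e, gstart, gend, strand)
                g_e = _tx_to_genomic(tx_s, gstart, gend, strand)
            else:
                g_s = _tx_to_genomic(tx_s, gstart, gend, strand)
                g_e = _tx_to_genomic(tx_e, gstart, gend, strand)
            effect = 0.0
            if dm_flags[i]:
                effect = float(config.dm_log2fc * (1 if rng.random() < 0.5 else -1))
            truth.planted_peaks.append(
                PlantedPeak(
                    gene=g, chrom=str(chrom_of[i]), start=g_s, end=g_e,
                    tx_start=tx_s, tx_end=tx_e, region=region,
                    baseline_log2_enrichment=config.baseline_log2_enrichment,
                    group_effect=effect,
                )
            )
        sequences[tid] = "".join(seq)

    models = pd.DataFrame(rows)
    return TranscriptomeSim(models=models, sequences=sequences, truth=truth)


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean mu, variance mu + mu^2 d); d = 0 falls back to Poisson."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _sample_names(n_per_group: int) -> tuple[list[str], list[str]]:
    high = [f"H{i + 1:02d}" for i in range(n_per_group)]
    low = [f"L{i + 1:02d}" for i in range(n_per_group)]
    return high, low


@dataclass
class MeripSim:
    """Per-group peak calls, the merged panel, and IP/input count tables."""

    peaks_high: list[GenomicInterval]
    peaks_low: list[GenomicInterval]
    panel: PeakPanel
    ip_counts: pd.DataFrame  # panel peaks x samples
    input_counts: pd.DataFrame
    sample_sheet: pd.DataFrame  # sample, group, role, total_reads
    expected_ip_mu: pd.DataFrame
    expected_input_mu: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_bed(self.peaks_high, outdir / "peaks_high.bed")
        write_bed(self.peaks_low, outdir / "peaks_low.bed")
        self.panel.to_frame().to_csv(outdir / "peak_panel.tsv", sep="\t", index=False)
        self.ip_counts.to_csv(outdir / "ip_counts.tsv", sep="\t")
        self.input_counts.to_csv(outdir / "input_counts.tsv", sep="\t")
        self.sample_sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)


def simulate_merip_counts(truth: SyntheticTruth, config: SimConfig) -> MeripSim:
    """Generate per-group peak calls and paired IP/input count tables.

    Input-library depth over each panel peak is negative-binomial with a
    gene-specific per-base rate; IP depth at methylated peaks is that
    rate multiplied by ``2^baseline_log2_enrichment`` and, for High-group
    samples, additionally by ``2^group_effect``. Per-group peak calls
    cover every planted peak (with boundary jitter) plus
    ``false_positive_peak_rate`` spurious peaks per group in
    unmethylated genes. Library totals are the column sums of the count
    tables they accompany.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    planted = truth.planted_peaks

    def jitter(iv_start: int, iv_end: int) -> tuple[int, int]:
        j = config.peak_boundary_jitter
        if j == 0:
            return iv_start, iv_end
        s = max(0, iv_start + int(rng.integers(-j, j + 1)))
        e = iv_end + int(rng.integers(-j, j + 1))
        return (s, e) if e > s else (iv_start, iv_end)

    peaks_high = []
    peaks_low = []
    for p in planted:
        s, e = jitter(p.start, p.end)
        peaks_high.append(GenomicInterval(p.chrom, s, e))
        s, e = jitter(p.start, p.end)
        peaks_low.append(GenomicInterval(p.chrom, s, e))

    methylated_genes = {p.gene for p in planted}
    free_genes = [g for g in truth.genes if g not in methylated_genes]
    n_fp = int(round(config.false_positive_peak_rate * len(planted)))
    for group_peaks in (peaks_high, peaks_low):
        if not free_genes or n_fp == 0:
            continue
        picks = rng.choice(len(free_genes), size=min(n_fp, len(free_genes)), replace=False)
        for k in picks:
            chrom, gs, ge = truth.gene_spans[free_genes[int(k)]]
            w = config.peak_width
            if ge - gs <= w + 2:
                continue
            s = int(rng.integers(gs, ge - w))
            group_peaks.append(GenomicInterval(chrom, s, s + w))

    panel = merge_intervals(
        list(peaks_high) + list(peaks_low),
        sources=["High"] * len(peaks_high) + ["Low"] * len(peaks_low),
    )

    high, low = _sample_names(config.n_samples_per_group)
    samples = high + low
    is_high = np.array([1] * len(high) + [0] * len(low))

    # gene-level per-base input rate, normalized to hit mean_library_size
    gene_rate = {
        g: float(v) for g, v in zip(
            truth.genes, rng.lognormal(mean=0.0, sigma=1.0, size=len(truth.genes))
        )
    }
    # map panel peaks to genes by coordinate overlap
    span_index: dict[str, list[tuple[int, int, str]]] = {}
    for g, (chrom, s, e) in truth.gene_spans.items():
        span_index.setdefault(chrom, []).append((s, e, g))
    peak_gene: list[str | None] = []
    for peak in panel.peaks:
        hit = None
        for s, e, g in span_index.get(peak.chrom, ()):
            if peak.start < e and s < peak.end:
                hit = g
                break
        peak_gene.append(hit)

    lengths = np.array(panel.lengths(), dtype=float)
    base = np.array([gene_rate.get(g, 0.1) if g else 0.1 for g in peak_gene])
    mu_unit = base * lengths
    mu_input = mu_unit * (config.mean_library_size / mu_unit.sum())

    effect_by_peak = np.zeros(len(panel))
    enrich_by_peak = np.ones(len(panel))
    for i, peak in enumerate(panel.peaks):
        for p in planted:
            if peak.chrom == p.chrom and peak.start < p.end and p.start < peak.end:
                enrich_by_peak[i] = 2.0 ** p.baseline_log2_enrichment
                effect_by_peak[i] = p.group_effect
                break

    # per-sample library-scale wobble
    scale = rng.lognormal(mean=0.0, sigma=0.1, size=len(samples))
    mu_in = mu_input[:, None] * scale[None, :]
    mu_ip = mu_in * enrich_by_peak[:, None] * np.power(
        2.0, effect_by_peak[:, None] * is_high[None, :]
    )
    input_counts = _nb_sample(rng, mu_in, config.nb_dispersion)
    ip_counts = _nb_sample(rng, mu_ip, config.nb_dispersion)

    ids = panel.ids
    ip_df = pd.DataFrame(ip_counts, index=ids, columns=samples)
    in_df = pd.DataFrame(input_counts, index=ids, columns=samples)
    ip_df.index.name = in_df.index.name = "peak"

    sheet = []
    for role, df in (("IP", ip_df), ("input", in_df)):
        for s in samples:
            sheet.append(
                {
                    "sample": s,
                    "group": "High" if s.startswith("H") else "Low",
                    "role": role,
                    "total_reads": int(df[s].sum()),
                }
            )
    sample_sheet = pd.DataFrame(sheet)

    return MeripSim(
        peaks_high=peaks_high,
        peaks_low=peaks_low,
        panel=panel,
        ip_counts=ip_df,
        input_counts=in_df,
        sample_sheet=sample_sheet,
        expected_ip_mu=pd.DataFrame(mu_ip, index=ids, columns=samples),
        expected_input_mu=pd.DataFrame(mu_in, index=ids, columns=samples),
    )


@dataclass
class ExpressionSim:
    """Gene-level counts, sample traits and the latent factor structure."""

    counts: pd.DataFrame  # genes x samples, integer
    traits: pd.DataFrame  # sample, group, imf_pct, m6a_ratio
    gene_lengths: pd.Series
    latent_log2_mu: pd.DataFrame
    module_factors: pd.DataFrame  # modules x samples

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / "expr_counts.tsv", sep="\t")
        self.traits.to_csv(outdir / "traits.tsv", sep="\t", index=False)
        self.gene_lengths.rename("length").to_csv(outdir / "gene_lengths.tsv", sep="\t")


def simulate_expression(truth: SyntheticTruth, config: SimConfig) -> ExpressionSim:
    """Generate module-structured expression counts and correlated traits.

    Genes of module *m* share a standard-normal latent factor with
    per-gene loadings in [0.6, 1]; their log2 mean is
    ``log2(base) + scale * loading * factor + N(0, expr_noise_sd)``.
    Background genes are independent; a subset carries a planted
    High-vs-Low log2 fold change. Trait 1 (IMF %) is built from the
    standardized factor of ``truth.trait_module`` so its population
    correlation equals ``trait_module_corr``; trait 2 (m6A/A ratio) uses
    ``trait2_module_corr``, negative by convention, mirroring the
    opposite phenotype trends of fat content and global methylation.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    high, low = _sample_names(config.n_samples_per_group)
    samples = high + low
    n_s = len(samples)
    group_sign = np.array([0.5] * len(high) + [-0.5] * len(low))
    genes = truth.genes

    # module assignment: first n_modules*module_size genes, blockwise
    module_of = np.zeros(len(genes), dtype=int)
    loadings = np.zeros(len(genes))
    for m in range(config.n_modules):
        lo, hi = m * config.module_size, (m + 1) * config.module_size
        module_of[lo:hi] = m + 1
        loadings[lo:hi] = rng.uniform(0.6, 1.0, size=hi - lo)
    truth.module_assignment = {g: int(m) for g, m in zip(genes, module_of)}
    truth.loadings = {g: float(l) for g, l in zip(genes, loadings)}
    truth.trait_module = 1

    # planted DE genes among the background
    background = [i for i in range(len(genes)) if module_of[i] == 0]
    n_de = int(round(config.frac_de_genes * len(genes)))
    de_idx = rng.choice(background, size=min(n_de, len(background)), replace=False)
    de_lfc = np.zeros(len(genes))
    de_lfc[de_idx] = config.de_log2fc * rng.choice([-1.0, 1.0], size=len(de_idx))
    truth.de_genes = {genes[i]: float(de_lfc[i]) for i in de_idx}

    factors = rng.normal(size=(config.n_modules, n_s))
    # trait-linked module gets a group shift so the High group is fatter
    shift = config.group_factor_shift
    factors[truth.trait_module - 1] += shift * group_sign

    base = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=len(genes))
    log2_mu = np.log2(base)[:, None] * np.ones((1, n_s))
    for m in range(1, config.n_modules + 1):
        idx = module_of == m
        log2_mu[idx] += (
            config.module_signal_scale * loadings[idx][:, None] * factors[m - 1][None, :]
        )
    log2_mu += de_lfc[:, None] * group_sign[None, :]  # +lfc/2 High, -lfc/2 Low
    if config.expr_noise_sd > 0:
        log2_mu = log2_mu + rng.normal(0, config.expr_noise_sd, size=log2_mu.shape)

    counts = _nb_sample(rng, np.power(2.0, log2_mu), config.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    counts_df.index.name = "gene"

    # traits from the standardized trait-module factor
    f = factors[truth.trait_module - 1]
    f_std = (f - shift * np.mean(group_sign)) / np.sqrt(1.0 + (shift ** 2) * 0.25)
    r1, r2 = config.trait_module_corr, config.trait2_module_corr
    z1 = rng.normal(size=n_s)
    z2 = rng.normal(size=n_s)
    t1 = r1 * f_std + np.sqrt(1 - r1 ** 2) * z1
    t2 = r2 * f_std + np.sqrt(1 - r2 ** 2) * z2
    traits = pd.DataFrame(
        {
            "sample": samples,
            "group": ["High"] * len(high) + ["Low"] * len(low),
            "imf_pct": np.round(2.5 + 1.2 * t1, 4),
            "m6a_ratio": np.round(0.40 + 0.05 * t2, 5),
        }
    )

    lengths = pd.Series(
        {g: sum(truth.region_lengths[g]) for g in genes}, name="length"
    ) if truth.region_lengths else pd.Series(
        np.full(len(genes), 1500), index=genes, name="length"
    )

    return ExpressionSim(
        counts=counts_df,
        traits=traits,
        gene_lengths=lengths.loc[genes],
        latent_log2_mu=pd.DataFrame(log2_mu, index=genes, columns=samples),
        module_factors=pd.DataFrame(
            factors, index=[f"module_{m + 1}" for m in range(config.n_modules)],
            columns=samples,
        ),
    )


@dataclass
class SyntheticDataset:
    """Bundle of all synthetic inputs plus the truth manifest."""

    config: SimConfig
    transcriptome: TranscriptomeSim
    merip: MeripSim
    expression: ExpressionSim

    @property
    def truth(self) -> SyntheticTruth:
        return self.transcriptome.truth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.transcriptome.write_fasta(outdir / "transcripts.fa")
        self.transcriptome.write_gtf(outdir / "models.gtf")
        self.merip.write(outdir)
        self.expression.write(outdir)
        self.truth.to_json(outdir / "truth.json")


def simulate_dataset(config: SimConfig | None = None, outdir: str | Path | None = None) -> SyntheticDataset:
    """Run all three generators under one config; optionally write to disk."""
    config = config or SimConfig()
    tx = simulate_transcriptome(config)
    merip = simulate_merip_counts(tx.truth, config)
    expr = simulate_expression(tx.truth, config)
    ds = SyntheticDataset(config=config, transcriptome=tx, merip=merip, expression=expr)
    if outdir is not None:
        ds.write(outdir)
    return ds
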