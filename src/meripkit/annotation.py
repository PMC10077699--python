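"""Transcript-region annotation, metagene profiling, RRACH motif analysis.

Transcript models are read from GTF (1-based closed, converted to the
package-wide 0-based half-open convention at the boundary). Peaks are
assigned to 5'UTR / CDS / 3'UTR by maximal overlap with priority
3UTR > 5UTR > CDS on ties — the m6A literature's convention that stop
codon-proximal 3'UTR signal dominates. The metagene profile maps each
peak midpoint to transcript coordinates, rescales within its region to
[0, 1] and histograms over three equal-width region axes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from meripkit.intervals import GenomicInterval

__all__ = [
    "TranscriptModel",
    "MetageneProfile",
    "read_gtf",
    "read_fasta",
    "segment_transcript",
    "genomic_to_transcript",
    "assign_peak_region",
    "map_peaks_to_genes",
    "peak_sequences",
    "metagene_profile",
    "scan_rrach",
    "dinucleotide_shuffle",
    "motif_enrichment",
]

RRACH_RE = re.compile(r"(?=([AG][AG]AC[ACT]))")
_GTF_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')

REGION_PRIORITY = {"3UTR": 3, "5UTR": 2, "CDS": 1, "intron/other": 0}


@dataclass
class TranscriptModel:
    """One transcript: exon structure and genomic CDS bounds.

    Coordinates are 0-based half-open. ``exons`` are sorted,
    non-overlapping genomic intervals; ``cds_start``/``cds_end`` are
    genomic bounds of the coding region irrespective of strand.
    """

    gene: str
    transcript: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(f"{self.transcript}: overlapping exons")
        if not (self.exons[0][0] <= self.cds_start < self.cds_end <= self.exons[-1][1]):
            raise ValueError(f"{self.transcript}: CDS outside exon span")

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0][0], self.exons[-1][1], self.strand)


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse exon and CDS records of a GTF file into transcript models.

    GTF is 1-based closed; intervals are converted to 0-based half-open
    here. Attributes must carry ``gene_id`` and ``transcript_id``.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("exon", "CDS"):
                continue
            attrs = dict(_GTF_ATTR_RE.findall(f[8]))
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id", tid)
            if tid is None:
                continue
            iv = (int(f[3]) - 1, int(f[4]))
            meta.setdefault(tid, (gid, f[0], f[6]))
            (exons if f[2] == "exon" else cds).setdefault(tid, []).append(iv)
    models = []
    for tid, (gid, chrom, strand) in meta.items():
        ex = sorted(exons.get(tid, []))
        cd = sorted(cds.get(tid, []))
        if not ex or not cd:
            continue
        models.append(
            TranscriptModel(
                gene=gid, transcript=tid, chrom=chrom, strand=strand,
                exons=ex, cds_start=cd[0][0], cds_end=cd[-1][1],
            )
        )
    return models


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id; RNA alphabet folded to DNA (U -> T)."""
    return {
        rec.id: str(rec.seq).upper().replace("U", "T")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def genomic_to_transcript(model: TranscriptModel, gpos: int) -> int | None:
    """Map a genomic position to mature-transcript coordinates.

    Returns None when the position falls outside the exons. On the
    minus strand transcript coordinates run right-to-left.
    """
    offset = 0
    tx = None
    for s, e in model.exons:
        if s <= gpos < e:
            tx = offset + (gpos - s)
            break
        offset += e - s
    if tx is None:
        return None
    if model.strand == "-":
        return model.mature_length - 1 - tx
    return tx


def segment_transcript(model: TranscriptModel) -> list[tuple[str, tuple[int, int]]]:
    """Partition the mature transcript into 5'UTR / CDS / 3'UTR intervals.

    Returns ``[(label, (tx_start, tx_end)), ...]`` in transcript order
    (5'->3'). Empty segments are omitted. On the minus strand the 5'UTR
    is the genomically rightmost UTR.
    """
    # CDS length in mature coordinates
    cds_len = sum(
        max(0, min(e, model.cds_end) - max(s, model.cds_start)) for s, e in model.exons
    )
    left_utr = sum(
        max(0, min(e, model.cds_start) - s) for s, e in model.exons
    )
    total = model.mature_length
    if model.strand == "-":
        len5 = total - left_utr - cds_len
    else:
        len5 = left_utr
    segs = [
        ("5UTR", (0, len5)),
        ("CDS", (len5, len5 + cds_len)),
        ("3UTR", (len5 + cds_len, total)),
    ]
    return [(lab, iv) for lab, iv in segs if iv[1] > iv[0]]


def _pick_longest(models: list[TranscriptModel]) -> list[TranscriptModel]:
    """One transcript per gene: the longest mature transcript."""
    best: dict[str, TranscriptModel] = {}
    for m in models:
        if m.gene not in best or m.mature_length > best[m.gene].mature_length:
            best[m.gene] = m
    return list(best.values())


def _index_by_chrom(models: list[TranscriptModel]) -> dict[str, list[TranscriptModel]]:
    idx: dict[str, list[TranscriptModel]] = {}
    for m in models:
        idx.setdefault(m.chrom, []).append(m)
    return idx


def _region_overlaps(model: TranscriptModel, peak: GenomicInterval) -> dict[str, int]:
    """Bases of overlap between the peak and each transcript region."""
    out = {"5UTR": 0, "CDS": 0, "3UTR": 0}
    segs = dict(segment_transcript(model))
    for s, e in model.exons:
        os, oe = max(s, peak.start), min(e, peak.end)
        for gpos in range(os, oe):
            tx = genomic_to_transcript(model, gpos)
            if tx is None:
                continue
            for lab, (ts, te) in segs.items():
                if ts <= tx < te:
                    out[lab] += 1
                    break
    return out


def assign_peak_region(
    peak: GenomicInterval,
    models: list[TranscriptModel] | dict[str, list[TranscriptModel]],
    longest_only: bool = True,
) -> str:
    """Label a peak 5UTR / CDS / 3UTR / intron-other by maximal overlap.

    Overlap is evaluated across all overlapping transcripts (longest
    per gene by default); ties break by priority 3UTR > 5UTR > CDS.
    """
    if isinstance(models, dict):
        cand = models.get(peak.chrom, [])
    else:
        cand = [m for m in models if m.chrom == peak.chrom]
        if longest_only:
            cand = _pick_longest(cand)
    best_label = "intron/other"
    best = (0, 0)
    for m in cand:
        if m.span.overlap(peak) == 0:
            continue
        for lab, bases in _region_overlaps(m, peak).items():
            key = (bases, REGION_PRIORITY[lab])
            if bases > 0 and key > best:
                best = key
                best_label = lab
    return best_label


@dataclass
class MetageneProfile:
    """Peak-midpoint density over scaled 5'UTR | CDS | 3'UTR axes.

    The x-axis runs 0..3 with one unit per region; ``density``
    integrates to 1 over that axis whenever any peak mapped.
    """

    density: np.ndarray
    counts: np.ndarray
    bins_per_region: int
    n_mapped: int
    n_unmapped: int

    @property
    def bin_centers(self) -> np.ndarray:
        w = 1.0 / self.bins_per_region
        return np.arange(len(self.density)) * w + w / 2

    def to_frame(self) -> pd.DataFrame:
        regions = (
            ["5UTR"] * self.bins_per_region
            + ["CDS"] * self.bins_per_region
            + ["3UTR"] * self.bins_per_region
        )
        return pd.DataFrame(
            {"x": self.bin_centers, "region": regions,
             "count": self.counts, "density": self.density}
        )


def metagene_profile(
    peaks: list[GenomicInterval],
    models: list[TranscriptModel],
    bins_per_region: int = 30,
) -> MetageneProfile:
    """Histogram peak midpoints over scaled transcript regions.

    Each peak's midpoint is mapped to the mature transcript of the
    longest overlapping model, scaled within its region to [0, 1) and
    binned; regions get ``bins_per_region`` bins each and the three
    axes are concatenated. Peaks not overlapping any exon are counted
    as unmapped.
    """
    chosen = _pick_longest(models)
    index = _index_by_chrom(chosen)
    counts = np.zeros(3 * bins_per_region, dtype=int)
    n_mapped = n_unmapped = 0
    region_order = ["5UTR", "CDS", "3UTR"]
    for peak in peaks:
        mid = (peak.start + peak.end) // 2
        placed = False
        for m in sorted(index.get(peak.chrom, []), key=lambda m: -m.mature_length):
            tx = genomic_to_transcript(m, mid)
            if tx is None:
                continue
            for ridx, (lab, (ts, te)) in enumerate(
                (lab, iv) for lab, iv in segment_transcript(m)
            ):
                if ts <= tx < te:
                    frac = (tx - ts) / (te - ts)
                    roff = region_order.index(lab)
                    b = min(int(frac * bins_per_region), bins_per_region - 1)
                    counts[roff * bins_per_region + b] += 1
                    placed = True
                    break
            if placed:
                break
        if placed:
            n_mapped += 1
        else:
            n_unmapped += 1
    width = 1.0 / bins_per_region
    total = counts.sum()
    density = counts / (total * width) if total > 0 else counts.astype(float)
    return MetageneProfile(
        density=density, counts=counts, bins_per_region=bins_per_region,
        n_mapped=n_mapped, n_unmapped=n_unmapped,
    )


def map_peaks_to_genes(
    peaks: list[GenomicInterval],
    models: list[TranscriptModel],
    ids: list[str] | None = None,
) -> pd.Series:
    """Assign each peak to the gene whose transcript it overlaps most.

    Uses the longest transcript per gene; peaks overlapping nothing map
    to NaN. Returns a Series indexed by peak id (``ids`` or positional).
    """
    chosen = _pick_longest(models)
    index = _index_by_chrom(chosen)
    out = []
    for peak in peaks:
        best_gene, best_ov = None, 0
        for m in index.get(peak.chrom, []):
            ov = m.span.overlap(peak)
            if ov > best_ov:
                best_gene, best_ov = m.gene, ov
        out.append(best_gene)
    idx = ids if ids is not None else list(range(len(peaks)))
    return pd.Series(out, index=idx, name="gene")


def peak_sequences(
    peaks: list[GenomicInterval],
    models: list[TranscriptModel],
    sequences: dict[str, str],
) -> list[str]:
    """Extract the mature-transcript subsequence under each peak.

    Each peak is projected onto the longest overlapping transcript; the
    transcript-coordinate footprint (min..max mapped exonic base) is
    sliced from that transcript's sequence. Peaks overlapping no exonic
    base are skipped.
    """
    chosen = _pick_longest(models)
    index = _index_by_chrom(chosen)
    out = []
    for peak in peaks:
        best, best_ov = None, 0
        for m in index.get(peak.chrom, []):
            ov = m.span.overlap(peak)
            if ov > best_ov and m.transcript in sequences:
                best, best_ov = m, ov
        if best is None:
            continue
        tx_pos = [
            t for gpos in range(max(peak.start, best.span.start),
                                min(peak.end, best.span.end))
            if (t := genomic_to_transcript(best, gpos)) is not None
        ]
        if not tx_pos:
            continue
        seq = sequences[best.transcript][min(tx_pos):max(tx_pos) + 1]
        if seq:
            out.append(seq)
    return out


def scan_rrach(seq: str) -> list[tuple[int, str]]:
    """All (overlapping) RRACH pentamer hits in a sequence.

    RRACH: R in {A, G}, H in {A, C, T/U}. Input may be DNA or RNA,
    any case; N never matches. Returns ``(offset, pentamer)`` pairs.
    """
    s = seq.upper().replace("U", "T")
    return [(m.start(), m.group(1)) for m in RRACH_RE.finditer(s)]


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Altschul–Erickson Euler-path shuffle on the dinucleotide multigraph:
    edge lists per source base are permuted subject to the last-exit
    edges forming a tree into the terminal vertex, then the Euler trail
    is read off. First and last base are preserved.
    """
    s = seq.upper()
    if len(s) < 3:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    vertices = list(edges.keys())
    for _ in range(10_000):
        trial = {v: list(rng.permutation(e)) for v, e in edges.items()}
        # last-exit edges must form a spanning tree oriented toward `last`
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen = {v}
            cur = v
            while cur != last:
                if cur not in trial or not trial[cur]:
                    ok = False
                    break
                cur = trial[cur][-1]
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if not ok:
            continue
        # walk the Euler trail
        out = [s[0]]
        pos = {v: 0 for v in trial}
        cur = s[0]
        n_edges = len(s) - 1
        for _ in range(n_edges):
            nxt = trial[cur][pos[cur]]
            pos[cur] += 1
            out.append(nxt)
            cur = nxt
        if len(out) == len(s):
            return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to converge")


def motif_enrichment(
    peak_seqs: list[str],
    n_shuffles: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """RRACH enrichment of peak sequences vs a dinucleotide-shuffled null.

    observed = mean RRACH hits per nt across sequences; the null
    distribution re-scans ``n_shuffles`` dinucleotide-preserving
    shuffles of every sequence. Empirical one-sided
    ``p = (1 + #null >= observed) / (1 + n_shuffles)``.
    """
    if not peak_seqs or any(len(s) == 0 for s in peak_seqs):
        raise ValueError("peak sequences must be non-empty")
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles")
    rng = np.random.default_rng(seed)
    total_nt = sum(len(s) for s in peak_seqs)
    observed = sum(len(scan_rrach(s)) for s in peak_seqs) / total_nt
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        null[i] = sum(
            len(scan_rrach(dinucleotide_shuffle(s, rng))) for s in peak_seqs
        ) / total_nt
    expected = float(null.mean())
    fold = observed / expected if expected > 0 else np.inf
    p = (1 + int((null >= observed).sum())) / (1 + n_shuffles)
    return {"observed": observed, "expected": expected, "fold": fold, "p_value": p}
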