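"""Descriptive genome-scale summaries.

TSS-anchored aggregate profiles and per-gene heat maps (the dose-dependent
5' read pile-up), enhancer-anchored aggregates, the first-5-kb fold-change
surrogate for whole-gene expression changes, nearest-gene assignment with
eRNA/gene change correlation, and the downsampling coefficient-of-variation
study of quantification stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotations_io import BinnedTrack, GeneSet, GenomicInterval, compute_rpkm
from .uve_caller import UVEPeak


@dataclass
class AggregateProfile:
    bin_offsets: np.ndarray
    values: np.ndarray
    n_regions: int
    normalization_reference: str | None = None


@dataclass
class FoldChangeRecord:
    gene_id: str
    rpkm_a: float
    rpkm_b: float
    fold: float
    short_gene: bool = False


def _rpkm_bin_values(
    track: BinnedTrack, gene, span: tuple[int, int], bin_width: int
) -> np.ndarray | None:
    """Per-bin signal around a gene's TSS in RPKM units, strand-oriented."""
    lo, hi = span
    n_bins = (hi - lo) // bin_width
    chrom = gene.interval.chrom
    if chrom not in track.data:
        return None
    per_bin = np.empty(n_bins)
    scale = (bin_width / 1000.0) * (track.total_reads / 1e6)
    for j in range(n_bins):
        off = lo + j * bin_width
        if gene.strand == "-":
            s, e = gene.tss - off - bin_width + 1, gene.tss - off + 1
        else:
            s, e = gene.tss + off, gene.tss + off + bin_width
        per_bin[j] = track.region_sum(chrom, max(s, 0), max(e, 0)) / scale
    return per_bin


def _select_genes(
    geneset: GeneSet,
    mock_track: BinnedTrack,
    min_gene_len: int,
    min_rpkm: float,
) -> list:
    keep = []
    for g in geneset:
        if len(g.interval) < min_gene_len:
            continue
        if g.interval.chrom not in mock_track.data:
            continue
        if compute_rpkm(mock_track, g.interval) < min_rpkm:
            continue
        keep.append(g)
    return keep


def aggregate_tss_profile(
    tracks: list[BinnedTrack],
    geneset: GeneSet,
    mock_track: BinnedTrack,
    min_gene_len: int = 60000,
    min_rpkm: float = 1.0,
    span: tuple[int, int] = (-2000, 60000),
    bin_width: int = 250,
    normalize_to_mock: bool = False,
) -> list[AggregateProfile]:
    """Median per-bin RPKM across long expressed genes, anchored at the TSS.

    Gene selection (length and expression filters) always uses the mock
    track; when ``normalize_to_mock`` is set each profile is divided bin-wise
    by the mock profile (so the mock profile itself becomes the unit profile).
    """
    genes = _select_genes(geneset, mock_track, min_gene_len, min_rpkm)
    if not genes:
        raise ValueError("no gene passes the length/expression filters")
    offsets = np.arange(span[0], span[1], bin_width)

    def profile(track: BinnedTrack) -> tuple[np.ndarray, int]:
        rows = [r for g in genes if (r := _rpkm_bin_values(track, g, span, bin_width)) is not None]
        return np.median(np.array(rows), axis=0), len(rows)

    mock_profile, _ = profile(mock_track)
    out = []
    for track in tracks:
        vals, n = profile(track)
        ref = None
        if normalize_to_mock:
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = np.where(mock_profile > 0, vals / mock_profile, 0.0)
            ref = "mock"
        out.append(AggregateProfile(offsets, vals, n, ref))
    return out


def aggregate_anchor_profile(
    track: BinnedTrack,
    anchors: list[tuple[str, int]],
    span: tuple[int, int] = (-5000, 5000),
    bin_width: int = 250,
) -> AggregateProfile:
    """Median per-bin RPKM around arbitrary anchor points (e.g. enhancer centers)."""
    offsets = np.arange(span[0], span[1], bin_width)
    scale = (bin_width / 1000.0) * (track.total_reads / 1e6)
    rows = []
    for chrom, center in anchors:
        if chrom not in track.data:
            continue
        row = [
            track.region_sum(chrom, max(center + o, 0), max(center + o + bin_width, 0)) / scale
            for o in offsets
        ]
        rows.append(row)
    if not rows:
        raise ValueError("no anchor on a known chromosome")
    return AggregateProfile(offsets, np.median(np.array(rows), axis=0), len(rows))


def heatmap_matrix(
    track: BinnedTrack,
    geneset: GeneSet,
    mock_track: BinnedTrack | None = None,
    min_gene_len: int = 60000,
    min_rpkm: float = 1.0,
    span: tuple[int, int] = (-2000, 60000),
    bin_width: int = 1000,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Per-gene rows min-max scaled to [0, 1], sorted by 5' signal load.

    Constant rows scale to all zeros and sort last.  Rows are ordered by
    descending sum of scaled values over the first 5 kb downstream of the
    TSS.  Returns (matrix, row gene ids, bin offsets).
    """
    mock_track = mock_track if mock_track is not None else track
    genes = _select_genes(geneset, mock_track, min_gene_len, min_rpkm)
    if not genes:
        raise ValueError("no gene passes the length/expression filters")
    offsets = np.arange(span[0], span[1], bin_width)
    rows, ids = [], []
    for g in genes:
        r = _rpkm_bin_values(track, g, span, bin_width)
        if r is None:
            continue
        lo, hi = r.min(), r.max()
        rows.append((r - lo) / (hi - lo) if hi > lo else np.zeros_like(r))
        ids.append(g.gene_id)
    mat = np.array(rows)
    first5 = (offsets >= 0) & (offsets < 5000)
    order = np.argsort(-mat[:, first5].sum(axis=1), kind="stable")
    return mat[order], [ids[i] for i in order], offsets


def fold_change_first_5kb(
    track_a: BinnedTrack,
    track_b: BinnedTrack,
    geneset: GeneSet,
    pseudocount: float = 0.25,
    whole_gene: bool = False,
) -> list[FoldChangeRecord]:
    """Per-gene (RPKM_b + c) / (RPKM_a + c) over the first 5 kb past the TSS.

    The first-5-kb window is strand-aware; genes shorter than 5 kb fall back
    to their full span and are flagged.  ``whole_gene`` switches both RPKMs
    to the full gene interval (the steady comparison side).
    """
    if track_a.total_reads <= 0 or track_b.total_reads <= 0:
        raise ValueError("both tracks need positive totals")
    out = []
    for g in geneset:
        short = len(g.interval) < 5000
        if whole_gene or short:
            iv = g.interval
        elif g.strand == "-":
            iv = GenomicInterval(g.interval.chrom, g.tss - 4999, g.tss + 1, g.strand)
        else:
            iv = GenomicInterval(g.interval.chrom, g.tss, g.tss + 5000, g.strand)
        ra = compute_rpkm(track_a, iv)
        rb = compute_rpkm(track_b, iv)
        out.append(
            FoldChangeRecord(g.gene_id, ra, rb, (rb + pseudocount) / (ra + pseudocount), short)
        )
    return out


def nearest_gene_assignment(
    peaks: list[UVEPeak], geneset: GeneSet
) -> dict[int, str]:
    """Assign each peak (by list index) to the gene with the nearest TSS.

    Distance is |peak midpoint - TSS| on the same chromosome, strand-agnostic;
    ties break to the lexicographically smaller gene_id.  Peaks on
    chromosomes without genes are left unassigned.
    """
    if len(geneset) == 0:
        raise ValueError("empty gene set")
    by_chrom: dict[str, list] = {}
    for g in geneset:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    assignment: dict[int, str] = {}
    for i, p in enumerate(peaks):
        genes = by_chrom.get(p.interval.chrom)
        if not genes:
            continue
        mid = (p.interval.start + p.interval.end) // 2
        best = min(genes, key=lambda g: (abs(mid - g.tss), g.gene_id))
        assignment[i] = best.gene_id
    return assignment


def erna_gene_change_correlation(
    peak_changes: dict[int, float],
    gene_changes: dict[str, float],
    assignment: dict[int, str],
) -> float:
    """Pearson r between per-peak and nearest-gene log2 fold changes."""
    xs, ys = [], []
    for peak_id, gene_id in assignment.items():
        if peak_id in peak_changes and gene_id in gene_changes:
            xs.append(peak_changes[peak_id])
            ys.append(gene_changes[gene_id])
    if len(xs) < 3:
        raise ValueError("need at least 3 paired changes")
    if np.var(xs) == 0 or np.var(ys) == 0:
        raise ValueError("zero variance in one variable")
    return float(stats.pearsonr(xs, ys)[0])


def downsampling_cv(
    gene_counts: pd.DataFrame,
    library_size: int,
    depths: list[int],
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Quantification stability under subsampling without replacement.

    ``gene_counts`` needs columns ``gene_id``, ``count`` (reads assigned to
    the quantified region: whole gene for steady-style input, first 5 kb for
    UV-style input) and ``length_bp`` (region length).  Reads not assigned to
    any gene make up the remainder of ``library_size``.  For each depth,
    ``reps`` subsamples are drawn (multivariate hypergeometric, equivalent to
    subsampling read labels), per-gene RPKM computed, and CV = sd/mean across
    the replicates reported.  Genes with zero reads in every replicate are
    dropped (their CV is undefined); at the full library depth every draw is
    the library itself, so CV is exactly 0.
    """
    counts = gene_counts["count"].to_numpy(np.int64)
    lengths = gene_counts["length_bp"].to_numpy(float)
    rest = int(library_size) - int(counts.sum())
    if rest < 0:
        raise ValueError("gene counts exceed library size")
    colors = np.concatenate([counts, [rest]])
    rng = np.random.default_rng(seed)
    records = []
    for depth in depths:
        if depth > library_size:
            raise ValueError(f"depth {depth} exceeds library size {library_size}")
        rpkms = np.empty((reps, len(counts)))
        for r in range(reps):
            draw = rng.multivariate_hypergeometric(colors, int(depth))[:-1]
            rpkms[r] = draw / ((lengths / 1000.0) * (depth / 1e6))
        mean = rpkms.mean(axis=0)
        sd = rpkms.std(axis=0, ddof=1) if reps > 1 else np.zeros_like(mean)
        sd[np.ptp(rpkms, axis=0) == 0] = 0.0  # identical replicates: exactly 0
        ok = mean > 0
        gids = gene_counts["gene_id"].to_numpy()[ok]
        for gid, m, s in zip(gids, mean[ok], sd[ok]):
            records.append({"depth": depth, "gene_id": gid, "cv": s / m})
    return pd.DataFrame(records, columns=["depth", "gene_id", "cv"])
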