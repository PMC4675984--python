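"""Genomic annotations, binned coverage tracks, and RPKM.

All coordinates are 0-based half-open internally.  GTF input (1-based closed)
is converted on read; BED dialects are native.  A gene's TSS is its interval
start on the plus strand and ``end - 1`` on the minus strand.

Isoform TSSs are merged in two steps mirroring how simplified annotations are
built for nascent-RNA TSS calling: identical TSSs collapse outright, and TSSs
of the same gene closer than ``merge_distance`` (default 1 kb) are
single-linkage clustered, each cluster keeping its most upstream member.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


class AnnotationParseError(ValueError):
    """Raised on a malformed annotation record; message names the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """One (possibly merged) gene entry with a strand-aware TSS.

    ``base_gene_id`` groups merged entries that originate from the same gene;
    it equals ``gene_id`` unless merging split a gene into several TSS
    clusters.
    """

    gene_id: str
    interval: GenomicInterval
    tss: int
    source_isoform_ids: tuple[str, ...] = ()
    base_gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.interval.start <= self.tss < self.interval.end:
            raise ValueError(
                f"TSS {self.tss} outside interval [{self.interval.start}, {self.interval.end})"
            )
        if not self.base_gene_id:
            object.__setattr__(self, "base_gene_id", self.gene_id)

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class GeneSet:
    """Ordered collection of gene models with unique ids."""

    genes: list[GeneModel] = field(default_factory=list)
    merge_distance: int = 1000

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene_id not unique within GeneSet")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def _tss_from_interval(iv: GenomicInterval) -> int:
    return iv.start if iv.strand == "+" else iv.end - 1


def _parse_bed12(path: str) -> list[GeneModel]:
    # Isoforms of one gene may repeat the BED name; entry ids are made unique
    # while base_gene_id keeps the shared name for TSS merging.
    genes = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise AnnotationParseError(
                    f"{path}:{lineno}: BED record needs >= 6 fields, got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise AnnotationParseError(f"{path}:{lineno}: missing/invalid strand {strand!r}")
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand)
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
            uid = name if name not in seen else f"{name}#{lineno}"
            seen.add(uid)
            base = name.split("#")[0]
            genes.append(
                GeneModel(
                    uid,
                    iv,
                    _tss_from_interval(iv),
                    source_isoform_ids=(name,),
                    base_gene_id=base,
                )
            )
    return genes


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf(path: str) -> list[GeneModel]:
    genes = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise AnnotationParseError(
                    f"{path}:{lineno}: GTF record needs 9 tab-separated fields"
                )
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "transcript":
                continue
            if strand not in ("+", "-"):
                raise AnnotationParseError(f"{path}:{lineno}: missing/invalid strand {strand!r}")
            attr = dict(_GTF_ATTR.findall(attrs))
            tid = attr.get("transcript_id") or attr.get("gene_id")
            if tid is None:
                raise AnnotationParseError(f"{path}:{lineno}: no transcript_id/gene_id attribute")
            base = attr.get("gene_id", tid)
            if tid in seen:  # duplicated transcript record
                tid = f"{tid}#{lineno}"
            seen.add(tid)
            try:
                # GTF is 1-based closed: [start, end] -> 0-based half-open.
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
            genes.append(
                GeneModel(
                    tid,
                    iv,
                    _tss_from_interval(iv),
                    source_isoform_ids=(tid,),
                    base_gene_id=base,
                )
            )
    return genes


def read_gene_annotation(path: str, format: str | None = None) -> GeneSet:
    """Read a GTF or BED6/BED12 annotation into a GeneSet (one entry per isoform).

    ``format`` is ``"GTF"`` or ``"BED12"``; when omitted it is inferred from
    the file extension.
    """
    if format is None:
        low = str(path).lower()
        format = "GTF" if low.endswith((".gtf", ".gff")) else "BED12"
    fmt = format.upper()
    if fmt == "GTF":
        genes = _parse_gtf(path)
    elif fmt in ("BED12", "BED6", "BED"):
        genes = _parse_bed12(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return GeneSet(genes)


def merge_isoform_tss(geneset: GeneSet, merge_distance: int = 1000) -> GeneSet:
    """Merge isoform TSSs per gene: identical TSSs collapse, and TSSs closer
    than ``merge_distance`` are single-linkage clustered (so a chain of TSSs
    each < 1 kb apart becomes one entry).  Each cluster is represented by its
    most upstream member: the smallest coordinate on ``+``, the largest on
    ``-``.  Idempotent.
    """
    groups: dict[tuple[str, str, str], list[GeneModel]] = {}
    order: list[tuple[str, str, str]] = []
    for g in geneset:
        key = (g.base_gene_id, g.interval.chrom, g.strand)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(g)

    merged: list[GeneModel] = []
    for key in order:
        base, chrom, strand = key
        members = sorted(groups[key], key=lambda g: g.tss)
        # single-linkage clusters along sorted TSSs; strict < merge_distance
        clusters: list[list[GeneModel]] = [[members[0]]]
        for g in members[1:]:
            if g.tss - clusters[-1][-1].tss < merge_distance:
                clusters[-1].append(g)
            else:
                clusters.append([g])
        multi = len(clusters) > 1
        for k, cluster in enumerate(clusters):
            tss = cluster[0].tss if strand == "+" else cluster[-1].tss
            start = min(g.interval.start for g in cluster)
            end = max(g.interval.end for g in cluster)
            sources = tuple(s for g in cluster for s in (g.source_isoform_ids or (g.gene_id,)))
            gid = f"{base}:{k}" if multi else base
            merged.append(
                GeneModel(
                    gid,
                    GenomicInterval(chrom, start, end, strand),
                    tss,
                    source_isoform_ids=sources,
                    base_gene_id=base,
                )
            )
    return GeneSet(merged, merge_distance=merge_distance)


@dataclass
class BinnedTrack:
    """Fixed-width per-bin counts for one sample.

    ``data`` maps chromosome name to a float vector; bin ``i`` covers
    ``[i*bin_width, (i+1)*bin_width)``.  ``total_reads`` is the library size
    used for RPKM; it need not equal the binned mass.
    """

    bin_width: int
    data: dict[str, np.ndarray]
    total_reads: float
    strand_mode: str = "combined"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.strand_mode not in ("combined", "plus", "minus"):
            raise ValueError(f"bad strand_mode {self.strand_mode!r}")
        for chrom, v in self.data.items():
            arr = np.asarray(v, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"negative bin value on {chrom}")
            self.data[chrom] = arr

    def scaled(self, factor: float) -> "BinnedTrack":
        return BinnedTrack(
            self.bin_width,
            {c: v * factor for c, v in self.data.items()},
            self.total_reads * factor,
            self.strand_mode,
        )

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        """Signal mass overlapping [start, end), counting partial bins
        fractionally (a bin half inside the region contributes half its value).
        """
        if start >= end:
            return 0.0
        v = self.data.get(chrom)
        if v is None:
            return 0.0
        w = self.bin_width
        lo = max(0, start // w)
        hi = min(len(v), -(-end // w))
        if lo >= hi:
            return 0.0
        idx = np.arange(lo, hi)
        bin_starts = idx * w
        overlap = np.minimum(bin_starts + w, end) - np.maximum(bin_starts, start)
        return float(np.sum(v[lo:hi] * (overlap / w)))

    def bin_values(self, chrom: str, first_bin: int, n_bins: int) -> tuple[np.ndarray, bool]:
        """Bin values for ``n_bins`` bins starting at index ``first_bin``;
        out-of-range bins are zero-filled.  Returns (values, clipped_flag)."""
        out = np.zeros(n_bins)
        v = self.data.get(chrom)
        clipped = False
        if v is None:
            return out, True
        for j in range(n_bins):
            i = first_bin + j
            if 0 <= i < len(v):
                out[j] = v[i]
            else:
                clipped = True
        return out, clipped


def bin_coverage(
    records: pd.DataFrame,
    bin_width: int,
    strand_mode: str = "combined",
    chrom_sizes: dict[str, int] | None = None,
    total_reads: float | None = None,
    mode: str = "fractional",
) -> BinnedTrack:
    """Aggregate reads or bedGraph records into fixed-width bins.

    ``records`` needs columns ``chrom``, ``start``, ``end`` and optionally
    ``value`` (default 1 per record, i.e. one read) and ``strand`` (needed for
    ``mode="five_prime"`` on minus-strand reads).  In the default
    ``fractional`` mode a record's value is spread uniformly over its span, so
    each overlapped bin receives ``value * overlap/length``; in ``five_prime``
    mode the whole value lands in the bin holding the record's 5' end
    (GRO-cap-like data).  ``total_reads`` defaults to the summed record values.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if mode not in ("fractional", "five_prime"):
        raise ValueError(f"bad mode {mode!r}")
    cols = set(records.columns)
    if not {"chrom", "start", "end"} <= cols:
        raise ValueError("records need chrom/start/end columns")
    if len(records) and (records["start"].min() < 0):
        raise ValueError("negative coordinates in coverage records")

    sizes: dict[str, int] = dict(chrom_sizes or {})
    data: dict[str, np.ndarray] = {}
    for chrom, sz in sizes.items():
        data[chrom] = np.zeros(-(-sz // bin_width))

    value = records["value"].to_numpy(float) if "value" in cols else np.ones(len(records))
    strand = records["strand"].to_numpy() if "strand" in cols else np.full(len(records), "+")
    chroms = records["chrom"].to_numpy()
    starts = records["start"].to_numpy(int)
    ends = records["end"].to_numpy(int)

    for chrom in pd.unique(chroms):
        m = chroms == chrom
        s, e, v, st = starts[m], ends[m], value[m], strand[m]
        if chrom not in data:
            n = int(max(e.max(), sizes.get(chrom, 0)))
            data[chrom] = np.zeros(-(-n // bin_width) or 1)
        vec = data[chrom]
        if mode == "five_prime":
            pos = np.where(st == "-", e - 1, s)
            np.add.at(vec, np.minimum(pos // bin_width, len(vec) - 1), v)
        else:
            for si, ei, vi in zip(s, e, v):
                if ei <= si:
                    continue
                b0, b1 = si // bin_width, (ei - 1) // bin_width
                if b0 == b1:
                    vec[b0] += vi
                    continue
                length = ei - si
                for b in range(b0, min(b1, len(vec) - 1) + 1):
                    lo = max(si, b * bin_width)
                    hi = min(ei, (b + 1) * bin_width)
                    vec[b] += vi * (hi - lo) / length

    total = float(value.sum()) if total_reads is None else float(total_reads)
    return BinnedTrack(bin_width, data, total, strand_mode)


def compute_rpkm(track: BinnedTrack, interval: GenomicInterval) -> float:
    """Reads per kilobase of interval per million mapped reads."""
    if track.total_reads <= 0:
        raise ValueError("track has no reads; RPKM undefined")
    reads = track.region_sum(interval.chrom, interval.start, interval.end)
    kb = len(interval) / 1000.0
    return reads / (kb * track.total_reads / 1e6)


def harmonize_tracks(*tracks: BinnedTrack) -> tuple[BinnedTrack, ...]:
    """Zero-pad tracks onto a common chromosome set and bin-grid length.

    Tracks built from separate coverage files infer chromosome extents from
    their own data; this aligns them so paired operations can compare bins.
    """
    widths = {t.bin_width for t in tracks}
    if len(widths) != 1:
        raise ValueError("tracks have different bin widths")
    chroms: dict[str, int] = {}
    for t in tracks:
        for c, v in t.data.items():
            chroms[c] = max(chroms.get(c, 0), len(v))
    out = []
    for t in tracks:
        data = {}
        for c, n in chroms.items():
            v = np.zeros(n)
            if c in t.data:
                v[: len(t.data[c])] = t.data[c]
            data[c] = v
        out.append(BinnedTrack(t.bin_width, data, t.total_reads, t.strand_mode))
    return tuple(out)


# ---------------------------------------------------------------------------
# plain-text serialization


def read_chrom_sizes(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_bedgraph(track: BinnedTrack, path: str) -> None:
    """One record per non-zero bin; exact round-trip with read_bedgraph_track."""
    w = track.bin_width
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            v = track.data[chrom]
            for i in np.flatnonzero(v):
                fh.write(f"{chrom}\t{i * w}\t{(i + 1) * w}\t{v[i]:.10g}\n")


def read_bedgraph(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    return df


def read_bedgraph_track(
    path: str,
    bin_width: int,
    strand_mode: str = "combined",
    total_reads: float | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> BinnedTrack:
    return bin_coverage(
        read_bedgraph(path),
        bin_width,
        strand_mode=strand_mode,
        total_reads=total_reads,
        chrom_sizes=chrom_sizes,
    )


def write_bed6(intervals, names, scores, path: str) -> None:
    with open(path, "w") as fh:
        for iv, name, score in zip(intervals, names, scores):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


def write_bed12(geneset: GeneSet, path: str) -> None:
    with open(path, "w") as fh:
        for g in geneset:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\t"
                f"{iv.start}\t{iv.end}\t0\t1\t{len(iv)},\t0,\n"
            )


def read_bed_intervals(path: str) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out
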