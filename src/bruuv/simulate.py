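"""Mechanistic paired mock/UV track simulator with ground truth.

The lesion model is a homogeneous Poisson process on the transcribed strand
at ``rate_per_bp_per_J`` * dose lesions per bp (default rate 1e-5, i.e. one
transcription-blocking photoproduct per 100 kb per J/m^2, so one lesion per
5 kb at 20 J/m^2).  A polymerase initiating at the TSS survives to offset x
with probability exp(-lambda x) where lambda = rate * dose; marginalizing
lesion placement analytically, the expected genic read density at
strand-oriented offset x is e_g * exp(-lambda x).  The mock sample is dose 0
(uniform density over the gene body).  Enhancers emit bidirectionally with a
symmetric triangular kernel (half-width 1 kb) whose amplitude is multiplied
by the stabilization factor s >= 1 in the UV sample only - labile eRNA is
protected from exosome degradation when its polymerase stalls.  Reads are
drawn multinomially to the requested depths, so generated library sizes are
exact and depth-scaling tests are deterministic in total.

``explicit_polymerase_density`` provides a slower per-lesion validation mode:
it places actual Poisson lesions and truncates polymerase runs at the first
lesion, converging to the same expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotations_io import (
    BinnedTrack,
    GeneModel,
    GeneSet,
    GenomicInterval,
    merge_isoform_tss,
    write_bed6,
    write_bed12,
    write_bedgraph,
)

DEFAULT_LESION_RATE = 1e-5  # lesions per bp per J/m^2: 1 per 100 kb per J/m^2


@dataclass
class LesionModel:
    rate_per_bp_per_J: float = DEFAULT_LESION_RATE
    dose_J: float = 20.0

    def __post_init__(self) -> None:
        if self.rate_per_bp_per_J <= 0:
            raise ValueError("lesion rate must be positive")
        if self.dose_J < 0:
            raise ValueError("dose cannot be negative")

    @property
    def lam(self) -> float:
        """Lesions per bp at this dose."""
        return self.rate_per_bp_per_J * self.dose_J


@dataclass
class SimEnhancer:
    chrom: str
    center: int
    base_amplitude: float
    stabilization: float = 5.0  # UV-sample amplitude multiplier s >= 1

    def __post_init__(self) -> None:
        if self.stabilization < 1:
            raise ValueError("stabilization factor must be >= 1")


@dataclass
class SimGenome:
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    expression: dict[str, float]  # gene_id -> weight e_g
    enhancers: list[SimEnhancer] = field(default_factory=list)


@dataclass
class SimTruth:
    lesions: dict[str, np.ndarray]
    active_tss: list[tuple[str, int, str, str]]  # chrom, tss, strand, gene_id
    enhancer_intervals: list[GenomicInterval]


def place_lesions(length: int, model: LesionModel, seed_or_rng) -> np.ndarray:
    """Sorted lesion positions of a homogeneous Poisson process on [0, length)."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    count = rng.poisson(length * model.lam)
    return np.sort(rng.uniform(0, length, size=count))


ENHANCER_HALF_WIDTH = 1000


def _triangular_kernel(bin_width: int) -> np.ndarray:
    """Per-bin mass of a symmetric triangular kernel of half-width 1 kb."""
    half = ENHANCER_HALF_WIDTH
    edges = np.arange(-half, half + bin_width, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0
    kern = np.clip(1.0 - np.abs(centers) / half, 0.0, None)
    return kern / kern.sum()


def expected_density(
    genome: SimGenome,
    model: LesionModel,
    bin_width: int,
    uv: bool,
    background_fraction: float = 0.0,
) -> dict[str, np.ndarray]:
    """Expected (unnormalized) per-bin read intensity for one sample.

    ``background_fraction`` of the total intensity is spread uniformly over
    all bins, emulating the low level of unassigned/background reads present
    in real libraries.
    """
    lam = model.lam if uv else 0.0
    dens = {
        c: np.zeros(-(-size // bin_width)) for c, size in genome.chrom_sizes.items()
    }
    for g in genome.genes:
        e_g = genome.expression[g.gene_id]
        vec = dens[g.interval.chrom]
        n = len(g.interval) // bin_width
        x = (np.arange(n) + 0.5) * bin_width  # offset of bin midpoint from TSS
        surv = e_g * np.exp(-lam * x)
        if g.strand == "-":
            b1 = (g.tss + 1) // bin_width
            b0 = max(b1 - n, 0)
            vec[b0:b1] += surv[: b1 - b0][::-1]
        else:
            b0 = g.tss // bin_width
            b1 = min(b0 + n, len(vec))
            vec[b0:b1] += surv[: b1 - b0]
    kern = _triangular_kernel(bin_width)
    half_bins = len(kern) // 2
    # stabilization is a UV effect: an unirradiated "UV" sample is a mock
    stabilized = uv and model.dose_J > 0
    for enh in genome.enhancers:
        amp = enh.base_amplitude * (enh.stabilization if stabilized else 1.0)
        vec = dens[enh.chrom]
        c = enh.center // bin_width
        lo, hi = c - half_bins, c - half_bins + len(kern)
        klo, khi = max(0, -lo), len(kern) - max(0, hi - len(vec))
        vec[max(lo, 0) : min(hi, len(vec))] += amp * kern[klo:khi]
    if background_fraction > 0:
        total = sum(v.sum() for v in dens.values())
        n_bins = sum(len(v) for v in dens.values())
        u = background_fraction / (1.0 - background_fraction) * total / n_bins
        for v in dens.values():
            v += u
    return dens


def explicit_polymerase_density(
    gene_length: int,
    model: LesionModel,
    n_polymerases: int,
    bin_width: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Validation mode: per-polymerase truncation at the first sampled lesion.

    Each polymerase's transcript spans [0, min(first lesion, gene end)); the
    per-bin occupancy of transcript 3' ends converges to the exp(-lambda x)
    survival density used by ``expected_density``.
    """
    n_bins = gene_length // bin_width
    counts = np.zeros(n_bins)
    for _ in range(n_polymerases):
        lesions = place_lesions(gene_length, model, rng)
        stop = lesions[0] if lesions.size else gene_length
        b = min(int(stop) // bin_width, n_bins - 1)
        counts[b] += 1
    return counts


def _sample_track(
    dens: dict[str, np.ndarray], depth: int, bin_width: int, rng: np.random.Generator
) -> BinnedTrack:
    chroms = sorted(dens)
    flat = np.concatenate([dens[c] for c in chroms])
    total = flat.sum()
    if total <= 0:
        raise ValueError("empty genome: zero total intensity")
    draw = rng.multinomial(depth, flat / total)
    data = {}
    i = 0
    for c in chroms:
        n = len(dens[c])
        data[c] = draw[i : i + n].astype(float)
        i += n
    return BinnedTrack(bin_width, data, float(depth))


def simulate_paired_tracks(
    genome: SimGenome,
    model: LesionModel,
    depth_mock: int = 1_000_000,
    depth_uv: int = 1_000_000,
    bin_width: int = 250,
    seed: int = 0,
    background_fraction: float = 0.0,
) -> tuple[BinnedTrack, BinnedTrack, SimTruth]:
    """Draw a paired mock/UV experiment; totals equal the requested depths."""
    if depth_mock <= 0 or depth_uv <= 0:
        raise ValueError("depths must be positive")
    if not genome.genes and not genome.enhancers:
        raise ValueError("empty genome")
    rng = np.random.default_rng(seed)
    mock = _sample_track(
        expected_density(genome, model, bin_width, uv=False, background_fraction=background_fraction),
        depth_mock, bin_width, rng,
    )
    uv = _sample_track(
        expected_density(genome, model, bin_width, uv=True, background_fraction=background_fraction),
        depth_uv, bin_width, rng,
    )
    lesions = {
        c: place_lesions(size, model, rng) for c, size in sorted(genome.chrom_sizes.items())
    }
    truth = SimTruth(
        lesions,
        [(g.interval.chrom, g.tss, g.strand, g.gene_id) for g in genome.genes],
        [
            GenomicInterval(
                e.chrom,
                max(e.center - ENHANCER_HALF_WIDTH, 0),
                e.center + ENHANCER_HALF_WIDTH,
            )
            for e in genome.enhancers
        ],
    )
    return mock, uv, truth


def make_step_track(
    n_genes: int = 200,
    frac_active: float = 0.5,
    step_sigma: float = 5.0,
    noise_sd: float = 1.0,
    baseline: float = 4.0,
    bin_width: int = 250,
    gene_length: int = 60_000,
    spacing: int = 80_000,
    seed: int = 0,
) -> tuple[BinnedTrack, GeneSet, dict[str, bool]]:
    """Step-signal benchmark for the TSS caller.

    ``n_genes`` plus-strand genes laid out along one chromosome; a fraction
    ``frac_active`` get a coverage step of ``step_sigma`` noise standard
    deviations starting at their TSS, the rest stay at the noisy baseline.
    Returns the track, the (merged) gene set, and the ground-truth activity
    map keyed by gene_id.
    """
    rng = np.random.default_rng(seed)
    active = rng.random(n_genes) < frac_active
    length = n_genes * spacing + 2 * spacing
    n_bins = length // bin_width
    v = np.clip(rng.normal(baseline, noise_sd, n_bins), 0.0, None)
    genes = []
    truth = {}
    for i in range(n_genes):
        tss = spacing + i * spacing
        gid = f"g{i:03d}"
        genes.append(GeneModel(gid, GenomicInterval("chrS", tss, tss + gene_length, "+"), tss))
        truth[gid] = bool(active[i])
        if active[i]:
            b0, b1 = tss // bin_width, (tss + gene_length) // bin_width
            v[b0:b1] += step_sigma * noise_sd
    track = BinnedTrack(bin_width, {"chrS": v}, float(v.sum()))
    return track, merge_isoform_tss(GeneSet(genes)), truth


def make_two_step_track(
    separation_bp: int,
    step: float = 5.0,
    bin_width: int = 250,
    tss_a: int = 25_000,
    gene_length: int = 60_000,
    chrom_len: int = 150_000,
) -> tuple[BinnedTrack, GeneSet]:
    """Two clean coverage steps ``separation_bp`` apart, annotated as two
    isoform TSSs of one gene (so the 1-kb annotation merge rule applies).

    The steps are noise-free; each plateau's emission sd therefore sits at
    the Gaussian sd floor, and ``step`` is expressed in multiples of that
    floor times ten (the default 5.0 is >= 5 emission sds after
    normalization).  Used to probe the caller's geometric resolution;
    robustness to noise is a separate benchmark (make_step_track).
    """
    tss_b = tss_a + separation_bp
    n_bins = chrom_len // bin_width
    v = np.zeros(n_bins)
    bins = np.arange(n_bins) * bin_width
    v[bins >= tss_a] += step
    v[bins >= tss_b] += step
    track = BinnedTrack(bin_width, {"chr1": v}, float(v.sum()))
    isoforms = [
        GeneModel("g.1", GenomicInterval("chr1", tss_a, tss_a + gene_length, "+"), tss_a, base_gene_id="g"),
        GeneModel("g.2", GenomicInterval("chr1", tss_b, tss_b + gene_length, "+"), tss_b, base_gene_id="g"),
    ]
    return track, merge_isoform_tss(GeneSet(isoforms))


DEFAULT_SIM_CONFIG = {
    "n_chroms": 2,
    "chrom_size": 12_000_000,
    "n_genes": 60,
    "n_enhancers": 24,
    "gene_length_range": [20_000, 90_000],
    "dose_J": 20.0,
    "stabilization": 5.0,
    "enhancer_amplitude": 0.02,  # fraction of a typical gene's weight
    "depth_mock": 1_000_000,
    "depth_uv": 1_000_000,
    "bin_width": 250,
    "background_fraction": 0.0,
}


def make_genome(config: dict | None = None, seed: int = 0) -> SimGenome:
    """Random non-overlapping genes and intergenic enhancers.

    Genes are laid left to right with >= 60 kb intergenic gaps (enhancers go
    in the gaps, >= 15 kb from any gene); expression weights are log-normal
    (sigma = 1), emulating the wide dynamic range of nascent transcription.
    """
    cfg = dict(DEFAULT_SIM_CONFIG, **(config or {}))
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(cfg["n_chroms"])]
    sizes = {c: int(cfg["chrom_size"]) for c in chroms}
    genes: list[GeneModel] = []
    enhancers: list[SimEnhancer] = []
    expression: dict[str, float] = {}
    n_per_chrom = -(-cfg["n_genes"] // len(chroms))
    e_per_chrom = -(-cfg["n_enhancers"] // len(chroms))
    gmin, gmax = cfg["gene_length_range"]
    gap = 60_000
    gi = ei = 0
    for c in chroms:
        pos = 50_000
        placed = 0
        while placed < n_per_chrom and gi < cfg["n_genes"]:
            length = int(rng.integers(gmin, gmax + 1))
            if pos + length + gap > sizes[c]:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(c, pos, pos + length, strand)
            gid = f"gene{gi:03d}"
            genes.append(GeneModel(gid, iv, iv.start if strand == "+" else iv.end - 1))
            expression[gid] = float(rng.lognormal(0.0, 1.0))
            if ei < cfg["n_enhancers"] and placed % (n_per_chrom // e_per_chrom or 1) == 0:
                center = pos + length + gap // 2
                enhancers.append(
                    SimEnhancer(
                        c,
                        center,
                        cfg["enhancer_amplitude"] * float(np.mean(list(expression.values()))),
                        cfg["stabilization"],
                    )
                )
                ei += 1
            pos += length + gap
            placed += 1
            gi += 1
    return SimGenome(sizes, genes, expression, enhancers)


def make_fixture(outdir: str, seed: int = 0, config: dict | None = None) -> dict[str, str]:
    """Write a deterministic paired fixture; files round-trip through the IO layer.

    Produces mock.bedGraph, uv.bedGraph, genes.bed12, truth_tss.bed and
    truth_enhancers.bed under ``outdir`` and returns their paths.
    """
    cfg = dict(DEFAULT_SIM_CONFIG, **(config or {}))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome = make_genome(cfg, seed=seed)
    model = LesionModel(dose_J=cfg["dose_J"])
    mock, uv, truth = simulate_paired_tracks(
        genome, model, cfg["depth_mock"], cfg["depth_uv"], cfg["bin_width"],
        seed=seed, background_fraction=cfg["background_fraction"],
    )
    paths = {k: str(out / v) for k, v in {
        "mock": "mock.bedGraph",
        "uv": "uv.bedGraph",
        "genes": "genes.bed12",
        "truth_tss": "truth_tss.bed",
        "truth_enhancers": "truth_enhancers.bed",
    }.items()}
    write_bedgraph(mock, paths["mock"])
    write_bedgraph(uv, paths["uv"])
    geneset = merge_isoform_tss(GeneSet(genome.genes))
    write_bed12(geneset, paths["genes"])
    tss_iv = [GenomicInterval(c, t, t + 1, s) for c, t, s, _ in truth.active_tss]
    write_bed6(tss_iv, [gid for *_, gid in truth.active_tss], [1] * len(tss_iv), paths["truth_tss"])
    write_bed6(
        truth.enhancer_intervals,
        [f"enh{i}" for i in range(len(truth.enhancer_intervals))],
        [1] * len(truth.enhancer_intervals),
        paths["truth_enhancers"],
    )
    return paths
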