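"""UV-enhancement (UVE) peak calling with a beta-binomial HMM.

After depth scaling, each read in a bin is treated as a Bernoulli trial for
"came from the UV sample"; the per-bin fraction of UV reads (f_UV) is the
observable.  Gene bodies far downstream of the TSS are UV-*repressed*
(elongating polymerases hit lesions before reaching them), so bins more than
``tss_exclusion_bp`` (default 20 kb) into genes expressed at >= ``rpkm_min``
(default 0.25 RPKM, mock sample) train the UVR state: the per-gene pooled
f_UV values give beta shape parameters (alpha, beta) by moment matching, and
the UVE state is the reflected beta (beta, alpha), so bins that look strongly
UVR look weakly UVE and vice versa.  Emissions are beta-binomial in the
rounded per-bin counts, and a two-state Viterbi pass with symmetric
transition probability (default 0.005) segments each chromosome; maximal
runs of UVE bins are reported as peaks.  Only gene annotations are used for
training, so peaks can fall anywhere in the genome; intergenic peaks
(overlapping no gene / transcription-unit exclusion interval) are putative
enhancers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy.special import betaln, gammaln

from .annotations_io import BinnedTrack, GeneSet, GenomicInterval, compute_rpkm
from .normalize import scale_pair_to_common_depth, smooth_track


@dataclass
class UveHmmConfig:
    bin_width: int = 250
    rpkm_min: float = 0.25
    tss_exclusion_bp: int = 20000
    p_transition: float = 0.005
    pooling: str = "per_gene"  # or "per_bin": mean of per-bin f_UV values

    def __post_init__(self) -> None:
        if not 0 < self.p_transition < 1:
            raise ValueError("p_transition must lie in (0, 1)")


@dataclass(frozen=True)
class BetaParams:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


@dataclass
class PairedBinSeries:
    """Per-chromosome scaled mock/UV counts with f_UV and rounded totals."""

    bin_width: int
    mock: dict[str, np.ndarray]
    uv: dict[str, np.ndarray]
    fuv: dict[str, np.ndarray]  # NaN where the bin total is zero
    k: dict[str, np.ndarray]  # rounded UV count
    n: dict[str, np.ndarray]  # rounded total (k + rounded mock)

    def chroms(self) -> list[str]:
        return sorted(self.mock)


@dataclass
class UVEPeak:
    interval: GenomicInterval
    n_bins: int
    mean_fuv: float
    rpkm_mock: float = 0.0
    rpkm_uv: float = 0.0
    intergenic: bool = True


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def compute_fuv(mock: BinnedTrack, uv: BinnedTrack) -> PairedBinSeries:
    """Per-bin UV read fraction on already depth-scaled, smoothed tracks.

    f_UV = uv / (uv + mock) where the scaled total is positive, NaN (missing)
    elsewhere.  Scaled counts are rounded half-up to integers for the
    beta-binomial: k = round(uv), n = k + round(mock), which keeps k <= n.
    """
    if mock.bin_width != uv.bin_width:
        raise ValueError("bin widths differ between the paired tracks")
    if set(mock.data) != set(uv.data):
        raise ValueError("chromosome sets differ between the paired tracks")
    fuv, kk, nn, mo, uvv = {}, {}, {}, {}, {}
    for chrom in mock.data:
        m, u = mock.data[chrom], uv.data[chrom]
        if m.shape != u.shape:
            raise ValueError(f"bin grids differ on {chrom}")
        tot = m + u
        f = np.full(m.shape, np.nan)
        pos = tot > 0
        f[pos] = u[pos] / tot[pos]
        k = _round_half_up(u)
        n = k + _round_half_up(m)
        fuv[chrom], kk[chrom], nn[chrom] = f, k, n
        mo[chrom], uvv[chrom] = m.copy(), u.copy()
    return PairedBinSeries(mock.bin_width, mo, uvv, fuv, kk, nn)


def collect_training_fuv(
    paired: PairedBinSeries,
    geneset: GeneSet,
    mock_track: BinnedTrack,
    cfg: UveHmmConfig | None = None,
) -> np.ndarray:
    """Per-gene cumulative f_UV from the presumptive UV-repressed gene bodies.

    Qualifying genes have mock RPKM >= rpkm_min and length > tss_exclusion_bp;
    their bins lying fully more than tss_exclusion_bp downstream of the TSS
    (strand-aware) contribute.  "Cumulative" pools a gene's UV and total
    scaled counts (sum uv / sum total); the per-bin alternative averages the
    bin f_UV values instead.  Genes with zero pooled total are dropped.
    """
    cfg = cfg or UveHmmConfig()
    w = paired.bin_width
    out = []
    for g in geneset:
        iv = g.interval
        if len(iv) <= cfg.tss_exclusion_bp or iv.chrom not in paired.mock:
            continue
        if compute_rpkm(mock_track, iv) < cfg.rpkm_min:
            continue
        if g.strand == "-":
            lo, hi = iv.start, g.tss - cfg.tss_exclusion_bp + 1
        else:
            lo, hi = g.tss + cfg.tss_exclusion_bp, iv.end
        b0, b1 = -(-lo // w), hi // w  # bins fully inside [lo, hi)
        b1 = min(b1, len(paired.mock[iv.chrom]))
        if b1 <= b0:
            continue
        u = paired.uv[iv.chrom][b0:b1]
        m = paired.mock[iv.chrom][b0:b1]
        if cfg.pooling == "per_bin":
            f = paired.fuv[iv.chrom][b0:b1]
            f = f[~np.isnan(f)]
            if f.size == 0:
                continue
            out.append(float(f.mean()))
        else:
            tot = float(u.sum() + m.sum())
            if tot <= 0:
                continue
            out.append(float(u.sum()) / tot)
    if not out:
        raise ValueError("cannot train UVR state: no qualifying gene")
    return np.asarray(out)


def fit_beta_by_moments(values: np.ndarray) -> BetaParams:
    """Invert beta mean/variance: c = mu(1-mu)/v - 1, alpha = mu c, beta = (1-mu) c."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    mu = x.mean()
    v = x.var(ddof=1)
    if v <= 0:
        raise ValueError("zero variance: beta fit undefined")
    bound = mu * (1.0 - mu)
    if v >= bound:
        raise ValueError("variance exceeds Bernoulli bound mu(1-mu)")
    c = bound / v - 1.0
    return BetaParams(mu * c, (1.0 - mu) * c)


def reflect_beta(params: BetaParams) -> BetaParams:
    """Density of 1 - f under the original beta; an involution."""
    return BetaParams(params.beta, params.alpha)


def beta_binomial_log_pmf(k, n, params: BetaParams):
    """log P(K = k | n, alpha, beta) via log-gamma; n = 0 gives log 1 = 0."""
    k = np.asarray(k)
    n = np.asarray(n)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n")
    choose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    ll = choose + betaln(k + params.alpha, n - k + params.beta) - betaln(
        params.alpha, params.beta
    )
    ll = np.where(n == 0, 0.0, ll)
    return float(ll) if ll.ndim == 0 else ll


def _viterbi_two_state(log_em: np.ndarray, p_transition: float) -> np.ndarray:
    """Generic two-state Viterbi, symmetric transitions, uniform start.

    ``log_em`` is (n, 2); returns the 0/1 state path.
    """
    n = log_em.shape[0]
    stay = np.log1p(-p_transition)
    switch = np.log(p_transition)
    delta = np.log(0.5) + log_em[0]
    back = np.zeros((n, 2), dtype=np.int8)
    # Runs of uninformative bins (zero emissions both states) make early and
    # late switches exactly tied; prefer the state-0 (UVR) predecessor unless
    # the alternative wins by more than float noise, so peaks never extend
    # over evidence-free bins.
    tol = 1e-9
    for t in range(1, n):
        into0 = delta + np.array([stay, switch])
        into1 = delta + np.array([switch, stay])
        back[t, 0] = int(into0[1] > into0[0] + tol)
        back[t, 1] = int(into1[1] > into1[0] + tol)
        delta = np.array([into0.max(), into1.max()]) + log_em[t]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def segment_uve(
    paired: PairedBinSeries,
    uvr: BetaParams,
    uve: BetaParams,
    p_transition: float = 0.005,
    mock_track: BinnedTrack | None = None,
    uv_track: BinnedTrack | None = None,
) -> tuple[dict[str, np.ndarray], list[UVEPeak]]:
    """Viterbi segmentation per chromosome; runs of UVE bins become peaks.

    Missing bins (zero total) emit log 1 in both states, so they never break
    a peak on their own but carry no evidence.  Peaks report mean f_UV over
    their informative bins and, when the tracks are supplied, mock/UV RPKM
    over the peak interval.
    """
    paths: dict[str, np.ndarray] = {}
    peaks: list[UVEPeak] = []
    w = paired.bin_width
    for chrom in paired.chroms():
        k, n = paired.k[chrom], paired.n[chrom]
        log_em = np.stack(
            [beta_binomial_log_pmf(k, n, uvr), beta_binomial_log_pmf(k, n, uve)],
            axis=1,
        )
        path = _viterbi_two_state(log_em, p_transition)
        paths[chrom] = path
        # Bins with zero total carry no evidence; the Viterbi path extends the
        # flanking state across them (delaying a switch saves one stay
        # factor), which would smear peaks over read-free deserts.  Peaks are
        # therefore restricted to evidence-bearing UVE bins: runs split at
        # missing bins.
        in_peak = np.flatnonzero((path == 1) & (n > 0))
        if in_peak.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(in_peak) > 1) + 1
        for run in np.split(in_peak, breaks):
            iv = GenomicInterval(chrom, int(run[0]) * w, (int(run[-1]) + 1) * w)
            f = paired.fuv[chrom][run[0] : run[-1] + 1]
            f = f[~np.isnan(f)]
            peak = UVEPeak(iv, len(run), float(f.mean()) if f.size else float("nan"))
            if mock_track is not None:
                peak.rpkm_mock = compute_rpkm(mock_track, iv)
            if uv_track is not None:
                peak.rpkm_uv = compute_rpkm(uv_track, iv)
            peaks.append(peak)
    return paths, peaks


def filter_intergenic(
    peaks: list[UVEPeak],
    exclusion: list[GenomicInterval],
    intergenic_only: bool = False,
) -> list[UVEPeak]:
    """Mark peaks overlapping (>= 1 bp, half-open) any exclusion interval."""
    trees: dict[str, IntervalTree] = {}
    for iv in exclusion:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    for p in peaks:
        tree = trees.get(p.interval.chrom)
        p.intergenic = not (tree and tree.overlap(p.interval.start, p.interval.end))
    return [p for p in peaks if p.intergenic] if intergenic_only else peaks


def call_uve_peaks(
    mock: BinnedTrack,
    uv: BinnedTrack,
    geneset: GeneSet,
    cfg: UveHmmConfig | None = None,
    exclusion: list[GenomicInterval] | None = None,
    smooth: bool = True,
) -> tuple[list[UVEPeak], BetaParams]:
    """End-to-end UVE pipeline on raw binned tracks.

    Wavelet smoothing first, then common-depth scaling, f_UV, UVR training
    from gene bodies, reflection for UVE, genome-wide segmentation, and
    intergenic annotation against ``exclusion`` (defaulting to the gene
    intervals themselves).  Returns the peaks and the fitted UVR parameters.
    """
    cfg = cfg or UveHmmConfig()
    if smooth:
        mock, uv = smooth_track(mock), smooth_track(uv)
    mock_s, uv_s, _p0 = scale_pair_to_common_depth(mock, uv)
    paired = compute_fuv(mock_s, uv_s)
    train = collect_training_fuv(paired, geneset, mock_s, cfg)
    uvr = fit_beta_by_moments(train)
    uve = reflect_beta(uvr)
    _, peaks = segment_uve(
        paired, uvr, uve, cfg.p_transition, mock_track=mock_s, uv_track=uv_s
    )
    excl = exclusion if exclusion is not None else [g.interval for g in geneset]
    return filter_intergenic(peaks, excl), uvr
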