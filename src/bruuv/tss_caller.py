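"""Active-TSS calling with a monotone two-state HMM.

UV pretreatment piles nascent-RNA signal just downstream of active start
sites, so the coverage around an active TSS looks like a step: low upstream
(state 1), high downstream (state 2).  Per merged annotation entry, signal in
fixed-width bins spanning a window around the TSS is quantile-normalized
across all windows, passed through the gamma-equivalent z-score, and
segmented by a two-state Gaussian HMM whose only allowed transition is
1 -> 2 (state 2 is absorbing, the chain starts in state 1).  Emission moments
come from two flanking training regions (by default 5-2 kb upstream for
state 1, 2-5 kb downstream for state 2).  A TSS is called active when the
Viterbi switch falls within ``activity_window_bp`` (default 500 bp) of the
annotated position.

The GRO-cap parameter mode (narrow 500 bp window, 50 bp bins, training
regions -500..-100 and 0..500) is the same code path with different config
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations_io import BinnedTrack, GeneSet
from .normalize import gamma_z_transform, quantile_normalize

SD_FLOOR = 0.1


@dataclass
class TssHmmConfig:
    upstream_bp: int = 5000
    downstream_bp: int = 5000
    bin_width: int = 250
    train_state1: tuple[int, int] = (-5000, -2000)
    train_state2: tuple[int, int] = (2000, 5000)
    p_transition: float = 1e-5
    activity_window_bp: int = 500
    gamma_mode: str = "gamma_z"
    pooled_emissions: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p_transition < 1:
            raise ValueError("p_transition must lie in (0, 1)")
        if self.upstream_bp % self.bin_width or self.downstream_bp % self.bin_width:
            raise ValueError("bin_width must divide the window extents")
        for lo, hi in (self.train_state1, self.train_state2):
            if lo >= hi or lo < -self.upstream_bp or hi > self.downstream_bp:
                raise ValueError("training ranges must lie inside the window")

    @classmethod
    def grocap(cls, **overrides) -> "TssHmmConfig":
        """Parameter set suited to the narrow peaks of 5'-cap run-on data."""
        kw = dict(
            upstream_bp=500,
            downstream_bp=500,
            bin_width=50,
            train_state1=(-500, -100),
            train_state2=(0, 500),
        )
        kw.update(overrides)
        return cls(**kw)

    @property
    def n_bins(self) -> int:
        return (self.upstream_bp + self.downstream_bp) // self.bin_width

    @property
    def bin_offsets(self) -> np.ndarray:
        """Strand-oriented start offset (bp, relative to TSS) of each bin."""
        return np.arange(self.n_bins) * self.bin_width - self.upstream_bp


@dataclass
class TssEmissionParams:
    state1: tuple[float, float]
    state2: tuple[float, float]

    def __post_init__(self) -> None:
        if self.state1[1] < SD_FLOOR or self.state2[1] < SD_FLOOR:
            raise ValueError(f"emission sd below floor {SD_FLOOR}")


@dataclass
class TssCall:
    gene_id: str
    base_gene_id: str
    tss: int
    active: bool
    transition_offset: int | None
    n_active_tss_for_gene: int = 0


@dataclass
class WindowMatrix:
    values: np.ndarray
    row_ids: list[str]
    bin_offsets: np.ndarray
    clipped: np.ndarray = field(default=None)  # rows touching a chromosome edge

    def __post_init__(self) -> None:
        if self.clipped is None:
            self.clipped = np.zeros(len(self.row_ids), dtype=bool)


def extract_tss_windows(
    track: BinnedTrack, geneset: GeneSet, cfg: TssHmmConfig
) -> WindowMatrix:
    """One row per gene entry, bins oriented 5'->3' along the gene strand.

    For a plus-strand gene the first bin starts ``upstream_bp`` left of the
    TSS; for a minus-strand gene the first (most upstream) bin is the
    rightmost one and the row is read right-to-left.  Bins falling off the
    chromosome are zero-filled and the row flagged.  Genes on chromosomes
    absent from the track are skipped.
    """
    w = cfg.bin_width
    rows, ids, clipped = [], [], []
    skipped = 0
    for g in geneset:
        chrom = g.interval.chrom
        if chrom not in track.data:
            skipped += 1
            continue
        if g.strand == "-":
            # most-upstream bin covers [tss + upstream - w + 1, ...): grid-aligned
            # window spans (tss - downstream, tss + upstream]; use bin indices
            # right-to-left.
            hi = g.tss + cfg.upstream_bp + 1  # exclusive genomic end
            first = hi // w - cfg.n_bins
            vals, clip = track.bin_values(chrom, first, cfg.n_bins)
            vals = vals[::-1]
        else:
            first = (g.tss - cfg.upstream_bp) // w
            vals, clip = track.bin_values(chrom, first, cfg.n_bins)
        rows.append(vals)
        ids.append(g.gene_id)
        clipped.append(clip)
    values = np.array(rows) if rows else np.zeros((0, cfg.n_bins))
    wm = WindowMatrix(values, ids, cfg.bin_offsets, np.array(clipped, dtype=bool))
    wm.n_skipped = skipped
    return wm


def _train_slices(cfg: TssHmmConfig) -> tuple[np.ndarray, np.ndarray]:
    off = cfg.bin_offsets
    s1 = (off >= cfg.train_state1[0]) & (off < cfg.train_state1[1])
    s2 = (off >= cfg.train_state2[0]) & (off < cfg.train_state2[1])
    return s1, s2


def fit_state_emissions(window_row: np.ndarray, cfg: TssHmmConfig) -> TssEmissionParams:
    """Gaussian emission moments from the two training regions; sd floored."""
    s1, s2 = _train_slices(cfg)
    if s1.sum() < 2 or s2.sum() < 2:
        raise ValueError("training region holds fewer than 2 bins")
    row = np.asarray(window_row, dtype=float)
    t1, t2 = row[s1], row[s2]
    return TssEmissionParams(
        (float(t1.mean()), max(float(t1.std(ddof=1)), SD_FLOOR)),
        (float(t2.mean()), max(float(t2.std(ddof=1)), SD_FLOOR)),
    )


def _gauss_loglik(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return -0.5 * ((x - mean) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2.0 * np.pi)


def viterbi_monotone_two_state(
    obs: np.ndarray, params: TssEmissionParams, p_transition: float
) -> tuple[np.ndarray, int | None]:
    """Most likely monotone state path: 1^k 2^(n-k) for some switch index k.

    The chain starts in state 1 before the first bin, may switch once
    (probability ``p_transition`` per step) and state 2 is absorbing, so only
    the n+1 monotone paths are admissible; the best one is found directly by
    scoring every switch index via cumulative sums.  Ties break toward the
    most upstream switch.  Returns the path over {1, 2} and the switch index
    (position of the first state-2 bin), or None if no switch occurred.
    """
    x = np.asarray(obs, dtype=float)
    if x.size == 0:
        raise ValueError("empty observation vector")
    if not np.isfinite(x).all():
        raise ValueError("non-finite observation")
    n = x.size
    ll1 = _gauss_loglik(x, *params.state1)
    ll2 = _gauss_loglik(x, *params.state2)
    cum1 = np.concatenate(([0.0], np.cumsum(ll1)))  # prefix sums of state-1 loglik
    cum2 = np.concatenate(([0.0], np.cumsum(ll2)))
    stay = np.log1p(-p_transition)
    switch = np.log(p_transition)
    # score(k): bins [0, k) in state 1, [k, n) in state 2
    k = np.arange(n + 1)
    scores = cum1[k] + (cum2[n] - cum2[k]) + k * stay
    scores[:n] += switch  # paths that do switch pay log p once
    best = int(np.argmax(scores))  # argmax takes the smallest (most upstream) tie
    path = np.where(np.arange(n) < best, 1, 2)
    return path, (best if best < n else None)


def call_active_tss(
    track: BinnedTrack, geneset: GeneSet, cfg: TssHmmConfig | None = None
) -> list[TssCall]:
    """Full per-TSS pipeline: windows -> quantile norm -> gamma z -> HMM -> call.

    Windows that are all zero (no signal anywhere near the TSS) or otherwise
    degenerate are reported inactive rather than erroring.  A TSS is active
    when the switch bin's start offset lies within
    [-activity_window_bp, +activity_window_bp].
    """
    cfg = cfg or TssHmmConfig()
    wm = extract_tss_windows(track, geneset, cfg)
    calls: list[TssCall] = []
    if len(wm.row_ids) == 0:
        return calls
    norm = quantile_normalize(wm.values)
    by_id = {g.gene_id: g for g in geneset}

    zrows = np.zeros_like(norm)
    degenerate = np.zeros(norm.shape[0], dtype=bool)
    for i, row in enumerate(norm):
        try:
            zrows[i] = gamma_z_transform(row, mode=cfg.gamma_mode)
        except ValueError:
            degenerate[i] = True

    pooled: TssEmissionParams | None = None
    if cfg.pooled_emissions and (~degenerate).any():
        s1, s2 = _train_slices(cfg)
        ok = zrows[~degenerate]
        t1, t2 = ok[:, s1].ravel(), ok[:, s2].ravel()
        pooled = TssEmissionParams(
            (float(t1.mean()), max(float(t1.std(ddof=1)), SD_FLOOR)),
            (float(t2.mean()), max(float(t2.std(ddof=1)), SD_FLOOR)),
        )

    for i, gid in enumerate(wm.row_ids):
        g = by_id[gid]
        if degenerate[i]:
            calls.append(TssCall(gid, g.base_gene_id, g.tss, False, None))
            continue
        params = pooled if pooled is not None else fit_state_emissions(zrows[i], cfg)
        _, k = viterbi_monotone_two_state(zrows[i], params, cfg.p_transition)
        if k is None:
            calls.append(TssCall(gid, g.base_gene_id, g.tss, False, None))
            continue
        offset = int(wm.bin_offsets[k])
        active = -cfg.activity_window_bp <= offset <= cfg.activity_window_bp
        calls.append(TssCall(gid, g.base_gene_id, g.tss, active, offset))

    counts: dict[str, int] = {}
    for c in calls:
        if c.active:
            counts[c.base_gene_id] = counts.get(c.base_gene_id, 0) + 1
    for c in calls:
        c.n_active_tss_for_gene = counts.get(c.base_gene_id, 0)
    return calls
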