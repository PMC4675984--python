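# Methods

## Coordinate and annotation conventions

All coordinates are 0-based half-open internally. GTF input (1-based closed)
is converted on read; BED dialects are native. A gene's TSS is
`interval.start` on the plus strand and `interval.end - 1` on the minus
strand, and "upstream" is always strand-relative (larger coordinates on the
minus strand).

Isoform merging happens in two stages: identical TSSs collapse, then TSSs of
the same gene are single-linkage clustered with a strict `< merge_distance`
criterion (default 1000 bp), each cluster represented by its most upstream
member. Strictness matters at the boundary: two TSSs exactly 1 kb apart stay
distinct, which is also the caller's resolution limit (below). Single
linkage means a chain of TSSs each 900 bp apart merges into one entry even
if its ends are kilobases apart; this is the simplest deterministic rule and
is idempotent. When one gene yields several clusters the entries get ids
`<gene>:<k>` with a shared `base_gene_id`, on which per-gene active-TSS
counts aggregate.

Read-to-bin assignment spreads each record's value uniformly over its span
(a 100-bp read with 60 bp in a bin contributes 0.6 there). Short-read
nascent-RNA fragments routinely straddle 250-bp bin borders, so whole-read
fractional weighting is the default; a `five_prime` mode assigns the whole
read to the bin holding its 5' end, which suits cap-selected data where the
5' position is the signal.

## Signal normalization

TSS windows are put on a common scale in two steps.

1. **Quantile normalization across windows.** Every window's value multiset
   becomes the per-rank mean of the row-sorted values; ties receive the mean
   of the reference values they span. This is what makes one emission model
   meaningful across genes with wildly different expression, and it is
   load-bearing for resolution: when two TSSs share a window, the
   intermediate plateau between their steps ranks high in the upstream
   gene's window and low in the downstream gene's, so after normalization
   each window's step-at-its-own-TSS is the dominant transition.
2. **Gamma-equivalent z-score per window.** A Gamma(k, θ) is fit by moments
   (k = m²/v, θ = v/m) to the window values plus a pseudocount (half the
   smallest positive value; 10⁻⁶ if none), the fitted CDF is evaluated,
   clamped to [10⁻⁶, 1−10⁻⁶], and mapped through the standard-normal
   quantile. If the data were gamma-distributed this is exactly a normal
   score; in general it is a monotone variance-stabilizing transform
   invariant (up to clamping) under uniform rescaling. A `plain_z` mode
   (subtract mean, divide by sd) is available via `TssHmmConfig.gamma_mode`;
   whether the original normalization used a fitted CDF or a rank-based
   gamma reference cannot be decided from first principles, so both
   behaviors exist and `gamma_z` is the default.

Paired mock/UV tracks are scaled to the smaller library total, which fixes
the baseline probability that a read is from the UV sample at p₀ = 0.5.
Wavelet smoothing (db4, symmetric boundary, soft universal threshold
σ√(2 ln n) with σ from the MAD of the finest detail coefficients, output
clamped at 0) precedes depth scaling, and runs per chromosome. The wavelet
family and threshold rule are fixed in configuration for reproducibility;
nothing in the method depends delicately on the choice.

## TSS activity model

Two Gaussian states on the normalized signal: state 1 (pre-TSS) trained on
bins with start offsets in [−5000, −2000), state 2 (post-TSS) on
[+2000, +5000), sample moments per window with the sd floored at 0.1 to
prevent likelihood spikes from constant training regions. The chain starts
in state 1 (a pre-TSS state must precede the TSS), the only transition is
1→2 with probability 10⁻⁵, and state 2 is absorbing, so exactly n+1 monotone
paths exist; the Viterbi optimum is found by direct scoring with cumulative
sums. Ties break toward the most upstream switch. A TSS is active when the
switch bin's *start* offset lies within ±500 bp (measuring from the start
rather than midpoint or end is an arbitrary but documented choice; at 250-bp
bins the difference is at most one bin).

Emissions are estimated per window by default, because the training regions
are defined relative to each TSS; a pooled mode (moments over all windows'
training bins) is available via `TssHmmConfig.pooled_emissions`.

The GRO-cap mode narrows the window to ±500 bp, bins at 50 bp, and trains on
[−500, −100) and [0, +500); it is purely a configuration preset.

**Resolution.** On clean two-step constructions the caller resolves two TSSs
at 1 kb separation and not below — below 1 kb the annotation merge rule
collapses them first. This geometric property is what
`scripts/acceptance.py` measures, and it is deterministic. Noise robustness
is a separate question, benchmarked by the step-fixture
sensitivity/specificity test (5σ steps, 200 genes, ≥ 0.95/0.95): with two
noisy steps inside one window the single monotone switch sits at whichever
step the realized noise favors, so the clean construction isolates the
resolution question from the noise question.

## UVE model

Each bin's rounded read counts (k = UV, n = UV + mock, half-up rounding of
the scaled values; rounding the two samples separately keeps k ≤ n) feed
beta-binomial emissions. The UVR state's (α, β) comes from moment matching
on per-gene pooled f_UV values — qualifying genes have mock RPKM ≥ 0.25 and
length > 20 kb, and only bins fully more than 20 kb downstream of the TSS
count, where elongating polymerases have almost certainly met a lesion.
Pooling (sum UV / sum total per gene) is the default reading of a
"cumulative" per-gene fraction; a per-bin-mean alternative sits behind
`UveHmmConfig.pooling`. The UVE state is the reflected beta (β, α), which
satisfies `log_pmf(k, n, reflect(p)) = log_pmf(n−k, n, p)` exactly — the
decision boundary between the states is k = n/2.

Transitions are symmetric at 0.005 with a uniform initial distribution (the
source material fixes only the single transition probability; symmetry and
uniformity are the minimal completions). Bins with zero total emit
probability 1 in both states. A consequence of that rule is that the optimal
path extends whichever state precedes a read-free gap — delaying a switch
across uninformative bins saves one stay factor — so the raw state path
would smear UVE runs across empty deserts. Peaks are therefore reported as
maximal runs of *evidence-bearing* (n > 0) UVE bins; the raw path is still
returned for inspection. Near-ties in the dynamic program (exact in zero
runs) resolve toward UVR within a 10⁻⁹ tolerance so peaks never grow on
float noise.

Intergenic annotation marks peaks overlapping (≥ 1 bp, half-open) any
exclusion interval — by default the gene intervals themselves, optionally a
transcription-unit BED. Only training touches the annotation; segmentation
is genome-wide.

## Descriptive analyses

TSS-anchored aggregate profiles take the per-bin median of per-gene
RPKM-scaled signal over genes ≥ 60 kb long (a 50 kb variant is a parameter)
and ≥ 1 RPKM in the mock sample, optionally divided bin-wise by the mock
profile (the mock against itself is the unit profile). Heat-map rows are
min-max scaled to [0, 1] (constant rows → 0) and sorted by descending scaled
signal over the first 5 kb. The first-5-kb fold change
(RPKM_b + c)/(RPKM_a + c) uses pseudocount c = 0.25 RPKM to stabilize
low-expression ratios; genes shorter than 5 kb fall back to full length and
are flagged. Nearest-gene assignment minimizes |peak midpoint − TSS| —
TSS distance rather than body distance, because promoter pairing is the
quantity of interest — with lexicographic tie-breaking. The downsampling
study subsamples a library without replacement (multivariate
hypergeometric, the exact distribution of subsampling read labels) at a grid
of depths, 10 replicates each, and reports per-gene CV = sd/mean of RPKM
across replicates; CV is exactly 0 at full depth, and genes with zero mean
are dropped. (One source text describes CV inverted, as mean/sd; the
standard definition is implemented.)

## Simulator

The generator is the package's test substrate, emulating the statistical
structure of a paired mock/UV experiment:

- **Lesions**: homogeneous Poisson process at `rate × dose` per bp, default
  rate 10⁻⁵ /bp/(J/m²) = 1 per 100 kb per J/m², so 1 per 5 kb at 20 J/m².
- **Genic signal**: expected density at strand-oriented offset x from the
  TSS is e_g·exp(−λx) with λ = rate × dose — the probability a polymerase
  survives past all lesions to x, marginalized analytically. Mock is dose 0
  (uniform over the body). An explicit per-polymerase mode
  (`explicit_polymerase_density`) truncates runs at sampled first lesions
  and is used to validate the closed form.
- **Enhancers**: symmetric triangular kernel of half-width 1 kb (matching
  the visual width scale of bidirectional eRNA signal), amplitude multiplied
  by a stabilization factor s (default 5) in the UV sample only and only at
  dose > 0 — an unirradiated "UV" sample is a mock sample. No quantitative
  stabilization factor exists in the source material; s is a free parameter
  with its default documented here.
- **Sampling**: reads are drawn multinomially to the requested depth, so
  library totals are exact and depth-scaling identities hold exactly.
- **Layout**: genes ≥ 60 kb apart, enhancers centered in intergenic gaps,
  log-normal (σ = 1) expression weights for a realistic dynamic range.
  Default: 2 × 12 Mb chromosomes, 60 genes of 20–90 kb, 24 enhancers,
  10⁶ reads per sample — sizes chosen so the full pipeline runs in about a
  second while every gene still carries hundreds of reads.
- **Background**: default 0 uniform background reads. Depth-normalized
  uniform background has f_UV ≈ 0.5, which the reflected emission model
  scores as weak enhancement — equal-ratio coverage *is* UV-enhanced
  relative to the repressed gene-body baseline — so a background floor
  floods the segmentation with shallow peaks. Real intergenic nascent-RNA
  coverage at these depths is overwhelmingly zero; a `background_fraction`
  parameter exists for sensitivity exploration.

What the simulator does not model: sequence content, mappability, GC bias,
fragment-length structure, replicate variability, PROMPTs (optional and off
by default), and UV-induced changes in initiation (real UV triggers a damage
response that activates or represses specific promoters; here expression
weights are dose-independent). Passing tests therefore demonstrate that the
inference machinery recovers the generative structure it assumes, not that
the model is adequate for any particular real dataset.

## Numerical choices and degenerate inputs

- Gaussian emission sd floor 0.1 (normalized units); beta parameters must be
  positive and the moment fit rejects v ≥ μ(1−μ) and v = 0.
- Gamma-CDF clamp [10⁻⁶, 1−10⁻⁶] bounds z-scores to ±4.75.
- All-zero or degenerate TSS windows are reported inactive, never errors;
  genes on chromosomes missing from a track are skipped and counted.
- Windows running off a chromosome edge are zero-filled and flagged.
- `total_reads` of 0 is an error wherever RPKM is needed.
- Viterbi ties: monotone variant → most upstream switch; two-state variant →
  UVR-preferring within 10⁻⁹.

## Known limitations

- Emission training for a TSS window assumes the flanks are representative;
  overlapping neighbor genes contaminate the training regions (mitigated but
  not removed by quantile normalization).
- The beta-binomial HMM treats smoothed, depth-scaled counts as integer
  trials; smoothing correlates adjacent bins, so the effective number of
  independent trials is overstated and peak boundaries are accordingly
  soft.
- The f_UV observable is symmetric in the samples; classifying equal-ratio
  background as weakly UVE is intrinsic to the reflection design (see
  Simulator/Background above).
- RPKM-based filters inherit RPKM's insensitivity to within-gene coverage
  shape.
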