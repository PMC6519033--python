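# Methods

`ldjump` estimates the variable population recombination rate ρ = 4·N_e·r
per base pair along a DNA sequence from a sample of haplotypes, and segments
the result into a parsimonious piecewise-constant recombination map with
hotspot calls. This note records the model, the numerical choices, and the
limits of what the simulation studies demonstrate.

## Model overview

The estimator is a two-step procedure.

**Step 1 — per-segment regression.** The sequence is cut into contiguous
windows (default 1 kb). For each window, seven summary statistics are
computed from the binary matrix of segregating sites: the number of distinct
haplotypes per bp and per sequence (`haps` = H/(n·L)), the variance and mean
of per-bp pairwise differences (`vapw`, `apwd`), Watterson's θ per bp
(`wath` = S/(a_n·L)), mean per-site heterozygosity with the n/(n−1) factor
(`hahe`), the maximal chi-squared over haplotype pairs and breakpoints
(`maxchi`), and the neighbour similarity score over adjacent-site
four-gamete compatibility (`nss`). A demography-aware variant adds Tajima's
D. These predictors feed an additive model of a Box-Cox transform of ρ,

    t(ρ_i) = f_1(z_i1) + … + f_q(z_iq) + ε_i,   t(ρ) = (ρ^λ − 1)/λ,

with each f_j a penalized cubic B-spline (P-spline: interior knots at
predictor quantiles, second-difference coefficient penalty). The model is
trained on coalescent simulations of a factorial constant-rate design:
sample sizes {10, 16, 20}, segment lengths {1, 2, 3} kb, 111 equidistant ρ
values spanning (0, 0.1], θ = 0.01 — 999 scenarios per replicate. λ is
chosen by profile maximum likelihood over a grid (0 to 1 in steps of 0.05)
against the additive fit and stored with the model; the demography model
reuses the neutral λ. Because low rates are overestimated on average and
high rates underestimated, a bias correction is fitted on an independent
calibration replicate of the same design: for each working quantile q in
{0.25, 0.35, 0.45, 0.5}, a linear q-quantile regression of t(ρ_true) on the
raw linear predictor; prediction applies the stored line and back-transforms,
flooring at 0. The default working quantile is 0.35.

**Step 2 — multiscale segmentation.** The back-transformed per-segment
estimates (natural scale — this gave better hotspot detection than the
transformed scale, which remains available behind a flag) are fed to a
SMUCE-style simultaneous multiscale change-point estimator: the
piecewise-constant fit with the fewest jumps such that on every interval
inside a constant block the local Gaussian likelihood-ratio statistic stays
below a scale-penalized threshold, with penalty sqrt(2·log(e·n/len)). The
threshold is the Monte-Carlo (1−α) quantile of the penalized multiscale
statistic under pure noise (no asymptotic table), so the probability of
overestimating the number of blocks is controlled at level α (default
0.05). When the noise level is estimated from the data (scaled MAD of first
differences / √2), the calibration replicates apply the same estimator, so
the procedure is calibrated exactly as run. Among minimal-jump fits the
constrained least-squares fit is returned; ties are broken toward the
leftmost change points. The dynamic program runs over all O(n²) intervals;
n is the number of segments (≈1,000 for a 1 Mb sequence at 1 kb windows),
so both calibration and fitting take seconds.

Segments with one or zero SNPs carry almost no information; their estimates
are imputed as the mean of the nearest informative neighbours (one-sided at
the boundaries) before segmentation.

**Hotspot calls.** On real data the background rate is unknown; it is
estimated by a deliberately downward-biased heuristic — the mean of the
per-segment estimates strictly below their median (the shared value if all
are equal) — and hotspots are maximal runs of map blocks exceeding
`hotspot_factor` (default 5) times that background. In the simulation
studies the evaluation instead anchors detection at the known design
background: the documented quantile orderings (background identification
best at the smallest bias quantile) only emerge under that reading, and
with an estimate-derived background the ordering inverts because the
background shifts together with the rates.

## Coalescent simulation and scalings

msprime generates all training and evaluation data. Haploid samples
(`ploidy=1`) are drawn from a reference population of size 2, making the
pairwise coalescence rate 1/2 per generation; per-bp simulation rates are
then θ/4 and ρ/4 and one ms-style coalescent unit equals 4 generations.
This was validated against Watterson's E[S] = θ·L·a_n and E[π] = θ·L.

The bottleneck-growth demography has relative sizes η = 100 (present epoch,
−0.5 < t ≤ 0), 0.1 (−0.58 < t ≤ −0.5) and 1 (ancestral), time in coalescent
units. The reference size that scales θ, ρ and time is anchored at the
**present-day** epoch (only size ratios enter the simulator). Anchoring at
the ancestral epoch instead makes genealogies star-like — lineages
accumulate mutations for half a coalescent unit without coalescing and ρ
becomes essentially unidentifiable (a gradient-boosting probe finds
cross-validated R² ≈ 0 between the statistics and ρ) — incompatible with
the accuracy this scenario is known to admit. Under present-epoch anchoring
diversity is ≈0.7× neutral and the distortion is subtle, which matches the
regime in which demography misspecification is reported to produce spurious
hotspots rather than destroy the signal.

## Synthetic designs

- *Constant-rate grid*: the factorial design above; used for training,
  calibration and the accuracy study (independent seeds for each role).
- *Simple setups*: 10/20 kb sequences with one central hotspot; background
  rates equidistant in [0.001, 0.03], intensities {5, 10, 15, 20, 40}-fold,
  hotspot lengths {1/5, 1/10, 1/20, 1/35, 1/50} of the sequence.
- *Natural setups*: 1 Mb, 15 hotspots evenly distributed (centres at
  L·i/16), intensities equidistant from 8- to 40-fold in position order,
  lengths alternating 1 kb / 2 kb, backgrounds equidistant in
  [0.001, 0.01]. The true map has 31 blocks.
- *Demography design*: 30 kb, 16 haplotypes, two 1 kb hotspots at 10 kb and
  20 kb with intensities 20 and 35, simulated under the bottleneck-growth
  demography.

Hotspot centre placement and the intensity/length assignment in the natural
setup are fixed conventions (the design is described only as "evenly
distributed" with intensities "between 8- and 40-fold").

What the generator does *not* emulate: gene conversion, migration or
admixture, mutation-rate heterogeneity along the sequence, genotyping or
phasing error, and missing data. Passing tests therefore demonstrate
correct behaviour under the idealized coalescent, not robustness to those
real-data complications.

## Numerical choices and degenerate inputs

- Spline bases use 8 interior knots per predictor (quantile-placed,
  deduplicated), cubic, with penalty weight 1.0 on squared second
  differences plus a 1e-8 ridge; all recorded in the model file.
- Predictions outside the training hull are clamped to the hull boundary
  (logged). Back-transforms below the Box-Cox domain floor at 0.
- ρ = 0 cannot enter the transform; the training grid's smallest rate is
  positive, and zero estimates arise only through flooring.
- Constant input to the segmenter returns one block without calibration;
  a zero MAD with non-constant input falls back to the standard deviation
  of differences.
- Multiallelic sites (recurrent mutation) are kept only when the two most
  frequent alleles cover every haplotype, otherwise dropped; sites with
  missing symbols are dropped. Monomorphic columns are removed on
  construction.
- All randomness flows from explicit integer seeds; model files serialize
  to JSON and reproduce predictions bit-exactly after reload.

## Problem sizes in the shipped studies

The test suite and the acceptance script run at the sizes chosen for the
package's own studies: the full 999-scenario grid for training, calibration
and evaluation; 20 replicates of the full 1 Mb natural design for the
parsimony check; 10 replicates per background rate for the demography
table; 2,000 noise replicates for the type-I error check; paired designs
(same alignments under both models, or all quantiles on one alignment) for
the direction studies, with Monte-Carlo-aware tolerances where the true
effect is small relative to replicate noise.

## Known limitations

- The per-segment statistics lose information below ≈400 bp windows; a
  warning is emitted for shorter segments.
- Estimates saturate near the training-grid maximum (ρ = 0.1/bp); hotspot
  rates above it are systematically underestimated (visible in the
  demography study at high backgrounds, where most of the error is hotspot
  saturation).
- At the lowest backgrounds (ρ ≈ 0.001) under the bottleneck-growth
  demography the per-segment regression is noisy and upward-biased: the
  mean grid RMSE of the two-hotspot study is ≈0.011 against ≈0.008 for the
  same pipeline on neutral data of equal information content.
- Numerical identity with the R implementations of the multiscale estimator
  (stepR/smuceR) and of PhiPack's NSS/MaxChi conventions is not claimed;
  the statistics are defined here once and used identically in training and
  prediction, which is the binding requirement for the regression.
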