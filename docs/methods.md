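# Methods

This note documents the models, estimators, numerical choices and known
limitations of `divnoise`, in the package's own terms.

## The dilution model

A population of cells is stained with a non-endogenous dye that is
neither produced nor (appreciably) degraded, so the amount *m* carried
by a cell changes only at division: a daughter receives *f·m* and its
sibling *(1 − f)·m*, with *f* drawn independently at each division from
a symmetric partition distribution Π(*f*) on [0, 1]. Exchangeability of
daughters forces E[*f*] = 1/2 and Var(*f*) = σ_f² ≤ 1/4. Under these
assumptions the population moments at generation *g* are exact:

- mean: μ_g = μ₀ / 2^g — independent of Π, because every fraction *f*
  handed to one daughter is mirrored by 1 − *f* in its sibling;
- variance: σ_g² = μ₀²(E[f²]^g − 4^(−g)) + σ₀² E[f²]^g, where
  E[f²] = σ_f² + 1/4. The second moment of the whole generation obeys
  the one-step recursion A_g = A_{g−1}·E[f²], which gives the closed
  form above.

Neglected on purpose: production/degradation during growth (excluded by
using a non-endogenous dye) and, in the baseline model, cycle-length
variability — the moments above are indexed by generation, not time, so
cycle-time noise only redistributes cells among coexisting generations.
The coupling of cycle length to partitioning is treated separately
(sizer mode, below).

### Partition families

`PartitionSpec` implements delta(1/2), a symmetric two-point
distribution, a Gaussian truncated to [0, 1] (truncation about the
symmetric center preserves the mean; the *effective* post-truncation
variance is what enters E[f²]), a symmetric double Gaussian
½[N(f_peak, σ′) + N(1 − f_peak, σ′)] renormalized on [0, 1], and the
large-N binomial limit (atoms at p, 1 − p). Continuous-family moments
use `scipy.stats.truncnorm` or adaptive quadrature; sampling of the
double Gaussian redraws out-of-range values, which is exactly sampling
from the truncated density.

## Estimating σ_f from cytometry

1. **Anchor.** The post-sort t = 0 snapshot is a narrow peak; its median
   log2 intensity anchors generation 0.
2. **Deconvolution.** Each acquisition's log2 intensities are fitted
   with a 1-D Gaussian mixture by EM. Generations appear at unit log2
   spacing (intensity halves per division), so the default `"comb"` mode
   ties component means to `anchor − g·spacing + δ` with a single shared
   offset δ, |δ| ≤ spacing/2. The δ update (precision-weighted mean
   residual) is the exact constrained M-step of a concave quadratic, so
   the likelihood is monotone; the bound breaks the aliasing between a
   window of generations and its neighbour shifted by one. Free-means
   and fixed-means modes exist; free means can drift off the comb and
   merge adjacent generations when peaks overlap, which is why they are
   not the default. Initialization is deterministic from the anchor
   (occupancy-based weights, σ₀ = 0.3); convergence at relative
   log-likelihood change < 1e-8 or 500 iterations (non-convergence is
   flagged, not raised). Component SDs are free per generation (the
   theory predicts width growth); a tied-σ option exists for low-count
   snapshots.
3. **Window selection.** Candidate components are consecutive
   generations bracketing the occupied range (0.5–99.5% quantiles of the
   anchor-relative offsets), with one generation of freedom at each
   edge; BIC selects among the candidates.
4. **Moments and pooling.** Each component (μ, σ in log2) converts to
   linear moments via the lognormal formulas (s = σ·ln 2;
   mean = 2^μ e^{s²/2}; var = mean²(e^{s²} − 1)). Per generation,
   moments are pooled across acquisitions as the π_g·n-weighted
   *average* of means and of variances — not as the moments of the
   concatenated mixture. The distinction matters only when a
   generation's mean drifts across acquisition times (as under
   division-time/partition coupling); averaging keeps that drift out of
   the variance, which must reflect within-population spread only. Two
   QC rules apply: components with mixture weight < 0.5% are skipped
   (they are outlier absorbers whose inflated SDs the log-to-linear
   conversion amplifies explosively), and generations with fewer than
   100 effective events over the whole course are excluded.
5. **Variance-law fit.** After normalizing by the generation-0 moments,
   the single parameter E[f²] ∈ [1/4, 1/2] is fitted to the variance law
   by weighted least squares (weights default to per-generation event
   counts; bounded scalar minimization with boundary snapping).
   σ_f = √(E[f²] − 1/4); CV% = 200·σ_f. The OLS slope of log2(mean)
   vs g is reported as a diagnostic (−1 expected); a nonparametric
   bootstrap over the non-anchor generations (default 1000 resamples,
   seeded) gives the standard error.

## Estimating f from microscopy traces

Each division event carries mother and daughter (time, total
fluorescence, pixel area) traces. Both daughters' log intensities are
fitted jointly with a shared decay slope and free intercepts (closed
form linear least squares, natural-log space); the inherited fraction is
f = e^{q₁}/(e^{q₁} + e^{q₂}), computed stably as a logistic of q₂ − q₁.
The mother trace is used only for QC and a conservation diagnostic
(daughters' first-frame sum over mother's last frame). f is exactly
invariant to time-origin shifts and to common intensity rescaling, and
the two daughters' fractions sum to one by construction.

QC keeps an event iff the mother and both daughters each span ≥ 2 h of
observation on their side of the division (elapsed time, with an fp
tolerance; at the 20-min default cadence that is 6 inter-frame
intervals) and each trace's |Pearson(intensity, area)| ≤ 0.9 — a strong
coupling of total fluorescence to projected size indicates a high
noise-to-signal ratio (e.g. segmentation error). The filter is applied
to all three traces; one failure rejects the event, the strictest
reading, logged with per-event reasons.

The empirical Π(f) is fitted by maximum likelihood with the symmetric
double Gaussian (L-BFGS-B over f_peak ∈ (0, 1/2], σ′ > 0, multiple
deterministic starts); a single central Gaussian is preferred when its
BIC is within 2 of the double-peak model. The partition variance uses
the exact mixture identity σ_f² = σ′² + (f_peak − 1/2)².

## Binomial bias mapping

With N components segregating independently (probability p per
component), Var(f | N) = pq/N; averaging over the mother-count
distribution P(N) and the two exchangeable branch labels gives
σ_f² = pq·Σ(N) + (p² + q²)/2 − 1/4, Σ(N) = E[1/N]. For the delta model
Σ = 1/N exactly; for the lognormal model (truncated at N ≥ 1 — counts
below one component are unphysical — and renormalized) Σ has an erf
closed form, cross-checked against adaptive quadrature. A printed
variant with a 1/2 prefactor on the Σ term is kept as a documented
compatibility function only: it does not reduce to pq/N at p = q = 1/2,
so the pq·Σ composition is authoritative. In the large-N regime
σ_f = |p − 1/2|, inverted as p = 1/2 − σ_f with the convention p ≤ 1/2
(daughter labels are exchangeable, so (p, q) and (q, p) are
indistinguishable).

## The simulators

`simulate_dilution` is generation-indexed: every division draws f ~ Π,
children receive f·m and m − f·m (conservation is exact in floating
point), and generation g holds 2^g cells per founder (guarded at
g ≤ 25). `simulate_sizer` and the uncoupled time-resolved run are
event-driven: in sizer mode cells grow exponentially at rate λ from
birth size and divide on reaching a threshold s* jittered by a lognormal
CV; one f per division splits *both* size and marker, the maximal
coupling of partitioning to cycle length (a daughter born at fraction f
of s* divides after ln(1/f)/λ when the threshold noise is zero). In
uncoupled mode cycle times are lognormal, the standard positive,
right-skewed choice for mammalian cycle-length data.

Defaults (chosen once as realistic study conditions): 18 h mean cycle
time with 20% CV (colon carcinoma-like doubling), acquisition grid
{0, 24, 36, 48, 60, 72, 84} h, sorted founder peak of 0.05 log2-units
width, per-component brightness 500 with 5% lognormal measurement noise
and zero background (background subtraction is assumed upstream; a
configurable floor exists), 10^4 events per acquisition by default and
8000 in the bundled analyses, sizer λ = ln 2 / 18 h⁻¹, s* = 2 (founders
at s*/2), 5% threshold CV. Microscopy events: 20-min frames, 7 frames
per side, intensity decay −0.02 h⁻¹, 3% per-frame multiplicative noise,
5% area noise; daughter areas proportional to f by default (cytoplasm),
switchable off to test the null of the size–fraction association.

What the generators do **not** emulate: instrument compensation and
scatter gating, autofluorescence spectra, debris/doublets, cell death,
segmentation artifacts beyond the intensity–area correlation knob, and
non-sizer homeostasis (adder/timer). Passing tests therefore show the
estimators are correct under the stated noise model, not that every
real-data pathology is handled.

## Problem sizes in the bundled analyses

The test suite and `scripts/acceptance.py` run dilution checks at 10^4
founders (g ≤ 6), time courses at 1500 founders × 8000 events × 7
acquisitions, mixture recovery at 2·10^4 events, microscopy at 500
events, sizer robustness over 5 seeded replicates, and cross-pipeline
comparisons at σ_f ∈ {0.05, 0.1} — sizes at which the Monte-Carlo error
of each check is comfortably below its tolerance.

## Known limitations

- **Extreme coupling + large noise.** Under full sizer coupling the
  cells reaching generation g early are those that repeatedly inherited
  large fractions, so apparent peak spacing compresses and
  within-generation-at-time distributions broaden. At σ_f ≈ 0.07 the
  pipeline recovers σ_f to ~+20%; at σ_f ≈ 0.12 adjacent peaks sit
  0.2–0.5 log2 apart with SDs ≈ 0.4 and no deconvolution can separate
  them. The telltale is the upward deviation of newer generations'
  means and a log2-mean slope above −1.
- **Microscopy overestimates.** Frame-noise propagates into f̂ with a
  spread that grows monotonically with the noise CV (property-tested);
  with few events and limited filtering this inflates the apparent
  asymmetry relative to cytometry.
- **Anchor drift.** Generation labels derive from the t = 0 anchor; a
  systematic per-generation log2 drift beyond half the peak spacing
  (not observed at the simulated conditions) would shift labels by one.
- The FCS reader covers list-mode FCS 3.0/3.1 with float or uniform
  16/32-bit integer data — the common cytometer export — not the full
  standard (no analysis segments, no bit-packed integers).
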