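# Methods

## The model

`dupdiv` simulates adaptation of a bacterial population in which expression
of a single selected locus can rise through two qualitatively different
mutation routes: copy-number mutations of a tandem array (frequent,
reversible) and promoter point mutations (rare, effectively permanent).

A genotype is the pair `(k, m)`: `k ≥ 1` tandem copies of the locus, `m` of
which carry the adaptive promoter allele. Total expression is additive in
dosage,

    E(k, m) = (k − m)·β_anc + m·β_mut,

with per-copy strengths `β_anc = 1` (leaky baseline of the random ancestral
promoter) and `β_mut = 20` (evolved promoter). Fitness follows a saturating
expression–demand map with a hard plateau and a linear per-copy cost:

    r(k, m) = r0 + (rmax − r0)·min(E/D, 1) − c·(k − 1),  clamped at 0,

with defaults `r0 = 0.2/h`, `rmax = 0.9/h`, `c = 0.01/h/copy`. The plateau
is the epistasis mechanism: once either route satisfies demand `D`, the
other route adds expression that buys nothing while extra copies still
cost — negative epistasis between the routes, and hence "amplification
hindrance" of point-mutation fixation whenever the frequent route suffices.

Three demand levels span the regimes: `D = 4` (low; satisfiable by
amplification to ~4 copies *or* one point mutation — the mutually exclusive
regime), `D = 25` (intermediate), `D = 60` (high; `E(1,1) = 20` and
`E(20,0) = 20` both fall short, so only combination genotypes reach the
plateau). The piecewise-linear form (rather than a smooth Hill curve) makes
these regime boundaries analytically checkable.

A hard plateau means the model has no numeric value for the per-copy cost
from first principles; `c` is a free parameter kept small relative to the
benefit slope `(rmax − r0)/D` so that amplification is adaptive below
demand in all three environments.

## Serial-passage dynamics

Each replicate is a vector of real-valued class abundances over `(k, m)`
with `k ≤ kmax = 20` (the state space is truncated there; amplification out
of the top class is suppressed). One day consists of:

1. **Growth to capacity.** The day duration `T` solves
   `Σ_i n_i·exp(r_i·T) = K_cap` by bracketed root finding in log space
   (relative tolerance ~1e-12; capped at 1000 h — a day that cannot reach
   capacity is truncated there and flagged on the trajectory).
2. **Tau-leaped mutation.** `T` is split into `G = 10` equal sub-intervals.
   Within each, classes grow exponentially at their own rates, then Poisson
   mutation flows move cells between classes with per-class generation
   counts `g_i = r_i·Δt/ln 2`:
   - duplication `(1, m) → (2, 2m)` at `μ_dup` (a tandem duplication copies
     the resident allele);
   - amplification `(k, m) → (k+1, m+1 w.p. m/k else m)` and deletion
     `(k, m) → (k−1, m−1 w.p. m/k else m)`, each at `μ_step·(k − 1)` for
     `k ≥ 2` — the rate scales with the junction count because
     recombination needs repeats, and the `m/k` rule encodes that a
     uniformly chosen copy is gained or lost (this is also why a single SNP
     inside a four-copy array has only a 1-in-4 chance of surviving
     collapse back to single copy);
   - point mutation `(k, m) → (k, m+1)` at `μ_pm·(k − m)` — every
     ancestral copy is an independent target.
   Flows are capped at the source abundance and conserve the total; a
   per-substep event probability reaching 1 raises an error instead of
   silently breaking the tau-leap assumption.
3. **Bottleneck.** `round(total/820)` cells are drawn multinomially by
   class frequency. Extinction stops the replicate (no resampling).

Snapshots are taken pre-dilution each day; day 0 is the inoculum
(`K_cap/820` ancestral cells). Strain presets differ only in the
duplication-formation rate: IS+ (`μ_dup = 1e-3` per cell per generation,
flanking insertion-sequence repeats) versus IS− (`μ_dup = 1e-6`,
repeat-independent events only); `μ_step = 1e-2` and `μ_pm = 1e-7` are
shared.

The class-abundance tau-leap representation was chosen over agent-based
simulation because populations of ~1e8 cells make per-cell tracking
pointless and the bottleneck — modelled exactly — is the dominant noise
source. `G = 10` keeps per-substep mutation probabilities ≤ ~0.2 at the
default rates.

**Problem sizes.** The packaged experiments run at `K_cap = 1e6` (the
protocol's ~10 generations/day regime is preserved; one replicate of 12
days takes ~40 ms), with 48 replicates per condition, 200 replicates for
the oracle comparison, and 1e5 reads per simulated amplicon library.

## The mean-field oracle, and when it applies

`deterministic_trajectory` runs the identical recursion with Poisson draws
replaced by their means and the bottleneck by exact division — the
infinite-population limit. Two caveats follow from the model itself:

- With *frequent* flows (the copy-number rates at IS+ levels) stochastic
  replicate means track the oracle closely, but a systematic residual of
  ~0.02–0.03 in class frequencies remains at `K_cap = 1e6`, because
  establishment still passes through ~1 duplicated cell per day at the
  bottleneck.
- With *rare* flows (point mutations at `μ_pm = 1e-7`) the oracle is not
  the correct limit at finite capacity: it keeps fractional mutant lineages
  that compound at the highest growth rate every day, whereas real
  (simulated) populations usually lose them at the bottleneck and only
  occasionally win a jackpot — the Luria–Delbrück effect. The oracle then
  systematically overweights point-mutant takeover; deviations approach
  ~0.9 in class frequency under the low-demand preset. This is a property
  of mean-field versus finite populations, not an implementation
  discrepancy; exact agreement is verified where it provably holds
  (zero-rate neutrality, pure two-type selection against the closed-form
  per-day recursion, and flow means).

The same establishment bottleneck shapes the regime comparisons at desk
scale: with `K_cap = 1e6` the point-mutant supply is ~0.14 mutants/day per
replicate, so the high-demand combination regime produces combination
mutants in a minority of 48 replicates over 12 days (consistently more
than under low demand, but the contrast at this scale is underpowered for
a p < 0.01 Fisher test).

## The virtual reporter and classification

YFP is fused to the selected gene (reports total expression `E`); CFP is
independently transcribed within the same cassette (reports copy number
`k` only). Single cells get multiplicative lognormal noise with mean
exactly 1 and CV 0.25 per channel (the exact noise law of the real
instrument is not modelled; lognormal matches strictly positive, unimodal
scatter). Fluorescence is linear in dosage with no saturation, consistent
with treating CFP as a copy-number proxy.

Populations and events are classified on ancestral-normalized values with
explicit thresholds: elevation cutoffs `θ_y = θ_c = 1.5` and a YFP/CFP
ratio cutoff `ρ = 1.5` separating pure amplification from the "mixed"
region that flags combination mutants. The four rules partition the
positive quadrant. The original gates were drawn by eye, so the thresholds
here are declared, configurable and written into output metadata rather
than inferred. Event normalization uses the medians of an ancestral control
sample (medians rather than means for outlier robustness; at the default
noise the difference is negligible). Note that at CV 0.25 the 1.5-fold
cutoffs sit at ~1.65σ, so ~10% of truly ancestral single cells fall
outside the ancestral gate and a 50/50 mixture of the two pure mutant
types shows ~9% mixed events — the per-event misclassification rates are
properties of the stated defaults, and the tests assert their closed-form
values. Subpopulations are called present at a detection floor of 1% of
events (~6000 events per sample).

## Assays

**Growth rate** is the steepest ordinary-least-squares slope of ln(OD)
versus time over every contiguous 20-point sliding window (10-minute
sampling), ties broken by the earliest window. Invariant to OD scaling and
time shifts.

**Relative copy number** uses efficiency-corrected relative quantification:
per-primer-pair efficiency `E = 10^(−1/s)` from the dilution-series slope
`s` of Cq against log10 dilution, combined as
`E_t^ΔCq_t / E_r^ΔCq_r` with `ΔCq = Cq(calibrator) − Cq(sample)` per
channel; the reference primer pair lies outside the amplified region.

**Amplicon divergence** counts exact 39-bp motif matches: the ancestral
upstream window `[−39, −1]` relative to the start codon (position −1
adjoins the A of ATG; position −n maps to 0-based index `39 − n`), the
same window carrying the known adaptive SNPs (−30T>A, −37C>T, and the
double mutant), and a downstream control window `[+1, +39]` in the coding
sequence. Matching is exact-substring on both strands: sequencing errors
land in "unassigned" rather than being miscalled as alleles
(conservative, and trivially checkable against a brute-force scanner).
Reads matching a contaminant motif (cross-library contamination) are
excluded before any counting. The divergence metric is
`count(evolved)/count(ancestral)` — deliberately diluted by copy number,
since a cell with one mutant copy among `k` contributes `k − 1` ancestral
templates and its SNP has only a `1/k` chance of surviving array
collapse. The single-SNP control reports the one-mismatch/zero-mismatch
read odds against the coding-region motif (~`39e/(1 − e)` at per-base
error `e`), scanning all alignments on both strands.

The true junction sequence between the random promoter and the start codon
is not reconstructible from published material, so the shipped reference
is synthetic (random sequence with the SNP reference bases planted and a
synthetic contaminant amplicon); real-data use must supply the actual
reference.

## Synthetic data

Generators emit the four data shapes with ground-truth sidecars: growth
curves (lag/exponential/logistic, 2% multiplicative OD noise), daily plate
endpoints (bulk fluorescence noise CV 0.05 — a well averages ~1e6 cells,
so single-cell noise vanishes and only instrument variation remains),
amplicon reads (templates drawn ∝ cell frequency × copy number with
evolved templates ∝ m, per-base substitution errors at 1e-3, random
strand, optional contaminant spike-in), and qPCR runs (4-point dilution
series, 3 technical replicates, 0.1-cycle Cq noise). All are deterministic
under a fixed seed.

What the generators do *not* emulate: PCR-cycle-resolved amplification
bias and chimeras, spectral bleed-through, FSC/SSC gating, growth-rate-
dependent fluorescence, resource dynamics beyond the capacity constraint,
and amplifications whose junctions exclude the copy-number reporter (such
partial amplifications exist in the real system and are deliberately not
modelled). Passing round-trip tests therefore demonstrates internal
consistency of the pipeline on data with this statistical structure, not
performance on real instrument output.

## Numerical choices

- Day-duration root finding in log space (`logsumexp`) so large `r·T`
  cannot overflow; relative tolerance ~1e-12.
- Lognormal noise parameterized as `σ² = ln(1 + CV²)`, `μ = −σ²/2` so the
  multiplier has mean exactly 1.
- Growth clamped at 0 (no death process; the medium supports growth
  without the selected gene).
- Seed fan-out: replicate `i` of an experiment uses seed `base_seed + i`,
  so any replicate is reproducible in isolation.
- CSV dialect fixed (UTF-8, comma, dot decimal, mandatory header); numeric
  parsing is exact strtod (the fast pandas parser can be 1 ulp off, which
  would break bit-for-bit round trips).
- Sliding-window OLS slopes are computed vectorized from centered
  cross-products; the brute-force per-window regression is kept in the
  test suite as an independent oracle.

## Known limitations

- The state space truncates at `kmax = 20` copies; runs that would push
  beyond it accumulate at the boundary.
- Mean-field comparisons are only meaningful for frequent-flow dynamics
  (see above).
- Bulk fraction classification cannot distinguish a true combination
  clone from a mixture of the two pure mutant types; both land in the
  mixed fraction, and only single-cell event classification separates
  them. Replicate tallies are therefore reported both with and without
  the mixed fraction.
- The qPCR generator assumes a copy-invariant reference locus and shared
  intercepts across channels up to the programmed offsets; it does not
  model pipetting covariance between technical replicates.
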