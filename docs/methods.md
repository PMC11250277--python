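# Methods

`msidyn` implements the quantitative core of an analysis of adaptive
mutability in mismatch-repair-deficient (MMRd) colorectal cancer: coding
homopolymers in the MMR genes themselves (e.g. the MSH6 C8 run) act as
stochastic ON/OFF switches for the cellular mutation rate, and the package
provides the statistics, the imaging workflow, the evolutionary model and the
mutation-rate estimator needed to study that process on synthetic data with
known ground truth. This note records the models, the parameters that matter,
and the design choices made where the design was genuinely open.

## Homopolymer frameshift calling and diversity

A locus is summarized by its read-length distribution (reads per observed
repeat length). The caller labels a site **mutant** when the unstable read
fraction — reads whose length differs from the reference repeat length,
insertions and deletions pooled — is at least 5% and at least 50 reads are
present; with fewer than 50 reads the site is a **no-call**. Both thresholds
are inclusive ("a minimum of" read as ≥). Catalogs are restricted to exonic
homopolymers of reference length 6–11, the range where slippage is frequent
but alignment is still reliable. When a matched normal shows the unstable
fraction at or above the same threshold the call carries a germline/artifact
flag; the tumor-only fraction is used for the call itself (whether the
original analysis subtracted normal reads is not stated; we do not).

Population diversity at a locus is the Shannon index
H = −Σᵢ pᵢ ln pᵢ over the R observed read lengths, with pᵢ the proportion of
reads at the i-th length and 0·ln 0 = 0 (natural log throughout). H is
invariant to uniform scaling of counts and bounded by ln R.

Premature-termination variants are classified for nonsense-mediated decay
(NMD) escape purely positionally: escape in the first exon within the first
200 nt of the CDS, in the last exon, or in the penultimate exon within 50 bp
of the last exon–exon junction.

## Ellipsoidal cell segmentation

The imaging workflow assumes nuclei/cells are well approximated by filled
ellipses:

1. **Binarization** — 5×5 Gaussian smoothing (σ=1), then an adaptive
   local-mean threshold (51 px square window, additive offset of 2% of the
   channel's dynamic range), then one erosion and one dilation with a
   radius-1 disk and removal of connected components under 30 px. Window,
   offset and morphology sizes are package defaults (the approach, not the
   sizes, is prescribed); they suit cells of ~5–10 px semi-axis at ~0.5 µm/px.
2. **Seeding** — regional maxima of the Euclidean distance transform; each
   plateau is represented by its lexicographically smallest pixel; maxima
   closer than 5 px are merged keeping the larger distance value (ties break
   toward the smallest (row, col)).
3. **EM ellipse fitting** — a full-covariance 2-D Gaussian mixture over
   foreground pixel coordinates, one component per seed, initialized by
   nearest-seed (1-NN) hard assignment, iterated until the observed-data
   log-likelihood gain falls below 1e-4 (at most 100 iterations). Covariances
   are ridge-regularized when an eigenvalue drops below 1e-3 px²; components
   initialized with fewer than 3 pixels are dropped with a warning. The
   log-likelihood trace is monotone non-decreasing (EM guarantee) and is
   asserted in tests.
4. **Model selection** — each component is drawn as its chi-square(2 dof)
   0.95-quantile Mahalanobis contour and the candidate set is scored by the
   fitness degree

       score = (A_F − A_B − A_T − W_I) / E

   with E the covered-pixel count with multiplicity over components,
   A_F / A_B its foreground / background parts (so A_F + A_B = E always),
   A_T the unordered pairwise overlap count Σₚ C(n(p), 2) — a duplicated
   component is strictly penalized, and a coincident duplicate on perfectly
   covered foreground scores exactly 0.5 — and W_I an intensity penalty.
   W_I sums, per component, the foreground-pixel count inside the ellipse
   times the excess of its within-ellipse foreground intensity variance over
   the whole-foreground variance, normalized by the latter. This form is our
   construction: it is zero for uniform foreground (required for the
   perfect-fit limit of exactly 1), charges nothing for photon noise common
   to all pixels, penalizes ellipses straddling regions more heterogeneous
   than the foreground at large, and excludes covered background, which A_B
   already charges. Erroneous seeds are rejected by greedy backward
   elimination (refit with each single seed removed, accept the removal that
   most improves the score, stop when none does); exhaustive subset search is
   exponential and not attempted. The final score never falls below the
   full-set score.
5. **Assignment and phenotyping** — each foreground pixel goes to the
   maximum-posterior component (ties to the lower index). Phenotypes gate on
   per-cell mean intensities: pan-CK⁺ cells are tumor, split
   MSH6-proficient/deficient; otherwise CD20⁺ → B cell, FoxP3⁺ → Treg,
   CD8⁺ → cytotoxic T, CD4⁺ → helper T, else unclassified. Default
   thresholds are an Otsu split of the per-cell mean distribution,
   overridable. Neighborhood reports count, per tumor MSH6 class, immune
   cells of each subtype whose center lies within R = 100 µm (inclusive) of
   at least one tumor cell of that class, each immune cell at most once per
   class per tile.

The whole workflow is deterministic: no random number is consumed.

Note on the score in practice: with the 0.95 contour the drawn ellipse of a
uniformly filled cell is ~22% larger in linear size than the cell itself, so
even a perfect segmentation of a noisy tile carries a background charge and
scores well below 1 (≈0.3 on the benchmark tile); the score is a relative
model-selection criterion, and only the idealized perfect-fit case attains 1.

## Tumor growth with mutation-rate switching

A discrete-generation branching process: each step, every cell dies with
probability d = clip(1 − (1 − d₀)·fitness, 0, 1) — survival proportional to
fitness with baseline death d₀ for fully fit cells — and survivors divide
into two daughters. Each daughter toggles its mutation-rate regime with
probability β (basal hypermutator µ=6 vs ultra-hypermutator µ=120
mutations/division), then draws K ~ Poisson(µ of its own, post-toggle,
regime) new mutations. Independently per mutation and non-exclusively:
antigenic with P_antigen = 0.1, immune-escape with P_escape = 10⁻⁶, lethal
with P_lethal = 5×10⁻⁴, microsatellite-hitting with P_ms = 10⁻³ (each hit
moves the tracked MS allele ±1 with equal probability). Escape and lethal
flags are permanent along a lineage. Fitness is 0 for lethal cells, 1 for
escaped or antigen-free cells, and 1 + s otherwise (one flat penalty
regardless of antigen count; s = −0.8 by default). Tumors start from 100
identical founders and run to elimination (0 cells) or detection (default
100,000 cells; the desk-scale experiments use 10,000), with a 10,000-step
cap returning a censored outcome.

Two choices here were genuinely open and deserve their rationale:

- **Death link and d₀.** Only the direction "death decreases with fitness"
  is prescribed. A reciprocal link d = d₀/fitness cannot simultaneously make
  antigen-bearing cells strongly disfavored at s = −0.8 (needs large d₀) and
  keep an escaped ultra-hypermutator lineage viable under elevated lethal
  load (at P_lethal = 5×10⁻³, 45% of µ=120 daughters acquire a lethal, so
  viability needs 2(1−d₀)·0.55 > 1, i.e. d₀ < 0.09): the growth-time
  experiment would have an empty no-switching arm. The linear
  survival-proportional link decouples the two: immune kill scales with
  1 + s directly, and d₀ = 0.02 keeps cell-intrinsic death rare so that the
  lethal-mutation load is the binding constraint in the ultra-hypermutated
  regime. All boundary behaviors are preserved (fit cells die with d₀,
  lethal cells with certainty, antigenic cells at s=−0.8 with 0.804).
- **Toggle-then-mutate.** The regime switch represents the MMR homopolymer
  frameshift state, which governs the fidelity of that cell's own
  replication, so a daughter's mutation count is drawn at its post-switch
  rate. This ordering is also what lets switching rescue lineages under
  strong selection (a daughter switching down to basal before mutating has a
  realistic chance of staying antigen-free), the mechanism behind the
  elimination experiment.

Experiments run replicate streams spawned from one root `SeedSequence`
(independent, order-stable, parallelizable). Growth time is t_final minus
the last step at which the immune-escaped cell count was below 20 (0 if the
count starts at or above 20); a detected tumor that never escaped has growth
time 0. The elimination experiment simulates lineages until 10 reach
detection and reports eliminated × 10 / detected, averaged over replicate
batches; the selection grid {0, −0.3, −0.6, −0.8} is a package default (the
original grid is not printed).

## Mutation rate from the neutral VAF tail

Under neutral growth the cumulative count of subclonal mutations with
frequency ≥ f follows M(f) = µ(1/f − 1/f_max). The estimator keeps SNVs
(InDels dropped) inside heterozygous-diploid copy-number segments
(major = minor = 1) at depth ≥ 30 and VAF ≥ 0.05, fits M against
x = 1/f − 1/f_max by least squares through the origin — one point per tail
mutation at its observed VAF, tied VAFs sharing one count, avoiding bin-width
sensitivity — over a fixed window [0.05, 0.25] (floor: the minimum accepted
VAF; ceiling: below the diploid clonal cluster at purity/2; both
configurable; the clonal cluster is excluded by the window, not by mixture
modeling), and normalizes by the callable diploid region size in bp.

The 95% CI is a nonparametric percentile bootstrap (default 200 replicates,
2.5%/97.5% quantiles) resampling mutations with replacement, with the
replicate size drawn as Poisson(n) before resampling. The count renewal
matters: the tail count is the numerator of µ̂, and a fixed n-out-of-n
resample holds it nearly constant, producing severely anti-conservative
intervals (~50% coverage on the default fixture vs ~92% with renewal).

## Synthetic data: what it emulates and what it does not

- **Tiles** (`synth.gen_cell_image`): filled ellipses (semi-axes 5–9 px at
  0.5 µm/px) at uniform foreground intensity 200 over background 10 with a
  linear ramp of amplitude 20 (10%) and additive clipped Gaussian noise of
  SD 5 (2.5%), per-phenotype marker channels, a configurable number of
  touching pairs (centers at 90% of the summed semi-minor axes — close
  enough to merge their masks, far enough that each keeps a distance
  transform peak), and full ground truth. Not emulated: point-spread
  blurring, autofluorescence, spectral bleed-through, intensity variation
  within and between cells, irregular (non-elliptical) shapes. Passing the
  segmentation benchmark therefore shows the workflow recovers
  ellipse-shaped objects under noise, ramp and contact — not performance on
  real multiplex immunofluorescence.
- **Read-length distributions** (`synth.gen_ms_reads`): multinomial reads
  over allele lengths with single-step ±1 stutter. Real stutter is
  length-dependent and multi-step; a single step suffices to exercise the
  caller's thresholds.
- **VAF spectra** (`synth.gen_neutral_vafs`): a clonal cluster (binomial
  reads around the cluster center) plus a neutral tail. Deterministic mode
  places VAFs at the exact inverse of M at counts 1..N — an exact recovery
  oracle (µ̂ equals µ to machine precision). Sampled mode draws
  N ~ Poisson(M(f_min)) positions from the 1/f² density with binomial read
  sampling at the stated depth. The estimator recovery study uses µ ∈ {10,
  100} with windows chosen to contain ≥1,000 tail mutations (f_min = 0.008
  at µ=10, 0.05 at µ=100) at depth 1000, a deep-coverage regime in which
  1% VAFs are callable. Not emulated: subclonal selection, copy-number
  contamination of the tail, sequencing error.

## Problem sizes

The replicated experiments run at detection size 10,000 (not the model's
100,000), 50 tumors per arm for the diversity contrast, 100 detected tumors
per arm for growth time, and 50 replicate batches of 10 surviving lineages
for elimination; the estimator study uses 100 replicate spectra with a
200-replicate bootstrap each. These sizes give rank-test p-values many
orders below the 0.05 bar while keeping the full suite in a few minutes.

## Known limitations

- The fitness degree's E/A_F/A_B multiplicity convention and the W_I form
  are conventions fixed here; alternative readings of the printed formula
  exist (set semantics, ordered-pair overlaps) and would change absolute
  scores but not the perfect-fit limit, the conservation identity or the
  selection behavior checked by tests.
- Greedy backward seed elimination can miss jointly redundant seed pairs
  that only help when removed together.
- The simulator's death-rate calibration (d₀ = 0.02) is a package default;
  all directional findings above were verified under this single
  calibration, not across a calibration sweep.
- The tail estimator assumes the window is below the clonal cluster; with a
  misplaced window the fit is biased, and only the n_tail floor (50) guards
  against a degenerate fit.
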