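# Methods

## The origin-firing model

The package is organized around a minimal quantitative model of S phase on
one chromosome:

- Origins are placed by a renewal process: exponential inter-origin spacing
  with a configurable mean (a Poisson process), or fixed spacing when exact
  geometry is needed in tests. Each origin is independently assigned to an
  *early* or *late* timing class; early origins carry a class firing time of
  0 min, late origins a later constant (default 90 min), so every early
  origin fires before every late one at the population level.
- Population replication timing of a locus is the earliest arrival time over
  all origins, t(x) = min_o (t_fire(o) + d(x, o)/v), with a constant fork
  speed v (default 1.5 kb/min, a typical mammalian value). Timing is
  linearly rescaled to the 0–100 convention with the earliest locus at 100.
- Histone-mark ChIP coverage per 1-kb interval is Poisson counting noise
  around a flat background (default 100 reads/interval, i.e. a 10⁶-read
  library over 10 Mb), multiplied inside a ±2-kb window around *early*
  origins by 1 + (fold − 1)·s, where *fold* is the mark's enrichment
  (default 4× for H3K4me3, 3× for H3K4me2, 2× for H3K4me1 — the scale of
  ChIP folds at active origins and promoters) and *s* is a knockdown scale
  (1 = control, 0 = fully flattened). Overlapping windows take the maximum
  factor; `mark="input"` ignores enrichment. The library size equals the
  emitted reads, so binning conserves mass exactly.
- Single molecules replicate stochastically: each origin fires all-or-none
  with a per-condition probability; firing times get a per-cell uniform
  jitter (default 15 min); an origin overrun by an incoming fork before its
  own firing time is passively replicated and never fires. Dual-pulse
  labelling marks loci by first-arrival time: IdU during pulse 1 (15 min),
  CldU during pulse 2 (30 min). Molecules are fragmented into fibers with
  exponential lengths (default mean 650 kb), track boundaries receive
  Gaussian measurement noise (0.7 kb, the scale of optical resolution in
  combing), and segments under the 1-kb detection threshold are lost.

All randomness flows through numpy Generator streams derived from the
mandatory config seed plus a per-operation tag, so a fixed configuration is
bit-reproducible while different operations draw independently.

## Study presets

Two presets freeze the scenario parameters:

- `chip_config`: origin spacing 25 kb — the density of mapped (licensed)
  human origins. At this density the ±2-kb enrichment windows cover ~10% of
  the genome around early origins (early fraction 0.5), which is what makes
  a several-fold mark enrichment visible as an early shift of the binned
  coverage distribution.
- `combing_config`: origin spacing 120 kb — the density of *efficient*
  origins that fiber assays observe as initiation events — with the firing
  cohort spread over 15 min and the IdU pulse starting with the cohort.
  This emulates labelling cells released into early S phase after
  synchronization. Two consequences are deliberate: because no origin fires
  during the CldU pulse, no CldU-only newborn track can fuse with an
  ongoing fork's CldU track, and the measured CldU length distribution is
  identical across firing conditions (fork velocity is exactly invariant to
  the firing probability); and because the firing-time spread is small
  relative to the inter-origin fork transit time, origin interference
  (passive replication) is rare, so halving the firing probability nearly
  doubles the inter-origin distance.

A single spacing cannot serve both scenarios: fiber figures need gaps
longer than the ~135-kb labelled span of one origin to stay resolvable,
while KS detection needs the enrichment windows to carry an appreciable
mass fraction. Treating ChIP-visible origin sites as denser than
per-molecule initiation events is also the standard resolution of the
licensing-vs-firing discrepancy in the field.

## Analysis conventions

- Coordinates are 0-based half-open (BED/bedGraph) throughout; reads are
  assigned to intervals by their strand-aware 5′ start, one interval per
  read; reads outside all intervals count toward the library size only.
- Timing bins are closed-left/open-right on [0,100] with the top value
  folded into the last raw bin, then reversed (displayed bin 1 = earliest).
  Intervals with timing values but zero coverage stay in their bins with
  zero mass, so total mass is conserved.
- The KS p-value uses the assumed-sample-size convention: the binned
  distributions are treated as empirical CDFs of n = 100 observations per
  sample, giving p = exp(−2·(n/2)·D⁺²) one-sided and the Kolmogorov series
  two-sided. A permutation cross-check (resampling 100 pseudo-observations
  per distribution) agrees within a factor of two wherever 10⁴ permutations
  can resolve the p-value. Both one-sided directions are computed; the
  early-shift call takes the larger D⁺.
- An initiation event on a fiber is an IdU core flanked on both sides by
  contiguous CldU, where the core may contain an internal unlabelled gap up
  to 10 kb (an origin that fired shortly before the pulse); two inward-facing
  forks farther apart are scored as independent structures, as a microscopist
  would score them. A divergent CldU-only pair across a gap of up to 3 kb
  (an origin whose IdU core fell below detection) also counts. Events are
  event midpoints; IODs never span fiber breaks.
- Fork velocity uses CldU tracks adjacent to IdU on exactly one side
  (CldU-only tracks may be forks born in pulse 2; CldU flanked by IdU on
  both sides is a termination junction) whose outer end lies strictly inside
  the fiber (tracks running off a fiber end are truncated).
- Figure classes: a fiber with ≥2 events scores one `interspersed_origins`
  structure; exactly one event scores `one_origin_bidirectional` when both
  flanking CldU tracks end inside the fiber, else `single_origin_only`;
  eventless fibers contribute one structure per connected track group —
  `termination` when the group contains a gap-free CldU junction flanked by
  IdU on both sides, otherwise `isolated_fork`. The counts are exhaustive
  and mutually exclusive by construction.
- Percentiles (box summaries) use linear interpolation (type 7); whiskers
  are the 10th/90th percentiles and outliers lie strictly outside them.
- Mann–Whitney: exact null enumeration when the pooled sample has no ties
  and n_a·n_b ≤ 400, otherwise the normal approximation with midrank tie
  correction and continuity correction; a fully tied pooled sample returns
  p = 1. Chi-square uses pooled expected counts; classes with pooled
  expected zero are dropped with a warning and the degrees of freedom
  adjusted.
- Percent input adjusts the input Ct by −log2(1/input_fraction) with
  input_fraction defaulting to 1 (pre-adjusted Cts); the formula is scale-free
  in any common Ct offset. FACS population intensity uses the mean
  (configurable in principle; medians would serve as well for lognormal
  populations).
- The Ct generator adds a lognormal mean-bias correction of ln2·σ² cycles to
  the IP Ct so the expected recovered % input equals the requested truth
  exactly rather than being biased by e^{(ln2·σ)²}.

## What the generator does and does not emulate

It reproduces the statistical structure the analyses rely on: early-timing
concentration of mark coverage, Poisson counting noise, all-or-none origin
firing with passive replication, dual-pulse label geometry, fiber
fragmentation, detection losses, boundary measurement noise, Ct noise, and
lognormal cytometry populations. It does not emulate sequence content, GC
or mappability biases, nucleosome structure, replication-timing domain
organisation (timing decays linearly with distance from the nearest origin),
origin clustering or correlated firing (origins fire independently),
checkpoint feedback, or fluorophore spectral artefacts. Passing tests
therefore demonstrate that the *procedures* behave as specified under the
modelled noise, not that real data will show effects of the same size. In
particular, because visible initiation events and visible structures both
scale with the firing probability under independent thinning, the
replication-figure census shifts less here than a clustered-firing genome
would shift; the isolated-fork excess and the interspersed-origin deficit
under a firing deficit reproduce, while their per-200-structure chi-square
significance is seed-dependent.

## Numerical and degenerate-input choices

- Interval/bin arithmetic is exact integer work; the only tolerances are
  1e-12 on conservation and 1e-9 on segment geometry.
- A genome whose rescaled timing is constant (single-class, zero span) maps
  every interval to 100; a genome with no origins is rejected.
- Zero-mass distributions and zero-size libraries are rejected rather than
  returning NaNs; negative net BrdU signal clips to 0 with a warning.
- Adjacency of fiber tracks uses a 1e-6 kb tolerance: the generator emits
  exactly touching label junctions, and the measurement-noise step moves
  shared boundary coordinates together so junctions stay junctions.
- Fragmentation cuts and the detection threshold can orphan part of a
  structure; all classification rules operate on what remains visible.

## Known limitations

- The firing-probability contrast reaches the figure census only through
  event thinning; condition-dependent fork speeds, origin clustering, or
  checkpoint-slowed forks are out of scope.
- The one-sided KS p-value at an assumed n is a convention, not a sampling
  statement about the intervals (which number in the thousands and are
  autocorrelated); treat it as a ranking score calibrated by the
  permutation cross-check.
- SAM/BAM input requires pysam; without it the coverage API accepts
  DataFrames or (chrom, pos) iterables.
- Fibers shorter than the detection threshold and segments squeezed to zero
  by measurement noise are silently dropped, which slightly thins the
  smallest structures.
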