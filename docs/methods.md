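# Methods

## Model

`cpgscan` segments DNA into background (B) and CpG-island (I) states with a
two-state hidden Markov model and then filters the decoded segmentation
with sliding-window composition criteria.

The hidden chain has initial probabilities π, a 2×2 transition matrix
a_{ij}, and per-state emissions that are conditional on the previous base:
e_s(b | p), a row-stochastic 4×4 table per state, plus a per-state
start-base distribution e_s(b) used at the first scored position. The
first-order emission model is deliberate: the island signal is the CpG
*dinucleotide* (C immediately followed by G), and the single entry
e_I(G | C) vs e_B(G | C) is exactly the CpG-enrichment contrast; an
order-0 model over single bases can represent GC richness but not CpG
richness. Equivalently, the model emits overlapping dinucleotides.

Masked positions (N, or any other IUPAC ambiguity code, which is collapsed
to N on input) contribute no emission factor; the state chain still
advances through them with the transition probabilities, and the first
unmasked base after a masked run is scored with the start-base
distribution. This avoids inventing emission probabilities for unknown
bases while keeping segment geometry intact across assembly gaps.

Likelihood and posteriors use the scaled forward-backward recursions (the
per-position scale factors' log-sum is the sequence log-likelihood);
decoding uses the Viterbi recurrence in log space. Both are O(L) with two
states, so chromosome-scale inputs neither underflow nor blow up in time.
Viterbi argmax ties are broken toward B at every step, which makes island
calling conservative and output deterministic.

## Parameter estimation

Baum-Welch (EM) re-estimates π, a, the 32 conditional emission entries and
the start-base distributions from the forward-backward posteriors. The
default starting point is π = (0.5, 0.5), sticky transitions
a_BB = 0.9995 and a_II = 0.995, and both states' emission rows set to the
genome-wide base frequencies with the island state's CpG continuation
e_I(G | C) tripled and the row renormalized. EM cannot break an exact
label symmetry on its own, so the asymmetric CpG boost (optionally plus a
seeded multiplicative jitter) is what separates the states; which state
ends up island-like is still arbitrary, so downstream code orders states by
e(G | C) (the CpG-richer state is I). Convergence is declared when the
relative log-likelihood improvement falls below `tol` (default 1e-6,
`tol = 0` disables early stopping and runs exactly `max_iter` iterations);
`max_iter` defaults to 500. Emission rows for previous-base contexts never
seen in the data keep their previous values rather than dividing by zero.

## Island calling

A window of `window_length` (default 500 bp) slides by 1 bp. A window
qualifies iff:

- GC fraction ≥ `min_gc` (default 0.55),
- Obs/Exp CpG = (N_CG · L)/(N_C · N_G) ≥ `min_obs_exp` (default 0.65),
  defined as 0 when the window lacks C or G,
- the Viterbi island fraction ≥ `min_island_fraction` (default 0.5; the
  criterion is dropped in `use_hmm = False` criteria-only mode), and
- the window contains no masked base (windows are disqualified rather than
  rescaled, so N runs cannot inflate the ratios).

Qualifying windows are unioned into candidates. In HMM mode each candidate
is then clipped to the span of Viterbi I labels inside it. This clip is the
step that turns the decoded path into boundary precision: the raw window
union necessarily over-reaches into background by up to a window length on
each side (any window that is mostly island still qualifies), whereas the
Viterbi boundary is sharp to a few tens of bases. It is also what excludes
Alu-like repeats: a ~280 bp high-GC, CpG-rich insert can drag qualifying
windows along with it, but its island-labeled span is far shorter than the
minimum island length, so the clipped candidate is discarded. Candidates
separated by ≤ `merge_gap` (default 100 bp) are merged when the merged
extent still passes the composition thresholds; each candidate is then
trimmed 1 bp at a time from whichever end improves the failing
full-interval criteria more (an exact tie shaves both ends, keeping the
procedure mirror-symmetric under reverse complement); finally intervals
shorter than `min_length` (default 500 bp) are dropped and all statistics
are recomputed over the exact emitted interval. Everything runs on prefix
sums, so a scan is O(L).

Both window statistics are strand-symmetric (CG is its own
reverse-complement dinucleotide class), so criteria-only calls on a
reverse-complemented sequence mirror the forward calls exactly.

Coordinates are 0-based half-open internally and in BED output; the
human-readable TSV report is 1-based inclusive.

## Methylation analysis

Islands are classified methylated iff score ≥ threshold (default 0.4, the
conventional 5mC log2-ratio cutoff; the boundary is inclusive, and
pre-assigned statuses are kept unless reclassification is requested). Group
comparisons per trait (length, GC %, Obs/Exp) use the two-sample
Kolmogorov–Smirnov statistic D = sup_t |F₁,n(t) − F₂,m(t)|, evaluated at
the pooled sorted unique points with right-continuous EDFs, which attains
the supremum and is deterministic under ties. The default p-value uses the
asymptotic Kolmogorov distribution at the effective sample size
n_e = nm/(n+m) with the standard small-sample correction
(√n_e + 0.12 + 0.11/√n_e)·D; a permutation alternative enumerates all
group assignments of the pooled sample when there are ≤ 20,000 of them and
otherwise uses 10,000 seeded Monte-Carlo draws. The asymptotic
approximation degrades for small groups, so a warning is emitted whenever
min(n₁, n₂) < 25. No multiple-testing correction is applied across the
three traits.

z-scores standardize each island's methylation score within its status
group (sample sd, n−1 denominator, matching the ± values in the group
table); a group needs ≥ 2 members and nonzero sd, otherwise its z-scores
are flagged undefined. Length histograms use half-open bins
[k·w, (k+1)·w), default width 300 bp.

## Synthetic data

The generator draws the hidden chain and then bases from exactly the
detection model's emission structure, so training on simulated data is a
well-posed parameter-recovery problem. Defaults describe a desk-scale
chromosome chosen to echo promoter-island biology:

- 200 kb, ten planted islands of 800–1200 bp (promoter islands typically
  run ~0.9–1.5 kb), ≥ 2 kb apart;
- background GC 0.40 with the CpG continuation e_B(G | C) depleted to
  0.08 (background vertebrate DNA is CpG-poor);
- island GC 0.62 with conditionally independent bases, giving
  Obs/Exp CpG ≈ 1 inside islands;
- transitions giving mean dwell times of 1 kb (island) and 19 kb
  (background), i.e. ~5 % island occupancy, when the chain itself is
  sampled instead of planting intervals;
- three 280 bp Alu-like decoys: exact base composition at GC 0.60 (exact
  counts make the decoy's GC level hold deterministically rather than on
  average) with a seeded random arrangement, so adjacent C·G pairs occur at
  the product rate and the insert is CpG-rich like a young Alu — a
  composition look-alike that only the length/HMM logic can reject. Decoys
  are placed in background regions and keep their B truth labels.
- methylation scores: a two-component normal mixture, N(1.2, 0.4) for
  methylated islands (probability 0.08, echoing the strong unmethylated
  majority among promoter islands) and N(−0.5, 0.4) otherwise, with the
  true component label recorded for accuracy scoring.

Everything is reproducible from a single integer seed.

What the simulator does *not* emulate: real chromosomal base-composition
heterogeneity (isochores), repeat families beyond the single decoy model,
assembly gaps beyond uniform N masking, and methylation scores correlated
with sequence features. Passing tests therefore demonstrate correctness of
the algorithms and calibration under the generative model, not detection
accuracy on real chromosomes.

## Numerical and design choices

- All probability work in log space or with per-position scaling; the two
  representations agree to 1e-8 on sequences short enough to compare.
- EM monotonicity holds to ~1e-12 per iteration at 10 kb scale; the test
  tolerance of 1e-9 allows fixed-point rounding noise.
- Problem sizes in the test suite (10 kb EM runs, a 200 kb
  training/detection fixture, 500-island analysis tables, brute-force
  enumeration exhaustive to length 3 and randomized to length 8) were
  chosen so that each check is statistically decisive while the whole
  suite stays interactive-fast.
- The Obs/Exp CpG ratio uses the Gardiner-Garden–Frommer form
  (N_CG · L)/(N_C · N_G).
- Degenerate inputs have named failure modes: empty/fully-masked
  sequences, transition rows of zeros, empty samples in the KS test,
  unresolvable island ids, and constant-score groups are all rejected or
  flagged rather than silently propagated.

## Known limitations

- Exactly two states and first-order emissions; no posterior-decoding
  alternative to the Viterbi path.
- The asymptotic KS p-value is unreliable for very small groups (warned,
  not corrected); permutation mode is the remedy.
- Training on a single concatenated record: the CLI trains on the first
  FASTA record only; multi-record training would require pooling
  sufficient statistics across records (the library's building blocks
  allow this, the CLI does not expose it).
- Island calls never span FASTA records, and soft-masked (lowercase) bases
  are treated as ordinary bases unless `--hard-mask` is given.
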