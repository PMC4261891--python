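# Methods

## Model and assumptions

A DNA sequence is treated as text over {A, C, G, T}; RNA input is
tolerated by mapping U to T. Each sequence is rewritten three times, once
per chemical bipartition of the bases (purine/pyrimidine R/Y, amino/keto
M/K, weak/strong W/S), shrinking the word universe per window size *k*
from 4^k to 2^k. A sliding window of length k and step 1 over a length-n
sequence yields m = n − k + 1 windows; window start positions are 1-based.

For each word the occurrence positions P₁ < … < P_R (P₀ := 0) give local
frequencies LF_r = 1/(P_r − P_{r−1}); these are embedded at their
positions into a length-m zero row, and the feature is the Shannon entropy
of the row's normalised partial sums (see the README for the formulas).
Three modelling conventions are fixed here:

* **0·log₂0 := 0.** Required for leading zeros in the partial sums; it
  also makes a single trailing occurrence score exactly 0.
* **Absent words score 0.** The Z = 0 limit of the entropy; it keeps all
  vectors 12-dimensional and comparable.
* **Entropy is taken over the full m-length embedded row**, zeros
  included, not over the occurrence list alone. The partial sums carry
  across non-occurrence positions, which is what encodes *position* (a
  lone occurrence at position r scores log₂(m − r + 1), so earlier
  occurrences score higher).

Features are deliberately **not** length-normalised: each component is
bounded by log₂ m and therefore grows slowly with sequence length. Mixing
sequences of very different lengths shifts all components of the longer
sequences upward; users clustering such mixtures should be aware the
distance then partly reflects length. The model is intended for sequences
up to a few thousand bases, where 12 dimensions retain enough signal.

Similarity is the Euclidean distance between feature vectors. No
reverse-complement canonicalisation is attempted.

## Baseline featurisers

* **k-tuple** (default k = 3): relative frequency of each of the 4^k DNA
  words over the m windows. Relative frequencies (not raw counts) are the
  default so that distances are comparable across lengths; raw counts are
  available behind a switch.
* **DMk** (default k = 3): the same LF/partial-sum entropy operator
  applied to each of the 4^k DNA words — identical core code path as CPF,
  including the full-length embedding convention (on a two-letter
  sequence, DMk at k = 2 coincides with the matching CPF scheme block,
  which the tests assert). Whether the original method embeds over the
  full window row or only over the occurrence list is ambiguous; the
  embedded form is adopted for consistency with CPF's worked examples.
* **TSM** (k = 2): category-mapped word frequencies, 12 dimensions, each
  scheme block normalised to sum 1.

## Clustering harness

Lloyd's k-means with:

* **Initialisation**: c centres drawn uniformly without replacement from
  the *distinct* data rows (duplicate sequences would yield coincident
  centres that immediately empty); greedy D² ("kmeans++") seeding is
  available as an option.
* **Restarts**: within one repeat, Lloyd runs from `restarts` (default 10)
  independent initialisations and the solution with the lowest
  within-cluster sum of squares is kept. A single random-point
  initialisation frequently leaves one tight group without a centre and
  merges it into a neighbour — a local optimum Lloyd cannot leave — and
  best-of-restarts by distortion is the classical remedy (it is also how
  the long-standing scipy `cluster.vq.kmeans` routine behaves). On the
  default synthetic conditions this raises mean purity from ≈ 0.82 to
  ≈ 0.98–1.0.
* **Convergence**: maximum centre movement < 1e-8, or 300 iterations.
* **Ties** in nearest-centre assignment break to the lowest centre index;
  clusters that empty are dropped, so the effective cluster count can fall
  below c.
* **Repeats and seeding**: because random initialisation dominates
  run-to-run variation, each experiment is repeated (default 10 times) and
  scores are arithmetic means over repeats. One master seed spawns
  per-repeat child seeds (`numpy.random.SeedSequence.spawn`), so repeats
  are independent yet exactly reproducible.

## Evaluation conventions

Purity, precision, recall and F are as in the README. Two weighting
conventions are this package's explicit choices: overall purity weights
clusters by size, and overall F weights families by size (the standard
reading). Argmax ties (a cluster split evenly between families) resolve to
the lexicographically smallest family label, for determinism. A family
whose label dominates no cluster scores precision = recall = F = 0.

## Synthetic data generator

`generate_families` emulates a collection of homologous gene families:
each family descends from an independent ancestor drawn i.i.d. over the
base alphabet, and each member substitutes every site independently with
probability μ to a uniformly chosen *different* base. Defaults — 6
families × 20 members, 600 bp, μ = 0.03, uniform composition — produce
families whose within-family spread is comparable to, but smaller than,
the nearest between-family distance in CPF space: separable, not trivial.
Options add single-base indels (length variation) and GC bias.

What the generator does *not* emulate: phylogenetic structure within a
family (members are independent draws from the ancestor, star-shaped),
rate heterogeneity, codon structure, repeats/low-complexity tracts, and
the heavy length variation of real gene families. Passing the synthetic
recovery tests therefore shows the pipeline separates point-substitution
families of this size and divergence; it does not certify performance on
real, overlapping families, where published alignment-free comparisons
show quality degrading substantially as family counts grow.

## Numerical choices

* IEEE double throughout; entropy sums use numpy reductions.
* Test tolerances: 1e-12 against the exact-rational brute-force oracle,
  1e-9 for float-algebra properties, and 1e-3 against 4-decimal printed
  reference values (which appear truncated rather than rounded).
* Degenerate inputs: all-zero entropy input returns 0; sequences shorter
  than the window are rejected (or skipped with a warning at I/O level);
  ambiguous residues are rejected by default or, under masking, excluded
  window-wise, with frequency denominators taken over counted windows so
  normalisation invariants survive.

## Problem sizes

The shipped tests and the acceptance script run entirely on generated
data: the largest clustering exercise is 120 sequences × 600 bp × 10
repeats × 10 restarts, which completes in seconds; entropy oracles
enumerate all 256 indicator rows of length 8. These sizes were chosen to
exercise every code path at full fidelity while keeping the suite quick to
run.

## Known limitations

* Window size k = 2 is the default and the well-tested regime; larger k
  (dimension 3·2^k) is supported for sweeps but not length-normalised.
* k-means assumes roughly isotropic clusters in feature space; families
  with strongly unequal sizes or internal structure may need a different
  clusterer.
* The purity/F implementation requires every clustered id to carry a
  truth label; partial truth is an error, not a filter.
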