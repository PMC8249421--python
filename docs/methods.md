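# Methods

## Model and procedure

The pipeline treats a DNA sequence as a set of binary occurrence signals
and measures local word abundance by digital filtering rather than by
alignment.

1. **Bins.** For word length *q*, the 4^q q-gram words over {A, C, G, T}
   are enumerated in lexicographic order (A < C < G < T). The guard
   q ≤ 12 bounds the alphabet at ~16.8M bins.
2. **Bin signatures.** For each bin, a bit vector of length n − q + 1
   marks every start position where the bin occurs. For an N-free
   sequence the signatures partition the positions: their element-wise sum
   is the all-ones vector. Any q-gram window touching an `N` matches no
   bin, so column sums can drop below 1 there; this is the conservative
   choice over fractional assignment across compatible bins.
3. **FIR filtering.** Each signature x is convolved causally with filter
   taps b_0..b_k, with zero initial conditions and output truncated to the
   input length (not full linear convolution, which would append k extra
   positions). With a uniform unit window of width W (k = W − 1, all taps
   1) the output at position i is the exact count of occurrences starting
   in signature positions max(1, i − W + 1)..i; with normalized taps 1/W
   it is the local occurrence fraction in [0, 1].
4. **Data matrix and PCA.** Each sequence's 4^q density rows are
   concatenated bin-major into one row of D (m × 4^q·(n − q + 1)).
   Columns are mean-centered but not variance-scaled: all columns are
   densities in identical units, and the embedding is deliberately not
   scale invariant. Scores are projections onto the top-k right singular
   vectors of the centered matrix — numerically preferable to forming the
   p × p covariance when p ≫ m. Explained-variance fractions are divided
   by the total variance over all components, not just the retained ones.
5. **Dissimilarity and tree.** The dissimilarity value (DV) between two
   sequences is the Euclidean distance between their k-dimensional score
   rows, serialized in condensed pair order (2,1), (3,1), …, (m,m−1).
   UPGMA merges the closest pair at half its dissimilarity and updates
   distances by the size-weighted arithmetic mean over all cross-cluster
   leaf pairs, producing a rooted ultrametric tree. Genetic distance (GD)
   between taxa is the cophenetic distance — twice the height of their
   lowest common ancestor.

## Assumptions

- Sequences are homologous, equal-length, and supplied on the sense
  strand; no reverse-complement canonicalization is applied. Unequal
  lengths are a hard error (length normalization schemes are out of
  scope).
- Only {A, C, G, T, N} are accepted (with `U` mapped to `T` on input);
  other IUPAC ambiguity codes are rejected loudly rather than coerced.

## Parameters

| Parameter | Meaning | Default | Rationale |
|---|---|---|---|
| q | word length (bases) | 1 | the four single-nucleotide densities analysed simultaneously are the headline configuration; q = 2, 3 expose di-/tri-nucleotide structure at 4^q× the columns |
| W | FIR window width (signature positions) | 10 | there is no canonical value; W trades spatial resolution against smoothing, and the CLI logs the W in use on every run to keep the choice visible |
| normalize | taps 1/W instead of 1 | off | unit taps give integer counts; normalization only rescales all columns by 1/W and leaves PCA scores and all downstream distances unchanged up to that factor |
| k | retained principal components | 3 | the top three components capture the bulk of the variance for sequence-family panels and make scores directly plottable |
| K | clusters to cut from the tree | none | optional; cutting removes the K − 1 highest merges |

## Numerical choices

- PCA sign ambiguity is fixed by flipping each loading vector so its
  largest-magnitude entry is positive; runs are bit-reproducible, and
  Euclidean distances downstream are sign-invariant anyway.
- Zero total variance after centering (all sequences identical) raises a
  degenerate-data error instead of returning zero scores.
- UPGMA ties within 1e-12 resolve to the lowest (row, column) cluster-id
  pair; Newick children are ordered by the smallest leaf index in their
  subtree. Both rules exist only to make output deterministic.
- Numeric TSV artifacts carry 12 significant digits, so chaining stages
  through files reproduces the in-memory pipeline to round-off (~1e-9
  relative); byte-identical determinism holds for repeated runs of the
  same path.
- Signatures are stored as uint8, densities as float64.

## Synthetic data generator

`synthetic_fixtures` emulates a panel of sequence families diverged from
common ancestors by point mutation: a uniform random root is mutated at
`inter_rate` per base to give each family ancestor, and each ancestor at
`intra_rate` to give the members. Substitution is Jukes–Cantor style —
uniform over the three other bases — so rates are capped at 0.75
(saturation) and lengths are preserved. Defaults (4 families × 3 members,
length 300, intra 0.01, inter 0.30) mirror the scale of a small
cross-species gene panel with well-separated families. One integer seed
drives root, ancestor, and member streams through a documented
seed-splitting rule, so any subset is reproducible in isolation.

What the generator does **not** model: insertions/deletions, rate
heterogeneity along the sequence, codon or GC-content structure,
back-mutation-aware evolutionary distances, and sequencing ambiguity
(no `N`s). Passing the cluster-recovery tests therefore demonstrates that
the pipeline separates substitution-diverged families at these rates and
lengths; it does not certify performance on real data with indels or
compositional bias, where equal-length homologous segments must first be
curated.

## Test problem sizes

Property and acceptance tests run at deliberately small scale: sequences
up to length 300–444, panels of 8–12 taxa, 20–100 random replicates per
property. These sizes already exercise every code path (the pipeline is
O(m·4^q·n) for densities and O(m³) for UPGMA) while keeping the full
suite in the low seconds.

## Known limitations

- The UPGMA implementation is the naive O(m³) algorithm — fine for tens
  to hundreds of taxa, not for thousands.
- Densities are dense arrays; for large q the 4^q × (n − q + 1) profile
  per sequence grows quickly (hence the q ≤ 12 guard; in practice q ≤ 3
  is typical).
- Equal-length input is required by construction; there is no built-in
  normalization for unequal lengths.
- GD values depend on the retained components k and the window W; they
  are internally consistent but not comparable across configurations.
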