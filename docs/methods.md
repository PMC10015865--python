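# Methods

## Model and procedure

`hics` treats domain-boundary detection in a single-cell Hi-C map as a 1D
density-peaks problem.  Density-peak clustering characterizes cluster
centers by two properties — high local density and large distance to any
point of higher density.  Here the "density" of a genomic bin is its
insulation strength ρ and the "distance to a denser point" is δ, the bin
distance to the nearest bin of strictly higher ρ.  Domain boundaries are
exactly the bins that score high on both: they insulate their flanks
strongly and dominate their neighborhood.

Per chromosome of one cell the pipeline is:

1. **Binning.** Contacts are aggregated into fixed-size bins (default
   40 kb, `bin_size`).  Internal coordinates are 0-based half-open bins;
   text inputs are 1-based bp; BED outputs 0-based half-open bp.
2. **Optional smoothing** (default on; `--no-embed` bypasses).  The map
   becomes an unweighted graph — one node per bin, one edge per nonzero
   off-diagonal pair.  Nodes are embedded from biased second-order random
   walks, and the smoothed "contact probability" of a bin pair is the
   cosine similarity of the two embedding vectors.  Only the top
   `keep_fraction` (default 5%) of non-gap upper-triangle pairs is kept;
   ties at the cutoff are all kept so the result is order-independent;
   the diagonal is removed.
3. **Insulation profile.** For each bin, I_intra = Ia + Ib sums contacts
   within the left flank (i−W ≤ u < v ≤ i) and right flank
   (i ≤ u < v ≤ i+W); I_inter = Ic sums contacts crossing the bin
   (i−W ≤ u < i < v ≤ i+W); windows truncate at chromosome ends and
   ρ = (I_intra − I_inter)/(I_intra + I_inter), with ρ := 0 when the
   denominator is 0.  The bin itself belongs to both flanks and to neither
   side of the cross region; this two-flank-inclusive convention is a
   documented choice.
4. **δ, normalization, ranking.** δ(i) = min{|i−j| : ρ(j) > ρ(i)} capped
   at `max_search` (MAX, default 500 bins); the profile maximum gets MAX,
   the density-peaks convention for the top point.  ρ′ is min–max scaled
   to [0, 1]; δ′ = δ/MAX; η = ρ′·δ′.  Bins are ranked by η descending
   (γ = 1 is the largest; ties break toward the lower bin index), and
   γ′ = γ/γmax.
5. **Automatic threshold.** The reflection point r minimizes
   √(η(i)² + γ′(i)²) along the ranked curve — the elbow where the strong
   head of the η curve gives way to the bulk.  Boundaries at scale α are
   bins with η > α·η(r); ties at the argmin resolve to the smallest rank.
6. **Hierarchy.** The profile is α-independent, so a ladder of α values
   (default 0.2, 1, 4, 8) re-screens the same profile.  Thresholds grow
   with α, so boundary sets are nested *exactly*; this is asserted, not
   assumed, on every hierarchy build.  A boundary bin opens the domain to
   its right; chromosome ends delimit implicitly; runs of gap bins split
   domains and belong to none.

**Gap regions.** A bin is a gap if it has no contacts at all, or if its
cross-window sum I_inter is 0.  Gap bins carry NaN metrics, are excluded
from ranking, from the δ search (in both roles), and from boundary
candidacy.  Note one consequence: a *perfectly* insulating bin also has
I_inter = 0 and is masked; on real sparse maps this does not occur at
informative bins, but on dense block-structured toys the call then lands
on the immediate flank of the ideal boundary bin.

### ρ normalization

ρ can be negative (cross-dominated neighborhoods), so scaling by ρmax
alone would not keep ρ′ within [0, 1]; `hics` uses min–max scaling
ρ′ = (ρ − ρmin)/(ρmax − ρmin), which preserves the intended range for any
profile.  A profile with all-equal ρ is rejected ("flat insulation
profile") rather than silently normalized.

## Graph-embedding smoothing

The walk generator follows the node2vec scheme: `walks_per_node` walks of
length `walk_length` from every non-isolated node, with second-order bias
controlled by `p` (return) and `q` (in–out); `p = q = 1` (the default)
reduces to uniform first-order walks, which are fully vectorized.  Instead
of training a stochastic word2vec model on the walks, co-occurrence counts
within `context_window` are converted to positive pointwise mutual
information and factorized by truncated SVD (embedding = U·√S, default 128
dimensions).  PPMI + SVD is the classical closed-form counterpart of
skip-gram with negative sampling; it is deterministic given the walks, so
the entire pipeline is bit-reproducible under a fixed seed — a property a
sampled SGD training loop cannot give without pinning thread counts.

The unweighted-graph design deliberately erases count magnitudes: for an
ultra-sparse cell (a few contacts per bin) a contact's *existence* is the
signal and its count is mostly noise, and in our own synthetic
measurements the smoothing improves boundary precision in that regime.
For deeply sampled maps the same erasure discards most of the information,
and `--no-embed` (insulation on raw counts) is the better route; the
recovery benchmarks below use it.

## Synthetic-data generator

`simulate_cell` emulates one chromosome of one cell:

- **Planted hierarchy.** Finest-level boundaries with spacing
  ≥ `min_domain_bins` (default 20 bins = 0.8 Mb at 40 kb) plus a geometric
  excess of mean ~10 bins; each coarser level keeps a random ~40% subset,
  so levels are nested by construction.
- **Intensity.** λ(i,j) ∝ |i−j|^(−decay_exponent) (default 1.0, the
  canonical contact-decay slope) multiplied by `intra_boost` (default 3.0)
  once per hierarchy level on which i and j share a domain — nested
  domains compound multiplicatively, like observed nested enrichment.
- **Sampling.** `depth` contacts (default 2,000 per 500-bin chromosome,
  the single-cell sparsity regime at reduced scale) are drawn
  multinomially from λ over the upper triangle, so total depth is exact
  and maps are reproducible by seed.  A 2% fraction of bins is zeroed as
  gaps (never on a planted boundary bin).

The default finest planted scale (20–40 bins) is chosen to be resolvable
by the default detection geometry: the insulation window half-width is
W = 20 bins, and with MAX = 500 the elbow threshold at α = 1 can admit at
most about n·√(ρ′/MAX) ≈ 20 boundaries on a 500-bin chromosome (a
boundary's η scales with its spacing/MAX, while the rank penalty γ′ scales
with the boundary count/n).  Planting domains much smaller than the window
produces boundaries that no window-based statistic at this parameterization
can separate from the bulk — α < 1 levels are the place where finer
structure appears, exactly as in the multi-scale design.

What the generator does **not** emulate: polymer-physics constraints,
compartment checkerboards, translocations, diploid homolog mixing,
restriction-site and mappability biases, or cell-cycle dependence of
contact decay.  Passing the recovery benchmarks therefore shows the
detector is correct and well-calibrated for block-structured,
distance-decaying sparse maps — not that it is robust to every artifact of
real single-cell libraries.

## Recovery benchmarks and their scale

The planted-boundary benchmark uses 10 cells of 500 bins at 50 contacts
per bin (depth 25,000), α = 1, matching within ±1 bin; recall/precision
are means over cells, computed with greedy one-to-one nearest-first
matching (empty call sets score precision 1 by convention).  Individual
cells sit near the detection limit — a cell with ~18 planted boundaries
can score markedly lower than one with 14 (the elbow lands inside the
boundary cluster) — which is why the benchmark is a mean over seeds, and
recall at one-tenth depth is reported to show the degradation direction.
Problem sizes (500-bin chromosomes, 10–20 cells per experiment) keep every
check within seconds on one CPU; the statistical behavior is unchanged at
larger n since all thresholds are scale-normalized (δ by MAX, γ by n).

## Enrichment instrument

`boundary_profile` averages a binned peak track at offsets −K..+K around
boundary bins (default K = 25, i.e. ±1 Mb at 40 kb), skipping
out-of-range positions.  The **concentration score** reported is the mean
count at |offset| ≤ 1 divided by the mean count at |offset| ≥ ⌈K/2⌉ — a
locally defined center-vs-background ratio (infinite when the background
is empty but the center is not, NaN when both are).  A uniform track gives
exactly 1 for any boundary set, which the tests assert as a guard against
positional artifacts.

## Numerical and degenerate-input choices

- δ computation visits bins in decreasing ρ keeping seen positions in a
  sorted list (O(n log n)); equal-ρ groups are queried before insertion so
  the "strictly higher" comparison is exact; an O(n·MAX) brute-force scan
  is kept in the test suite as the independent oracle.
- All tie-breaks (γ ranking, reflection argmin) resolve toward the smaller
  index/rank, making every output deterministic.
- The top-fraction cut keeps ⌈fraction·P⌉ pairs plus any ties at the
  cutoff value; candidate pairs are the non-gap upper-triangle pairs of
  the chromosome.
- Similarities are not clipped at 0 before the cut; the strict value
  ordering means a negative similarity can never displace a positive one.
- ρ with zero denominator is 0 (neutral); such bins are usually also gaps
  via the I_inter = 0 rule.
- W ≥ n_bins, flat ρ profiles, η(r) = 0, edgeless graphs, and empty
  boundary sets for profiling all raise informative errors instead of
  propagating NaN.

## Known limitations

- The reflection-point threshold is scale-sensitive: on short chromosomes
  (small n) the rank penalty γ′ grows quickly and α = 1 admits few
  boundaries; fine structure must be accessed via α < 1.
- The I_inter = 0 gap rule can mask a perfectly insulating bin on
  idealized inputs (see above).
- `boundary_ratio_per_bin` requires a common bin frame across cells and
  does not lift calls across assemblies or resolutions.
- The CLI infers chromosome length from the largest observed coordinate;
  trailing contact-free bins of a real chromosome are not represented
  (supply pre-binned triples with explicit `n_bins` via the library for
  exact framing).
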