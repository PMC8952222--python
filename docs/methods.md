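# Methods

This note documents the model behind `coevscreen`, the choices made where
the design was genuinely open, and what the synthetic benchmarks do and do
not demonstrate.

## Input model and preparation

The unit of input is one protein's orthologue set: one amino-acid sequence
per species, aligned (the package consumes alignments; it does not align).
Curation mirrors standard practice for orthologue panels:

- **Best-hit selection.** When a species contributes several candidates
  (isoforms, duplicates), each is globally aligned to the reference
  sequence with Needleman–Wunsch (BLOSUM62, affine gaps: a gap of length k
  costs `open + (k−1)·extend`, defaults 10/1). Only the top-scoring
  candidate per species is eligible, and it is dropped when identity over
  aligned positions falls below 35% or the gapped fraction of alignment
  columns exceeds 25%. Ties are broken by the smallest candidate id.
- **Divergence screen.** Each retained sequence scores its mean pairwise
  identity to the rest of the set (edit-distance based, global); scores are
  rescaled by the set maximum and sequences below `0.95 × median` are
  removed. This is a deliberately simple stand-in for
  alignment-confidence screening: it asks only "is this sequence an
  outlier in this family", which is the property the downstream statistic
  is sensitive to. On the simulated mammal-like panels it typically removes
  the 3–6 longest-branch species of 50.

Column quality is summarised per protein in the spirit of conserved-block
selection: a column is *highly conserved* when its majority residue covers
more than 85% of rows, *conserved* above a strict majority, *nonconserved*
otherwise, and forced nonconserved when more than half its rows are gaps.
Good blocks are maximal runs free of nonconserved stretches longer than 8,
trimmed to conserved ends, of length ≥ 10 (the classical block-selection
defaults). Only the per-column good/poor flag and the gap fraction are
consumed downstream; byte-level agreement with any particular external
block-selection tool is a non-goal.

## Trees and divergence times

Each protein pair analysis needs divergence times `t_ij` between species.
By default each (trimmed) protein alignment gets its own tree: pairwise
Poisson-corrected p-distances `d = −ln(1 − p)` with pairwise gap deletion
(`p` capped at 0.95 with a warning, since the correction diverges at
saturation), followed by plain Saitou–Nei neighbour joining. Negative
branch-length estimates are clamped to zero with the deficit moved to the
sibling branch, preserving the joined pair's distance. On additive
matrices the construction is exact, which the tests exploit. An external
species tree (e.g. from a dated phylogeny resource) can be supplied
instead and is pruned to the shared species; pruning contracts unary nodes
and sums their branch lengths, so the patristic metric is preserved
exactly. Rooting, where needed, places the root at the point minimising
tree height (the midpoint of the diameter path).

## The coevolution statistic

For column *a* of a protein with *n* shared species, over all
`P = n(n−1)/2` unordered species pairs:

- `theta_hat_a(i,j) = B(x_i, x_j) / max(t_ij, t_min)` with BLOSUM62 scores
  `B` and `t_min = 1e-6` substitutions/site guarding near-zero divergence;
- pairs where either residue is a gap or `X`, or `t_ij ≤ 0`, are masked;
  a column with fewer than half its pairs usable is not scored;
- the classical per-site variation `D_a = (theta_hat_a − mean_a)²` is kept
  as the public per-column summary.

**Phylogenetic background correction.** The two proteins of a pair evolve
on the same species tree, so the raw `theta_hat` (and `D`) vectors of
*any* two columns share the `1/t` profile: measured on fully independent
simulated proteins, raw column-pair correlations average ≈ 0.8. Any
permutation-style null that scrambles the species-pair indexing destroys
exactly this shared structure and is therefore catastrophically
anticonservative (measured false-positive fraction ≈ 1 at α = 0.01).
The screen therefore correlates a corrected signal:

1. centre `theta_hat_a` over its usable pairs and standardise the column
   to unit variance;
2. subtract the per-species-pair mean of these standardised columns over
   all informative columns of the protein — the empirical phylogenetic
   background profile.

Columns with no residue variation on usable pairs are excluded outright:
their standardised vector *is* the background profile (identically,
whatever the conserved residue), so they would otherwise form large blocks
of spurious mutual correlation. Squared-deviation variation (`D`) is
retained as the per-site descriptor but is not what the scan correlates:
squaring discards which species pairs were *separated* by substitutions —
the sign structure that actually distinguishes co-substitution from
coincidence — and measurably has no detection power against the tree
background.

**Null distribution and p-values.** Significance is self-calibrated per
protein pair: the null is the empirical distribution of signal
correlations over *all* informative column pairs of the same two proteins,
kept as up to 10,000 evenly spaced order statistics of the sorted
background (deterministic; the thinning preserves every quantile to
resolution 1/10,000 and sets the p-value floor at ≈ 1e-4). The hit
threshold is the `(1 − alpha)` order statistic (with 10,000 samples and
α = 0.01, the 9,900th value), and
`p = (1 + #{null ≥ rho}) / (N + 1)`. Because a protein pair's own
background is overwhelmingly composed of non-coevolving column pairs, this
conditions the test on the shared tree and the two proteins' rate
structure; the cost is that p-values are *relative* within a protein pair,
so every pair yields ≈ α·comparisons above-threshold pairs by
construction — enrichment between protein pairs is the job of the χ² step,
not of the per-site threshold.

**Bootstrap support and the double run.** Candidate hits must keep their
correlation above the threshold in ≥ 60% of 100 resamples of the species
pairs (with replacement). Each protein pair is scanned twice with the A/B
roles exchanged; the statistic is symmetric, so the runs share threshold
and p-values and differ in their bootstrap streams, making the double run
a repeated-stability filter. Only residue pairs reported by both runs
survive, with the larger p-value. If the forward run finds nothing the
reverse run is skipped.

All Monte-Carlo streams derive from the global seed plus the pair id,
direction, and site coordinates (SHA-256 based), so results are bitwise
independent of worker count, scheduling, and input listing order.

## Post-processing

Benjamini–Hochberg adjustment is applied once across all residue-pair
p-values pooled over protein pairs (the screen is one testing family;
per-pair families are available by flag). The per-pair χ² statistic
compares each pair's hit count with its expectation under the pooled rate:
`p̂ = Σ hits / Σ comparisons`, `E = comparisons·p̂`,
`χ² = (hits − E)²/E`, upper tail with 1 df. Final reporting filters are
strict: `p < 0.005`, both columns flagged good, both gap fractions
< 0.20. Outputs are a residue table, a pair table including zero-hit
pairs, and sorted Cytoscape-ready edge/node TSVs; coordinates are 1-based
alignment columns of the untrimmed per-protein alignments, plus the
ungapped position and residue in the reference species' sequence.

## Synthetic data

The generator emulates the study conditions of a mammalian orthologue
screen: a random-birth species tree (50 taxa by default, the size of a
placental-mammal panel; exponential branch lengths, mean 0.05
substitutions/site), root sequences from BLOSUM62-implied background
frequencies, and a reversible substitution process whose symmetric
exchangeabilities are `2^(S/2)` for BLOSUM62 scores `S` (normalised to one
expected substitution per unit branch length), with gamma site-rate
heterogeneity (shape 1 by default). Coupled site pairs are re-simulated
jointly: every substitution event at site A forces, with probability equal
to the coupling, a simultaneous substitution at site B on the same branch
(to a residue scoring ≥ 0 against A's new residue); B's independent events
are thinned by one minus the coupling, so at coupling 1 the two sites'
substitution branch sets are identical. Coupled sites evolve at 2.5× the
mean rate — functionally coupled sites must vary to leave any signal, and
this operating point (50 taxa, rate factor 2.5, coupling 1) was fixed
after oracle runs and is frozen in the tests. No indels are simulated by
default; a gap-injection flag gaps out random row blocks for exercising
gap handling.

What passing the synthetic benchmarks shows: the null machinery is
calibrated on data matching its assumptions (independent evolution on a
shared tree), and branch-coincident substitution is detected with high
sensitivity at strong coupling. What it does not show: robustness to
alignment error, indels, recombination or horizontal transfer, lineage
lotteries of rate variation, or the weaker and noisier coupling of real
interacting proteins — on real data the screen should be read as a ranking
device, not a calibrated hypothesis test.

## Numerical and degenerate-input conventions

- Correlations need ≥ 3 jointly usable species pairs and non-degenerate
  variance on the intersection; otherwise the column pair is skipped.
- A protein pair aborts (logged, not silently dropped) when fewer than 10
  informative columns remain on either side; the pipeline exits non-zero
  if any pair aborted.
- Protein pairs sharing fewer than 20 species are rejected before
  scanning; all-gap columns created by species trimming are removed, with
  an index map preserving original coordinates in every report.
- p-distances at the 0.95 cap, BH inputs outside (0, 1], unknown config
  keys, and out-of-range parameters all fail loudly.

## Known limitations

- The background correction removes one shared factor (the mean
  phylogenetic profile); higher-order shared structure — most visibly,
  bursts on the same long terminal branch appearing in both proteins —
  remains and is the dominant source of top-ranked false positives.
- Because the null is each protein pair's own background, p-values between
  protein pairs are not directly comparable when background shapes differ
  strongly.
- The divergence screen is identity-based and will not flag sequences that
  are similar but misaligned.
- Intra-protein coevolution is out of scope by design.
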