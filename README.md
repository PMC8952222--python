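# coevscreen

Large-scale screening for **inter-protein coevolution** from orthologue
alignments.

When two proteins interact or functionally depend on each other, selective
constraints can couple the evolution of specific residue positions: a
substitution at a site in protein A tends to be accompanied by a
compensatory substitution at a site in protein B on the same lineage.
`coevscreen` takes per-protein multiple sequence alignments of orthologues
(one sequence per species), and reports residue pairs across protein pairs
whose evolutionary variation is significantly correlated — a screening
signal for direct or indirect functional partnership that requires nothing
but sequences. It is aimed at researchers with a candidate protein list
(for example from a proximity-proteomics experiment) who want a ranked
protein-interaction network before committing to wet-lab validation.

## The statistic

For one protein, each alignment column *a* is summarised over all unordered
species pairs *(i, j)*:

```
theta_hat_a(i,j) = B(x_i, x_j) / max(t_ij, t_min)
```

where `B` is a BLOSUM substitution score of the two residues in column *a*
and `t_ij` the patristic distance between species *i* and *j* on the
protein's tree (built in-package by neighbour joining from Poisson-corrected
p-distances, or supplied externally). The classical per-site variation
`D_a(i,j) = (theta_hat_a(i,j) − mean_a)²` is exposed for each column; the
screen itself correlates the **background-corrected signal**: the centred,
per-column-standardised `theta_hat`, minus the per-species-pair mean profile
over all informative columns of the protein. This correction is essential —
both proteins share one species tree, so uncorrected vectors of *any* two
columns correlate strongly through the common divergence-time profile alone
(see `docs/methods.md`).

Two columns *a* (in A) and *b* (in B) coevolve when the Pearson correlation
`rho(a, b)` of their signals is extreme against the **empirical background
null**: the distribution of `rho` over all informative column pairs of the
same two proteins. A hit must (1) reach the `(1 − alpha)` background
quantile (default `alpha = 0.01`), (2) keep bootstrap support ≥ 0.6 under
resampling of species pairs, and (3) be detected in both runs of a
bidirectional double-scan with independent Monte-Carlo streams. Per-pair
empirical p-values are pooled across all protein pairs for
Benjamini–Hochberg FDR control, each protein pair receives a χ² test of
hit-count enrichment against the pooled hit rate, and the final tables
export directly to Cytoscape.

## Worked example

Simulate three orthologue families over 50 species, with 10 site pairs
between `prot01` and `prot02` forced to substitute on the same branches
(full coupling), and screen them:

```bash
coevscreen simulate --scenario coevolving --proteins 3 --taxa 50 \
    --length 200 --coupling 1.0 --seed 11 --out demo/input
coevscreen run --input demo/input --work-dir demo/work --seed 11
```

The pair table (`demo/work/results/pair_table.tsv`):

```
       pair_id protein_a protein_b  n_hits  n_comparisons     chi2   chi2_p    min_q
prot01__prot02    prot01    prot02     203          23200 0.001742 0.966704 0.008933
prot01__prot03    prot01    prot03     215          24311 0.012833 0.909808 0.008933
prot02__prot03    prot02    prot03     199          22797 0.005606 0.940316 0.008933
```

Each protein pair screens ~23,000 column pairs; by construction of the
self-calibrated null about 1% exceed the per-pair significance threshold,
so `n_hits ≈ 200` everywhere and the χ² test (which asks whether a pair is
*enriched* relative to the pooled rate) stays flat. The injected signal
shows up at the residue level: 9 of the 10 truly coupled site pairs are
recovered in the `prot01__prot02` residue table, e.g.

```
 site_a  site_b  rho_fwd  support_fwd  support_rev      p        q
    148     104 0.879731         1.00         1.00 0.0016 0.008933
    170     125 0.958585         1.00         1.00 0.0011 0.008933
    195     141 0.945999         1.00         1.00 0.0011 0.008933
```

`rho_fwd` is the signal correlation, `support_*` the bootstrap fractions of
the two directional runs, `p` the larger of the two empirical p-values and
`q` its BH adjustment. Applying the final reporting filters (`p < 0.005`,
both columns in good alignment blocks, gap fractions < 20%) keeps 343 of
617 rows; `demo/work/results/network_filtered/` holds the Cytoscape-ready
edge and node tables.

## Layout

- `src/coevscreen/core_io.py` — alignment/tree containers, FASTA/Newick,
  NJ, min-height rooting, pruning, patristic distances
- `src/coevscreen/ortholog_curation.py` — best-hit selection and the
  divergence screen
- `src/coevscreen/msa_quality.py` — column conservation classes and
  good-block flags
- `src/coevscreen/pairing.py` — pair enumeration and shared-species
  trimming
- `src/coevscreen/caps_engine.py` — the coevolution statistic, null,
  bootstrap, bidirectional scan
- `src/coevscreen/postprocess.py` — BH-FDR, χ², filters, network export
- `src/coevscreen/synthetic_data.py` — species-tree/protein simulator with
  coupled-site injection and ground truth
- `src/coevscreen/pipeline.py`, `cli.py`, `config.py` — orchestration,
  command line, settings
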