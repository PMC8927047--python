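# stressrna

Layered RNA-seq analysis of the transcriptome response to mechanical
stress in osteoarthritis-like chondrocytes: differential expression over
four transcript layers (mRNA, miRNA, lncRNA, circRNA), novel lncRNA
discovery, lncRNA target assignment, and competing-endogenous-RNA
(ceRNA) network inference — exercised end-to-end on synthetic data with
planted ground truth.

## The problem

Mechanical overload reshapes the chondrocyte transcriptome across all
RNA layers, and non-coding RNAs (lncRNAs, circRNAs) are thought to
buffer miRNA activity as ceRNA "sponges". Given raw count matrices from
a two-group design (stress vs control, 3 biological replicates each),
the pipeline answers, layer by layer:

1. **Which transcripts respond?** Counts are filtered (group mean >= 5
   coding / >= 2 non-coding in at least one group), TMM-normalized, and
   tested with the conditional negative-binomial exact test: the
   stress-group sum A is compared with its distribution given the total
   T = A + B under NB(mean mu, common dispersion phi), where a sum of n
   replicates is NB(size n/phi). Calls require strict |log2FC| > 1 plus
   BH FDR < 0.05 (mRNA/lncRNA) or p < 0.05 (miRNA/circRNA), yielding the
   four differential sets DEM / DEMI / DEL / DEC.
2. **Which lncRNAs are novel?** The intersection rule: non-coding by
   both the Fickett TESTCODE statistic and longest-ORF coverage, absent
   from the known catalogue, and >= 200 nt.
3. **What do the lncRNAs regulate?** Coding targets assigned by
   genomic structure — cis (gap < 100 kb), antisense (opposite-strand
   overlap, with a duplex-stability score), trans (co-expression only) —
   each gated by Pearson |r| > 0.9, p < 0.05 over pooled samples.
4. **Which sponges compete for which miRNAs?** Seed sites (>= 7mer-m8)
   on 3'UTRs, anti-correlation r < -0.9 per (miRNA, sponge) pair, and an
   edge between two sponges when their shared-miRNA overlap k passes
   P(X >= k) < 0.05, X ~ Hypergeometric(N = #DEMIs, K, n), with positive
   sponge co-expression. Node degree = distinct shared miRNAs; degree
   >= 5 marks a hub; mRNAs split into commonly regulated (lncRNA and
   circRNA partners) vs lncRNA-specific.
5. **What are the responders doing?** Hypergeometric over-representation
   and weighted-KS GSEA (gene-set permutation null) against a gene-set
   collection.

The headline numbers of the motivating study depend on its raw
sequencing data, which is not available at desk scale; validation here
is therefore property-based, against a synthetic-data generator that
plants known differential transcripts, cis/antisense/trans pairs, miRNA
seed sites and ceRNA sponge modules (see `docs/methods.md`).

## Worked example

The numbered drivers under `analysis/` run the whole study on a
generated dataset (seed 1) and write their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_differential_expression.py
python analysis/03_novel_lncrnas.py
python analysis/04_lncrna_targets.py
python analysis/05_cerna_network.py
python analysis/06_enrichment.py
python analysis/07_validate_recovery.py
```

Output of the run this README was written against:

```
mRNA: 2000 -> 1982 after filtering; 268 DEMs (144 up, 124 down), dispersion 0.120
  PCA: PC1 63.9%, PC2 9.9% of variance; PC1 separates stress from control
miRNA: 50 -> 50 after filtering; 33 DEMIs (16 up, 17 down), dispersion 0.369
lncRNA: 300 -> 300 after filtering; 96 DELs (48 up, 48 down), dispersion 0.190
circRNA: 100 -> 100 after filtering; 18 DECs (9 up, 9 down), dispersion 0.138
300 lncRNA transcripts: 150 novel, 150 known, 0 coding-like (50.0% novel)
96 DELs x 268 DEMs: 36 cis candidates, 15 antisense candidates
emitted 10802 co-expressed pairs: 15 antisense, 19 cis, 10768 trans
  antisense duplex scores: best -80, median -80 (perfect 40-mer hybrid = -80)
33 DEMIs, 104 seed sites, 104 gated miRNA-target pairs
network: 69 nodes, 34 sponge edges, 7 hubs (degree >= 5)
DEM partition: 15 commonly regulated (lncRNA and circRNA partners), 4 lncRNA-specific
ORA ... top term SET_PLANTED_UP (k=27/K=30, gene ratio 0.10, FDR 3.25e-20)
GSEA (500 permutations): top term SET_PLANTED_UP ES 0.94, NES 1.71, p 0.004, direction up
```

Reading it: the exact test recovers most of the 275 planted mRNA
effects at ~2% empirical false discovery; all 150 planted novel lncRNAs
are called novel with no false positives; the 15/19 antisense/cis pairs
sit on top of the 15/20 planted ones (one planted cis pair missed the
correlation gate), while the ~10k trans pairs illustrate how coarse a
+/-0.9 correlation gate is at n = 6 — any two strongly regulated
transcripts co-vary; the ceRNA network recovers the planted sponge
modules (90/96 triplets) with zero spurious edges, and its 7 hubs are
exactly the planted hub-module members. The final driver prints the
recovery report (sensitivities per structure class).

One pipeline call does all of this in one go, with a deterministic
run manifest:

```sh
stressrna run --simulate --seed 7 --outdir results/full
stressrna validate --outdir results/full --truth results/full/sim/ground_truth.json
```

`stressrna simulate` and `stressrna diffexpr` expose the generator and
the one-layer DE stage separately.

## Output columns

DE tables (`de_<layer>.tsv`): `transcript_id, mean_cpm_stress,
mean_cpm_control, log2fc, p, fdr, dispersion, layer, status`.
`novelty.tsv`: the two scorer values, their boolean calls, the
catalogue hit and the final class. `regulatory_pairs.tsv`: `lnc_id,
target_gene_id, mode, r, p, distance_bp (cis), duplex_score
(antisense)`. `cerna_edges.tsv`: `nodeA, typeA, nodeB, typeB,
shared_mirna_count, shared_mirnas, r, p`. Enrichment tables: `term_id,
k, K, n, N, gene_ratio, p, fdr` (+ `es, nes, direction` for GSEA).
`run_summary.json` holds the four DE-set counts; `manifest.json` the
config hash, seed and per-file SHA-256 checksums.

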