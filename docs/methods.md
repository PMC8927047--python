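# Methods

`stressrna` reimplements, as a tested pipeline over synthetic data with
planted ground truth, a whole-transcriptome regulatory analysis of
mechanically stressed, osteoarthritis-like chondrocytes: layered
differential expression (mRNA, miRNA, lncRNA, circRNA; 3 stress vs 3
control replicates), novel lncRNA discovery, cis/trans/antisense lncRNA
target assignment, and competing-endogenous-RNA (ceRNA) network
inference. This note records the statistical models, the tunable
parameters and their defaults, what the generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Differential expression

**Filtering.** A transcript is kept iff its group-wise *mean* raw count
reaches 5 (coding) or 2 (non-coding) in at least one group. "Low in both
groups" is operationalised as the group mean rather than the group sum so
the rule is invariant to the number of replicates.

**Normalization.** Trimmed mean of M-values (TMM) against the
highest-depth sample as reference: genes positive in both samples
contribute an M (log2 expression ratio) and A (log2 abundance) value,
doubly trimmed at 30% (M) and 5% (A) per tail, then averaged with
inverse delta-method-variance weights; factors are rescaled to geometric
mean 1. The implementation reproduces edgeR's `calcNormFactors` to ~1e-9
on a 200-gene fixture (frozen oracle in the test suite). Effective
library size = raw depth x factor; CPM and log2(CPM+1) use effective
sizes. TMM is applied per layer.

**Exact test.** Library sizes are pseudo-equalised by scaling counts to
the geometric-mean effective library. For gene g with group sums A and
B, a sum of n iid NB(mean mu, dispersion phi) variables is NB(size
n/phi); the test conditions on T = A + B, giving

P(A = a | T = t) proportional to C(a + n1/phi - 1, a) * C(t - a + n2/phi - 1, t - a),

and the two-sided p sums the probabilities of all outcomes no more
likely than the observed one (the sum-of-smaller-probabilities variant
was chosen over edgeR's tail-doubling because it is deterministic in tie
cases). As phi -> 0 (below 1e-8) the law reduces to Binomial(t,
n1/(n1+n2)); a zero total gives p = 1. A *common* dispersion per layer
(n = 3 per group is too little for tagwise estimation) is estimated by
maximising the within-group conditional likelihood, which is free of the
group means; on null simulations with true phi = 0.1 the estimate lands
in 0.096-0.103 and the empirical type-I error at p < 0.05 is 0.04-0.06.
On layers with strongly coupled planted genes (see below) the common
estimate is inflated by the shared latent factor, making calls on those
layers conservative — visible as reduced sensitivity for small effects
in the 50-gene miRNA layer.

**log2 fold change** uses normalized group mean CPM with a pseudocount
equivalent to 0.5 raw counts at the mean effective library. No attempt
is made to reproduce edgeR's shrinkage constant exactly.

**Calling.** mRNA/lncRNA: |log2FC| > 1 (strict) and BH FDR < 0.05;
miRNA/circRNA: |log2FC| > 1 and raw p < 0.05. BH is delegated to
statsmodels and cross-checked against a from-the-definition
implementation to 1e-12.

**PCA** is computed on log2(CPM+1), genes centred (the input transform
was an open choice; log-CPM is the field's default).

## Novel lncRNA discovery

Novelty = intersection rule: non-coding by *both* screens AND no hit in
the known-transcript catalogue AND length >= 200 nt. The two screens
stand in for external coding-potential tools that cannot run in-repo:

* **Fickett TESTCODE** — the published position-asymmetry/composition
  statistic with its standard lookup tables; cutoff `fickett_max = 0.95`
  (the published "coding" threshold).
* **ORF coverage** — longest complete ATG..stop ORF over the three
  forward frames (transcript sequences are stranded), divided by length;
  cutoff `orf_frac_max = 0.30`.

The annotation screen is an ID-list membership test (sequence-similarity
search against a protein database is out of scope). The intersection
logic itself — the defined computation — is preserved exactly, and
`call_novelty` is monotone in both cutoffs.

## lncRNA target assignment

Candidates are structural: **cis** = DEL and DEM on one chromosome with
interval gap strictly below 100 kb (1-based inclusive coordinates; gap =
max(0, max(starts) - min(ends) - 1), overlap = 0); **antisense** = >= 1 bp
overlap on opposite strands; **trans** = every remaining DEL x DEM pair
(restricting trans to the differential sets was an open choice;
`trans_all_genes` widens it). Every candidate must pass |Pearson r| >
0.9 with two-sided t-test p < 0.05 (df = n - 2) on log2(CPM+1) pooled
across all six samples — pooling maximises n at the cost of conflating
group effect with within-group covariation, a caveat inherent to n = 6.
A pair qualifying under several modes is reported once with priority
antisense > cis > trans (the priority is an invented uniqueness rule).

Antisense pairs are annotated with a **duplex score**: minimum over all
ungapped antiparallel window-40 alignments of (WC pair -2, G.U wobble
-1, mismatch +3); a perfect window scores -80. It is a fast
complementarity surrogate for minimum-free-energy hybrid prediction, an
annotation only by default (`duplex_max` turns it into a gate; no
published cutoff exists to default to).

## ceRNA network

miRNA binding is canonical seed matching on 3'UTRs: the 6mer core is the
reverse complement of miRNA nt 2-7, extended to 7mer-m8 (pairing at nt
8), 7mer-A1 (A opposite nt 1) or 8mer (both). Targets require at least
one site of class >= 7mer-m8 (the two strongest classes are unambiguous
to plant and detect). A (miRNA, sponge) pair survives only if Pearson
r < -0.9 (strict). Two sponges (mRNA-lncRNA or mRNA-circRNA;
lncRNA-circRNA behind a flag) are linked when they share >= 1 surviving
miRNA, their own correlation is positive, and the shared-miRNA overlap
passes P(X >= k) < 0.05 under X ~ Hypergeometric(N, K, n) with N = the
number of DEMIs (configurable to all expressed miRNAs; the universe
choice was open). Node degree is the number of *distinct* shared
miRNAs (the plain edge count is reported alongside); degree >= 5 marks a
hub. mRNAs with both lncRNA and circRNA partners are "commonly
regulated", those with lncRNA partners only are "lncRNA-specific".

## Enrichment

ORA: hypergeometric tail of the query against each gene set, BH across
terms. GSEA: ranking metric sign(log2FC) x -log10(max(p, 1e-300)), ties
broken lexicographically; weighted KS running sum (hits proportional to
|metric|^p, p = 1; misses 1/(N-K)); ES = maximum deviation from zero.
The null is **gene-set (label) permutation** — with 3 + 3 samples only
10 phenotype permutations exist, far too few for an empirical null — and
NES = ES / mean(|null ES| of the same sign), with a one-tailed empirical
p in the same-sign pool and BH across terms (simpler than the original
NES-pooling FDR; documented deviation).

## The synthetic-data generator

The generator defines the study conditions; it is validated code, not a
fixture. Defaults: 2,000 coding genes, 300 lncRNAs, 50 miRNAs, 100
circRNAs on one chromosome (genes 1 Mb apart so a lncRNA is near at most
its designated partner); 10% of lncRNAs placed < 100 kb from a gene (cis
candidates), 10% overlapping a gene on the opposite strand (antisense);
50% of lncRNAs novel. Counts are NB with dispersion 0.1 and per-layer
library sizes 2e5 / 1e4 / 5e4 / 2e4 (mean ~100 counts per transcript, a
realistic bulk depth at this gene count), +/-10% depth jitter.

**Planted effects.** The plain DE cohort gets |log2 effect| = 2 on 10%
of each layer, restricted to transcripts with baseline mean >= 50
counts. Structural members (pairs, modules) get |effect| = 5, baseline
mean 300, plus a shared log-normal latent factor (SD 1.0 in log2 units,
sign +1 for sponges and lncRNA targets, -1 for miRNAs). The combination
was calibrated once, before any acceptance run, from the sampling
distribution of Pearson r at n = 6: the +/-0.9 gate demands a true r of
roughly 0.97, i.e. shared variance ~30x the NB noise — weaker planting
would make the published gate unreachable at this design size, which is
a property of the method at n = 6, not of this implementation. Effect
signs alternate deterministically so each layer stays compositionally
balanced; unbalanced strong effects in the small miRNA layer would
otherwise break TMM's majority-not-DE assumption on unlucky seeds.

**ceRNA modules.** A module couples 2 mRNAs + 1 lncRNA + 1 circRNA
through a dedicated set of miRNAs (2 per module; 2 "hub" modules carry
5, pushing members past the hub threshold), so module mRNAs become
commonly regulated genes; 4 extra mRNA-lncRNA-only pairs provide
lncRNA-specific genes. Sharing >= 2 miRNAs per sponge pair makes the
hypergeometric gate decisive (k = K = n = 2 gives p = 1/C(N,2) ~ 0.002
at N ~ 30 DEMIs, where a single shared miRNA would sit at the marginal
1/N).

**Sequences.** Coding transcripts carry an ORF covering ~80% of their
length; lncRNAs are mutated ORF-poor (< 25% coverage) and novel ones
re-drawn if Fickett-coding-like; every planted (miRNA, sponge) pair gets
one exact 8mer site in the sponge's UTR, and all other UTRs are scrubbed
of 6mer cores for every generated miRNA, so false binding predictions
are structurally impossible. Antisense lncRNAs embed the reverse
complement of a 60-mer of their partner mRNA, making the duplex score
informative. The planted enrichment gene set contains up-regulated
planted genes only, because GSEA is direction-sensitive and a mixed-sign
set self-cancels.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: splicing and isoform structure, batch
effects, GC/length biases, tagwise dispersion heterogeneity, imperfect
or non-canonical miRNA sites, sequence homology between transcripts, and
realistic correlation between structural proximity and co-expression
strength (planted pairs are coupled by construction). Trans "false
positives" among strongly regulated gene pairs are expected and real: at
n = 6, any two strongly differential transcripts correlate near +/-1, a
known property of small-n co-expression gating, visible in the worked
example's ~10,000 trans pairs.

## Numerical choices and degenerate inputs

Exact-test tie tolerance 1e-10 on log-probabilities; correlations of
zero-variance vectors are flagged undefined and the pair skipped, never
NaN-propagated; r is clipped to [-1, 1] and |r| = 1 maps to p = 0; BH
input outside [0, 1] is an error; an all-zero transcript gets log2FC 0,
p 1; an all-zero sample is a normalization error; GTF parse errors carry
line numbers; T/U are normalised to the DNA alphabet at read time so
seed matching and duplex scoring share one alphabet. All randomness
flows from explicit seeds; end-to-end runs are bit-reproducible
(manifest SHA-256 equality).

## Problem sizes used in validation

Type-I calibration: 10 null replicates of 2,000 genes. Structure
recovery: 20 replicate simulations at the default conditions above.
GSEA permutations: 50 in pipeline validation runs, 500 in the worked
example. These sizes give stable Monte-Carlo means (recovery SEs ~0.01)
while keeping a full validation cycle around a minute.

## Known limitations

The exact test assumes a common dispersion and pseudo-equalised
libraries (quantile adjustment is approximated by scaling+rounding);
no GLM/covariates/batch correction. The coding-potential screens are
deliberately simple stand-ins; the annotation screen is ID membership,
not homology search. The duplex score ignores thermodynamic stacking and
intramolecular structure. The hypergeometric universe (DEMIs after
filtering) is a documented choice, not the only defensible one. With
n = 6 the +/-0.9 correlation gates are extremely coarse instruments;
every conclusion drawn from them inherits that coarseness.
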