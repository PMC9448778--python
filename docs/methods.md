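# Methods

This note records the scientific and numerical decisions behind the
package: what each stage assumes, what the synthetic data do and do not
emulate, and where the design was genuinely open.

## Discovery

The classifier evaluates all six criteria on every contig (so a report
always shows the full profile) but `rejected_at` is the first failure in
the printed order: size, k-mer signal, hallmark genes, bacterial
markers/rRNA, database balance, provirus fraction. Inequalities are strict
exactly where the screening rules say "more than": a 130 bp terminal repeat
is not circular, a tie between viral and plasmid database hits is kept, a
shared-protein fraction of exactly 20% does not group two vOTUs.

*Terminal redundancy* is an ungapped suffix–prefix comparison
(substitutions only). Indels inside a terminal repeat of an assembly are
rare, the ungapped scan has an exact brute-force oracle, and match counts
for all candidate overlap lengths come from one FFT autocorrelation, which
is algebraically identical to the exhaustive per-length scan.

*Provirus fraction* stands in for a database-driven completeness tool.
Host-flagged genes (bacterial marker, rRNA) break the contig into
segments; within a segment the viral region runs from the first to the
last gene with viral evidence, except that a segment touching a contig end
extends to that end — no host gene bounds it there, and draft ends
truncated mid-gene should not be penalised. A fully viral contig therefore
scores exactly 1.0. *Contamination* is the fraction of genes that are
host-flagged or sit entirely outside the viral span without viral evidence
of their own; drafts with more than 10% such genes are dropped in the
linear-recovery arm only — circular complete genomes are never down-tiered.

*Draft recovery* replaces an e-value cutoff with a local-alignment score
cutoff (BLOSUM62, affine gaps −11/−1, score ≥ 100, configurable); an exact
shared 8-mer between two proteins gates the quadratic alignment, which
unrelated proteins essentially never pass. Completeness tiers use the
conventional ≥ 90% / 50–90% / < 50% bounds.

## Catalogue

Species clustering is a single greedy centroid pass at 95% ANI / 85%
coverage, ordered by (quality tier, length) descending — one algorithm in
place of a two-stage dereplicate-then-recluster pipeline, with the same
thresholds. ANI is fragment-based (1 kb non-overlapping fragments, final
fragment absorbing the tail so that self-ANI is exactly (1.0, 1.0));
fragments align semi-globally via edit distance, counting only fragments at
≥ 80% identity. A 50-probe exact 16-mer prescreen skips hopeless pairs; the
oracle-equivalence test runs the same clustering against an independent
implementation with no prescreen.

MCL follows the standard iteration — self-loops at each node's maximum
incident weight, column normalisation, expansion (power 2), inflation
(elementwise power 2), pruning below 1e-5 — to a fixed point (tolerance
1e-8, cap 100 iterations); clusters are connected components of the
converged non-zero structure. The shared-protein-cluster denominator is
min(|A|, |B|) (symmetric; union and directional variants were the
alternatives), and VCs are single-linkage components of the > 20% graph.
Taxonomy ties (two families with equal top counts) are unclassified.

## Host prediction

The array detector is a stand-in for a dedicated repeat finder: exact
20-mer seeds occurring ≥ 3 times at spacings of 40–160 bp (repeat 20–50 bp
plus spacer 20–110 bp) are chained and extended while the column is
unanimous across copies. Candidate chains are ranked by copy number before
claiming regions, so a "shadow" seed that happens to straddle a repeat
boundary cannot truncate an array. Unanimous extension recovers exact
boundaries for exact repeat copies; diverged copies yield a shorter shared
core, and externally predicted spacer tables can be supplied instead.

Spacer matching allows 100% identity or exactly one mismatch/indel. ">95%
of the spacer aligned" is interpreted as aligned-spacer-length fraction: a
one-indel hit on a spacer of ≥ 25 bp covers at least 24/25 = 96% and is
accepted. Both strands are searched. The pigeonhole search (one exact half
anchors every ≤ 1-edit match) is verified against a position-exhaustive
edit-distance scan. Host assignment is genus-level; a fixed list of 22
non-intestinal genera is excluded before labelling
specialist/generalist/unknown.

## Quantification

Only hallmark genes are indexed (21-mer seeds, every position), keyed to
the owning vOTU. A read maps at ≥ 95% identity over ≥ 90% of its length;
equal-best hits in distinct vOTUs discard the read, so multi-mapped reads
are never fractionally assigned. Detection is ≥ 1 mapped read; "relative
abundance" is per-sample normalised RPKM. Recovery is assessed against the
generator's truth table of reads originating inside hallmark genes,
normalised per hallmark kilobase — the quantity RPKM estimates.

## Statistics

Shannon uses the natural log. The phage–host pair-exclusion rule removes
samples where *both* members are zero (the co-absence reading); a config
switch (`pair_exclusion="either"`) applies the stricter reading. The
Wilcoxon rank-sum test enumerates all rank assignments exactly for
combined n ≤ 12 and otherwise uses the tie-corrected normal approximation.
Tertile boundaries are the empirical 1/3 and 2/3 quantiles with boundary
ties to the lower group.

The univariate scan is the closed-form OLS slope t-test computed
column-wise; BH correction is applied once over all (feature, variable)
pairs. Zeros are transformed as log10(x + c) with c = half the smallest
non-zero value in the matrix. Stepwise selection is bidirectional from the
full gated model under AIC = n·ln(RSS/n) + 2k with a fixed variable order;
because AIC retains a null variable with probability ≈ P(χ²₁ > 2) ≈ 0.16,
the reported verdict requires both selection and coefficient p < 0.05,
which calibrates the null reporting rate to ≈ 0.05. PERMANOVA uses the
Gower-centred G = −½JD²J and the hat matrix of (intercept + variable), so
continuous predictors need no discretisation; permutations relabel samples,
and p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1). On univariate Euclidean
two-group data the pseudo-F reduces exactly to the classical one-way
ANOVA F.

## Synthetic communities

The default community is 30 phages (10 circular with 150–300 bp terminal
repeats, 15 linear drafts planted as 75–98% windows of the circular
genomes at 1% divergence, 5 prophages embedded with short host flanks),
20 plasmids (5 circular) and 30 bacterial contigs with marker genes, rRNA,
CRISPR arrays targeting the planted phages, and a few low-fraction embedded
prophages. Genes are random DNA; proteins are a fixed codon-table encoding
of the gene interval (stop codons folded into a standard residue — open
reading frames are not enforced). Phage genomes within one "family" draw
~30% of their genes from a shared ancestral pool at ~5% divergence each, so
protein clustering and VC construction have real structure to recover. The
first and last genes of every phage gene set always carry database
evidence, reflecting the strong conservation of terminal
packaging/structural modules and guaranteeing that the noise-free
community is separable by construction. CRISPR spacers are 33–40 bp copies
of their source phage with at most one edit, drawn with rejection against
all other planted species so that a spacer identifies its source
unambiguously at the ≤ 1-edit matching threshold.

Annotation evidence is generator-written, standing in for homology-search
and k-mer-classifier output. The flip-noise model (default 2%) drops each
true flag independently and mis-draws the contig-level k-mer p-value at
the same rate — i.e. it models annotation *misses*. The tools being
emulated run at high-confidence cutoffs where spurious positive calls are
rare; a symmetric flip model would scatter plasmid-hallmark and marker
false positives over nearly half of all phage contigs, which does not
resemble any real annotator. Under miss-noise the dominant loss mode is a
flipped k-mer p-value, which can also cascade: a lost complete genome
removes the recovery reference for its planted drafts.

Cohorts couple each vOTU to its host genus on the abundance scale,
v = α·g + (1−α)·e with g the mean-normalised host-genus abundance (mean
over genera for generalists, diluting their per-genus correlation) and e
an independent log-normal; defaults are α = 0.8 for specialists, 0.2 for
generalists, 60 vOTUs, 20 genera, detection probability 0.6
(zero-inflation matching sparse real profiles). Because no closed form
exists for the Spearman correlation of a zero-inflated mixture of
log-normals after compositional closure, the generator's expected
correlations are computed from the same model at large fixed n
(`expected_pair_correlations`), and recovery is judged against those
targets. Planted metadata effects add β·x (x standardised) to log₁₀
abundance before exponentiation. Effect-recovery experiments plant β on
low-abundance vOTUs of fully-detected profiles: closure otherwise smears a
positive effect into genuine negative associations across the remaining
features, and the zero-inflation floor (zeros at log10 of the pseudocount,
several decades below detected values) dominates the residual variance and
masks slopes of this size — both true properties of compositional
zero-inflated data, noted as limitations rather than worked around
silently. Defence-system abundances are exp(a + b·Shannon + ε) per system,
monotone in realised virome diversity by construction.

What the generator does not emulate: assembly artefacts, read quality
scores and indel errors, strain-level microdiversity, inter-individual
coupling of virome and bacteriome *diversity* (only abundance coupling is
planted), and real hallmark-gene sequence content. Passing tests therefore
demonstrate correctness of the pipeline's logic and calibration of its
statistics on data with known truth, not performance on real gut
metagenomes.

## Problem sizes

Test and reproduction runs use an 80-contig community (genomes 20–40 kb),
cohorts of 500 samples, ~10–19 k reads per quantification run, PERMANOVA
at n = 200 with 999 permutations (10,000 remains the library default), and
null calibrations of 120–200 replicates. These sizes make every planted
quantity statistically recoverable while keeping a full run in tens of
seconds.
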