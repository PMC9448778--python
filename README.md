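# phageome

Discovery and population-level analysis of double-stranded DNA
bacteriophages from bulk (whole) gut metagenomes.

Most reads in a whole faecal metagenome come from bacterial chromosomes and
plasmids, so building a phage genome catalogue from assembled contigs
demands high specificity. `phageome` implements a strict six-criterion
classifier for that purpose, and everything downstream of it: a
species-level (vOTU) and family-level (VC) catalogue, CRISPR-spacer host
prediction, hallmark-gene-based abundance profiles, and the cohort
statistics that relate the virome to the bacteriome and to host metadata.
It is written for computational microbiologists who want a transparent,
fully testable re-implementation of this workflow, exercised end to end on
synthetic communities whose ground truth is planted and therefore known.

## What it computes

**Discovery.** A contig ≥ 10 kb is called a phage iff it passes all six
screens: (1) size ≥ 10 kb; (2) viral k-mer signal p ≤ 0.05; (3) ≥ 1 viral
hallmark gene (terminase, capsid, portal, …) and no plasmid hallmark gene;
(4) no bacterial single-copy marker or rRNA gene; (5) not more genes
hitting a plasmid protein database than a viral one; (6) viral (provirus)
region ≥ 80% of the contig. Circular contigs — terminal redundancy > 130 bp
at > 97% identity — become *complete* genomes; linear contigs are recovered
as drafts when they share > 40% of their genes with a complete genome and
have 70–120% of its length, then tiered by completeness (≥ 90% high,
50–90% medium) with low-quality or > 10%-contaminated drafts dropped.

**Catalogue.** Genomes cluster into vOTUs by greedy centroid clustering at
ANI ≥ 95% with ≥ 85% length coverage. Proteins cluster with a from-scratch
Markov Cluster algorithm (inflation 2) on the all-vs-all BLOSUM62
similarity graph; vOTUs sharing > 20% of protein clusters
(|A∩B| / min(|A|,|B|), single linkage) form a VC. Taxonomy is a best-hit
family vote (> 20% of proteins); lifestyle is temperate iff the temperate
score > 0.8 or the genome aligns > 1 kb at > 95% identity to a bacterial
genome.

**Host prediction.** CRISPR arrays (≥ 3 repeat copies, repeat 20–50 bp,
spacers 20–110 bp) are detected by seed-and-extend; spacers of 25–100 bp
are matched to phage genomes at 100% identity or exactly one mismatch/indel
with > 95% of the spacer aligned, on both strands, by a pigeonhole
exact-half search verified against brute force. Hosts are assigned at genus
level; phages infecting one genus are specialists, several are generalists.

**Quantification.** Reads are mapped (≥ 95% identity over ≥ 90% of the
read, ties across vOTUs discarded) to viral hallmark genes only — this
avoids over-counting reads from horizontally transferred genes — and
RPKM(v) = count(v) / VHG_kb(v) / (total_reads/10⁶).

**Ecology & association.** Shannon α-diversity (natural log), Bray–Curtis
β-diversity, per-(vOTU, host genus) Spearman correlations with the
abundance filters (vOTU > 0.01%, genus > 0.5% mean relative abundance),
defence-system tertile comparisons (Wilcoxon rank-sum, exact for small
samples), log₁₀ abundance regression scans with Benjamini–Hochberg FDR,
bidirectional stepwise-AIC multivariable models, and a hat-matrix PERMANOVA
(pseudo-F, R²) that handles categorical and continuous metadata uniformly.

## Worked example

```python
from phageome.synthetic_community import generate_community
from phageome.discovery import run_discovery, evaluate_pipeline
from phageome.catalogue import cluster_votus

community = generate_community(seed=42, noise=0.02)   # 30 phages, 20 plasmids, 30 bacterial contigs
calls, reports = run_discovery(community.contigs)
tpr, fpr = evaluate_pipeline(calls, community.labels)
votus = cluster_votus([(c.contig_id, c.genome) for c in calls],
                      tiers={c.contig_id: c.tier for c in calls})
print(f"complete genomes: {sum(c.tier == 'complete' for c in calls)}")
print(f"draft genomes:    {sum(c.tier != 'complete' for c in calls)}")
print(f"sensitivity: {tpr:.3f}   false-positive rate: {fpr:.3f}")
print(f"species-level clusters (vOTUs): {len(votus)}")
```

prints

```
complete genomes: 9
draft genomes:    18
sensitivity: 0.900   false-positive rate: 0.000
species-level clusters (vOTUs): 9
```

At 2% annotation miss-noise, 27 of the 30 planted phages are recovered
(one complete genome loses its viral k-mer call and takes its dependent
drafts with it) and no plasmid or bacterial contig is called a phage; with
noise 0 recovery is exact. The 27 genomes collapse to 9 species-level
clusters because drafts are planted as truncated variants of the circular
source genomes.

The same stages are available from the shell:

```
phageome simulate --seed 42 --out sim/
phageome discover --contigs sim/contigs.fa --genes sim/genes.tsv --kmer-p sim/truth.tsv --out disc/
phageome cohort --seed 3 --n-samples 500 --out cohort/
phageome associate --abund cohort/votu_rel.tsv --meta cohort/metadata.tsv --seed 7 --out assoc/
```

All commands are byte-identical across reruns with the same seed.

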