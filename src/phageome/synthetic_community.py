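"""Synthetic sequence communities and cohorts with planted ground truth.

Every downstream stage of the pipeline is exercised against data produced
here, where the right answer is known by construction:

* phage genomes carrying viral hallmark genes, circular (terminal
  redundancy) or linear (truncated drafts of a complete genome);
* plasmids with plasmid hallmark genes and plasmid-database hits;
* bacterial contigs with single-copy marker genes, rRNA, optional embedded
  prophages and CRISPR arrays whose spacers are copied (with at most one
  edit) from planted phages;
* a multi-sample cohort in which each phage's abundance is coupled to its
  host genus, defence-gene abundance follows virome diversity, and chosen
  metadata variables shift log10 abundance by a planted effect size.

Evidence that real pipelines obtain from annotation tools (hallmark HMM
hits, marker-gene detection, database alignments, viral k-mer p-values) is
emitted directly as generator-written flags.  The optional flip-noise
models annotation *misses*: each true flag independently drops to False at
the noise rate, and the contig-level k-mer p-value is drawn from the wrong
class's distribution at the same rate.  The annotators being emulated are
run at high-confidence cutoffs where spurious positive calls are rare, so
missed annotations are the dominant error mode.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import ContigRecord, GeneAnnotation
from .seqcore import revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# standard genetic code with the three stop codons folded into W so that any
# in-frame DNA window yields a valid 20-letter protein (ORFs are not enforced)
_CODON_TABLE = {}
_AA_ORDER = "FFLLSSSSYYWWCCWWLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_BASE_ORDER = "TCAG"
for _i, _b1 in enumerate(_BASE_ORDER):
    for _j, _b2 in enumerate(_BASE_ORDER):
        for _k, _b3 in enumerate(_BASE_ORDER):
            _CODON_TABLE[_b1 + _b2 + _b3] = _AA_ORDER[16 * _i + 4 * _j + _k]

GENUS_PHYLUM = {
    "Bacteroides": "Bacteroidetes",
    "Prevotella": "Bacteroidetes",
    "Parabacteroides": "Bacteroidetes",
    "Ruminococcus": "Firmicutes",
    "Blautia": "Firmicutes",
    "Faecalibacterium": "Firmicutes",
    "Roseburia": "Firmicutes",
    "Clostridium": "Firmicutes",
    "Bifidobacterium": "Actinobacteria",
    "Escherichia": "Proteobacteria",
}
GENERA = list(GENUS_PHYLUM)

FAMILIES = ["Siphoviridae", "Podoviridae", "Myoviridae", "Crassviridae"]

DEFENCE_SYSTEMS = ["CRISPR-Cas", "RM", "Abi", "CRISPR-Cas_I", "RM_II", "Abi_like"]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_dna(rng, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode("ascii")


def translate(dna: str) -> str:
    """Deterministic DNA -> protein encoding (stops folded, see module doc)."""
    if len(dna) % 3:
        raise ValueError("length not a multiple of 3")
    return "".join(_CODON_TABLE[dna[i : i + 3]] for i in range(0, len(dna), 3))


def gene_protein(contig_seq: str, gene: GeneAnnotation) -> str:
    sub = contig_seq[gene.start - 1 : gene.end]
    return translate(sub if gene.strand == "+" else revcomp(sub))


def mutate(seq: str, rate: float, rng) -> str:
    """I.i.d. substitutions at the given per-base rate."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _lay_genes(rng, length: int, prefix: str, min_codons=200, max_codons=400) -> List[Tuple[int, int, str]]:
    """Non-overlapping gene intervals (1-based inclusive) with short gaps."""
    genes = []
    cursor = int(rng.integers(20, 101))
    i = 0
    while True:
        glen = 3 * int(rng.integers(min_codons, max_codons + 1))
        if cursor + glen - 1 > length - 20:
            break
        strand = "+" if rng.random() < 0.85 else "-"
        genes.append((cursor, cursor + glen - 1, strand))
        cursor += glen + int(rng.integers(20, 101))
        i += 1
    return genes


# --- sequence-level truth records -------------------------------------------

@dataclass
class PhageTruth:
    contig_id: str
    species_id: str  # circular source genome this phage descends from
    genome: str  # genome proper (terminal redundancy removed)
    circular: bool
    lifestyle: str  # temperate | virulent
    host_genera: Tuple[str, ...]
    hallmark_gene_ids: Tuple[str, ...]


@dataclass
class ArrayTruth:
    contig_id: str
    genus: str
    repeat_seq: str
    repeat_positions: Tuple[int, ...]
    spacers: Tuple[Tuple[str, str], ...]  # (spacer_seq, source phage contig_id)


@dataclass
class CommunityTruth:
    contigs: List[ContigRecord]
    labels: Dict[str, str]  # contig id -> phage | plasmid | bacterial
    phages: List[PhageTruth]
    arrays: List[ArrayTruth]
    references: List[Tuple[str, str]]  # (genus, genome) labelled reference sequences
    prophage_intervals: Dict[str, Tuple[int, int]]
    manifest: Dict


def _hallmark_indices(n_genes: int, n_hallmarks: int) -> List[int]:
    n_hallmarks = min(n_hallmarks, n_genes)
    if n_hallmarks == 0:
        return []
    idx = list(np.unique(np.round(np.linspace(0, n_genes - 1, n_hallmarks)).astype(int)))
    # linspace can collapse indices for tiny gene counts; pad from the left
    pool = [i for i in range(n_genes) if i not in set(idx)]
    while len(idx) < n_hallmarks and pool:
        idx.append(pool.pop(0))
    return sorted(idx)


def _assign_phage_flags(rng, genes: List[GeneAnnotation], hallmark_idx: List[int], temperate: bool, family: str):
    n = len(genes)
    for i in hallmark_idx:
        genes[i].viral_hallmark = True
    for g in genes:
        if rng.random() < 0.7:
            g.viral_db_hit = True
        if rng.random() < 0.03:
            g.plasmid_db_hit = True
        if rng.random() < 0.4:
            g.besthit_family = family
    # terminal packaging/structural modules are the best conserved: the first
    # and last genes always carry database evidence, which keeps noise-free
    # communities separable by construction
    genes[0].viral_db_hit = True
    genes[-1].viral_db_hit = True
    # keep the database-count criterion separable by construction
    if sum(g.plasmid_db_hit for g in genes) >= sum(g.viral_db_hit for g in genes):
        for g in genes:
            g.plasmid_db_hit = False
    if temperate:
        genes[int(rng.integers(0, n))].temperate_marker = True


def generate_phage_genome(
    length: int,
    n_hallmarks: int = 3,
    temperate: bool = False,
    circular: bool = False,
    rng_seed=0,
    contig_id: str = "phage",
    family: Optional[str] = None,
    shared_pool: Optional[List[str]] = None,
    shared_frac: float = 0.0,
) -> ContigRecord:
    """One phage genome with annotated genes.

    Circular genomes get a 150–300 bp terminal repeat appended (the contig
    is ``length + repeat`` long; the genome proper is the first ``length``
    bases).  Temperate genomes carry one integrase-like temperate-marker
    gene.  When a ``shared_pool`` of ancestral gene sequences is supplied,
    roughly ``shared_frac`` of the (non-hallmark) genes are diverged copies
    of pool genes, so phages built from the same pool share homologous
    protein content the way members of one viral family do.
    """
    rng = _rng(rng_seed)
    if length < 1000:
        raise ValueError("phage genome too short to lay out genes")
    seq = random_dna(rng, length)
    layout = _lay_genes(rng, length, contig_id)
    if not layout:
        raise ValueError("gene layout does not fit the requested length")
    family = family or FAMILIES[int(rng.integers(0, len(FAMILIES)))]
    hallmark_idx = _hallmark_indices(len(layout), n_hallmarks)
    if shared_pool and shared_frac > 0:
        candidates = [i for i in range(len(layout)) if i not in set(hallmark_idx)]
        k = min(len(candidates), len(shared_pool), int(round(shared_frac * len(layout))))
        picks = rng.choice(len(candidates), size=k, replace=False)
        pool_ids = rng.choice(len(shared_pool), size=k, replace=False)
        for i, j in zip(sorted(int(p) for p in picks), pool_ids):
            start, end, _ = layout[candidates[i]]
            glen = end - start + 1
            donor = shared_pool[int(j)]
            gene_dna = mutate(donor[:glen], 0.05, rng)
            seq = seq[: start - 1] + gene_dna + seq[end:]
    genes = []
    for i, (start, end, strand) in enumerate(layout):
        g = GeneAnnotation(gene_id=f"{contig_id}_g{i + 1:03d}", start=start, end=end, strand=strand)
        g.protein_seq = gene_protein(seq, g)
        genes.append(g)
    _assign_phage_flags(rng, genes, hallmark_idx, temperate, family)
    if circular:
        repeat = int(rng.integers(150, 301))
        seq = seq + seq[:repeat]
    return ContigRecord(id=contig_id, seq=seq, genes=genes)


def generate_plasmid(length: int, rng_seed=0, contig_id: str = "plasmid", circular: bool = False) -> ContigRecord:
    """A plasmid negative control: plasmid hallmark genes, plasmid-db excess."""
    rng = _rng(rng_seed)
    if length < 1000:
        raise ValueError("plasmid too short to lay out genes")
    seq = random_dna(rng, length)
    layout = _lay_genes(rng, length, contig_id)
    if not layout:
        raise ValueError("gene layout does not fit the requested length")
    genes = []
    for i, (start, end, strand) in enumerate(layout):
        g = GeneAnnotation(gene_id=f"{contig_id}_g{i + 1:03d}", start=start, end=end, strand=strand)
        g.protein_seq = gene_protein(seq, g)
        g.plasmid_db_hit = rng.random() < 0.7
        g.viral_db_hit = rng.random() < 0.1
        genes.append(g)
    for i in rng.choice(len(genes), size=min(2, len(genes)), replace=False):
        genes[int(i)].plasmid_hallmark = True
    if sum(g.viral_db_hit for g in genes) >= sum(g.plasmid_db_hit for g in genes):
        for g in genes:
            g.viral_db_hit = False
    if circular:
        repeat = int(rng.integers(150, 301))
        seq = seq + seq[:repeat]
    return ContigRecord(id=contig_id, seq=seq, genes=genes)


def _make_spacer(rng, phage_genome: str, min_len=33, max_len=40, decoys: Sequence[str] = ()) -> str:
    """A spacer copied from the source phage, with at most one edit applied.

    Candidate positions whose sequence also occurs (within one edit) in any
    decoy genome are rejected, so each spacer identifies its source species
    unambiguously even when phage families share diverged gene content.
    """
    import edlib as _edlib

    from .seqcore import revcomp as _rc

    def occurs_within_two_edits(query: str, decoy: str) -> bool:
        for s in (query, _rc(query)):
            d = _edlib.align(s, decoy, mode="HW", task="distance", k=2)["editDistance"]
            if d != -1:
                return True
        return False

    for _ in range(40):
        slen = int(rng.integers(min_len, max_len + 1))
        pos = int(rng.integers(0, len(phage_genome) - slen + 1))
        candidate = phage_genome[pos : pos + slen]
        if not any(occurs_within_two_edits(candidate, decoy) for decoy in decoys):
            break
    spacer = candidate
    if rng.random() < 0.5:  # one edit: substitution, insertion or deletion
        kind = rng.choice(["sub", "ins", "del"])
        i = int(rng.integers(0, len(spacer)))
        if kind == "sub":
            alt = "ACGT".replace(spacer[i], "")[int(rng.integers(0, 3))]
            spacer = spacer[:i] + alt + spacer[i + 1 :]
        elif kind == "ins":
            spacer = spacer[:i] + "ACGT"[int(rng.integers(0, 4))] + spacer[i:]
        else:
            spacer = spacer[:i] + spacer[i + 1 :]
    return spacer


def generate_bacterial_contig(
    length: int,
    genus: str,
    with_crispr: bool = False,
    target_phages: Sequence[PhageTruth] = (),
    prophage: Optional[ContigRecord] = None,
    rng_seed=0,
    contig_id: str = "bact",
    decoy_genomes: Sequence[str] = (),
) -> Tuple[ContigRecord, Optional[ArrayTruth], Optional[Tuple[int, int]]]:
    """A bacterial contig with marker genes, rRNA and optional extras.

    Returns (contig, array_truth_or_None, prophage_interval_or_None).  The
    CRISPR array is 4–8 copies of a 30 bp repeat interleaved with spacers
    copied (with at most one edit) from the target phages; the prophage, if
    given, is inserted verbatim with host genes flanking it.
    """
    rng = _rng(rng_seed)
    if with_crispr and not target_phages:
        raise ValueError("with_crispr requires target phages")
    if prophage is not None and len(prophage.seq) >= length:
        raise ValueError("prophage longer than the contig")

    host_len = length - (len(prophage.seq) if prophage is not None else 0)
    array_seq = ""
    repeat = ""
    spacers: List[Tuple[str, str]] = []
    if with_crispr:
        repeat = random_dna(rng, 30)
        n_spacers = int(rng.integers(3, 8))
        parts = [repeat]
        for j in range(n_spacers):
            phage = target_phages[j % len(target_phages)]
            spacer = _make_spacer(rng, phage.genome, decoys=decoy_genomes)
            spacers.append((spacer, phage.contig_id))
            parts.extend([spacer, repeat])
        array_seq = "".join(parts)
    host_len -= len(array_seq)
    if host_len < 3000:
        raise ValueError("contig too short for the requested extras")

    # host sequence split into blocks around the array and the prophage
    cut1 = int(rng.integers(1000, host_len - 2000)) if (with_crispr or prophage is not None) else host_len
    cut2 = int(rng.integers(cut1 + 500, host_len - 500)) if (with_crispr and prophage is not None) else None

    blocks: List[Tuple[str, str]] = [("host", random_dna(rng, cut1))]
    if with_crispr:
        blocks.append(("array", array_seq))
    if prophage is not None:
        mid_end = cut2 if cut2 is not None else cut1
        if cut2 is not None:
            blocks.append(("host", random_dna(rng, cut2 - cut1)))
        blocks.append(("prophage", prophage.seq))
        blocks.append(("host", random_dna(rng, host_len - (mid_end))))
    else:
        blocks.append(("host", random_dna(rng, host_len - cut1)))

    seq_parts = []
    genes: List[GeneAnnotation] = []
    offset = 0
    array_start = None
    prophage_interval = None
    gi = 0
    for kind, block in blocks:
        if kind == "host":
            layout = _lay_genes(rng, len(block), contig_id)
            for start, end, strand in layout:
                gi += 1
                g = GeneAnnotation(
                    gene_id=f"{contig_id}_g{gi:03d}", start=offset + start, end=offset + end, strand=strand
                )
                g.viral_db_hit = rng.random() < 0.05
                g.plasmid_db_hit = rng.random() < 0.1
                genes.append(g)
        elif kind == "array":
            array_start = offset + 1
        elif kind == "prophage":
            prophage_interval = (offset + 1, offset + len(block))
            for pg in prophage.genes:
                gi += 1
                g = GeneAnnotation(
                    gene_id=f"{contig_id}_g{gi:03d}",
                    start=offset + pg.start,
                    end=offset + pg.end,
                    strand=pg.strand,
                    protein_seq=pg.protein_seq,
                    viral_hallmark=pg.viral_hallmark,
                    viral_db_hit=pg.viral_db_hit,
                    plasmid_db_hit=pg.plasmid_db_hit,
                    temperate_marker=pg.temperate_marker,
                    besthit_family=pg.besthit_family,
                )
                genes.append(g)
        seq_parts.append(block)
        offset += len(block)
    seq = "".join(seq_parts)

    # marker genes and one rRNA interval on host genes
    host_genes = [g for g in genes if not g.viral_hallmark and not g.viral_db_hit]
    if len(host_genes) < 3:
        raise ValueError("not enough host genes for markers")
    picks = rng.choice(len(host_genes), size=3, replace=False)
    host_genes[int(picks[0])].bacterial_marker = True
    host_genes[int(picks[1])].bacterial_marker = rng.random() < 0.5 or host_genes[int(picks[1])].bacterial_marker
    rrna = host_genes[int(picks[2])]
    rrna.rRNA = True
    rrna.protein_seq = ""

    genes = [g for g in genes]
    contig = ContigRecord(id=contig_id, seq=seq, genes=[g for g in genes])
    for g in contig.genes:  # fill proteins for host genes laid above
        if not g.protein_seq and not g.rRNA:
            g.protein_seq = gene_protein(seq, g)

    array_truth = None
    if with_crispr:
        positions = []
        pos = array_start
        positions.append(pos)
        for spacer, _ in spacers:
            pos += 30 + len(spacer)
            positions.append(pos)
        array_truth = ArrayTruth(
            contig_id=contig_id,
            genus=genus,
            repeat_seq=repeat,
            repeat_positions=tuple(positions),
            spacers=tuple(spacers),
        )
    return contig, array_truth, prophage_interval


# --- annotation noise --------------------------------------------------------

def apply_annotation_noise(truth: "CommunityTruth", rate: float, rng_seed=0) -> None:
    """Drop true evidence flags and mis-draw k-mer p-values at the given rate."""
    if rate <= 0:
        return
    rng = _rng(rng_seed)
    flags = [
        "viral_hallmark",
        "plasmid_hallmark",
        "bacterial_marker",
        "rRNA",
        "viral_db_hit",
        "plasmid_db_hit",
        "temperate_marker",
    ]
    for contig in truth.contigs:
        for g in contig.genes:
            for flag in flags:
                if getattr(g, flag) and rng.random() < rate:
                    setattr(g, flag, False)
        if rng.random() < rate:
            is_phage = truth.labels[contig.id] == "phage"
            contig.kmer_p = float(rng.uniform(0.05, 1.0)) if is_phage else float(rng.uniform(0.0, 0.05))


def _assign_kmer_p(truth: "CommunityTruth", rng) -> None:
    for contig in truth.contigs:
        if truth.labels[contig.id] == "phage":
            contig.kmer_p = float(rng.uniform(0.0, 0.05))
        else:
            contig.kmer_p = float(rng.uniform(0.05, 1.0))


def _phage_variant(source: ContigRecord, trimmed_len: int, window: Tuple[int, int], mu: float, rng, contig_id: str):
    """Mutated sub-window [lo, hi) of a source genome with re-derived genes."""
    lo, hi = window
    sub = mutate(source.seq[lo:hi], mu, rng)
    genes = []
    for g in source.genes:
        if g.start - 1 >= lo and g.end <= hi:
            ng = GeneAnnotation(
                gene_id=f"{contig_id}_{g.gene_id.split('_')[-1]}",
                start=g.start - lo,
                end=g.end - lo,
                strand=g.strand,
                viral_hallmark=g.viral_hallmark,
                viral_db_hit=g.viral_db_hit,
                plasmid_db_hit=g.plasmid_db_hit,
                temperate_marker=g.temperate_marker,
                besthit_family=g.besthit_family,
            )
            ng.protein_seq = gene_protein(sub, ng)
            genes.append(ng)
    if genes:  # terminal genes stay database-evidenced (see _assign_phage_flags)
        genes[0].viral_db_hit = True
        genes[-1].viral_db_hit = True
    return ContigRecord(id=contig_id, seq=sub, genes=genes)


def _window_with_hallmark(rng, source: ContigRecord, trimmed_len: int, ratio: float) -> Tuple[int, int]:
    wlen = int(round(ratio * trimmed_len))
    hallmarks = [g for g in source.genes if g.viral_hallmark and g.end <= trimmed_len]
    for _ in range(50):
        lo = int(rng.integers(0, trimmed_len - wlen + 1))
        if any(g.start - 1 >= lo and g.end <= lo + wlen for g in hallmarks):
            return lo, lo + wlen
    g = hallmarks[0]
    lo = max(0, min(g.start - 1, trimmed_len - wlen))
    return lo, lo + wlen


def generate_community(
    seed: int = 42,
    n_circular: int = 10,
    n_linear: int = 15,
    n_prophage: int = 5,
    n_plasmids: int = 20,
    n_bacteria: int = 30,
    noise: float = 0.02,
    frac_generalist: float = 0.3,
    mu_variant: float = 0.01,
) -> CommunityTruth:
    """The default study community: 30 phages (10 circular complete genomes,
    15 linear drafts, 5 prophage-embedded), 20 plasmids and 30 bacterial
    contigs, with CRISPR arrays targeting the planted phages."""
    rng = np.random.default_rng(seed)
    contigs: List[ContigRecord] = []
    labels: Dict[str, str] = {}
    phages: List[PhageTruth] = []
    arrays: List[ArrayTruth] = []
    prophage_intervals: Dict[str, Tuple[int, int]] = {}

    # ancestral per-family gene pools: phages of one family share diverged
    # copies of pool genes, giving the VC stage real structure to recover
    n_families = min(len(FAMILIES), max(1, n_circular // 3))
    pools = [[random_dna(rng, 1200) for _ in range(12)] for _ in range(n_families)]

    # circular source phages, one host genus each (generalists get a second)
    sources: List[ContigRecord] = []
    trimmed_lens: List[int] = []
    host_map: Dict[str, Tuple[str, ...]] = {}
    for i in range(n_circular):
        length = int(rng.integers(20_000, 40_001))
        temperate = rng.random() < 0.4
        cid = f"phage_c{i + 1:02d}"
        fam_idx = i % n_families
        contig = generate_phage_genome(
            length,
            n_hallmarks=int(rng.integers(2, 6)),
            temperate=temperate,
            circular=True,
            rng_seed=rng,
            contig_id=cid,
            family=FAMILIES[fam_idx],
            shared_pool=pools[fam_idx],
            shared_frac=0.3,
        )
        genera = [GENERA[i % len(GENERA)]]
        if rng.random() < frac_generalist:
            genera.append(GENERA[int(rng.integers(0, len(GENERA) - 1))])
            if genera[1] == genera[0]:
                genera[1] = GENERA[-1]
        host_map[cid] = tuple(dict.fromkeys(genera))
        sources.append(contig)
        trimmed_lens.append(length)
        contigs.append(contig)
        labels[cid] = "phage"
        phages.append(
            PhageTruth(
                contig_id=cid,
                species_id=cid,
                genome=contig.seq[:length],
                circular=True,
                lifestyle="temperate" if temperate else "virulent",
                host_genera=host_map[cid],
                hallmark_gene_ids=tuple(g.gene_id for g in contig.genes if g.viral_hallmark),
            )
        )

    # linear drafts: mutated truncations of the circular sources
    for i in range(n_linear):
        src_idx = i % n_circular
        src, tlen = sources[src_idx], trimmed_lens[src_idx]
        ratio = float(rng.uniform(0.75, 0.98))
        cid = f"phage_l{i + 1:02d}"
        window = _window_with_hallmark(rng, src, tlen, ratio)
        contig = _phage_variant(src, tlen, window, mu_variant, rng, cid)
        contigs.append(contig)
        labels[cid] = "phage"
        phages.append(
            PhageTruth(
                contig_id=cid,
                species_id=src.id,
                genome=contig.seq,
                circular=False,
                lifestyle=phages[src_idx].lifestyle,
                host_genera=host_map[src.id],
                hallmark_gene_ids=tuple(g.gene_id for g in contig.genes if g.viral_hallmark),
            )
        )

    # prophage-embedded phages: near-full-length variant with short host flanks
    for i in range(n_prophage):
        src_idx = (i * 2) % n_circular
        src, tlen = sources[src_idx], trimmed_lens[src_idx]
        cid = f"phage_p{i + 1:02d}"
        body = _phage_variant(src, tlen, (0, tlen), mu_variant, rng, cid)
        flank = max(800, int(0.04 * tlen))
        left, right = random_dna(rng, flank), random_dna(rng, flank)
        genes = []
        gi = 0
        # cap host-gene count so the flanks stay below the contamination limit
        n_flank_genes = max(1, len(body.genes) // 15)
        for block_off, block in ((0, left), (flank + tlen, right)):
            quota = n_flank_genes - gi
            if quota <= 0:
                break
            for start, end, strand in _lay_genes(rng, len(block), cid, min_codons=60, max_codons=200)[:quota]:
                gi += 1
                g = GeneAnnotation(gene_id=f"{cid}_h{gi:02d}", start=block_off + start, end=block_off + end, strand=strand)
                genes.append(g)
        for g in body.genes:
            genes.append(
                GeneAnnotation(
                    gene_id=g.gene_id,
                    start=g.start + flank,
                    end=g.end + flank,
                    strand=g.strand,
                    protein_seq=g.protein_seq,
                    viral_hallmark=g.viral_hallmark,
                    viral_db_hit=g.viral_db_hit,
                    plasmid_db_hit=g.plasmid_db_hit,
                    temperate_marker=g.temperate_marker,
                    besthit_family=g.besthit_family,
                )
            )
        seq = left + body.seq + right
        contig = ContigRecord(id=cid, seq=seq, genes=sorted(genes, key=lambda g: g.start))
        for g in contig.genes:
            if not g.protein_seq:
                g.protein_seq = gene_protein(seq, g)
        contigs.append(contig)
        labels[cid] = "phage"
        prophage_intervals[cid] = (flank + 1, flank + tlen)
        phages.append(
            PhageTruth(
                contig_id=cid,
                species_id=src.id,
                genome=body.seq,
                circular=False,
                lifestyle=phages[src_idx].lifestyle,
                host_genera=host_map[src.id],
                hallmark_gene_ids=tuple(g.gene_id for g in contig.genes if g.viral_hallmark),
            )
        )

    # plasmids (a few circular) and bacterial contigs
    for i in range(n_plasmids):
        cid = f"plasmid_{i + 1:02d}"
        contig = generate_plasmid(int(rng.integers(12_000, 30_001)), rng_seed=rng, contig_id=cid, circular=i < 5)
        contigs.append(contig)
        labels[cid] = "plasmid"

    # ensure every (phage, genus) pair is witnessed by at least one array
    demands: List[Tuple[str, PhageTruth]] = []
    by_id = {p.contig_id: p for p in phages}
    for p in phages[:n_circular]:
        for genus in p.host_genera:
            demands.append((genus, p))
    references: List[Tuple[str, str]] = []
    n_crispr = max(len({g for g, _ in demands}), min(10, n_bacteria // 3))
    demand_by_genus: Dict[str, List[PhageTruth]] = {}
    for genus, p in demands:
        demand_by_genus.setdefault(genus, []).append(p)
    crispr_genera = list(demand_by_genus)
    for i in range(n_bacteria):
        cid = f"bact_{i + 1:02d}"
        length = int(rng.integers(25_000, 45_001))
        with_crispr = i < len(crispr_genera)
        genus = crispr_genera[i] if with_crispr else GENERA[i % len(GENERA)]
        targets = demand_by_genus.get(genus, []) if with_crispr else []
        prophage = None
        if not with_crispr and i % 10 == 9:  # a few low-fraction embedded prophages
            src_idx = int(rng.integers(0, n_circular))
            src, tlen = sources[src_idx], trimmed_lens[src_idx]
            frag = _window_with_hallmark(rng, src, tlen, 0.3)
            prophage = _phage_variant(src, tlen, frag, mu_variant, rng, f"{cid}_pro")
            length = max(length, int(len(prophage.seq) / 0.3))
        target_ids = {p.contig_id for p in targets}
        decoys = [
            sources[j].seq[: trimmed_lens[j]] for j in range(n_circular) if sources[j].id not in target_ids
        ]
        contig, array_truth, interval = generate_bacterial_contig(
            length,
            genus,
            with_crispr=with_crispr,
            target_phages=targets,
            prophage=prophage,
            rng_seed=rng,
            contig_id=cid,
            decoy_genomes=decoys if with_crispr else (),
        )
        contigs.append(contig)
        labels[cid] = "bacterial"
        if array_truth is not None:
            arrays.append(array_truth)
        if interval is not None:
            prophage_intervals[cid] = interval
        references.append((genus, mutate(contig.seq, 0.01, rng)))

    truth = CommunityTruth(
        contigs=contigs,
        labels=labels,
        phages=phages,
        arrays=arrays,
        references=references,
        prophage_intervals=prophage_intervals,
        manifest={
            "seed": int(seed),
            "n_circular": n_circular,
            "n_linear": n_linear,
            "n_prophage": n_prophage,
            "n_plasmids": n_plasmids,
            "n_bacteria": n_bacteria,
            "noise": noise,
            "mu_variant": mu_variant,
        },
    )
    _assign_kmer_p(truth, rng)
    apply_annotation_noise(truth, noise, rng)
    return truth


# --- reads -------------------------------------------------------------------

def generate_reads(
    phages: Sequence[PhageTruth],
    hallmark_intervals: Dict[str, List[Tuple[int, int]]],
    depth_per_votu,
    read_len: int = 150,
    error_rate: float = 0.0,
    rng_seed=0,
):
    """Uniform-position shotgun reads from phage genomes.

    ``depth_per_votu`` is either an int (reads per genome) or a mapping
    contig_id -> reads.  Returns (reads, truth_counts) where reads is a list
    of (read_id, seq) and truth_counts maps contig_id to the number of reads
    that originate fully inside a viral hallmark gene.
    """
    rng = _rng(rng_seed)
    reads: List[Tuple[str, str]] = []
    truth_counts: Dict[str, int] = {}
    for p in phages:
        depth = depth_per_votu[p.contig_id] if isinstance(depth_per_votu, dict) else int(depth_per_votu)
        genome = p.genome
        if read_len > len(genome):
            raise ValueError(f"{p.contig_id}: read length exceeds genome length")
        intervals = hallmark_intervals.get(p.contig_id, [])
        truth_counts.setdefault(p.contig_id, 0)
        for i in range(depth):
            start = int(rng.integers(0, len(genome) - read_len + 1))
            frag = genome[start : start + read_len]
            inside_vhg = any(start + 1 >= lo and start + read_len <= hi for lo, hi in intervals)
            if inside_vhg:
                truth_counts[p.contig_id] += 1
            if rng.random() < 0.5:
                frag = revcomp(frag)
            frag = mutate(frag, error_rate, rng)
            reads.append((f"{p.contig_id}|r{i}|{start + 1}", frag))
    return reads, truth_counts


# --- cohort ------------------------------------------------------------------

@dataclass
class CohortTruth:
    votu_rel: pd.DataFrame  # samples x vOTUs, rows sum to 1
    genus_rel: pd.DataFrame  # samples x genera, rows sum to 1
    metadata: pd.DataFrame
    hosts: Dict[str, Tuple[Tuple[str, ...], str, float]]  # votu -> (genera, label, alpha)
    planted_effects: List[Tuple[str, str, float]]
    defence: pd.DataFrame  # samples x defence systems
    lifestyle: Dict[str, str]
    detection_prob: float
    manifest: Dict = field(default_factory=dict)


def _lognormal_mean1(rng, shape, sigma=1.0):
    return np.exp(rng.normal(0.0, sigma, size=shape) - sigma**2 / 2)


def generate_cohort(
    n_samples: int = 500,
    n_votus: int = 60,
    n_genera: int = 20,
    coupling_specialist: float = 0.8,
    coupling_generalist: float = 0.2,
    frac_specialist: float = 0.7,
    detection_prob: float = 0.6,
    planted_effects: Optional[List[Tuple[int, str, float]]] = None,
    n_extra_continuous: int = 4,
    n_extra_binary: int = 4,
    rng_seed=0,
) -> CohortTruth:
    """Multi-sample cohort with phage–host coupling and planted effects.

    Genus abundances are log-normal.  Each vOTU's abundance is
    ``alpha * host + (1 - alpha) * noise`` (host = mean-normalised abundance
    of its host genus, or the mean over genera for generalists), scaled by a
    per-vOTU log-normal factor, shifted by ``beta * x`` on the log10 scale
    for every planted (vOTU, variable, beta) effect, and zero-inflated with
    per-sample detection probability ``detection_prob``.  Defence-system
    abundances are a monotone function of the realised virome Shannon
    diversity plus Gaussian noise.
    """
    if not (0 <= coupling_generalist <= coupling_specialist <= 1):
        raise ValueError("require 0 <= alpha_g <= alpha_s <= 1")
    rng = _rng(rng_seed)
    genera = [f"g{j:02d}" if j >= len(GENERA) else GENERA[j] for j in range(n_genera)]
    votus = [f"vOTU_{k + 1:03d}" for k in range(n_votus)]
    samples = [f"S{s + 1:04d}" for s in range(n_samples)]

    mu_g = rng.normal(0.0, 1.5, size=n_genera)
    genus_abs = np.exp(mu_g[None, :] + rng.normal(0.0, 1.0, size=(n_samples, n_genera)))
    genus_norm = genus_abs / genus_abs.mean(axis=0, keepdims=True)

    # metadata
    meta = pd.DataFrame(index=samples)
    meta["age"] = np.clip(rng.normal(66.4, 12.6, n_samples), 20, 90)
    meta["sex"] = rng.binomial(1, 0.59, n_samples)
    for j in range(n_extra_continuous):
        meta[f"x_cont{j + 1}"] = rng.normal(0.0, 1.0, n_samples)
    for j in range(n_extra_binary):
        meta[f"x_bin{j + 1}"] = rng.binomial(1, 0.5, n_samples)
    meta_std = (meta - meta.mean()) / meta.std(ddof=0)

    planted_effects = planted_effects or []
    effects_named: List[Tuple[str, str, float]] = [
        (votus[k] if isinstance(k, (int, np.integer)) else k, var, float(beta)) for k, var, beta in planted_effects
    ]

    hosts: Dict[str, Tuple[Tuple[str, ...], str, float]] = {}
    lifestyle: Dict[str, str] = {}
    votu_abs = np.zeros((n_samples, n_votus))
    scale = 10 ** rng.normal(-2.0, 0.7, size=n_votus)
    for k, votu in enumerate(votus):
        specialist = rng.random() < frac_specialist
        if specialist:
            hg = (genera[int(rng.integers(0, n_genera))],)
            alpha = coupling_specialist
        else:
            picks = rng.choice(n_genera, size=int(rng.integers(2, 4)), replace=False)
            hg = tuple(genera[int(j)] for j in picks)
            alpha = coupling_generalist
        hosts[votu] = (hg, "specialist" if specialist else "generalist", alpha)
        lifestyle[votu] = "temperate" if rng.random() < 0.4 else "virulent"
        idx = [genera.index(h) for h in hg]
        signal = genus_norm[:, idx].mean(axis=1)
        noise_part = _lognormal_mean1(rng, n_samples)
        base = alpha * signal + (1 - alpha) * noise_part
        log10_shift = np.zeros(n_samples)
        for name, var, beta in effects_named:
            if name == votu:
                log10_shift += beta * meta_std[var].to_numpy()
        votu_abs[:, k] = scale[k] * base * 10**log10_shift
    detected = rng.random((n_samples, n_votus)) < detection_prob
    votu_abs = votu_abs * detected
    # guard: a sample with nothing detected cannot be normalised
    empty = votu_abs.sum(axis=1) == 0
    if empty.any():
        votu_abs[empty, 0] = scale[0]

    votu_rel = votu_abs / votu_abs.sum(axis=1, keepdims=True)
    genus_rel = genus_abs / genus_abs.sum(axis=1, keepdims=True)
    votu_rel = pd.DataFrame(votu_rel, index=samples, columns=votus)
    genus_rel = pd.DataFrame(genus_rel, index=samples, columns=genera)

    p = votu_rel.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        shannon = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    defence = {}
    for j, system in enumerate(DEFENCE_SYSTEMS):
        b = 0.5 + 0.2 * j
        defence[system] = np.exp(0.5 + b * shannon + rng.normal(0.0, 0.5, n_samples))
    defence = pd.DataFrame(defence, index=samples)

    return CohortTruth(
        votu_rel=votu_rel,
        genus_rel=genus_rel,
        metadata=meta,
        hosts=hosts,
        planted_effects=effects_named,
        defence=defence,
        lifestyle=lifestyle,
        detection_prob=detection_prob,
        manifest={
            "n_samples": n_samples,
            "n_votus": n_votus,
            "n_genera": n_genera,
            "alpha_s": coupling_specialist,
            "alpha_g": coupling_generalist,
            "detection_prob": detection_prob,
        },
    )


def expected_spearman(
    alpha: float, detection_prob: float = 0.6, n_hosts: int = 1, n: int = 200_000, seed: int = 12345
) -> float:
    """Model-implied Spearman correlation between a vOTU and one host genus.

    Computed from the same stochastic model as :func:`generate_cohort` at
    large fixed n (no closed form exists for a zero-inflated linear mixture
    of log-normals).  Generalist phages couple to the mean of ``n_hosts``
    genera, which dilutes the correlation against any single genus.
    """
    from scipy.stats import spearmanr

    rng = np.random.default_rng(seed)
    gs = np.exp(rng.normal(0.0, 1.0, (n, n_hosts)))
    gs = gs / gs.mean(axis=0, keepdims=True)
    e = _lognormal_mean1(rng, n)
    v = alpha * gs.mean(axis=1) + (1 - alpha) * e
    v = v * (rng.random(n) < detection_prob)
    return float(spearmanr(v, gs[:, 0]).statistic)


def expected_pair_correlations(n: int = 30_000, seed: int = 777, **cohort_kwargs):
    """Large-sample mean specialist/generalist phage–host Spearman correlation.

    The asymptotic target the cohort model implies for the full correlation
    workflow (including relative-abundance closure and zero-inflation),
    obtained by running the same generative model at large fixed n.
    Returns (mean_specialist_rho, mean_generalist_rho).
    """
    from .ecology import phage_host_correlations
    from .host_prediction import HostAssignment

    cohort = generate_cohort(n_samples=n, rng_seed=seed, **cohort_kwargs)
    assignments = {v: HostAssignment(v, h[0], h[1]) for v, h in cohort.hosts.items()}
    records = phage_host_correlations(cohort.votu_rel, cohort.genus_rel, assignments)
    spec = [r.r_s for r in records if r.label == "specialist"]
    gen = [r.r_s for r in records if r.label == "generalist"]
    return float(np.mean(spec)), float(np.mean(gen))
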