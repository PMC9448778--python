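"""vOTU/VC catalogue construction.

Species-level clusters (vOTUs) come from greedy centroid clustering at
>=95% ANI with >=85% length coverage.  Family/subfamily-level viral
clusters (VCs) come from the fraction of shared protein clusters: proteins
are clustered with the Markov Cluster algorithm (inflation 2) on the
all-vs-all local-alignment similarity graph, and vOTUs sharing >20% of
protein clusters (single-linkage) are grouped into one VC.  Taxonomy is a
best-hit vote at the family level, lifestyle a temperate-score /
bacterial-alignment rule, and rarefaction an empirical subsampling curve.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .config import PipelineConfig
from .seqcore import align_protein_score, estimate_ani, revcomp


@dataclass
class VOTU:
    votu_id: str
    members: Tuple[str, ...]
    representative: str
    representative_length: int


@dataclass(frozen=True)
class ProteinCluster:
    pc_id: str
    members: Tuple[str, ...]


@dataclass
class ViralCluster:
    vc_id: str
    members: Tuple[str, ...]
    mean_shared_fraction: float


_TIER_RANK = {"complete": 3, "high": 2, "medium": 1, "low": 0}


def cluster_votus(
    genomes: Sequence[Tuple[str, str]],
    cfg: PipelineConfig = None,
    tiers: Optional[Dict[str, str]] = None,
) -> List[VOTU]:
    """Greedy centroid clustering of genomes into species-level vOTUs.

    Genomes are sorted by (quality tier, length) descending; each genome
    joins the first centroid reached at ANI >= 95% with aligned fraction
    >= 85% of its own length, otherwise it seeds a new vOTU.
    """
    cfg = cfg or PipelineConfig()
    if not genomes:
        raise ValueError("no genomes to cluster")
    tiers = tiers or {}
    order = sorted(
        genomes, key=lambda g: (_TIER_RANK.get(tiers.get(g[0], "complete"), 0), len(g[1]), g[0]), reverse=True
    )

    def probe_kmers(seq: str, k: int = 16, n_probe: int = 50) -> List[str]:
        step = max(1, (len(seq) - k) // n_probe)
        return [seq[i : i + k] for i in range(0, len(seq) - k + 1, step)][:n_probe]

    centroids: List[Tuple[str, str, frozenset]] = []
    membership: Dict[str, List[str]] = {}
    for gid, seq in order:
        placed = False
        probes = probe_kmers(seq)
        for cid, cseq, ckmers in centroids:
            if len(seq) < 1000 or len(cseq) < 1000:
                continue
            # cheap shared-k-mer prescreen: genomes within 5% divergence share
            # plenty of exact 16-mers, unrelated genomes essentially none
            shared = sum(1 for p in probes if p in ckmers or revcomp(p) in ckmers)
            if shared < max(2, len(probes) // 10):
                continue
            ani, af = estimate_ani(seq, cseq)
            if ani >= cfg.ani_cluster and af >= cfg.cov_cluster:
                membership[cid].append(gid)
                placed = True
                break
        if not placed:
            kset = frozenset(seq[i : i + 16] for i in range(len(seq) - 15))
            centroids.append((gid, seq, kset))
            membership[gid] = [gid]
    lengths = dict((gid, len(seq)) for gid, seq in genomes)
    out = []
    for i, (cid, _, _) in enumerate(centroids):
        out.append(
            VOTU(
                votu_id=f"vOTU_{i + 1:04d}",
                members=tuple(membership[cid]),
                representative=cid,
                representative_length=lengths[cid],
            )
        )
    return out


def mcl(
    adjacency: np.ndarray,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_below: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> List[Tuple[int, ...]]:
    """Markov Cluster algorithm on a symmetric non-negative adjacency matrix.

    Self-loops are added with each node's maximum incident weight, columns
    are normalised to stochastic, and expansion (matrix power) alternates
    with inflation (elementwise power + renormalisation + pruning) until the
    matrix stops changing.  Clusters are the connected components of the
    non-zero structure of the converged matrix.
    """
    M = np.asarray(adjacency, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("adjacency must be square")
    if (M < 0).any():
        raise ValueError("adjacency must be non-negative")
    n = M.shape[0]
    M = M.copy()
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(M, loop)
    M = M / M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = M**inflation
        M[M < prune_below] = 0.0
        M = M / M.sum(axis=0, keepdims=True)
        if np.abs(M - prev).max() < tol:
            break
    G = nx.Graph()
    G.add_nodes_from(range(n))
    rows, cols = np.nonzero(M > prune_below)
    G.add_edges_from(zip(rows.tolist(), cols.tolist()))
    comps = [tuple(sorted(c)) for c in nx.connected_components(G)]
    return sorted(comps)


def _protein_kmers(seq: str, k: int = 8) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def cluster_proteins(
    proteins: Sequence[Tuple[str, str]],
    score_min: float = 100.0,
    inflation: float = 2.0,
) -> List[ProteinCluster]:
    """All-vs-all protein similarity graph clustered with MCL (inflation 2).

    Edges require a local-alignment score >= ``score_min``; an exact shared
    8-mer gates the quadratic alignment (unrelated proteins almost never
    share one).  Singleton proteins form their own clusters.
    """
    if not proteins:
        raise ValueError("no proteins to cluster")
    ids = [pid for pid, _ in proteins]
    seqs = [seq for _, seq in proteins]
    kmers = [_protein_kmers(s) for s in seqs]
    n = len(proteins)
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if kmers[i] & kmers[j]:
                score = align_protein_score(seqs[i], seqs[j])
                if score >= score_min:
                    A[i, j] = A[j, i] = score
    clusters = mcl(A, inflation=inflation)
    return [ProteinCluster(pc_id=f"PC_{k + 1:05d}", members=tuple(ids[i] for i in comp)) for k, comp in enumerate(clusters)]


def build_vcs(
    votu_pcs: Dict[str, set],
    cfg: PipelineConfig = None,
) -> List[ViralCluster]:
    """Group vOTUs into VCs by shared protein-cluster fraction.

    ``votu_pcs`` maps each vOTU id to the set of protein-cluster ids of its
    representative.  The pairwise shared fraction is |A ∩ B| / min(|A|, |B|);
    pairs above 20% (strict) are edges and VCs are the connected components.
    vOTUs with no proteins are excluded.
    """
    cfg = cfg or PipelineConfig()
    items = sorted((v, pcs) for v, pcs in votu_pcs.items() if pcs)
    G = nx.Graph()
    shared: Dict[Tuple[str, str], float] = {}
    G.add_nodes_from(v for v, _ in items)
    for i in range(len(items)):
        vi, pi = items[i]
        for j in range(i + 1, len(items)):
            vj, pj = items[j]
            frac = len(pi & pj) / min(len(pi), len(pj))
            if frac > cfg.shared_pc_min:
                G.add_edge(vi, vj)
                shared[(vi, vj)] = frac
    comps = sorted(tuple(sorted(c)) for c in nx.connected_components(G))
    out = []
    for k, comp in enumerate(comps):
        fracs = [shared[(a, b)] for a, b in shared if a in comp and b in comp]
        out.append(
            ViralCluster(
                vc_id=f"VC_{k + 1:03d}",
                members=comp,
                mean_shared_fraction=float(np.mean(fracs)) if fracs else 0.0,
            )
        )
    return out


def assign_taxonomy(besthit_families: Sequence[Optional[str]], vote_min: float = 0.20) -> str:
    """Family-level vote: the most common best-hit family wins if its share
    of all proteins exceeds the vote threshold; ties are unclassified."""
    if not besthit_families:
        raise ValueError("phage has no proteins")
    counts = Counter(f for f in besthit_families if f)
    if not counts:
        return "unclassified"
    ranked = counts.most_common()
    top_family, top_count = ranked[0]
    if len(ranked) > 1 and ranked[1][1] == top_count:
        return "unclassified"
    if top_count / len(besthit_families) > vote_min:
        return top_family
    return "unclassified"


def classify_lifestyle(
    temperate_score: float,
    bacterial_alignments: Sequence[Tuple[int, float]] = (),
    cfg: PipelineConfig = None,
) -> str:
    """Temperate iff the temperate score exceeds 0.8 or the genome aligns to
    a bacterial genome over >1000 bp at >95% identity; otherwise virulent.

    ``bacterial_alignments`` holds (alignment_length_bp, identity) pairs.
    """
    cfg = cfg or PipelineConfig()
    if not (0 <= temperate_score <= 1):
        raise ValueError("temperate score must lie in [0, 1]")
    if temperate_score > cfg.lifestyle_score:
        return "temperate"
    for aln_len, ident in bacterial_alignments:
        if aln_len > cfg.lifestyle_aln and ident > cfg.lifestyle_ident:
            return "temperate"
    return "virulent"


def temperate_score_standin(genes) -> float:
    """Fraction-of-temperate-marker stand-in for an external lifestyle score:
    1.0 when any temperate-marker gene is present, else 0.0 scaled by count."""
    n = sum(1 for g in genes if g.temperate_marker)
    return min(1.0, float(n))


def rarefy(detection: np.ndarray, depths: Sequence[int], reps: int = 30, rng=None) -> Dict[int, float]:
    """Mean cumulative feature richness over random sample subsets.

    ``detection`` is a binary samples x features matrix.  For each depth d,
    ``reps`` random d-subsets of samples are drawn and the number of
    features detected in at least one subset member is averaged.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    det = np.asarray(detection, dtype=bool)
    n_samples = det.shape[0]
    out: Dict[int, float] = {}
    for d in depths:
        if d < 1 or d > n_samples:
            raise ValueError(f"depth {d} outside 1..{n_samples}")
        richness = []
        for _ in range(reps):
            idx = rng.choice(n_samples, size=d, replace=False)
            richness.append(int(det[idx].any(axis=0).sum()))
        out[int(d)] = float(np.mean(richness))
    return out
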