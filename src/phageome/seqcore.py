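"""Sequence and alignment primitives shared by every pipeline stage.

This module provides the four low-level operations the catalogue workflow is
built on:

* :func:`detect_terminal_redundancy` — circularity check for assembled
  contigs: a circular (complete) genome assembles with an identical copy of
  its start at its end, so a suffix–prefix overlap of >130 bp at >97%
  identity marks the contig as circular.
* :func:`align_protein` — local protein alignment (BLOSUM62, affine gaps)
  used for draft-genome recovery and protein clustering.
* :func:`estimate_ani` — fragment-based average nucleotide identity between
  two genomes, the basis of species-level (vOTU) clustering.
* :func:`map_read` — a minimal seed-and-extend read mapper with a >=95%
  identity requirement, used to count reads on viral hallmark genes.

All coordinates are 1-based and inclusive on the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

NUC_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N stays N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence over {A, C, G, T, N}, uppercase."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")
        if not set(self.seq) <= NUC_ALPHABET:
            bad = sorted(set(self.seq) - NUC_ALPHABET)
            raise ValueError(f"{self.id}: non-ACGTN characters {bad}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    target_id: str
    identity: float
    aln_len: int
    query_cov: float
    target_cov: float
    mismatches: int
    gaps: int
    score: float


@dataclass(frozen=True)
class CircularityResult:
    is_circular: bool
    overlap_len: int
    overlap_identity: float
    trimmed_length: int


def _as_str(seq) -> str:
    return seq.seq if isinstance(seq, NucSequence) else str(seq)


def detect_terminal_redundancy(
    seq,
    min_overlap: int = 131,
    min_identity: float = 0.97,
) -> CircularityResult:
    """Find the longest ungapped suffix–prefix overlap marking circularity.

    The comparison is substitutions-only (no indels).  For every candidate
    overlap length L (min_overlap <= L <= len/2) the first L bases are
    compared with the last L bases; the longest L whose identity exceeds
    ``min_identity`` wins.  Match counts for all L at once are obtained from
    the sequence autocorrelation computed with FFTs, which is exactly
    equivalent to the exhaustive per-L scan.

    Thresholds are strict: the defaults accept only overlaps longer than
    130 bp at identity above 0.97 (a 130 bp exact repeat is rejected).
    """
    s = _as_str(seq)
    n = len(s)
    if n <= 2 * min_overlap:
        raise ValueError(f"sequence too short for circularity check (len {n} <= {2 * min_overlap})")
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    max_overlap = n // 2
    # matches(L) = #{i < L : s[i] == s[n-L+i]} = autocorrelation at lag n-L
    size = 1 << int(np.ceil(np.log2(2 * n)))
    total = np.zeros(n)
    for base in b"ACGT":
        x = (arr == base).astype(np.float64)
        f = np.fft.rfft(x, size)
        total += np.fft.irfft(f * np.conj(f), size)[:n]
    matches = np.rint(total).astype(np.int64)  # indexed by lag d = n - L
    eps = 1e-9
    for L in range(max_overlap, min_overlap - 1, -1):
        m = int(matches[n - L])
        if m / L > min_identity - eps:
            return CircularityResult(True, L, m / L, n - L)
    return CircularityResult(False, 0, 0.0, n)


# --- protein alignment -------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner

_ALIGNER = _make_aligner()


def _check_protein(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty protein sequence")
    if not set(seq) <= AA_ALPHABET:
        bad = sorted(set(seq) - AA_ALPHABET)
        raise ValueError(f"{name}: non-standard amino acids {bad}")


def align_protein_score(q: str, t: str) -> float:
    """Local-alignment score only (no traceback); 0.0 when nothing aligns."""
    _check_protein(q, "query")
    _check_protein(t, "target")
    return float(_ALIGNER.score(q, t))


def align_protein(q: str, t: str, query_id: str = "query", target_id: str = "target") -> AlignmentHit:
    """Best local alignment of two proteins under BLOSUM62 with affine gaps.

    Tie-breaking is deterministic (biopython's first reported optimal path).
    Identity is matches / alignment columns (gap columns included).
    """
    _check_protein(q, "query")
    _check_protein(t, "target")
    alignments = _ALIGNER.align(q, t)
    if len(alignments) == 0 or alignments.score <= 0:
        return AlignmentHit(query_id, target_id, 0.0, 0, 0.0, 0.0, 0, 0, 0.0)
    aln = alignments[0]
    blocks = aln.aligned  # ((qstart,qend)...), ((tstart,tend)...)
    qblocks, tblocks = blocks
    matches = 0
    mismatches = 0
    aligned_cols = 0
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        aligned_cols += qe - qs
        for a, b in zip(q[qs:qe], t[ts:te]):
            if a == b:
                matches += 1
            else:
                mismatches += 1
    qspan = qblocks[-1][1] - qblocks[0][0]
    tspan = tblocks[-1][1] - tblocks[0][0]
    gaps = (qspan - aligned_cols) + (tspan - aligned_cols)
    aln_len = aligned_cols + gaps
    return AlignmentHit(
        query_id,
        target_id,
        identity=matches / aln_len,
        aln_len=aln_len,
        query_cov=qspan / len(q),
        target_cov=tspan / len(t),
        mismatches=mismatches,
        gaps=gaps,
        score=float(aln.score),
    )


# --- ANI ---------------------------------------------------------------------

def _fragment_bounds(n: int, fragment: int):
    """Non-overlapping fragments covering [0, n); the last one absorbs the tail."""
    k = n // fragment
    bounds = [(i * fragment, (i + 1) * fragment) for i in range(k)]
    if bounds:
        bounds[-1] = (bounds[-1][0], n)
    return bounds


def _best_infix_identity(frag: str, target: str, good_enough: float = 0.95) -> float:
    """Identity of the best semi-global placement of frag in target (both strands).

    The reverse strand is only tried when the forward placement is poor.
    """
    d = edlib.align(frag, target, mode="HW", task="distance")["editDistance"]
    if d > (1 - good_enough) * len(frag):
        rc = edlib.align(revcomp(frag), target, mode="HW", task="distance")["editDistance"]
        d = min(d, rc)
    return 1.0 - d / len(frag)


def estimate_ani(a, b, fragment: int = 1000, min_frag_identity: float = 0.8):
    """Fragment-based ANI of genome ``a`` against genome ``b``.

    ``a`` is cut into non-overlapping ~``fragment`` bp pieces; each piece is
    aligned semi-globally to ``b`` (both strands).  Fragments reaching
    ``min_frag_identity`` count as aligned.  Returns ``(ani, aligned_fraction)``
    where ani is the mean identity of aligned fragments and aligned_fraction
    the summed aligned fragment length over len(a).
    """
    sa, sb = _as_str(a), _as_str(b)
    if len(sa) < fragment or len(sb) < fragment:
        raise ValueError(f"sequences must be >= fragment length ({fragment} bp)")
    identities = []
    aligned_len = 0
    for lo, hi in _fragment_bounds(len(sa), fragment):
        frag = sa[lo:hi]
        ident = _best_infix_identity(frag, sb)
        if ident >= min_frag_identity:
            identities.append(ident)
            aligned_len += hi - lo
    ani = float(np.mean(identities)) if identities else 0.0
    return ani, aligned_len / len(sa)


# --- read mapping ------------------------------------------------------------

@dataclass(frozen=True)
class ReadHit:
    gene_id: str
    votu_id: str
    strand: str
    identity: float
    aligned_len: int


@dataclass
class GeneIndex:
    """Exact k-mer index over a gene set, keyed back to the owning vOTU."""

    k: int = 21
    genes: list = field(default_factory=list)  # (gene_id, votu_id, seq)
    _kmers: dict = field(default_factory=dict, repr=False)
    votu_gene_bp: dict = field(default_factory=dict, repr=False)

    def add(self, gene_id: str, votu_id: str, seq: str) -> None:
        idx = len(self.genes)
        self.genes.append((gene_id, votu_id, seq))
        self.votu_gene_bp[votu_id] = self.votu_gene_bp.get(votu_id, 0) + len(seq)
        for pos in range(len(seq) - self.k + 1):
            self._kmers.setdefault(seq[pos : pos + self.k], []).append((idx, pos))

    def __len__(self) -> int:
        return len(self.genes)


def build_gene_index(genes: Sequence, k: int = 21) -> GeneIndex:
    """Index (gene_id, votu_id, seq) triples for read mapping."""
    index = GeneIndex(k=k)
    for gene_id, votu_id, seq in genes:
        index.add(gene_id, votu_id, _as_str(seq))
    return index


def _ungapped_hit(read: str, gene: str, offset: int):
    """Overlap of read placed at gene offset; returns (matches, aligned_len)."""
    rs = max(0, -offset)
    gs = max(0, offset)
    length = min(len(read) - rs, len(gene) - gs)
    if length <= 0:
        return 0, 0
    r = np.frombuffer(read[rs : rs + length].encode(), dtype=np.uint8)
    g = np.frombuffer(gene[gs : gs + length].encode(), dtype=np.uint8)
    return int((r == g).sum()), length


def map_read_status(read, index: GeneIndex, min_identity: float = 0.95, min_cov: float = 0.90):
    """Map one read; returns (hit_or_None, status in {mapped, unmapped, tie}).

    Seeds are exact k-mers taken every k bases along the read (both strands);
    each seeded placement is scored by ungapped comparison.  A hit requires
    identity >= min_identity over >= min_cov of the read.  When distinct
    vOTUs tie for the best placement the read is discarded (status "tie") so
    that multi-mapping reads are never double-counted.
    """
    if len(index) == 0:
        raise ValueError("empty gene index")
    r = _as_str(read)
    k = index.k
    if len(r) < k:
        raise ValueError(f"read shorter than seed size k={k}")
    best = None  # (matches, ReadHit)
    best_votus = set()
    for strand, rseq in (("+", r), ("-", revcomp(r))):
        seen = set()
        seed_starts = list(range(0, len(rseq) - k + 1, k))
        if seed_starts[-1] != len(rseq) - k:
            seed_starts.append(len(rseq) - k)
        for spos in seed_starts:
            for gidx, gpos in index._kmers.get(rseq[spos : spos + k], ()):
                offset = gpos - spos
                if (gidx, offset) in seen:
                    continue
                seen.add((gidx, offset))
                gene_id, votu_id, gseq = index.genes[gidx]
                matches, length = _ungapped_hit(rseq, gseq, offset)
                if length < min_cov * len(rseq) or matches < min_identity * length:
                    continue
                if best is None or matches > best[0]:
                    best = (matches, ReadHit(gene_id, votu_id, strand, matches / length, length))
                    best_votus = {votu_id}
                elif matches == best[0]:
                    best_votus.add(votu_id)
    if best is None:
        return None, "unmapped"
    if len(best_votus) > 1:
        return None, "tie"
    return best[1], "mapped"


def map_read(read, index: GeneIndex, min_identity: float = 0.95, min_cov: float = 0.90) -> Optional[ReadHit]:
    """Best unique hit for a read, or None (unmapped or ambiguous)."""
    return map_read_status(read, index, min_identity=min_identity, min_cov=min_cov)[0]
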