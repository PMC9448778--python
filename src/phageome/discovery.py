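"""Six-criterion phage discovery over annotated contigs.

A contig is called a phage only if it passes all six screening criteria, in
this order:

1. size — contigs under 10 kb are excluded (typical dsDNA phage genomes are
   larger);
2. viral k-mer signal — contigs whose viral k-mer p-value exceeds 0.05 are
   excluded;
3. hallmark genes — at least one viral hallmark gene (terminase, capsid,
   portal, ...) and no plasmid hallmark gene;
4. no bacterial essential genes — contigs carrying single-copy housekeeping
   marker genes or rRNA genes are excluded;
5. database balance — contigs with more genes hitting the plasmid protein
   database than the viral one are excluded (ties are kept: the rule removes
   only contigs with strictly more plasmid hits);
6. provirus fraction — contigs in which the viral region covers less than
   80% of the length are excluded.

Circular contigs (terminal redundancy) passing all six become *complete*
genomes.  Linear contigs are then recovered as drafts when they share >40%
of their genes with a complete genome and fall inside the (70%, 120%) size
window; drafts that end up low quality (<50% completeness) or with >10%
contamination are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .config import PipelineConfig
from .io import ContigRecord, GeneAnnotation
from .seqcore import CircularityResult, align_protein_score, detect_terminal_redundancy

CRITERIA = ("size", "kmer", "hallmark", "marker", "dbcount", "provirus")


@dataclass(frozen=True)
class CriteriaReport:
    contig_id: str
    size_pass: bool
    kmer_pass: bool
    hallmark_pass: bool
    marker_pass: bool
    dbcount_pass: bool
    provirus_pass: bool
    kmer_p: float
    provirus_fraction: float

    @property
    def passes(self) -> Tuple[bool, ...]:
        return (
            self.size_pass,
            self.kmer_pass,
            self.hallmark_pass,
            self.marker_pass,
            self.dbcount_pass,
            self.provirus_pass,
        )

    @property
    def verdict(self) -> str:
        return "phage" if all(self.passes) else "rejected"

    @property
    def rejected_at(self) -> Optional[int]:
        """1-based index of the first failing criterion, or None."""
        for i, ok in enumerate(self.passes, start=1):
            if not ok:
                return i
        return None


@dataclass(frozen=True)
class PhageCall:
    contig_id: str
    circular: bool
    completeness: float
    contamination: float
    tier: str  # complete | high | medium | low
    matched_complete_ref: Optional[str]
    genome: str  # trimmed sequence for circular contigs
    genes: tuple


def _viral_evidence(g: GeneAnnotation) -> bool:
    return g.viral_hallmark or g.viral_db_hit


def _host_flagged(g: GeneAnnotation) -> bool:
    return g.bacterial_marker or g.rRNA


def estimate_provirus_fraction(contig: ContigRecord) -> float:
    """Fraction of the contig covered by its largest viral region.

    Host-flagged genes (bacterial markers, rRNA) break the contig into
    segments.  Within a segment the viral region spans the first to the
    last gene with viral evidence (hallmark or viral-database hit); where
    the segment touches a contig end the region extends to that end, since
    no host gene bounds it.  The returned value is the largest region over
    the contig length: a fully viral contig scores 1.0, a 30 kb prophage
    wedged between host genes on a 100 kb contig ~0.3.
    """
    if not contig.genes:
        return 0.0
    n = len(contig.seq)
    genes = sorted(contig.genes, key=lambda g: g.start)
    best = 0
    seg_start = 1  # current segment start (1-based)
    bounded_left = False  # segment delimited by a host gene (vs the contig end)
    first_viral = last_viral = None
    for g in genes:
        if _host_flagged(g):
            if first_viral is not None:
                # closed on the right by this host gene: region is the viral
                # span, extended to the contig start when the segment is open
                lo = first_viral if bounded_left else seg_start
                best = max(best, last_viral - lo + 1)
            seg_start = g.end + 1
            bounded_left = True
            first_viral = last_viral = None
        elif _viral_evidence(g):
            if first_viral is None:
                first_viral = g.start
            last_viral = max(last_viral or 0, g.end)
    if first_viral is not None:
        lo = first_viral if bounded_left else seg_start
        best = max(best, n - lo + 1)  # open right end extends to the contig end
    return best / n


def estimate_contamination(contig: ContigRecord) -> float:
    """Stand-in contamination estimate.

    Fraction of genes that are host-flagged or lie entirely outside the
    viral span (first to last gene with viral evidence) without viral
    evidence of their own.  A pure phage scores 0; a prophage with host
    flanks scores roughly the flank gene fraction; a contig with no viral
    genes at all scores 1.
    """
    if not contig.genes:
        return 0.0
    viral = [g for g in contig.genes if _viral_evidence(g)]
    if not viral:
        return 1.0
    span_lo = min(g.start for g in viral)
    span_hi = max(g.end for g in viral)
    host_like = sum(
        1
        for g in contig.genes
        if _host_flagged(g) or (not _viral_evidence(g) and (g.end < span_lo or g.start > span_hi))
    )
    return host_like / len(contig.genes)


def classify_contig(contig: ContigRecord, cfg: PipelineConfig = None) -> CriteriaReport:
    """Evaluate all six criteria (each is reported even after a failure)."""
    cfg = cfg or PipelineConfig()
    if contig.kmer_p is None:
        raise ValueError(f"contig {contig.id}: missing k-mer p-value")
    if not contig.genes:
        raise ValueError(f"contig {contig.id}: missing gene annotations")
    n_viral_db = sum(g.viral_db_hit for g in contig.genes)
    n_plasmid_db = sum(g.plasmid_db_hit for g in contig.genes)
    provirus = estimate_provirus_fraction(contig)
    return CriteriaReport(
        contig_id=contig.id,
        size_pass=len(contig.seq) >= cfg.min_size,
        kmer_pass=contig.kmer_p <= cfg.kmer_p_max,
        hallmark_pass=any(g.viral_hallmark for g in contig.genes)
        and not any(g.plasmid_hallmark for g in contig.genes),
        marker_pass=not any(_host_flagged(g) for g in contig.genes),
        dbcount_pass=not (n_plasmid_db > n_viral_db),
        provirus_pass=provirus >= cfg.provirus_min,
        kmer_p=contig.kmer_p,
        provirus_fraction=provirus,
    )


def screen_circular(
    contigs: Sequence[ContigRecord], cfg: PipelineConfig = None
) -> Tuple[List[PhageCall], Dict[str, CriteriaReport], Dict[str, CircularityResult]]:
    """Complete-genome screen: circular contigs passing all six criteria.

    Returns (calls, reports, circularity) where reports/circularity cover
    every input contig long enough to be checked.
    """
    cfg = cfg or PipelineConfig()
    calls: List[PhageCall] = []
    reports: Dict[str, CriteriaReport] = {}
    circ: Dict[str, CircularityResult] = {}
    for contig in contigs:
        if len(contig.seq) < cfg.min_size:
            circ[contig.id] = CircularityResult(False, 0, 0.0, len(contig.seq))
            continue
        result = detect_terminal_redundancy(contig.seq)
        circ[contig.id] = result
        if not result.is_circular:
            continue
        report = classify_contig(contig, cfg)
        reports[contig.id] = report
        if report.verdict == "phage":
            trimmed = contig.seq[: result.trimmed_length]
            genes = tuple(g for g in contig.genes if g.end <= result.trimmed_length)
            calls.append(
                PhageCall(
                    contig_id=contig.id,
                    circular=True,
                    completeness=1.0,
                    contamination=estimate_contamination(contig),
                    tier="complete",
                    matched_complete_ref=None,
                    genome=trimmed,
                    genes=genes,
                )
            )
    return calls, reports, circ


def _protein_kmers(seq: str, k: int = 8) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def _gene_match_fraction(contig: ContigRecord, genome_genes, genome_kmers, score_min: float) -> float:
    """Fraction of the contig's genes with a protein alignment (score >= cutoff)
    to some gene of the candidate complete genome.  An exact shared 8-mer is
    required before running the dynamic-programming alignment (fast screen)."""
    if not contig.genes:
        return 0.0
    matched = 0
    for g in contig.genes:
        if not g.protein_seq:
            continue
        qk = _protein_kmers(g.protein_seq)
        hit = False
        for tprot, tk in zip(genome_genes, genome_kmers):
            if qk & tk and align_protein_score(g.protein_seq, tprot) >= score_min:
                hit = True
                break
        if hit:
            matched += 1
    return matched / len(contig.genes)


def completeness_tier(completeness: float) -> str:
    if completeness >= 0.9:
        return "high"
    if completeness >= 0.5:
        return "medium"
    return "low"


def recover_linear(
    linear_contigs: Sequence[ContigRecord],
    complete_genomes: Sequence[PhageCall],
    cfg: PipelineConfig = None,
) -> Tuple[List[PhageCall], Dict[str, CriteriaReport]]:
    """Draft-genome recovery of linear contigs against complete genomes.

    A linear contig is a candidate when, for some complete genome, >40% of
    its genes align (protein level) to that genome's genes and its size is
    >70% and <120% of the genome's.  Candidates must then pass the six
    criteria; surviving calls are tiered by completeness = len/len(matched)
    and drafts that are low quality or >10% contaminated are excluded.
    """
    cfg = cfg or PipelineConfig()
    calls: List[PhageCall] = []
    reports: Dict[str, CriteriaReport] = {}
    prepared = []
    for genome in complete_genomes:
        prots = [g.protein_seq for g in genome.genes if g.protein_seq]
        prepared.append((genome, prots, [_protein_kmers(p) for p in prots]))
    for contig in linear_contigs:
        best: Tuple[float, Optional[PhageCall]] = (0.0, None)
        for genome, prots, kmers in prepared:
            ratio = len(contig.seq) / len(genome.genome)
            if not (cfg.recovery_size_lo < ratio < cfg.recovery_size_hi):
                continue
            frac = _gene_match_fraction(contig, prots, kmers, cfg.recovery_score_min)
            if frac > cfg.recovery_gene_frac and frac > best[0]:
                best = (frac, genome)
        if best[1] is None:
            continue
        report = classify_contig(contig, cfg)
        reports[contig.id] = report
        if report.verdict != "phage":
            continue
        matched = best[1]
        completeness = min(1.0, len(contig.seq) / len(matched.genome))
        contamination = estimate_contamination(contig)
        tier = completeness_tier(completeness)
        if tier == "low" or contamination > cfg.contamination_max:
            continue
        calls.append(
            PhageCall(
                contig_id=contig.id,
                circular=False,
                completeness=completeness,
                contamination=contamination,
                tier=tier,
                matched_complete_ref=matched.contig_id,
                genome=contig.seq,
                genes=tuple(contig.genes),
            )
        )
    return calls, reports


def run_discovery(
    contigs: Sequence[ContigRecord],
    cfg: PipelineConfig = None,
    external_completes: Sequence[PhageCall] = (),
):
    """Circular-first screening followed by linear draft recovery.

    Returns (calls, reports) where calls holds complete genomes first and
    drafts second (ids are disjoint by construction).
    """
    cfg = cfg or PipelineConfig()
    complete_calls, reports, circ = screen_circular(contigs, cfg)
    complete_ids = {c.contig_id for c in complete_calls}
    linear = [
        c
        for c in contigs
        if c.id not in complete_ids and not circ.get(c.id, CircularityResult(False, 0, 0.0, 0)).is_circular
    ]
    draft_calls, draft_reports = recover_linear(
        linear, list(complete_calls) + list(external_completes), cfg
    )
    reports = {**reports, **draft_reports}
    return list(complete_calls) + draft_calls, reports


def evaluate_pipeline(calls: Sequence[PhageCall], truth: Dict[str, str]) -> Tuple[float, float]:
    """(TPR, FPR) of a set of phage calls against per-contig truth labels.

    TPR = true phages called / true phages; FPR = non-phage contigs called
    phage / non-phage contigs.  ``truth`` maps contig id -> label in
    {"phage", "plasmid", "bacterial"}.
    """
    if not truth:
        raise ValueError("empty truth labelling")
    called = {c.contig_id for c in calls}
    n_phage = sum(1 for v in truth.values() if v == "phage")
    n_other = len(truth) - n_phage
    if n_phage == 0 or n_other == 0:
        raise ValueError("truth must contain both phage and non-phage contigs")
    tp = sum(1 for cid, v in truth.items() if v == "phage" and cid in called)
    fp = sum(1 for cid, v in truth.items() if v != "phage" and cid in called)
    return tp / n_phage, fp / n_other
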