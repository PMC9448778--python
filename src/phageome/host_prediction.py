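"""CRISPR-spacer host prediction.

Spacers in a bacterial CRISPR array are fragments of phages that previously
infected that lineage, so a spacer matching a phage genome (protospacer)
ties the phage to the bacterium.  The workflow: detect repeat/spacer arrays
in bacterial or metagenomic contigs, keep spacers of 25–100 bp, match them
against phage genomes allowing 100% identity or exactly one mismatch/indel
with >95% of the spacer aligned (both strands), resolve the source contig's
genus, and label each phage specialist (one predicted genus) or generalist
(several).  A fixed list of non-intestinal genera is excluded from
assignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import edlib

from .config import PipelineConfig
from .seqcore import estimate_ani, revcomp

# genera flagged as non-(human-)intestinal: spacer hits resolving only to
# these are treated as spurious and dropped
EXCLUDED_HOST_GENERA = frozenset(
    {
        "Dickeya",
        "Anaerobutyricum",
        "Rubellimicrobium",
        "Eisenbergiella",
        "Harryflintia",
        "Leucothrix",
        "Photorhabdus",
        "Spirosoma",
        "Syntrophobotulus",
        "Thermincola",
        "Algoriphagus",
        "Franconibacter",
        "Kandleria",
        "Lawsonibacter",
        "Methylomonas",
        "Provencibacterium",
        "Pseudoruminoccoccus",
        "Rhodanobacter",
        "Romboutsia",
        "Sharpea",
        "Varibaculum",
        "Thioalkalivibrio",
    }
)


@dataclass
class CrisprArray:
    contig_id: str
    repeat_seq: str
    repeat_positions: Tuple[int, ...]  # 1-based starts
    spacers: Tuple[Tuple[str, int], ...]  # (sequence, 1-based start)
    source_taxonomy: Optional[str] = None


@dataclass(frozen=True)
class SpacerHit:
    spacer_id: str
    phage_id: str
    strand: str
    position: int  # 1-based start of the matched protospacer window
    edits: int
    coverage: float


@dataclass
class HostAssignment:
    votu_id: str
    genera: Tuple[str, ...]
    label: str  # specialist | generalist | unknown


# --- array detection ---------------------------------------------------------

_SEED_K = 20
_MIN_COPIES = 3
_MIN_PERIOD = 40  # repeat >= 20 plus spacer >= 20
_MAX_PERIOD = 160  # repeat <= 50 plus spacer <= 110
_MAX_REPEAT = 50
_MIN_SPACER = 20
_MAX_SPACER = 110
_MAX_HAMMING = 2


def _chain_positions(positions: List[int]) -> List[List[int]]:
    """Maximal runs of seed positions with inter-start gaps in the CRISPR period range."""
    chains: List[List[int]] = []
    current = [positions[0]]
    for p in positions[1:]:
        gap = p - current[-1]
        if _MIN_PERIOD <= gap <= _MAX_PERIOD:
            current.append(p)
        else:
            if len(current) >= _MIN_COPIES:
                chains.append(current)
            current = [p]
    if len(current) >= _MIN_COPIES:
        chains.append(current)
    return chains


def _extend_repeat(seq: str, starts: List[int], k: int):
    """Grow the seed left/right while the column is unanimous across copies
    and the repeat/spacer length constraints hold.  Unanimous extension
    recovers exact repeat boundaries; copies that diverge from the
    consensus simply yield a shorter shared core."""
    left, right = 0, k
    min_gap = min(b - a for a, b in zip(starts, starts[1:]))

    def column_unanimous(offset: int) -> bool:
        chars = {seq[s + offset] for s in starts}
        return len(chars) == 1

    while (
        left > -starts[0]
        and (right - left) < _MAX_REPEAT
        and min_gap - (right - left) - 1 >= _MIN_SPACER
        and column_unanimous(left - 1)
    ):
        left -= 1
    while (
        starts[-1] + right < len(seq)
        and (right - left) < _MAX_REPEAT
        and min_gap - (right - left) - 1 >= _MIN_SPACER
        and column_unanimous(right)
    ):
        right += 1
    return left, right


def detect_crispr_arrays(contig_id: str, seq: str) -> List[CrisprArray]:
    """Greedy seed-and-extend CRISPR array detector.

    Seeds are exact 20-mers occurring >=3 times at spacings compatible with
    a repeat (20–50 bp) plus spacer (20–110 bp) structure; seeds are
    extended to the full repeat, and spacers are read off between
    consecutive repeat copies.  Overlapping candidate arrays are collapsed
    to the first-detected one.
    """
    if len(seq) < 200:
        return []
    occurrences: Dict[str, List[int]] = {}
    for i in range(len(seq) - _SEED_K + 1):
        occurrences.setdefault(seq[i : i + _SEED_K], []).append(i)
    # every compatible chain from every repeated seed; chains with more
    # copies win a region over shadow seeds that straddle a boundary
    chains: List[List[int]] = []
    for kmer, positions in occurrences.items():
        if len(positions) >= _MIN_COPIES:
            chains.extend(_chain_positions(positions))
    chains.sort(key=lambda c: (-len(c), c[0]))
    claimed: List[Tuple[int, int]] = []
    arrays: List[CrisprArray] = []
    for chain in chains:
        lo, hi = chain[0], chain[-1] + _SEED_K
        if any(not (hi <= a or lo >= b) for a, b in claimed):
            continue
        left, right = _extend_repeat(seq, chain, _SEED_K)
        starts = [p + left for p in chain]
        rlen = right - left
        if rlen < 20:
            continue
        repeat = seq[starts[0] : starts[0] + rlen]
        spacers = []
        ok = True
        for a, b in zip(starts, starts[1:]):
            s_start, s_end = a + rlen, b
            slen = s_end - s_start
            if not (_MIN_SPACER <= slen <= _MAX_SPACER):
                ok = False
                break
            spacers.append((seq[s_start:s_end], s_start + 1))
        if not ok or not spacers:
            continue
        arrays.append(
            CrisprArray(
                contig_id=contig_id,
                repeat_seq=repeat,
                repeat_positions=tuple(s + 1 for s in starts),
                spacers=tuple(spacers),
            )
        )
        claimed.append((starts[0], starts[-1] + rlen))
    arrays.sort(key=lambda a: a.repeat_positions[0])
    return arrays


def filter_spacers(spacers: Sequence[str], cfg: PipelineConfig = None) -> List[str]:
    """Keep spacers of 25–100 bp (shorter/longer ones are discarded)."""
    cfg = cfg or PipelineConfig()
    return [s for s in spacers if cfg.spacer_min <= len(s) <= cfg.spacer_max]


# --- spacer matching ---------------------------------------------------------

def _edit_at_start(spacer: str, genome: str, start: int) -> Optional[int]:
    """Min edit distance over protospacer windows starting at ``start``
    (lengths len-1, len, len+1); None if above 1."""
    n = len(spacer)
    best = None
    for L in (n - 1, n, n + 1):
        if L <= 0 or start + L > len(genome):
            continue
        d = edlib.align(spacer, genome[start : start + L], mode="NW", task="distance", k=1)["editDistance"]
        if d != -1 and (best is None or d < best):
            best = d
    return best


def match_spacer(
    spacer_id: str, spacer: str, phage_id: str, genome: str, cfg: PipelineConfig = None
) -> List[SpacerHit]:
    """All protospacer placements of a spacer in a phage genome at <=1 edit.

    Pigeonhole search: with at most one edit, at least one half of the
    spacer occurs exactly, so exact occurrences of both halves anchor
    candidate start positions which are then verified by banded edit
    distance.  Both strands are searched; a one-deletion hit still covers
    (len-1)/len > 95% of any spacer of >= 25 bp.
    """
    cfg = cfg or PipelineConfig()
    n = len(spacer)
    hits: List[SpacerHit] = []
    for strand, s in (("+", spacer), ("-", revcomp(spacer))):
        half = n // 2
        anchors = ((s[:half], 0), (s[half:], half))
        candidates: Set[int] = set()
        for part, offset in anchors:
            pos = genome.find(part)
            while pos != -1:
                base = pos - offset
                for shift in (-1, 0, 1):
                    start = base + shift
                    if 0 <= start <= len(genome):
                        candidates.add(start)
                pos = genome.find(part, pos + 1)
        for start in sorted(candidates):
            d = _edit_at_start(s, genome, start)
            if d is None:
                continue
            coverage = (n - (1 if d == 1 else 0)) / n  # worst case: the edit is a deletion
            if coverage > cfg.spacer_cov:
                hits.append(
                    SpacerHit(
                        spacer_id=spacer_id,
                        phage_id=phage_id,
                        strand=strand,
                        position=start + 1,
                        edits=d,
                        coverage=coverage,
                    )
                )
    return hits


def assign_contig_taxonomy(
    contig_seq: str, references: Sequence[Tuple[str, str]], cfg: PipelineConfig = None
) -> Optional[str]:
    """Transfer the genus of the best reference alignment with identity
    > 90% over > 70% of the contig; None when no reference qualifies."""
    cfg = cfg or PipelineConfig()
    best: Tuple[float, Optional[str]] = (0.0, None)
    for genus, ref in references:
        if len(contig_seq) < 1000 or len(ref) < 1000:
            continue
        ani, af = estimate_ani(contig_seq, ref)
        if ani > cfg.ctg_tax_ident and af > cfg.ctg_tax_cov and ani > best[0]:
            best = (ani, genus)
    return best[1]


def assign_hosts(
    votu_id: str,
    spacer_hits: Sequence[SpacerHit],
    spacer_taxonomy: Dict[str, Optional[str]],
    exclusion: frozenset = EXCLUDED_HOST_GENERA,
) -> HostAssignment:
    """Genus-level host set for one vOTU from its spacer hits.

    ``spacer_taxonomy`` maps spacer ids to the genus of their source array
    (None when the source contig could not be classified).  Excluded genera
    never appear; an empty remainder gives label "unknown".
    """
    genera = {
        spacer_taxonomy.get(h.spacer_id)
        for h in spacer_hits
        if spacer_taxonomy.get(h.spacer_id) is not None
    }
    genera -= set(exclusion)
    if not genera:
        return HostAssignment(votu_id, (), "unknown")
    label = "specialist" if len(genera) == 1 else "generalist"
    return HostAssignment(votu_id, tuple(sorted(genera)), label)


def predict_hosts(
    votu_genomes: Dict[str, str],
    arrays: Sequence[CrisprArray],
    cfg: PipelineConfig = None,
) -> Tuple[Dict[str, HostAssignment], List[SpacerHit]]:
    """Full host-prediction pass: filter spacers from the given arrays,
    match each against every vOTU representative genome, and assign hosts.
    Arrays must carry ``source_taxonomy`` (set it from reference labels or
    :func:`assign_contig_taxonomy` beforehand)."""
    cfg = cfg or PipelineConfig()
    spacer_records: List[Tuple[str, str, Optional[str]]] = []
    for ai, arr in enumerate(arrays):
        for si, (spacer, _pos) in enumerate(arr.spacers):
            if cfg.spacer_min <= len(spacer) <= cfg.spacer_max:
                spacer_records.append((f"{arr.contig_id}|a{ai}|s{si}", spacer, arr.source_taxonomy))
    taxonomy = {sid: tax for sid, _, tax in spacer_records}
    all_hits: List[SpacerHit] = []
    by_votu: Dict[str, List[SpacerHit]] = {v: [] for v in votu_genomes}
    for votu, genome in votu_genomes.items():
        for sid, spacer, _ in spacer_records:
            hits = match_spacer(sid, spacer, votu, genome, cfg)
            all_hits.extend(hits)
            by_votu[votu].extend(hits)
    assignments = {v: assign_hosts(v, by_votu[v], taxonomy) for v in votu_genomes}
    return assignments, all_hits
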