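"""vOTU abundance from reads mapped to viral hallmark genes only.

Mapping the whole genome would over-count reads from horizontally
transferred genes shared with other phages or bacteria, so abundance is
quantified on the hallmark (signature) genes alone: reads are mapped at
>=95% identity to the pooled VHG set of the vOTU representatives,
multi-mapping ties across vOTUs are discarded, and RPKM is computed per
vOTU from the per-vOTU VHG length.  VC-level profiles are the per-VC sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .seqcore import GeneIndex, build_gene_index, map_read_status


def build_vhg_index(votu_genes: Dict[str, Sequence[Tuple[str, str]]], k: int = 21) -> GeneIndex:
    """Index hallmark genes only, keyed to their owning vOTU.

    ``votu_genes`` maps votu_id -> [(gene_id, gene_nucleotide_seq), ...]
    (hallmark genes of the representative).  vOTUs without hallmark genes
    are skipped with a warning.
    """
    import warnings

    triples = []
    for votu_id in sorted(votu_genes):
        genes = votu_genes[votu_id]
        if not genes:
            warnings.warn(f"{votu_id}: representative has no hallmark genes; excluded from index")
            continue
        for gene_id, seq in genes:
            triples.append((gene_id, votu_id, seq))
    if not triples:
        raise ValueError("no hallmark genes to index")
    return build_gene_index(triples, k=k)


@dataclass
class SampleQuant:
    rpkm: pd.Series  # per-vOTU RPKM
    counts: pd.Series
    total_reads: int
    mapped: int
    discarded_ties: int

    @property
    def mapped_fraction(self) -> float:
        return self.mapped / self.total_reads


def quantify_sample(
    reads: Sequence[Tuple[str, str]], index: GeneIndex, cfg: PipelineConfig = None
) -> SampleQuant:
    """Map one sample's reads to the VHG index and return per-vOTU RPKM.

    RPKM(v) = count(v) / VHG_kb(v) / (total_reads / 1e6).
    """
    cfg = cfg or PipelineConfig()
    total = len(reads)
    if total == 0:
        raise ValueError("no reads in sample")
    votus = sorted(index.votu_gene_bp)
    counts = {v: 0 for v in votus}
    mapped = 0
    ties = 0
    for _rid, seq in reads:
        hit, status = map_read_status(seq, index, min_identity=cfg.map_ident, min_cov=cfg.map_cov)
        if status == "tie":
            ties += 1
        elif status == "mapped":
            counts[hit.votu_id] += 1
            mapped += 1
    counts = pd.Series(counts, dtype=float)
    kb = pd.Series({v: index.votu_gene_bp[v] / 1000.0 for v in votus})
    rpkm = counts / kb / (total / 1e6)
    return SampleQuant(rpkm=rpkm, counts=counts, total_reads=total, mapped=mapped, discarded_ties=ties)


def aggregate_to_vc(votu_matrix: pd.DataFrame, vc_membership: Dict[str, str]) -> pd.DataFrame:
    """Sum vOTU columns into their VC; every vOTU must belong to one VC."""
    orphans = [v for v in votu_matrix.columns if v not in vc_membership]
    if orphans:
        raise ValueError(f"vOTUs without a VC: {orphans[:5]}")
    groups = votu_matrix.T.groupby([vc_membership[v] for v in votu_matrix.columns]).sum().T
    return groups.sort_index(axis=1)


def to_relative(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample normalisation to relative abundance (all-zero rows kept)."""
    import warnings

    sums = matrix.sum(axis=1)
    if (sums == 0).any():
        warnings.warn(f"{int((sums == 0).sum())} all-zero sample(s) left unnormalised")
    out = matrix.div(sums.replace(0, np.nan), axis=0).fillna(0.0)
    return out


def detect_features(matrix: pd.DataFrame) -> Tuple[pd.DataFrame, pd.Series]:
    """Detection calls (>=1 mapped read, i.e. value > 0) and per-sample richness."""
    binary = (matrix > 0).astype(int)
    return binary, binary.sum(axis=1)
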