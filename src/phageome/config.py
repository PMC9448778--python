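"""Pipeline configuration.

Every numeric threshold used by the discovery, cataloguing, host-prediction,
quantification and statistics stages lives here, so that a whole run is
reproducible from one serialisable object.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass
class PipelineConfig:
    """Thresholds for the full phage-catalogue workflow.

    Defaults follow the published screening rules: 10 kb minimum contig size,
    viral k-mer p <= 0.05, >=80% provirus fraction, 40% gene-sharing and a
    (70%, 120%) size window for draft recovery, 95%/85% ANI/coverage for vOTU
    clustering, >20% shared protein clusters for VCs, and the abundance
    filters used by the correlation and association analyses.
    """

    # discovery (six criteria + linear recovery)
    min_size: int = 10_000
    kmer_p_max: float = 0.05
    provirus_min: float = 0.8
    recovery_gene_frac: float = 0.4
    recovery_size_lo: float = 0.7
    recovery_size_hi: float = 1.2
    recovery_score_min: float = 100.0  # local-alignment score standing in for e-value < 1e-5
    contamination_max: float = 0.10

    # catalogue
    ani_cluster: float = 0.95
    cov_cluster: float = 0.85
    shared_pc_min: float = 0.20
    pc_score_min: float = 100.0
    mcl_inflation: float = 2.0
    tax_vote_min: float = 0.20
    lifestyle_score: float = 0.8
    lifestyle_aln: int = 1000
    lifestyle_ident: float = 0.95

    # host prediction
    spacer_min: int = 25
    spacer_max: int = 100
    spacer_cov: float = 0.95
    ctg_tax_ident: float = 0.90
    ctg_tax_cov: float = 0.70

    # quantification
    map_ident: float = 0.95
    map_cov: float = 0.90
    seed_k: int = 21

    # ecology / association
    corr_votu_min: float = 1e-4
    corr_genus_min: float = 5e-3
    pair_exclusion: str = "both"  # drop a sample when "both" (or "either") of the pair is zero
    assoc_votu_min: float = 5e-4
    assoc_vc_min: float = 1e-3
    fdr: float = 0.05
    n_perm: int = 10_000

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        """Load from a JSON string or a path to a JSON file."""
        if isinstance(source, str) and source.lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
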