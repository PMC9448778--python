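"""Diversity and co-occurrence statistics for virome/bacteriome profiles.

Alpha diversity is Shannon entropy (natural log) of the vOTU-level relative
abundance profile; beta diversity is the Bray–Curtis distance, summarised
per individual as the mean distance against all other individuals.
Phage–host association is the Spearman correlation between each vOTU and
every genus it is predicted to infect, with the abundance-prevalence
filters and sample-exclusion rule applied before the correlation.
Defence-system association splits samples into tertiles of total defence
abundance and compares virome diversity across tertiles (Wilcoxon rank-sum,
two-sided), alongside per-system Spearman correlations with BH-adjusted
p-values.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .host_prediction import HostAssignment


def shannon(profile) -> float:
    """Shannon diversity H = -sum p ln p of a non-negative profile."""
    p = np.asarray(profile, dtype=float)
    if (p < 0).any():
        raise ValueError("negative entries in abundance profile")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero profile has undefined diversity")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(a, b) -> float:
    """Bray–Curtis distance 1 - 2*sum(min)/(sum(a)+sum(b))."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles differ in length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative entries")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValueError("both profiles are all-zero")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def bray_curtis_matrix(matrix) -> np.ndarray:
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = bray_curtis(X[i], X[j])
    return D


def mean_pairwise_distance(matrix) -> np.ndarray:
    """Per-sample mean Bray–Curtis distance against all other samples."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    D = bray_curtis_matrix(X)
    n = D.shape[0]
    return D.sum(axis=1) / (n - 1)


def spearman(x, y) -> Tuple[float, float]:
    """Spearman rho (midranks for ties) with two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: rho undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CorrelationRecord:
    votu_id: str
    genus: str
    r_s: float
    p: float
    n_used: int
    label: str  # specialist | generalist
    lifestyle: Optional[str] = None


def phage_host_correlations(
    votu_rel: pd.DataFrame,
    genus_rel: pd.DataFrame,
    host_assignments: Dict[str, HostAssignment],
    cfg: PipelineConfig = None,
    lifestyle: Optional[Dict[str, str]] = None,
) -> List[CorrelationRecord]:
    """Spearman correlation of each vOTU with each of its predicted genera.

    vOTUs below 0.01% and genera below 0.5% mean relative abundance are
    excluded; samples where the pair is absent are dropped (the default
    rule removes samples where *both* members are zero; set
    ``cfg.pair_exclusion = "either"`` for the stricter reading).
    Generalists contribute one record per predicted genus.
    """
    cfg = cfg or PipelineConfig()
    lifestyle = lifestyle or {}
    if not votu_rel.index.equals(genus_rel.index):
        raise ValueError("sample sets differ between the two profiles")
    votu_ok = votu_rel.columns[votu_rel.mean(axis=0) > cfg.corr_votu_min]
    genus_ok = set(genus_rel.columns[genus_rel.mean(axis=0) > cfg.corr_genus_min])
    records: List[CorrelationRecord] = []
    for votu in votu_ok:
        assignment = host_assignments.get(votu)
        if assignment is None or assignment.label == "unknown":
            continue
        v = votu_rel[votu].to_numpy()
        for genus in assignment.genera:
            if genus not in genus_ok:
                continue
            g = genus_rel[genus].to_numpy()
            if cfg.pair_exclusion == "either":
                keep = (v > 0) & (g > 0)
            else:
                keep = (v > 0) | (g > 0)
            if keep.sum() < 3 or np.ptp(v[keep]) == 0 or np.ptp(g[keep]) == 0:
                warnings.warn(f"{votu} vs {genus}: fewer than 3 usable samples or constant profile; dropped")
                continue
            rho, p = spearman(v[keep], g[keep])
            records.append(
                CorrelationRecord(
                    votu_id=votu,
                    genus=genus,
                    r_s=rho,
                    p=p,
                    n_used=int(keep.sum()),
                    label=assignment.label,
                    lifestyle=lifestyle.get(votu),
                )
            )
    return records


def compare_groups(values_a, values_b) -> Tuple[float, float]:
    """Wilcoxon rank-sum test, two-sided, with midranks for ties.

    The statistic W is the rank sum of the first group.  For combined sizes
    up to 12 the p-value is exact, by enumerating every assignment of ranks
    to group A; above that a normal approximation with tie correction is
    used.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    w_obs = ranks[:n_a].sum()
    mean_w = n_a * (n + 1) / 2.0
    if n <= 12:
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), n_a):
            w = ranks[list(combo)].sum()
            total += 1
            if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9:
                count += 1
        return float(w_obs), count / total
    # normal approximation with tie correction
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var_w = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_w == 0:
        return float(w_obs), 1.0
    z = (w_obs - mean_w) / math.sqrt(var_w)
    return float(w_obs), float(2 * stats.norm.sf(abs(z)))


def tertile_groups(total_abundance: pd.Series) -> pd.Series:
    """Split samples at the 1/3 and 2/3 empirical quantiles into
    low/middle/high groups; ties at a boundary go to the lower group."""
    x = total_abundance.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant abundance: tertiles undefined")
    q1, q2 = np.quantile(x, [1 / 3, 2 / 3])
    labels = np.where(x <= q1, "low", np.where(x <= q2, "middle", "high"))
    return pd.Series(labels, index=total_abundance.index)


@dataclass
class DefenceAssociation:
    groups: pd.Series  # sample -> low | middle | high
    group_comparisons: pd.DataFrame  # pair, W, p
    per_system: pd.DataFrame  # system, rho, p, q


def defence_association(
    defence_abund: pd.DataFrame, votu_rel: pd.DataFrame, cfg: PipelineConfig = None
) -> DefenceAssociation:
    """Virome diversity vs anti-phage defence-system abundance.

    Samples are grouped by tertiles of the total defence abundance, Shannon
    diversity of the virome is compared pairwise across groups (rank-sum),
    and each defence subsystem is correlated (Spearman) with diversity,
    BH-adjusted across subsystems.
    """
    from .association import bh_fdr

    cfg = cfg or PipelineConfig()
    if len(defence_abund) < 3:
        raise ValueError("need >= 3 samples")
    if not defence_abund.index.equals(votu_rel.index):
        raise ValueError("sample sets differ")
    H = votu_rel.apply(shannon, axis=1)
    groups = tertile_groups(defence_abund.sum(axis=1))
    comparisons = []
    for g1, g2 in itertools.combinations(["low", "middle", "high"], 2):
        w, p = compare_groups(H[groups == g1], H[groups == g2])
        comparisons.append({"pair": f"{g1}_vs_{g2}", "W": w, "p": p})
    per_system = []
    for system in defence_abund.columns:
        rho, p = spearman(defence_abund[system], H)
        per_system.append({"system": system, "rho": rho, "p": p})
    per_system = pd.DataFrame(per_system)
    per_system["q"] = bh_fdr(per_system["p"].to_numpy())
    return DefenceAssociation(
        groups=groups,
        group_comparisons=pd.DataFrame(comparisons),
        per_system=per_system,
    )


def aggregate_by_host(
    votu_rel: pd.DataFrame,
    host_assignments: Dict[str, HostAssignment],
    genus_to_phylum: Optional[Dict[str, str]] = None,
    level: str = "phylum",
) -> pd.DataFrame:
    """Per-sample phage abundance grouped by predicted host taxon.

    Generalist phages are counted in every predicted group (so group sums
    can exceed the total phage abundance); phages with no prediction go to
    "host unknown".
    """
    if level not in ("phylum", "genus"):
        raise ValueError("level must be phylum or genus")
    if level == "phylum" and genus_to_phylum is None:
        raise ValueError("phylum-level aggregation needs a genus->phylum lookup")
    groups: Dict[str, List[str]] = {}
    for votu in votu_rel.columns:
        assignment = host_assignments.get(votu)
        if assignment is None or not assignment.genera:
            groups.setdefault("host unknown", []).append(votu)
            continue
        targets = assignment.genera
        if level == "phylum":
            targets = tuple(genus_to_phylum.get(g, "unknown phylum") for g in targets)
        for t in dict.fromkeys(targets):
            groups.setdefault(t, []).append(votu)
    out = pd.DataFrame(
        {group: votu_rel[cols].sum(axis=1) for group, cols in sorted(groups.items())},
        index=votu_rel.index,
    )
    return out
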