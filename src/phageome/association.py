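"""Metadata association: univariate scan, BH FDR, stepwise multivariable
regression, and PERMANOVA.

Relative abundances are log10-transformed (zeros get a pseudocount of half
the smallest non-zero value).  Each (feature, variable) pair is tested by
ordinary least squares; Benjamini–Hochberg correction is applied jointly
over all pairs, and for each feature the variables passing the FDR gate
enter a multivariable model with bidirectional stepwise selection under
AIC = n ln(RSS/n) + 2k.  Variables surviving selection are reported
significant at coefficient p < 0.05 (no further correction, since the gate
already controlled the FDR).  PERMANOVA tests each metadata variable
against the Bray–Curtis distance matrix with the hat-matrix (regression)
formulation, which handles categorical and continuous variables alike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import PipelineConfig


def log10_transform(rel_abund: pd.DataFrame, pseudocount: Optional[float] = None) -> pd.DataFrame:
    """log10(x + c) with c = half the smallest non-zero value by default."""
    X = rel_abund.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("negative abundances")
    nonzero = X[X > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero matrix cannot be log-transformed")
    c = pseudocount if pseudocount is not None else nonzero.min() / 2.0
    return pd.DataFrame(np.log10(X + c), index=rel_abund.index, columns=rel_abund.columns)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class UnivariateScan:
    p: pd.DataFrame  # features x variables
    q: pd.DataFrame
    beta: pd.DataFrame
    flagged: List[Tuple[str, str]]  # (feature, variable) with q < fdr


def univariate_scan(Y: pd.DataFrame, X: pd.DataFrame, cfg: PipelineConfig = None) -> UnivariateScan:
    """OLS slope t-test of every (feature, variable) pair, BH over all pairs.

    ``Y`` holds transformed abundances (samples x features) already filtered
    by the abundance thresholds; ``X`` holds numeric metadata (samples x
    variables).  Constant variables get p = 1 with a warning.
    """
    cfg = cfg or PipelineConfig()
    if not Y.index.equals(X.index):
        raise ValueError("sample sets differ between Y and X")
    n = len(Y)
    yc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
    p_mat = np.ones((Y.shape[1], X.shape[1]))
    b_mat = np.zeros_like(p_mat)
    sy = yc.std(axis=0, ddof=0)
    for j, var in enumerate(X.columns):
        x = X[var].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"variable {var} is constant; p set to 1")
            continue
        xc = x - x.mean()
        sx = xc.std(ddof=0)
        cov = yc.T @ xc / n
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(sy > 0, cov / (sx * sy), 0.0)
        r = np.clip(r, -1.0, 1.0)
        b_mat[:, j] = np.where(sy > 0, r * sy / sx, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r**2))
        p_col = 2 * stats.t.sf(np.abs(t), df=n - 2)
        p_mat[:, j] = np.where(sy > 0, p_col, 1.0)
    p = pd.DataFrame(p_mat, index=Y.columns, columns=X.columns)
    beta = pd.DataFrame(b_mat, index=Y.columns, columns=X.columns)
    q = pd.DataFrame(
        bh_fdr(p_mat.ravel()).reshape(p_mat.shape), index=Y.columns, columns=X.columns
    )
    flagged = [
        (feat, var)
        for feat in Y.columns
        for var in X.columns
        if q.loc[feat, var] < cfg.fdr
    ]
    return UnivariateScan(p=p, q=q, beta=beta, flagged=flagged)


@dataclass
class AssociationResult:
    feature_id: str
    variable: str
    beta: float
    p_uni: float
    q_uni: float
    selected: bool
    beta_multi: Optional[float]
    p_multi: Optional[float]

    @property
    def significant(self) -> bool:
        return bool(self.selected and self.p_multi is not None and self.p_multi < 0.05)


def _aic(n: int, rss: float, k: int) -> float:
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


def _fit_ols(y: np.ndarray, X: pd.DataFrame, variables: Sequence[str]):
    design = sm.add_constant(X[list(variables)].to_numpy(dtype=float)) if variables else np.ones((len(y), 1))
    model = sm.OLS(y, design).fit()
    return model


def stepwise_aic(y: np.ndarray, X: pd.DataFrame, variables: Sequence[str]) -> List[str]:
    """Bidirectional stepwise selection starting from the full model.

    At each step the single add/drop move that most reduces
    AIC = n ln(RSS/n) + 2k is taken; variable order is fixed for
    determinism.
    """
    n = len(y)
    current = list(variables)
    dropped: List[str] = []

    def aic_of(vs: Sequence[str]) -> float:
        model = _fit_ols(y, X, vs)
        return _aic(n, float(model.ssr), len(vs) + 1)

    best_aic = aic_of(current)
    improved = True
    while improved:
        improved = False
        moves = []
        for v in current:
            trial = [w for w in current if w != v]
            moves.append((aic_of(trial), "drop", v, trial))
        for v in dropped:
            trial = current + [v]
            moves.append((aic_of(trial), "add", v, trial))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        if moves[0][0] < best_aic - 1e-10:
            best_aic, _, v, trial = moves[0]
            if moves[0][1] == "drop":
                dropped.append(v)
            else:
                dropped.remove(v)
            current = trial
            improved = True
    return current


def multivariable_fit(
    feature_id: str,
    y: pd.Series,
    X: pd.DataFrame,
    gated_variables: Sequence[str],
    scan: Optional[UnivariateScan] = None,
) -> List[AssociationResult]:
    """Stepwise-AIC multivariable regression for one feature.

    All variables passing the univariate FDR gate enter; collinear columns
    (rank-deficient design) are dropped with a warning, later-listed first.
    Returns one row per gated variable recording whether it survived
    selection and its multivariable coefficient and p-value.
    """
    if not gated_variables:
        return []
    usable: List[str] = []
    for v in gated_variables:
        trial = usable + [v]
        mat = X[trial].to_numpy(dtype=float)
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(mat)), mat])) < len(trial) + 1:
            warnings.warn(f"{feature_id}: variable {v} collinear with earlier variables; dropped")
            continue
        usable.append(v)
    yv = y.to_numpy(dtype=float)
    selected = stepwise_aic(yv, X, usable)
    model = _fit_ols(yv, X, selected) if selected else None
    results = []
    for v in gated_variables:
        in_model = v in selected
        beta_multi = p_multi = None
        if in_model:
            i = selected.index(v) + 1  # constant first
            beta_multi = float(model.params[i])
            p_multi = float(model.pvalues[i])
        p_uni = float(scan.p.loc[feature_id, v]) if scan is not None else np.nan
        q_uni = float(scan.q.loc[feature_id, v]) if scan is not None else np.nan
        beta_uni = float(scan.beta.loc[feature_id, v]) if scan is not None else np.nan
        results.append(
            AssociationResult(
                feature_id=feature_id,
                variable=v,
                beta=beta_uni,
                p_uni=p_uni,
                q_uni=q_uni,
                selected=in_model,
                beta_multi=beta_multi,
                p_multi=p_multi,
            )
        )
    return results


def association_workflow(
    rel_abund: pd.DataFrame,
    metadata: pd.DataFrame,
    cfg: PipelineConfig = None,
    min_mean_abund: Optional[float] = None,
) -> Tuple[UnivariateScan, List[AssociationResult]]:
    """Filter features, log10-transform, scan, and fit multivariable models."""
    cfg = cfg or PipelineConfig()
    threshold = cfg.assoc_votu_min if min_mean_abund is None else min_mean_abund
    keep = rel_abund.columns[rel_abund.mean(axis=0) > threshold]
    Y = log10_transform(rel_abund[keep])
    scan = univariate_scan(Y, metadata, cfg)
    results: List[AssociationResult] = []
    by_feature: Dict[str, List[str]] = {}
    for feat, var in scan.flagged:
        by_feature.setdefault(feat, []).append(var)
    for feat, variables in by_feature.items():
        results.extend(multivariable_fit(feat, Y[feat], metadata, variables, scan))
    return scan, results


@dataclass(frozen=True)
class PermanovaResult:
    variable: str
    pseudo_F: float
    R2: float
    p_perm: float
    n_perm: int


def permanova(
    D: np.ndarray,
    x,
    n_perm: int = 10_000,
    rng=None,
    variable: str = "x",
) -> PermanovaResult:
    """Permutational multivariate ANOVA of a distance matrix on one variable.

    Uses the Gower-centred inner-product matrix G = -1/2 J D^2 J and the
    hat matrix H of the design (intercept + x, with categorical x dummy-
    coded), so continuous and categorical variables are handled uniformly:
    pseudo-F = [tr(HGH)/(k-1)] / [tr((I-H)G(I-H))/(n-k)], R^2 =
    tr(HGH)/tr(G), and the p-value comes from permuting sample labels.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("D must be a symmetric distance matrix with zero diagonal")
    x = np.asarray(x)
    if x.dtype.kind in "OUS" or x.dtype == bool:
        levels = np.unique(x)
        if len(levels) < 2:
            raise ValueError("categorical variable needs >= 2 levels")
        design = np.column_stack([np.ones(n)] + [(x == lv).astype(float) for lv in levels[1:]])
    else:
        if np.ptp(x.astype(float)) == 0:
            raise ValueError("constant variable")
        design = np.column_stack([np.ones(n), x.astype(float)])
    k = np.linalg.matrix_rank(design)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    H = design @ np.linalg.pinv(design)
    tr_G = np.trace(G)

    def f_stat(Gm) -> float:
        tr_HG = float((H * Gm).sum())  # tr(HGH) = tr(HG) for idempotent H
        return (tr_HG / (k - 1)) / ((np.trace(Gm) - tr_HG) / (n - k))

    F_obs = f_stat(G)
    R2 = float((H * G).sum() / tr_G)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if f_stat(G[np.ix_(perm, perm)]) >= F_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermanovaResult(variable=variable, pseudo_F=float(F_obs), R2=R2, p_perm=p, n_perm=n_perm)


def permanova_scan(
    D: np.ndarray, metadata: pd.DataFrame, n_perm: int = 10_000, rng=None
) -> pd.DataFrame:
    """PERMANOVA per metadata variable with BH correction across variables."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows = []
    for var in metadata.columns:
        res = permanova(D, metadata[var].to_numpy(), n_perm=n_perm, rng=rng, variable=var)
        rows.append({"variable": var, "pseudo_F": res.pseudo_F, "R2": res.R2, "p": res.p_perm})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
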