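"""PCA of the beta matrix and association screening of components against
technical covariates (extraction method, chip position, DNA yield, purity).

Samples are observations and sites are variables; the matrix is site-centred
(and optionally site-scaled) before the singular value decomposition.
Categorical covariates are screened per component with Kruskal-Wallis tests,
numeric covariates with two-sided Spearman correlations; p-values are
Bonferroni-adjusted per covariate across the components tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .io_model import BetaDataset

__all__ = [
    "PCAResult",
    "AssociationResult",
    "run_pca",
    "kruskal_wallis",
    "spearman",
    "pc_association_screen",
    "CATEGORICAL_COVARIATES",
    "NUMERIC_COVARIATES",
]

CATEGORICAL_COVARIATES = {"method", "chip_position", "subject_id"}
NUMERIC_COVARIATES = {"yield_ug", "a260_280", "a260_230"}


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    variance_explained: np.ndarray  # fractions, non-increasing
    n_components: int


@dataclass
class AssociationResult:
    component_index: int  # 1-based (PC1, PC2, ...)
    covariate: str
    test: str             # "kruskal_wallis" or "spearman"
    statistic: float
    p_raw: float
    p_adjusted: float


def run_pca(
    ds: BetaDataset,
    n_components: int | None = None,
    center: bool = True,
    scale: bool = False,
) -> PCAResult:
    """Principal components of samples in site space.

    ``variance_explained`` fractions are singular values squared over the
    total variance of the processed matrix, so they sum to 1 when all
    min(n_samples - 1, n_sites) components are kept.
    """
    if ds.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if ds.has_missing():
        raise ValueError("missing beta values; run filter_sites first")
    X = ds.betas.to_numpy(dtype=float).T  # samples x sites
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1, keepdims=True)
        sd[sd == 0.0] = 1.0
        X = X / sd
    max_rank = min(ds.n_samples - 1 if center else ds.n_samples, ds.n_sites)
    k = max_rank if n_components is None else min(n_components, max_rank)
    U, s, _ = linalg.svd(X, full_matrices=False)
    total = float(np.sum(X**2))
    ratios = s**2 / total if total > 0 else np.zeros_like(s)
    scores = (U * s)[:, :k]
    return PCAResult(
        scores=pd.DataFrame(
            scores, index=ds.betas.columns, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        variance_explained=ratios[:k],
        n_components=k,
    )


def kruskal_wallis(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p with df = k - 1."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    parts = [values[groups == g] for g in labels]
    if any(p.size == 0 for p in parts):
        raise ValueError("empty group")
    if np.ptp(values) == 0.0:
        warnings.warn("all values identical: H = 0, p = 1", RuntimeWarning)
        return 0.0, 1.0
    h, p = stats.kruskal(*parts)
    return float(h), float(p)


def spearman(values: np.ndarray, covariate: np.ndarray) -> tuple[float, float]:
    """Two-sided Spearman rank correlation."""
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if values.size != covariate.size or values.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(covariate) == 0.0 or np.ptp(values) == 0.0:
        warnings.warn("constant input: Spearman rho undefined", RuntimeWarning)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(values, covariate)
    return float(rho), float(p)


def pc_association_screen(
    pca: PCAResult,
    samples: pd.DataFrame,
    covariates: list[str],
) -> list[AssociationResult]:
    """One test per (component, covariate); Bonferroni family per covariate
    across components (p_adj = min(1, n_components * p))."""
    results: list[AssociationResult] = []
    samples = samples.loc[pca.scores.index]
    m = pca.n_components
    for cov in covariates:
        if cov not in samples.columns:
            raise KeyError(f"unknown covariate {cov!r} (have {list(samples.columns)})")
        is_cat = cov in CATEGORICAL_COVARIATES or not np.issubdtype(
            samples[cov].dtype, np.number
        )
        for j in range(m):
            scores = pca.scores.iloc[:, j].to_numpy()
            if is_cat:
                test = "kruskal_wallis"
                try:
                    stat, p = kruskal_wallis(scores, samples[cov].to_numpy())
                except ValueError as err:
                    warnings.warn(f"degenerate groups for {cov!r}: {err}", RuntimeWarning)
                    stat, p = float("nan"), float("nan")
            else:
                test = "spearman"
                stat, p = spearman(scores, samples[cov].to_numpy(dtype=float))
            p_adj = min(1.0, m * p) if np.isfinite(p) else float("nan")
            results.append(
                AssociationResult(
                    component_index=j + 1,
                    covariate=cov,
                    test=test,
                    statistic=stat,
                    p_raw=p,
                    p_adjusted=p_adj,
                )
            )
    return results
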