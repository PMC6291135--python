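"""Heteroscedastic Bland-Altman agreement analysis for a pair of methods.

Classical Bland-Altman limits of agreement assume the paired differences are
normally distributed with constant variance. Genome-wide beta-value
differences violate both assumptions: their spread depends strongly on the
mean methylation level x, largest at intermediate methylation. The model
used here is

    d_i = sigma(x_i) * e_i,   e_i ~ N(0, 1),
    sigma(x) = exp(a + b * (x - 0.5)^2),

with (a, b) estimated by minimizing the Gaussian negative log-likelihood,
and x-dependent limits of agreement +/- z * sigma(x) (z = 1.96 by default).

The model has no bias (mean-difference) term; the empirical mean difference
is reported alongside the fit because classical Bland-Altman centres on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_model import BetaDataset

__all__ = [
    "BlandAltmanPoints",
    "VarianceModelFit",
    "DifferenceDistribution",
    "NormalityScreenResult",
    "pairwise_points",
    "fit_variance_model",
    "variance_nll",
    "limits_of_agreement",
    "normality_screen",
    "difference_distribution",
    "DIFFERENCE_BIN_EDGES",
    "ba_density_grid",
]


@dataclass
class BlandAltmanPoints:
    """Per subject-site (average, difference) pairs for one method pair.

    x[k] = (beta1 + beta2) / 2 and d[k] = beta1 - beta2 for point k;
    ``site_code``/``subject_code`` index into ``site_ids``/``subject_ids``.
    """

    x: np.ndarray
    d: np.ndarray
    site_ids: np.ndarray
    subject_ids: np.ndarray
    site_code: np.ndarray
    subject_code: np.ndarray
    method1: str
    method2: str

    @property
    def n_points(self) -> int:
        return self.x.size


@dataclass
class VarianceModelFit:
    """Fitted constants of sigma(x) = exp(a + b*(x-0.5)^2) plus diagnostics."""

    a: float
    b: float
    converged: bool
    n_used: int
    final_objective: float
    z: float = 1.96
    mean_d: float = 0.0
    b_fixed: bool = False

    def sigma(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.exp(self.a + self.b * (np.asarray(x, dtype=float) - 0.5) ** 2)


@dataclass
class DifferenceDistribution:
    """Binned percentages of per-site absolute mean differences."""

    bin_edges: np.ndarray
    percentages: np.ndarray
    n_sites: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "percent": self.percentages,
            }
        )


@dataclass
class NormalityScreenResult:
    """Shapiro-Wilk p-values on repeated random subsamples of differences."""

    p_values: np.ndarray
    subsample_n: int
    n_repeats: int
    seed: int


def pairwise_points(ds: BetaDataset, method1: str, method2: str) -> BlandAltmanPoints:
    """One point per subject-site: x = (b1+b2)/2, d = b1 - b2 (method1 - method2)."""
    subjects = ds.require_complete_design(method1, method2)
    m1 = ds.method_matrix(method1, subjects).to_numpy(dtype=float)
    m2 = ds.method_matrix(method2, subjects).to_numpy(dtype=float)
    if np.isnan(m1).any() or np.isnan(m2).any():
        raise ValueError("missing beta values; run filter_sites first")
    x = (m1 + m2) / 2.0
    d = m1 - m2
    n_sites, n_subjects = x.shape
    site_code = np.repeat(np.arange(n_sites), n_subjects)
    subject_code = np.tile(np.arange(n_subjects), n_sites)
    return BlandAltmanPoints(
        x=x.ravel(),
        d=d.ravel(),
        site_ids=ds.betas.index.to_numpy(),
        subject_ids=np.asarray(subjects),
        site_code=site_code,
        subject_code=subject_code,
        method1=method1,
        method2=method2,
    )


def variance_nll(a: float, b: float, x: np.ndarray, d: np.ndarray) -> float:
    """Gaussian negative log-likelihood (constants dropped) of
    d ~ N(0, sigma(x)^2) with sigma(x) = exp(a + b*(x-0.5)^2)."""
    s = a + b * (x - 0.5) ** 2
    return float(np.sum(s) + 0.5 * np.sum(d**2 * np.exp(-2.0 * s)))


def _nll_and_grad(theta: np.ndarray, u: np.ndarray, d2: np.ndarray) -> tuple[float, np.ndarray]:
    a, b = theta
    s = a + b * u
    w = d2 * np.exp(-2.0 * s)
    nll = np.sum(s) + 0.5 * np.sum(w)
    ga = u.size - np.sum(w)
    gb = np.sum(u) - np.sum(u * w)
    return float(nll), np.array([ga, gb])


def fit_variance_model(
    pts: BlandAltmanPoints,
    z: float = 1.96,
    subsample: int | None = None,
    seed: int = 0,
) -> VarianceModelFit:
    """Estimate (a, b) by non-linear minimization of the Gaussian NLL.

    Starting point a0 = 0.5*log(mean d^2) (the constant-variance MLE),
    b0 = 0; L-BFGS-B with analytic gradient. If all x are identical, b is
    unidentifiable: it is fixed at 0 (closed-form a) with a warning. An
    optional seeded uniform subsample of points speeds up huge inputs.
    """
    x, d = pts.x, pts.d
    if x.size < 10:
        raise ValueError("need at least 10 points to fit the variance model")
    if np.all(d == 0.0):
        raise ValueError("all differences are zero; sigma is degenerate")
    if subsample is not None and subsample < x.size:
        rng = np.random.default_rng(seed)
        idx = rng.choice(x.size, size=subsample, replace=False)
        x, d = x[idx], d[idx]

    mean_d = float(np.mean(d))
    u = (x - 0.5) ** 2
    d2 = d**2
    a0 = 0.5 * np.log(np.mean(d2))

    if np.ptp(u) < 1e-12:
        warnings.warn(
            "all x identical: b is unidentifiable, fixing b = 0", RuntimeWarning
        )
        return VarianceModelFit(
            a=float(a0),
            b=0.0,
            converged=True,
            n_used=x.size,
            final_objective=variance_nll(float(a0), 0.0, x, d),
            z=z,
            mean_d=mean_d,
            b_fixed=True,
        )

    res = optimize.minimize(
        _nll_and_grad,
        x0=np.array([a0, 0.0]),
        args=(u, d2),
        jac=True,
        method="L-BFGS-B",
        options={"ftol": 1e-8 / max(1.0, x.size), "gtol": 1e-10, "maxiter": 500},
    )
    if not res.success:
        warnings.warn(f"variance-model fit did not converge: {res.message}", RuntimeWarning)
    return VarianceModelFit(
        a=float(res.x[0]),
        b=float(res.x[1]),
        converged=bool(res.success),
        n_used=x.size,
        final_objective=float(res.fun),
        z=z,
        mean_d=mean_d,
    )


def limits_of_agreement(
    fit: VarianceModelFit, x_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise limits +/- z*sigma(x) on a grid of mean-methylation values."""
    x_grid = np.asarray(x_grid, dtype=float)
    if ((x_grid < 0.0) | (x_grid > 1.0)).any():
        raise ValueError("x_grid must lie in [0, 1]")
    upper = fit.z * np.asarray(fit.sigma(x_grid))
    return -upper, upper


def normality_screen(
    pts: BlandAltmanPoints,
    subsample_n: int = 5000,
    n_repeats: int = 10,
    seed: int = 0,
) -> NormalityScreenResult:
    """Repeated Shapiro-Wilk tests on random subsamples of the differences.

    Genome-wide difference vectors are far too large for a single normality
    test, so the screen draws ``n_repeats`` seeded subsamples of size
    ``subsample_n`` without replacement and records one p-value each.
    """
    if pts.n_points < subsample_n:
        raise ValueError(
            f"need at least subsample_n={subsample_n} points, have {pts.n_points}"
        )
    rng = np.random.default_rng(seed)
    p_values = np.empty(n_repeats)
    for r in range(n_repeats):
        sub = rng.choice(pts.d, size=subsample_n, replace=False)
        if np.ptp(sub) == 0.0:
            warnings.warn("constant subsample: Shapiro-Wilk p undefined", RuntimeWarning)
            p_values[r] = np.nan
            continue
        with warnings.catch_warnings():
            # scipy warns that p-values above n=5000 may be inaccurate; the
            # screen only needs gross non-normality, so that is acceptable.
            warnings.simplefilter("ignore")
            p_values[r] = stats.shapiro(sub).pvalue
    return NormalityScreenResult(
        p_values=p_values, subsample_n=subsample_n, n_repeats=n_repeats, seed=seed
    )


DIFFERENCE_BIN_EDGES = np.array(
    [0.0, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.10, np.inf]
)


def difference_distribution(
    ds: BetaDataset, method1: str, method2: str
) -> DifferenceDistribution:
    """Percentages of sites per bin of absolute mean difference.

    Per site the difference method1 - method2 is averaged over subjects, its
    absolute value binned into half-open intervals
    [0, 0.01), [0.01, 0.02), ..., [0.09, 0.10), [0.10, inf).
    """
    subjects = ds.require_complete_design(method1, method2)
    m1 = ds.method_matrix(method1, subjects).to_numpy(dtype=float)
    m2 = ds.method_matrix(method2, subjects).to_numpy(dtype=float)
    abs_mean_diff = np.abs((m1 - m2).mean(axis=1))
    counts, _ = np.histogram(abs_mean_diff, bins=DIFFERENCE_BIN_EDGES)
    pct = counts / abs_mean_diff.size * 100.0
    return DifferenceDistribution(
        bin_edges=DIFFERENCE_BIN_EDGES.copy(), percentages=pct, n_sites=abs_mean_diff.size
    )


def ba_density_grid(
    pts: BlandAltmanPoints,
    n_bins_x: int = 200,
    n_bins_d: int = 200,
    d_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D histogram of (x, d) for shaded Bland-Altman plotting.

    Returns (counts, x_edges, d_edges); counts sum to n_points.
    """
    if n_bins_x < 2 or n_bins_d < 2:
        raise ValueError("need at least 2 bins per axis")
    if d_range is None:
        m = float(np.max(np.abs(pts.d))) or 1e-12
        d_range = (-m, m)
    counts, x_edges, d_edges = np.histogram2d(
        pts.x, pts.d, bins=[n_bins_x, n_bins_d], range=[(0.0, 1.0), d_range]
    )
    return counts, x_edges, d_edges
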