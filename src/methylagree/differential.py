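"""Global, per-CpG and regional differential-methylation testing between
paired extraction methods.

* Global: paired t-test on per-subject genome-wide mean betas.
* Per CpG: paired t-tests across subjects with Benjamini-Hochberg FDR.
* Regional: a bump-hunting search — sites are grouped into genomic clusters
  (new cluster when the gap to the previous site exceeds ``max_gap``), the
  per-site mean paired difference is loess-smoothed within each cluster,
  candidate regions are maximal same-sign runs with |smoothed effect| at or
  above a cutoff, and region-level family-wise error rates come from a
  sign-flip bootstrap of the per-subject difference vectors (exchangeable
  under the paired null), using the genome-wide maximum null area.

The bump hunting here is a deliberately simplified variant of the
Bumphunter-style approach: the two-group paired design makes subject-level
sign flips the natural null, in place of a linear-model residual bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io_model import BetaDataset

__all__ = [
    "PairedTestResult",
    "ClusterParams",
    "BumpRegion",
    "global_paired_t",
    "per_site_paired_t",
    "bh_adjust",
    "make_clusters",
    "find_bumps",
    "directional_summary",
    "paired_wilcoxon",
]


@dataclass
class PairedTestResult:
    site_id: str
    mean_diff: float
    t: float
    df: int
    p_raw: float
    p_bh: float = float("nan")


@dataclass
class ClusterParams:
    max_gap: int = 1000

    def __post_init__(self) -> None:
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")


@dataclass
class BumpRegion:
    cluster_id: int
    chrom: str
    start: int
    end: int
    n_sites: int
    area: float
    direction: str  # "hyper" (method1 > method2) or "hypo"
    fwer: float


def _paired_diffs(ds: BetaDataset, method1: str, method2: str) -> np.ndarray:
    subjects = ds.require_complete_design(method1, method2)
    m1 = ds.method_matrix(method1, subjects).to_numpy(dtype=float)
    m2 = ds.method_matrix(method2, subjects).to_numpy(dtype=float)
    if np.isnan(m1).any() or np.isnan(m2).any():
        raise ValueError("missing beta values; run filter_sites first")
    return m1 - m2  # sites x subjects


def _paired_t_from_diffs(diffs: np.ndarray) -> tuple[float, float, float, int]:
    """(mean, t, p, df) for one vector of paired differences.

    All-zero differences give t = 0, p = 1 (no evidence of a difference);
    zero variance around a non-zero mean leaves t undefined (NaN) with a
    warning.
    """
    n = diffs.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 subjects")
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 0.0, 1.0, df
        warnings.warn("zero-variance differences with non-zero mean: t undefined", RuntimeWarning)
        return mean, float("nan"), float("nan"), df
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return mean, float(t), float(p), df


def global_paired_t(ds: BetaDataset, method1: str, method2: str) -> PairedTestResult:
    """Paired t-test on per-subject global (genome-wide mean) methylation."""
    diffs = _paired_diffs(ds, method1, method2).mean(axis=0)
    mean, t, p, df = _paired_t_from_diffs(diffs)
    return PairedTestResult(site_id="global", mean_diff=mean, t=t, df=df, p_raw=p, p_bh=p)


def per_site_paired_t(ds: BetaDataset, method1: str, method2: str) -> pd.DataFrame:
    """One paired t-test per site, vectorised, with BH-adjusted p-values.

    Returns a DataFrame indexed by site_id with columns mean_diff, t, df,
    p_raw, p_bh. Sites whose differences have zero variance get NaN p-values
    and are excluded from the BH family (count logged via a warning).
    """
    d = _paired_diffs(ds, method1, method2)
    n = d.shape[1]
    if n < 2:
        raise ValueError("paired t-test needs at least 2 subjects")
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_var = sd == 0.0
    if zero_var.any():
        n_zero = int(zero_var.sum())
        warnings.warn(
            f"{n_zero} sites with zero-variance differences excluded from BH",
            RuntimeWarning,
        )
        t[zero_var] = np.nan
        p[zero_var] = np.nan
    out = pd.DataFrame(
        {
            "mean_diff": mean,
            "t": t,
            "df": df,
            "p_raw": p,
            "p_bh": bh_adjust(p),
        },
        index=ds.betas.index,
    )
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries are excluded from the family and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def make_clusters(sites: pd.DataFrame, params: ClusterParams | None = None) -> pd.Series:
    """Assign genomic cluster ids: a new cluster starts at each chromosome
    change or when the gap to the previous site exceeds ``max_gap`` (a gap
    of exactly max_gap stays in the same cluster).

    Returns integer ids aligned with the input index (input order preserved).
    """
    params = params or ClusterParams()
    order = sites.sort_values(["chrom", "pos"], kind="stable").index
    chrom = sites.loc[order, "chrom"].to_numpy()
    pos = sites.loc[order, "pos"].to_numpy()
    new = np.ones(len(order), dtype=bool)
    if len(order) > 1:
        same_chrom = chrom[1:] == chrom[:-1]
        close = (pos[1:] - pos[:-1]) <= params.max_gap
        new[1:] = ~(same_chrom & close)
    ids = np.cumsum(new) - 1
    return pd.Series(ids, index=order).loc[sites.index]


def _smoother_matrix(pos: np.ndarray, span: float) -> np.ndarray:
    """Linear smoother matrix S of lowess at the input positions, so that
    smoothing any response y is S @ y.

    With zero robustness iterations lowess is linear in y, so S is obtained
    by smoothing the canonical unit vectors.
    """
    k = pos.size
    S = np.empty((k, k))
    e = np.zeros(k)
    for j in range(k):
        e[j] = 1.0
        S[:, j] = lowess(e, pos.astype(float), frac=span, it=0, return_sorted=False)
        e[j] = 0.0
    return S


def _candidate_regions(
    smoothed: np.ndarray, cutoff: float
) -> list[tuple[int, int, float, int]]:
    """Maximal same-sign runs with |smoothed| >= cutoff within one cluster.

    Returns (start_idx, end_idx inclusive, area, sign) tuples.
    """
    sign = np.sign(smoothed) * (np.abs(smoothed) >= cutoff)
    regions = []
    i = 0
    k = sign.size
    while i < k:
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < k and sign[j + 1] == sign[i]:
            j += 1
        regions.append((i, j, float(np.sum(np.abs(smoothed[i : j + 1]))), int(sign[i])))
        i = j + 1
    return regions


def find_bumps(
    ds: BetaDataset,
    method1: str,
    method2: str,
    clusters: pd.Series | None = None,
    cutoff: float = 0.01,
    loess_span: float = 0.75,
    n_boot: int = 250,
    seed: int = 0,
    min_sites: int = 7,
    max_gap: int = 1000,
) -> list[BumpRegion]:
    """Bump-hunting search for differentially methylated regions.

    Per site the effect is the mean over subjects of (beta1 - beta2). Within
    clusters of at least ``min_sites`` sites the effects are loess-smoothed
    over genomic position (smaller clusters keep raw effects). Candidate
    regions are maximal same-sign runs with |smoothed effect| >= cutoff;
    a region's area is the sum of |smoothed effect| over its sites. The null
    distribution flips the sign of each subject's whole difference vector
    independently with probability 1/2 (``n_boot`` seeded draws); a region's
    FWER is the fraction of bootstrap draws whose genome-wide maximum null
    area reaches its observed area.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    d = _paired_diffs(ds, method1, method2)
    n_sites, n_subjects = d.shape
    if clusters is None:
        clusters = make_clusters(ds.sites, ClusterParams(max_gap=max_gap))
    clusters = clusters.loc[ds.sites.index]

    # order sites by (chrom, pos) within cluster once; everything downstream
    # works on this ordering
    order = ds.sites.sort_values(["chrom", "pos"], kind="stable").index
    d_ord = pd.DataFrame(d, index=ds.sites.index).loc[order].to_numpy()
    pos_ord = ds.sites.loc[order, "pos"].to_numpy()
    chrom_ord = ds.sites.loc[order, "chrom"].to_numpy()
    cl_ord = clusters.loc[order].to_numpy()

    cluster_slices: list[tuple[int, slice]] = []
    start = 0
    for i in range(1, n_sites + 1):
        if i == n_sites or cl_ord[i] != cl_ord[start]:
            cluster_slices.append((int(cl_ord[start]), slice(start, i)))
            start = i

    # Lowess with zero robustness iterations is linear in the response, so
    # for clusters smaller than the bootstrap count it pays to precompute the
    # k x k smoother matrix once (k lowess calls) and smooth every bootstrap
    # replicate by matrix multiply; large clusters call lowess directly.
    smoothers: dict[int, np.ndarray | str | None] = {}
    for cid, sl in cluster_slices:
        k = sl.stop - sl.start
        if k < min_sites:
            smoothers[cid] = None
        elif k > n_boot + 1:
            smoothers[cid] = "direct"
        else:
            try:
                S = _smoother_matrix(pos_ord[sl], loess_span)
                if not np.all(np.isfinite(S)):
                    raise FloatingPointError("non-finite smoother weights")
                smoothers[cid] = S
            except Exception as err:  # loess failure -> raw effects
                warnings.warn(
                    f"loess failed in cluster {cid} ({err}); using raw effects",
                    RuntimeWarning,
                )
                smoothers[cid] = None

    def _smooth(effect: np.ndarray) -> np.ndarray:
        out = np.empty_like(effect)
        for cid, sl in cluster_slices:
            S = smoothers[cid]
            if S is None:
                out[sl] = effect[sl]
            elif isinstance(S, str):
                try:
                    sm = lowess(
                        effect[sl], pos_ord[sl].astype(float),
                        frac=loess_span, it=0, return_sorted=False,
                    )
                    if not np.all(np.isfinite(sm)):
                        raise FloatingPointError("non-finite smoothed effects")
                    out[sl] = sm
                except Exception as err:
                    warnings.warn(
                        f"loess failed in cluster {cid} ({err}); using raw effects",
                        RuntimeWarning,
                    )
                    out[sl] = effect[sl]
            else:
                out[sl] = S @ effect[sl]
        return out

    effect = d_ord.mean(axis=1)
    smoothed = _smooth(effect)

    observed: list[BumpRegion] = []
    for cid, sl in cluster_slices:
        for i, j, area, sign in _candidate_regions(smoothed[sl], cutoff):
            lo, hi = sl.start + i, sl.start + j
            observed.append(
                BumpRegion(
                    cluster_id=cid,
                    chrom=str(chrom_ord[lo]),
                    start=int(pos_ord[lo]),
                    end=int(pos_ord[hi]),
                    n_sites=hi - lo + 1,
                    area=area,
                    direction="hyper" if sign > 0 else "hypo",
                    fwer=float("nan"),
                )
            )
    if not observed:
        return []

    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_boot, n_subjects))
    null_max = np.zeros(n_boot)
    for b in range(n_boot):
        eff_b = d_ord @ flips[b] / n_subjects
        sm_b = _smooth(eff_b)
        best = 0.0
        for cid, sl in cluster_slices:
            for _, _, area, _ in _candidate_regions(sm_b[sl], cutoff):
                if area > best:
                    best = area
        null_max[b] = best

    for r in observed:
        r.fwer = float(np.mean(null_max >= r.area))
    observed.sort(key=lambda r: (r.fwer, -r.area))
    return observed


def directional_summary(
    results: dict[tuple[str, str], pd.DataFrame],
    p_cutoffs: tuple[float, ...] = (0.002, 0.01),
    p_floor: float = 0.75,
) -> dict[str, pd.DataFrame]:
    """Directional tabulation of per-CpG test results across method pairs.

    ``results`` maps (method1, method2) to a per-site frame with columns
    mean_diff and p_raw (all pairs over the same site universe; typically
    the three pairwise combinations of three methods).

    Returns two tables:

    * ``sign``: per p-value group ("p<c" for each cutoff, plus "p>floor")
      and per pair, the percentage of that group's sites with method1 higher
      (``"X>Y"``), lower (``"X<Y"``) or tied (``"X=Y"``); rows sum to 100.
    * ``ranking``: per p-value group and method, the percentage of ranking
      labels of the form "X lowest"/"X highest" — X lowest requires the
      group's p-criterion to hold in BOTH comparisons involving X with X on
      the lower side in both. Sites can carry two labels (one lowest, one
      highest); percentages are over labels so each row sums to 100.
    """
    pairs = list(results.keys())
    methods_present = {m for pair in pairs for m in pair}
    if len(methods_present) == 3 and len(pairs) != 3:
        missing = [
            p for p in combinations(sorted(methods_present), 2)
            if p not in pairs and p[::-1] not in pairs
        ]
        raise ValueError(f"results missing for comparisons: {missing}")
    universes = [set(df.index) for df in results.values()]
    if not universes or any(u != universes[0] for u in universes):
        raise ValueError("all pairs must share the same site universe")
    index = next(iter(results.values())).index
    aligned = {pair: df.loc[index] for pair, df in results.items()}

    groups: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    for c in p_cutoffs:
        groups[f"p<{c:g}"] = {
            pair: (df["p_raw"].to_numpy() < c) for pair, df in aligned.items()
        }
    groups[f"p>{p_floor:g}"] = {
        pair: (df["p_raw"].to_numpy() > p_floor) for pair, df in aligned.items()
    }

    sign_rows = []
    for gname, masks in groups.items():
        for (m1, m2), mask in masks.items():
            sub = aligned[(m1, m2)].loc[mask, "mean_diff"].to_numpy()
            n = sub.size
            row = {"group": gname, "pair": f"{m1}vs{m2}", "n": n}
            if n:
                row[f"{m1}>{m2}"] = float(np.mean(sub > 0) * 100)
                row[f"{m1}<{m2}"] = float(np.mean(sub < 0) * 100)
                row[f"{m1}={m2}"] = float(np.mean(sub == 0) * 100)
            sign_rows.append(row)

    methods = sorted({m for pair in pairs for m in pair})
    rank_rows = []
    for gname, masks in groups.items():
        label_counts: dict[str, int] = {}
        for m in methods:
            involving = [pair for pair in pairs if m in pair]
            if len(involving) != 2:
                continue
            both = np.ones(len(index), dtype=bool)
            lower = np.ones(len(index), dtype=bool)
            higher = np.ones(len(index), dtype=bool)
            for pair in involving:
                both &= masks[pair]
                diff = aligned[pair]["mean_diff"].to_numpy()
                # diff = first - second; m lower means diff sign depends on slot
                m_minus_other = diff if pair[0] == m else -diff
                lower &= m_minus_other < 0
                higher &= m_minus_other > 0
            label_counts[f"{m} lowest"] = int(np.sum(both & lower))
            label_counts[f"{m} highest"] = int(np.sum(both & higher))
        total = sum(label_counts.values())
        row: dict[str, object] = {"group": gname, "n_labels": total}
        for lab, cnt in label_counts.items():
            row[lab] = float(cnt / total * 100) if total else float("nan")
        rank_rows.append(row)

    return {"sign": pd.DataFrame(sign_rows), "ranking": pd.DataFrame(rank_rows)}


def paired_wilcoxon(
    table: pd.DataFrame,
    samples: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank tests of per-sample statistics between
    methods, Bonferroni-corrected over all (statistic, pair) tests.

    ``table`` is samples x statistics (e.g. externally predicted ages or
    cell-type fractions) indexed by sample_id; ``samples`` is the matching
    sample sheet. Returns one row per (statistic, pair).
    """
    methods = list(pd.unique(samples["method"]))
    if pairs is None:
        pairs = list(combinations(methods, 2))
    rows = []
    for stat_name in table.columns:
        for m1, m2 in pairs:
            s1 = samples[samples["method"] == m1].reset_index().set_index("subject_id")
            s2 = samples[samples["method"] == m2].reset_index().set_index("subject_id")
            subjects = [s for s in s1.index if s in s2.index]
            v1 = table.loc[s1.loc[subjects, "sample_id"], stat_name].to_numpy(dtype=float)
            v2 = table.loc[s2.loc[subjects, "sample_id"], stat_name].to_numpy(dtype=float)
            diff = v1 - v2
            if np.all(diff == 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.wilcoxon(v1, v2)
            rows.append(
                {
                    "statistic_name": stat_name,
                    "pair": f"{m1}vs{m2}",
                    "n_subjects": len(subjects),
                    "statistic": float(stat),
                    "p_raw": float(p),
                }
            )
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * m)
    return out
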