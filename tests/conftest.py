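"""Shared fixtures and small dataset builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methylagree import BetaDataset, SimulationParams, simulate
from methylagree.synthetic import default_annotation


def make_dataset(
    betas_by_method: dict[str, np.ndarray],
    chrom: list[str] | str = "chr1",
    pos: list[int] | None = None,
    context: list[str] | str = "cpg",
    subjects: list[str] | None = None,
) -> BetaDataset:
    """Build a small BetaDataset from per-method (sites x subjects) arrays."""
    first = next(iter(betas_by_method.values()))
    n_sites, n_subjects = np.atleast_2d(first).shape
    if subjects is None:
        subjects = [f"S{j + 1:02d}" for j in range(n_subjects)]
    site_ids = [f"cg{i:08d}" for i in range(n_sites)]
    if pos is None:
        pos = list(range(1, 1 + 500 * n_sites, 500))
    sites = pd.DataFrame(
        {
            "chrom": chrom if isinstance(chrom, list) else [chrom] * n_sites,
            "pos": pos,
            "context": context if isinstance(context, list) else [context] * n_sites,
        },
        index=pd.Index(site_ids, name="site_id"),
    )
    cols = {}
    rows = []
    k = 0
    for method, mat in betas_by_method.items():
        mat = np.atleast_2d(np.asarray(mat, dtype=float))
        for j, subj in enumerate(subjects):
            sid = f"{subj}_{method}"
            cols[sid] = mat[:, j]
            rows.append(
                {
                    "sample_id": sid,
                    "subject_id": subj,
                    "method": method,
                    "chip_position": f"R{(k % 6) + 1:02d}C01",
                    "yield_ug": 10.0 + k,
                    "a260_280": 1.95,
                    "a260_230": 2.0 + 0.01 * k,
                }
            )
            k += 1
    betas = pd.DataFrame(cols, index=sites.index)
    samples = pd.DataFrame(rows).set_index("sample_id")
    return BetaDataset(betas=betas, sites=sites, samples=samples)


def clustered_annotation(n_clusters: int, sites_per_cluster: int) -> pd.DataFrame:
    """Annotation with well-separated clusters (within: 500 bp, between: 50 kb)."""
    n = n_clusters * sites_per_cluster
    ann = default_annotation(n)
    pos = []
    for c in range(n_clusters):
        pos.extend(c * 50_000 + i * 500 + 1 for i in range(sites_per_cluster))
    return ann.assign(pos=pos)


@pytest.fixture(scope="session")
def sim_pair():
    """A moderately sized null three-method simulation (shared, read-only)."""
    ds, truth = simulate(SimulationParams(n_sites=2000, seed=42))
    return ds, truth


@pytest.fixture(scope="session")
def sim_ds(sim_pair):
    return sim_pair[0]
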