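"""Synthetic paired multi-method methylation datasets.

The generator emulates the statistical structure the agreement analysis
assumes for whole-blood 450K-style beta values:

* a bimodal-to-trimodal marginal distribution of site-level methylation
  (mixture of mostly-unmethylated, intermediate and mostly-methylated
  components);
* per-subject biological variation around each site mean (normal on the
  logit scale), substantially larger than technical method variation;
* zero-mean per-method technical noise whose pairwise-difference standard
  deviation follows sigma(x) = exp(a + b*(x - 0.5)^2), largest at
  intermediate methylation when b < 0;
* optional global per-method offsets and injected method-effect regions
  (contiguous genomic windows where one method is shifted by a delta).

Each measurement gets independent noise with SD sigma(x)/sqrt(2) so that the
difference between any two methods has SD sigma(x).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import BetaDataset, write_beta_dataset

__all__ = [
    "MixtureComponent",
    "InjectedRegion",
    "SimulationParams",
    "SimulatedTruth",
    "simulate_truth",
    "simulate_dataset",
    "simulate",
    "sigma",
    "default_annotation",
    "write_simulation",
]

_EPS = 1e-6


def sigma(x: np.ndarray | float, a: float, b: float) -> np.ndarray | float:
    """Difference SD as a function of mean methylation: exp(a + b*(x-0.5)^2)."""
    return np.exp(a + b * (np.asarray(x, dtype=float) - 0.5) ** 2)


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    alpha: float
    beta: float


@dataclass(frozen=True)
class InjectedRegion:
    """A genomic window where one method's measurements are shifted by delta."""

    chrom: str
    start: int
    end: int
    affected_method: str
    delta: float


@dataclass
class SimulationParams:
    """Generative settings for a paired multi-method beta dataset.

    Defaults mirror the paired whole-blood study design the analysis targets:
    10 subjects, three extraction methods (M = magnetic beads, A =
    salting-out/isopropanol, O = organic), site-level methylation drawn from
    a low/mid/high beta mixture, between-subject logit-scale SD 0.5, and the
    variance-function constants a = -3, b = -4 (difference SD about 0.05 at
    x = 0.5 falling to about 0.018 at the boundaries).
    """

    n_subjects: int = 10
    n_sites: int = 10_000
    methods: tuple[str, ...] = ("M", "A", "O")
    mixture: tuple[MixtureComponent, MixtureComponent, MixtureComponent] = (
        MixtureComponent(0.40, 2.0, 18.0),   # mostly unmethylated
        MixtureComponent(0.15, 6.0, 6.0),    # intermediate
        MixtureComponent(0.45, 18.0, 2.0),   # mostly methylated
    )
    subject_sd: float = 0.5
    noise_a: float = -3.0
    noise_b: float = -4.0
    method_bias: dict[str, float] = field(default_factory=dict)
    injected_regions: tuple[InjectedRegion, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        w = np.array([c.weight for c in self.mixture], dtype=float)
        if np.isnan(w).any():
            raise ValueError("mixture weight is NaN")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError(f"mixture weights must sum to 1 (got {w.sum()})")
        for r in self.injected_regions:
            if r.affected_method not in self.methods:
                raise ValueError(
                    f"injected region targets unknown method {r.affected_method!r}"
                )
        self.injected_regions = tuple(self.injected_regions)
        self.methods = tuple(self.methods)


@dataclass
class SimulatedTruth:
    """Latent per-subject methylation plus site annotation and region masks."""

    true_methylation: np.ndarray  # sites x subjects, values in [0, 1]
    annotation: pd.DataFrame      # indexed by site_id: chrom, pos, context
    region_mask: pd.DataFrame     # sites x injected regions (bool)


def default_annotation(n_sites: int, chrom: str = "chr1", spacing: int = 500) -> pd.DataFrame:
    """Evenly spaced sites on one chromosome; 500-bp spacing keeps adjacent
    sites within a 1000-bp clustering gap."""
    ids = [f"cg{i:08d}" for i in range(n_sites)]
    ann = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(n_sites, dtype=int) * spacing + 1,
            "context": "cpg",
        },
        index=pd.Index(ids, name="site_id"),
    )
    return ann


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return np.log(p / (1.0 - p))


def _expit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def simulate_truth(
    params: SimulationParams, annotation: pd.DataFrame | None = None
) -> SimulatedTruth:
    """Draw latent per-subject methylation.

    Per site a mixture component is chosen and a site mean drawn from its
    beta distribution; per subject the value is the site mean perturbed by
    N(0, subject_sd) on the logit scale. Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng((params.seed, 0))
    if annotation is None:
        annotation = default_annotation(params.n_sites)
    if len(annotation) != params.n_sites:
        raise ValueError("annotation length must equal n_sites")

    weights = np.array([c.weight for c in params.mixture], dtype=float)
    comp = rng.choice(len(params.mixture), size=params.n_sites, p=weights)
    site_mean = np.empty(params.n_sites)
    for k, c in enumerate(params.mixture):
        idx = comp == k
        site_mean[idx] = rng.beta(c.alpha, c.beta, size=int(idx.sum()))

    if params.subject_sd == 0.0:
        truth = np.repeat(site_mean[:, None], params.n_subjects, axis=1)
    else:
        z = _logit(site_mean)[:, None] + rng.normal(
            0.0, params.subject_sd, size=(params.n_sites, params.n_subjects)
        )
        truth = _expit(z)

    mask = pd.DataFrame(index=annotation.index)
    for i, r in enumerate(params.injected_regions):
        mask[f"region_{i}"] = (
            (annotation["chrom"] == r.chrom)
            & (annotation["pos"] >= r.start)
            & (annotation["pos"] <= r.end)
        ).to_numpy()
    return SimulatedTruth(true_methylation=truth, annotation=annotation, region_mask=mask)


def _metadata_for(method: str, rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Plausible per-sample yield and purity metadata, with method-specific
    tendencies (the salting-out method yields less DNA and lower A260/230)."""
    ranges = {
        # (yield lo, hi), (260/280 mu, sd), (260/230 mu, sd)
        "default": ((8.0, 30.0), (1.94, 0.03), (2.10, 0.15)),
        "A": ((2.0, 19.0), (1.92, 0.03), (1.45, 0.30)),
        "O": ((8.0, 36.0), (1.92, 0.02), (2.35, 0.10)),
    }
    (ylo, yhi), (r1m, r1s), (r2m, r2s) = ranges.get(method, ranges["default"])
    return pd.DataFrame(
        {
            "yield_ug": np.round(rng.uniform(ylo, yhi, n), 1),
            "a260_280": np.round(rng.normal(r1m, r1s, n), 2),
            "a260_230": np.round(np.abs(rng.normal(r2m, r2s, n)), 2),
        }
    )


def simulate_dataset(
    params: SimulationParams,
    truth: SimulatedTruth,
) -> BetaDataset:
    """Measured betas for every subject x method.

    measured = clip(true + method bias + region delta + eps, 0, 1) with
    eps ~ N(0, sigma(true)/sqrt(2)) independent per measurement, so the
    difference of two methods has SD sigma(true). Deterministic given
    ``params.seed``.
    """
    rng = np.random.default_rng((params.seed, 1))
    n_sites, n_subjects = truth.true_methylation.shape
    if n_sites != params.n_sites or n_subjects != params.n_subjects:
        raise ValueError("truth dimensions do not match params")

    sd = sigma(truth.true_methylation, params.noise_a, params.noise_b) / np.sqrt(2.0)

    subjects = [f"S{j + 1:02d}" for j in range(n_subjects)]
    columns: dict[str, np.ndarray] = {}
    rows = []
    chip_positions = [f"R{r:02d}C{c:02d}" for c in (1, 2) for r in range(1, 7)]
    k = 0
    for method in params.methods:
        eps = rng.normal(0.0, 1.0, size=truth.true_methylation.shape) * sd
        mat = truth.true_methylation + params.method_bias.get(method, 0.0) + eps
        for i, r in enumerate(params.injected_regions):
            if r.affected_method == method and truth.region_mask.shape[1] > i:
                in_region = truth.region_mask[f"region_{i}"].to_numpy()
                mat[in_region, :] += r.delta
        mat = np.clip(mat, 0.0, 1.0)
        meta = _metadata_for(method, rng, n_subjects)
        for j, subj in enumerate(subjects):
            sid = f"{subj}_{method}"
            columns[sid] = mat[:, j]
            rows.append(
                {
                    "sample_id": sid,
                    "subject_id": subj,
                    "method": method,
                    "chip_position": chip_positions[k % len(chip_positions)],
                    **meta.iloc[j].to_dict(),
                }
            )
            k += 1

    betas = pd.DataFrame(columns, index=truth.annotation.index)
    samples = pd.DataFrame(rows).set_index("sample_id")
    return BetaDataset(betas=betas, sites=truth.annotation.copy(), samples=samples)


def simulate(params: SimulationParams, annotation: pd.DataFrame | None = None) -> tuple[BetaDataset, SimulatedTruth]:
    """Convenience wrapper: draw truth, then measurements."""
    truth = simulate_truth(params, annotation)
    return simulate_dataset(params, truth), truth


def write_simulation(
    params: SimulationParams, out_dir: str | Path, annotation: pd.DataFrame | None = None
) -> dict[str, Path]:
    """Write beta/annotation/sample-sheet TSVs plus the latent truth and the
    parameters used."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, truth = simulate(params, annotation)
    paths = write_beta_dataset(ds, out, prefix="simulated")
    truth_df = pd.DataFrame(
        truth.true_methylation,
        index=truth.annotation.index,
        columns=[f"S{j + 1:02d}" for j in range(params.n_subjects)],
    )
    paths["truth"] = out / "simulated_truth.tsv"
    truth_df.to_csv(paths["truth"], sep="\t", index_label="site_id", float_format="%.17g")
    paths["params"] = out / "simulated_params.json"
    payload = {
        "n_subjects": params.n_subjects,
        "n_sites": params.n_sites,
        "methods": list(params.methods),
        "mixture": [
            {"weight": c.weight, "alpha": c.alpha, "beta": c.beta} for c in params.mixture
        ],
        "subject_sd": params.subject_sd,
        "noise_a": params.noise_a,
        "noise_b": params.noise_b,
        "method_bias": params.method_bias,
        "injected_regions": [vars(r) for r in params.injected_regions],
        "seed": params.seed,
    }
    paths["params"].write_text(json.dumps(payload, indent=2) + "\n")
    return paths
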